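"""Error measures and aggregation tables against hand-computed values
and brute-force recomputation."""

import numpy as np
import pandas as pd
import pytest

from limbaug.datamodel import MarkerSequence
from limbaug.kinematics import AXES, JOINTS, SIDES, JointAngleSeries
from limbaug.metrics import (
    ErrorRecord,
    aggregate_table,
    angle_rmsd,
    landmark_errors,
    records_from_angles,
    records_from_positions,
)


def _seq(positions, names=("A", "B")):
    return MarkerSequence(names, positions, 30.0, "gait")


class TestLandmarkErrors:
    def test_identical_series_give_zero(self, rng):
        pos = rng.normal(size=(4, 2, 3))
        means, mat = landmark_errors(_seq(pos), _seq(pos.copy()))
        assert (means == 0).all() and (mat == 0).all()

    def test_constant_offset_one_landmark(self):
        truth = np.zeros((5, 2, 3))
        pred = truth.copy()
        pred[:, 1, 0] += 0.01  # 1 cm along X on landmark B
        means, _ = landmark_errors(_seq(pred), _seq(truth))
        assert means["A"] == 0.0
        assert np.isclose(means["B"], 1.0, atol=1e-12)

    def test_two_frame_hand_arithmetic(self):
        truth = np.zeros((2, 1, 3))
        pred = truth.copy()
        pred[0, 0, 0] = 0.03  # 3 cm
        pred[1, 0, 1] = 0.04  # 4 cm
        means, mat = landmark_errors(_seq(pred, ("A",)),
                                     _seq(truth, ("A",)))
        assert np.allclose(mat[:, 0], [3.0, 4.0], atol=1e-12)
        assert np.isclose(means["A"], 3.5, atol=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=(2, 3, 2, 3))
        m1, _ = landmark_errors(_seq(a), _seq(b))
        m2, _ = landmark_errors(_seq(b), _seq(a))
        pd.testing.assert_series_equal(m1, m2)

    def test_name_mismatch_rejected(self, rng):
        pos = rng.normal(size=(2, 2, 3))
        with pytest.raises(ValueError, match="mismatch"):
            landmark_errors(_seq(pos), _seq(pos, names=("A", "C")))


def _angles(arr):
    return JointAngleSeries(arr, 30.0, "gait")


class TestAngleRmsd:
    def test_identical_series_zero(self, rng):
        arr = rng.normal(size=(6, 3, 3, 2))
        assert (angle_rmsd(_angles(arr), _angles(arr.copy())) == 0).all()

    def test_hand_arithmetic(self):
        truth = np.zeros((2, 3, 3, 2))
        pred = truth.copy()
        pred[0, 0, 0, 0] = 3.0
        pred[1, 0, 0, 0] = 4.0
        rmsd = angle_rmsd(_angles(pred), _angles(truth))
        assert np.isclose(rmsd[("hip", "FE", "L")], np.sqrt(12.5),
                          atol=1e-12)
        assert rmsd.drop(("hip", "FE", "L")).eq(0).all()

    def test_constant_bias_gives_absolute_bias(self, rng):
        truth = rng.normal(size=(8, 3, 3, 2))
        pred = truth - 7.5
        rmsd = angle_rmsd(_angles(pred), _angles(truth))
        assert np.allclose(rmsd.to_numpy(), 7.5, atol=1e-9)

    def test_jensen_ordering(self, rng):
        truth = rng.normal(size=(30, 3, 3, 2))
        pred = truth + rng.normal(size=truth.shape)
        rmsd = angle_rmsd(_angles(pred), _angles(truth))
        mae = np.abs(pred - truth).mean(axis=0)
        for (j, a, s), v in rmsd.items():
            assert v >= mae[JOINTS.index(j), AXES.index(a),
                            SIDES.index(s)] - 1e-12
            assert v >= 0


def _random_records(rng, n=1000):
    models = ["mlp", "lstm", "transformer"]
    movements = ["gait", "running", "squats"]
    landmarks = ["L-ASIS", "R-ASIS", "SACR", "L-LM"]
    out = []
    for i in range(n):
        out.append(ErrorRecord(
            subject_id=f"S{rng.integers(8):02d}",
            model=models[rng.integers(3)],
            movement=movements[rng.integers(3)],
            kind="position",
            landmark=landmarks[rng.integers(4)],
            value=float(rng.gamma(2.0, 1.0)),
        ))
    return out


class TestAggregation:
    def test_single_record(self):
        rec = ErrorRecord(subject_id="s", model="mlp", movement="gait",
                          kind="position", landmark="SACR", value=1.3)
        table = aggregate_table([rec], rows="landmark", cols="movement")
        assert table.loc["SACR", "gait"] == 1.3
        assert table.loc["Across", "Across"] == 1.3

    def test_cell_mean_over_subjects(self):
        recs = [
            ErrorRecord(subject_id=s, model="mlp", movement="gait",
                        kind="position", landmark="SACR", value=v)
            for s, v in (("a", 1.0), ("b", 3.0))
        ]
        table = aggregate_table(recs, rows="landmark", cols="movement")
        assert table.loc["SACR", "gait"] == 2.0

    def test_margins_are_record_means(self, rng):
        records = _random_records(rng)
        table = aggregate_table(records, rows="landmark", cols="movement")
        # brute-force recomputation from the raw records
        for lm in {r.landmark for r in records}:
            vals = [r.value for r in records if r.landmark == lm]
            assert np.isclose(table.loc[lm, "Across"], np.mean(vals))
        for mv in {r.movement for r in records}:
            vals = [r.value for r in records if r.movement == mv]
            assert np.isclose(table.loc["Across", mv], np.mean(vals))
        assert np.isclose(table.loc["Across", "Across"],
                          np.mean([r.value for r in records]))

    def test_balanced_margin_equals_mean_of_cells(self):
        recs = []
        for lm in ("A", "B"):
            for mv in ("gait", "squats"):
                for s, v in (("x", 1.0), ("y", 2.0)):
                    recs.append(ErrorRecord(
                        subject_id=s, model="m", movement=mv,
                        kind="position", landmark=lm,
                        value=v + (lm == "B") + 2 * (mv == "squats")))
        table = aggregate_table(recs, rows="landmark", cols="movement")
        inner = table.drop("Across").drop(columns="Across")
        assert np.isclose(table.loc["Across", "Across"],
                          inner.to_numpy().mean())

    def test_permutation_invariance(self, rng):
        records = _random_records(rng, n=200)
        t1 = aggregate_table(records, rows="model", cols="movement")
        shuffled = [records[i] for i in rng.permutation(len(records))]
        t2 = aggregate_table(shuffled, rows="model", cols="movement")
        pd.testing.assert_frame_equal(t1, t2)

    def test_mixed_kinds_rejected(self, rng):
        recs = _random_records(rng, n=5)
        recs.append(ErrorRecord(subject_id="s", model="mlp",
                                movement="gait", kind="angle", value=1.0,
                                joint="hip", axis="FE", side="L"))
        with pytest.raises(ValueError, match="mix"):
            aggregate_table(recs, rows="model", cols="movement")


class TestRecordBuilders:
    def test_one_record_per_landmark(self, gait_trial, profile):
        from limbaug.preprocess import substitute_sacr
        truth = substitute_sacr(gait_trial.landmarks)
        pred = truth.with_positions(truth.positions + 0.01)
        recs = records_from_positions(pred, truth, "S000", "mlp")
        assert len(recs) == 17
        assert {r.movement for r in recs} == {"gait"}
        assert all(r.value >= 0 for r in recs)

    def test_one_record_per_joint_axis_side(self, gait_trial):
        truth = gait_trial.true_angles
        pred = JointAngleSeries(truth.angles + 2.0, truth.fps,
                                truth.movement)
        recs = records_from_angles(pred, truth, "S000", "lstm")
        assert len(recs) == 18
        assert all(np.isclose(r.value, 2.0) for r in recs)

    def test_record_key_families_enforced(self):
        with pytest.raises(ValueError, match="landmark"):
            ErrorRecord(subject_id="s", model="m", movement="gait",
                        kind="position", value=1.0)
        with pytest.raises(ValueError, match="joint"):
            ErrorRecord(subject_id="s", model="m", movement="gait",
                        kind="angle", value=1.0, joint="hip")
        with pytest.raises(ValueError, match="non-negative"):
            ErrorRecord(subject_id="s", model="m", movement="gait",
                        kind="position", landmark="SACR", value=-0.1)
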
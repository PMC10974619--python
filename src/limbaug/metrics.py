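"""Error measures and factor-wise aggregation tables.

Two error families mirror the evaluation design:

* **position** — per-landmark Euclidean distance between predicted and
  reference landmark trajectories, averaged over the movement sequence,
  reported in centimeters;
* **angle** — root-mean-square deviation (RMSD) between predicted and
  reference joint-angle series, per (joint, axis, side), in degrees.

Each trial contributes one :class:`ErrorRecord` per landmark (or per
joint-axis-side), the unit of analysis of the mixed-model stage.
Aggregation tables collapse records over factors with trailing "Across"
margins computed from the raw records (not from cell means), so unbalanced
cells are weighted by their record counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import MarkerSequence
from .kinematics import AXES, JOINTS, SIDES, JointAngleSeries

__all__ = [
    "ErrorRecord",
    "landmark_errors",
    "angle_rmsd",
    "records_from_positions",
    "records_from_angles",
    "records_to_frame",
    "aggregate_table",
]


@dataclass(frozen=True)
class ErrorRecord:
    """One error observation.

    ``kind`` is "position" (value in cm, keyed by ``landmark``) or "angle"
    (value in degrees RMSD, keyed by ``joint``/``axis``/``side``).
    """

    subject_id: str
    model: str
    movement: str
    kind: str
    value: float
    landmark: Optional[str] = None
    joint: Optional[str] = None
    axis: Optional[str] = None
    side: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("position", "angle"):
            raise ValueError(f"kind must be 'position' or 'angle', "
                             f"got {self.kind!r}")
        if self.value < 0:
            raise ValueError("error value must be non-negative")
        if self.kind == "position":
            if self.landmark is None or self.joint is not None:
                raise ValueError(
                    "position records carry a landmark key only")
        else:
            if self.landmark is not None or None in (self.joint, self.axis,
                                                     self.side):
                raise ValueError(
                    "angle records carry joint/axis/side keys only")


def landmark_errors(pred: MarkerSequence, truth: MarkerSequence
                    ) -> Tuple[pd.Series, np.ndarray]:
    """Per-landmark mean Euclidean distance (cm) and the per-frame matrix.

    Returns ``(means, distances)`` where ``means`` is indexed by landmark
    name and ``distances`` has shape (T, P), both in centimeters.
    """
    if pred.point_names != tuple(truth.point_names):
        raise ValueError(
            "landmark name mismatch: "
            f"{pred.point_names} vs {truth.point_names}")
    if pred.n_frames != truth.n_frames:
        raise ValueError(
            f"frame count mismatch: {pred.n_frames} vs {truth.n_frames}")
    dist_cm = np.linalg.norm(pred.positions - truth.positions,
                             axis=-1) * 100.0
    means = pd.Series(dist_cm.mean(axis=0), index=list(pred.point_names),
                      name="mean_distance_cm")
    return means, dist_cm


def angle_rmsd(pred: JointAngleSeries, truth: JointAngleSeries) -> pd.Series:
    """Per-(joint, axis, side) RMSD in degrees."""
    if pred.n_frames != truth.n_frames:
        raise ValueError(
            f"frame count mismatch: {pred.n_frames} vs {truth.n_frames}")
    sq = (pred.angles - truth.angles) ** 2
    rmsd = np.sqrt(sq.mean(axis=0))
    index = pd.MultiIndex.from_product(
        [JOINTS, AXES, SIDES], names=["joint", "axis", "side"])
    values = [rmsd[JOINTS.index(j), AXES.index(a), SIDES.index(s)]
              for j, a, s in index]
    return pd.Series(values, index=index, name="rmsd_deg")


def records_from_positions(pred: MarkerSequence, truth: MarkerSequence,
                           subject_id: str, model: str,
                           movement: Optional[str] = None
                           ) -> List[ErrorRecord]:
    """One position record per landmark for a predicted trial."""
    means, _ = landmark_errors(pred, truth)
    movement = movement if movement is not None else truth.movement
    return [
        ErrorRecord(subject_id=subject_id, model=model, movement=movement,
                    kind="position", landmark=name, value=float(v))
        for name, v in means.items()
    ]


def records_from_angles(pred: JointAngleSeries, truth: JointAngleSeries,
                        subject_id: str, model: str,
                        movement: Optional[str] = None) -> List[ErrorRecord]:
    """One angle record per (joint, axis, side) for a predicted trial."""
    rmsd = angle_rmsd(pred, truth)
    movement = movement if movement is not None else truth.movement
    return [
        ErrorRecord(subject_id=subject_id, model=model, movement=movement,
                    kind="angle", joint=j, axis=a, side=s, value=float(v))
        for (j, a, s), v in rmsd.items()
    ]


def records_to_frame(records: Iterable[ErrorRecord]) -> pd.DataFrame:
    """Flat table of error records (one row per observation)."""
    rows = []
    for r in records:
        rows.append({
            "subject": r.subject_id, "model": r.model,
            "movement": r.movement, "kind": r.kind, "value": r.value,
            "landmark": r.landmark, "joint": r.joint, "axis": r.axis,
            "side": r.side,
        })
    return pd.DataFrame(rows)


_FACTORS = ("model", "movement", "landmark", "joint", "axis", "side",
            "subject")


def aggregate_table(records: Sequence[ErrorRecord], rows: str, cols: str
                    ) -> pd.DataFrame:
    """Mean error per (rows x cols) factor cell with "Across" margins.

    Cells average all underlying records (collapsing subjects and any
    factors not shown); margins are means of the raw records, so when cell
    counts differ the margin is the record-weighted mean, not the mean of
    cell means.  Empty cells are NaN.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    kinds = {r.kind for r in records}
    if len(kinds) != 1:
        raise ValueError(f"records mix kinds: {sorted(kinds)}")
    for factor in (rows, cols):
        if factor not in _FACTORS:
            raise ValueError(f"unknown factor {factor!r}")
    df = records_to_frame(records)
    if df[rows].isna().any() or df[cols].isna().any():
        raise ValueError(
            f"records lack values for factor {rows!r} or {cols!r}")
    table = df.pivot_table(index=rows, columns=cols, values="value",
                           aggfunc="mean")
    table["Across"] = df.groupby(rows)["value"].mean()
    margin = df.groupby(cols)["value"].mean()
    margin["Across"] = df["value"].mean()
    table.loc["Across"] = margin
    table.index.name = rows
    table.columns.name = cols
    return table
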
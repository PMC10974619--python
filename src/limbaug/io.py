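"""Readers and writers for marker trajectories and subject profiles.

Two on-disk dialects are supported for trajectories:

* **TRC** — the tab-delimited marker format common to biomechanics
  toolchains (5-line header: file line, field-name line, value line,
  marker-name line, axis-suffix line).  Written in millimeters with
  ``Units	mm``; values are converted to meters on load.
* **wide CSV** — columns ``Frame, Time`` followed by ``<name>_X, <name>_Y,
  <name>_Z`` per point, in meters.

Axis conventions: files are assumed to use the canonical Y-up convention.
Pass ``axes="z-up"`` to rotate a Z-up file (X anterior, Z vertical) into the
canonical frame on load; writing with ``axes="z-up"`` applies the inverse,
so an import/export cycle is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datamodel import AnthropometricProfile, MarkerSequence

__all__ = [
    "read_markers",
    "write_markers",
    "read_profile",
    "write_profile",
    "MarkerParseError",
]

PathLike = Union[str, Path]

_UNIT_TO_M = {"mm": 1e-3, "cm": 1e-2, "m": 1.0}

# Rotation taking Z-up coordinates to canonical Y-up: (x, y, z) -> (x, z, -y)
_ZUP_TO_YUP = np.array([[1.0, 0.0, 0.0],
                        [0.0, 0.0, 1.0],
                        [0.0, -1.0, 0.0]])


class MarkerParseError(ValueError):
    """A marker file does not conform to its declared dialect."""


def _axes_matrix(axes: str) -> np.ndarray:
    if axes == "y-up":
        return np.eye(3)
    if axes == "z-up":
        return _ZUP_TO_YUP
    raise ValueError(f"unknown axis convention {axes!r} (use 'y-up'/'z-up')")


def read_markers(path: PathLike, format: str = None, *,
                 axes: str = "y-up") -> MarkerSequence:
    """Read a TRC or wide-CSV trajectory file into a :class:`MarkerSequence`.

    ``format`` defaults to the file extension ('trc' or 'csv').
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "trc":
        seq = _read_trc(path)
    elif fmt == "csv":
        seq = _read_csv(path)
    else:
        raise ValueError(f"unknown marker format {fmt!r}")
    R = _axes_matrix(axes)
    if not np.allclose(R, np.eye(3)):
        seq = seq.with_positions(seq.positions @ R.T)
    return seq


def write_markers(seq: MarkerSequence, path: PathLike, format: str = None, *,
                  axes: str = "y-up") -> None:
    """Write a :class:`MarkerSequence`; TRC in millimeters, CSV in meters."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    R = _axes_matrix(axes)
    if not np.allclose(R, np.eye(3)):
        seq = seq.with_positions(seq.positions @ R)  # inverse rotation
    if fmt == "trc":
        _write_trc(seq, path)
    elif fmt == "csv":
        _write_csv(seq, path)
    else:
        raise ValueError(f"unknown marker format {fmt!r}")


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def _read_trc(path: Path) -> MarkerSequence:
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise MarkerParseError(f"{path}: TRC file has fewer than 6 lines")
    header_names = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    meta = dict(zip(header_names, header_vals))
    for key in ("DataRate", "NumFrames", "NumMarkers", "Units"):
        if key not in meta:
            raise MarkerParseError(
                f"{path}: TRC header line 2 missing field {key!r}: "
                f"{lines[1]!r}"
            )
    try:
        fps = float(meta["DataRate"])
        n_frames = int(meta["NumFrames"])
        n_markers = int(meta["NumMarkers"])
    except ValueError as exc:
        raise MarkerParseError(
            f"{path}: malformed TRC header value line: {lines[2]!r}"
        ) from exc
    units = meta["Units"].strip()
    if units not in _UNIT_TO_M:
        raise MarkerParseError(f"{path}: unknown units {units!r}")
    scale = _UNIT_TO_M[units]

    name_fields = lines[3].rstrip("\t\n").split("\t")
    names = [n for n in name_fields[2:] if n.strip()]
    if len(names) != n_markers:
        raise MarkerParseError(
            f"{path}: header declares {n_markers} markers but name line "
            f"lists {len(names)}: {lines[3]!r}"
        )

    data_rows = []
    for lineno, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        fields = line.split("\t")
        expected = 2 + 3 * n_markers
        if len(fields) < expected:
            raise MarkerParseError(
                f"{path}: line {lineno} has {len(fields)} fields, "
                f"expected {expected}"
            )
        try:
            row = [float(f) for f in fields[2:expected]]
        except ValueError:
            raise MarkerParseError(
                f"{path}: line {lineno}: non-numeric coordinate"
            ) from None
        data_rows.append(row)
    if len(data_rows) != n_frames:
        raise MarkerParseError(
            f"{path}: header declares {n_frames} frames, found "
            f"{len(data_rows)} data rows"
        )
    pos = np.asarray(data_rows).reshape(n_frames, n_markers, 3) * scale
    if not np.all(np.isfinite(pos)):
        t, p, _ = np.argwhere(~np.isfinite(pos))[0]
        raise MarkerParseError(
            f"{path}: NaN coordinate at frame {t + 1}, marker {names[p]!r}"
        )
    return MarkerSequence(names, pos, fps)


def _write_trc(seq: MarkerSequence, path: Path) -> None:
    T, P = seq.n_frames, seq.n_points
    fps = seq.fps
    mm = seq.positions * 1000.0
    lines = []
    lines.append(f"PathFileType\t4\t(X/Y/Z)\t{path.name}")
    lines.append("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames")
    lines.append(f"{fps:g}\t{fps:g}\t{T}\t{P}\tmm\t{fps:g}\t1\t{T}")
    lines.append("Frame#\tTime\t" + "\t\t\t".join(seq.point_names) + "\t\t")
    suffixes = "\t".join(
        f"X{i}\tY{i}\tZ{i}" for i in range(1, P + 1)
    )
    lines.append("\t\t" + suffixes)
    for t in range(T):
        coords = "\t".join(f"{v:.8f}" for v in mm[t].ravel())
        lines.append(f"{t + 1}\t{t / fps:.6f}\t{coords}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# wide CSV
# ---------------------------------------------------------------------------

def _read_csv(path: Path) -> MarkerSequence:
    df = pd.read_csv(path)
    for col in ("Frame", "Time"):
        if col not in df.columns:
            raise MarkerParseError(f"{path}: missing column {col!r}")
    names = []
    for col in df.columns:
        if col.endswith("_X"):
            names.append(col[:-2])
    if not names:
        raise MarkerParseError(f"{path}: no <name>_X coordinate columns")
    cols = []
    for name in names:
        for ax in ("X", "Y", "Z"):
            col = f"{name}_{ax}"
            if col not in df.columns:
                raise MarkerParseError(f"{path}: missing column {col!r}")
            cols.append(col)
    pos = df[cols].to_numpy(dtype=float).reshape(len(df), len(names), 3)
    if np.isnan(pos).any():
        t, p, _ = np.argwhere(np.isnan(pos))[0]
        raise MarkerParseError(
            f"{path}: NaN coordinate at frame {t + 1}, marker {names[p]!r}"
        )
    times = df["Time"].to_numpy(dtype=float)
    if len(times) > 1:
        dt = np.median(np.diff(times))
        if dt <= 0:
            raise MarkerParseError(f"{path}: non-increasing Time column")
        fps = 1.0 / dt
    else:
        fps = 1.0
    return MarkerSequence(names, pos, fps)


def _write_csv(seq: MarkerSequence, path: Path) -> None:
    T = seq.n_frames
    data = {"Frame": np.arange(1, T + 1),
            "Time": np.arange(T) / seq.fps}
    for i, name in enumerate(seq.point_names):
        for j, ax in enumerate(("X", "Y", "Z")):
            data[f"{name}_{ax}"] = seq.positions[:, i, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

_SEX_CODES = {"female": 0, "male": 1, 0: 0, 1: 1, "0": 0, "1": 1}


def read_profile(path: PathLike) -> AnthropometricProfile:
    """Read a subject profile from JSON.

    Expected keys: ``subject_id``, ``sex`` ("female"/"male" or 0/1),
    ``height_m``, ``weight_kg``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("subject_id", "sex", "height_m", "weight_kg"):
        if key not in raw:
            raise ValueError(f"{path}: profile missing key {key!r}")
    sex = raw["sex"]
    sex_key = sex.lower() if isinstance(sex, str) else sex
    if sex_key not in _SEX_CODES:
        raise ValueError(f"{path}: unrecognized sex value {sex!r}")
    return AnthropometricProfile(
        subject_id=str(raw["subject_id"]),
        sex_code=_SEX_CODES[sex_key],
        height=float(raw["height_m"]),
        weight=float(raw["weight_kg"]),
    )


def write_profile(profile: AnthropometricProfile, path: PathLike) -> None:
    payload = {
        "subject_id": profile.subject_id,
        "sex": "male" if profile.sex_code == 1 else "female",
        "height_m": profile.height,
        "weight_kg": profile.weight,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
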
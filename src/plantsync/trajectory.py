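"""Trajectory containers, CSV round trip, and pseudo-dyad alignment.

A :class:`TrajectorySeries` is one plant's sampled 3D tendril-tip path:
x and z span the horizontal plane where circumnutation unfolds, y is the
vertical growth axis.  A :class:`DyadRecord` pairs a handler with a grasper
and is labelled ``real`` (grown and recorded together, hence simultaneous
acquisition) or ``pseudo`` (an artificial pairing of plants from different
dyads, used as the synchrony null).

Pseudo-dyad members were not recorded together, so before any comparison
each series is cut at its own movement onset and both are truncated to the
shorter of the two post-onset durations (:func:`align_pseudo`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrajectorySeries",
    "DyadRecord",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "align_pseudo",
    "align_dyad",
    "extract_axis",
    "read_manifest",
    "write_manifest",
    "TrajectoryParseError",
]

Role = Literal["handler", "grasper"]
AXES = ("x", "y", "z")


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file violates the column contract."""


@dataclass
class TrajectorySeries:
    """One plant's tendril-tip path sampled at a fixed interval.

    Positions are in millimetres; ``dt`` in seconds.  ``onset_index`` is the
    first frame of analysable movement (given as metadata; this package does
    not detect onsets).
    """

    plant_id: str
    dyad_id: str
    role: Role
    dt: float
    onset_index: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.role not in ("handler", "grasper"):
            raise ValueError(f"role must be handler or grasper, got {self.role!r}")
        n = len(self.x)
        if not (len(self.y) == n and len(self.z) == n):
            raise ValueError("x, y, z must have equal length")
        if n < 2:
            raise ValueError(f"series needs >= 2 samples, got {n}")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not (0 <= self.onset_index < n):
            raise ValueError(
                f"onset_index {self.onset_index} outside [0, {n})"
            )
        for name in AXES:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def post_onset_length(self) -> int:
        return len(self) - self.onset_index


@dataclass
class DyadRecord:
    """A handler/grasper pair, real or pseudo."""

    handler: TrajectorySeries
    grasper: TrajectorySeries
    kind: Literal["real", "pseudo"]
    aligned: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("real", "pseudo"):
            raise ValueError(f"kind must be real or pseudo, got {self.kind!r}")
        if abs(self.handler.dt - self.grasper.dt) > 1e-9:
            raise ValueError("dyad members must share the sampling interval")
        if self.kind == "real":
            # simultaneous acquisition: same length, same onset
            if len(self.handler) != len(self.grasper):
                raise ValueError("real dyad members must have equal length")
            if self.handler.onset_index != self.grasper.onset_index:
                raise ValueError("real dyad members must share the onset")
        if self.aligned:
            if self.handler.post_onset_length != self.grasper.post_onset_length:
                raise ValueError("aligned dyad members must have equal post-onset length")

    @property
    def dyad_id(self) -> str:
        if self.kind == "real":
            return self.handler.dyad_id
        return f"{self.handler.dyad_id}x{self.grasper.dyad_id}"


# ---------------------------------------------------------------------------
# CSV round trip
#
# Layout: '#'-prefixed key=value header lines, then frame,t_s,x_mm,y_mm,z_mm.

_COLUMNS = ["frame", "t_s", "x_mm", "y_mm", "z_mm"]


def write_trajectory_csv(series: TrajectorySeries, path: str | Path) -> None:
    """Write a series to CSV with its metadata in '#' header lines."""
    path = Path(path)
    n = len(series)
    header = (
        f"# plant_id={series.plant_id}, dyad_id={series.dyad_id}, "
        f"role={series.role}, dt={series.dt!r}, onset_index={series.onset_index}\n"
    )
    frame = np.arange(n)
    df = pd.DataFrame(
        {
            "frame": frame,
            "t_s": frame * series.dt,
            "x_mm": series.x,
            "y_mm": series.y,
            "z_mm": series.z,
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.9f")


def _parse_header(line: str, path: Path) -> dict:
    meta = {}
    for item in line.lstrip("#").strip().split(","):
        if "=" not in item:
            raise TrajectoryParseError(f"{path}: malformed header item {item!r}")
        key, value = item.split("=", 1)
        meta[key.strip()] = value.strip()
    missing = {"plant_id", "dyad_id", "role", "dt", "onset_index"} - meta.keys()
    if missing:
        raise TrajectoryParseError(f"{path}: header missing {sorted(missing)}")
    return meta


def read_trajectory_csv(path: str | Path) -> TrajectorySeries:
    """Read and validate a trajectory CSV written by :func:`write_trajectory_csv`.

    Raises :class:`TrajectoryParseError` naming the first offending row or
    column on missing columns, gaps in frame numbering, a time column
    inconsistent with ``dt``, or non-finite positions.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise TrajectoryParseError(f"{path}: missing '#' metadata header")
        meta = _parse_header(first, path)
        df = pd.read_csv(fh)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    dt = float(meta["dt"])
    frames = df["frame"].to_numpy()
    gaps = np.flatnonzero(np.diff(frames) != 1)
    if gaps.size:
        raise TrajectoryParseError(
            f"{path}: gap in frame numbering at row {int(gaps[0]) + 1} "
            f"(frame {int(frames[gaps[0]])} -> {int(frames[gaps[0] + 1])})"
        )
    t = df["t_s"].to_numpy()
    bad_t = np.flatnonzero(np.abs(t - frames * dt) > 1e-6)
    if bad_t.size:
        raise TrajectoryParseError(
            f"{path}: time column inconsistent with dt={dt} at row {int(bad_t[0])}"
        )
    for col in ("x_mm", "y_mm", "z_mm"):
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy()))
        if bad.size:
            raise TrajectoryParseError(
                f"{path}: non-finite value in column {col} at row {int(bad[0])}"
            )
    return TrajectorySeries(
        plant_id=meta["plant_id"],
        dyad_id=meta["dyad_id"],
        role=meta["role"],  # type: ignore[arg-type]
        dt=dt,
        onset_index=int(meta["onset_index"]),
        x=df["x_mm"].to_numpy(),
        y=df["y_mm"].to_numpy(),
        z=df["z_mm"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Alignment and axis extraction


def align_pseudo(
    a: TrajectorySeries, b: TrajectorySeries
) -> tuple[TrajectorySeries, TrajectorySeries]:
    """Align two series from their own movement onsets.

    Each output starts at its series' onset and both are truncated to
    ``L = min(post-onset durations)`` samples, after which ``onset_index``
    is 0.  Idempotent: applying it to already-aligned series is a no-op.
    """
    if abs(a.dt - b.dt) > 1e-9:
        raise ValueError("series must share the sampling interval")
    length = min(a.post_onset_length, b.post_onset_length)
    if length < 2:
        raise ValueError(
            f"degenerate overlap: only {length} post-onset samples in common"
        )

    def cut(s: TrajectorySeries) -> TrajectorySeries:
        lo = s.onset_index
        return replace(
            s,
            onset_index=0,
            x=s.x[lo : lo + length].copy(),
            y=s.y[lo : lo + length].copy(),
            z=s.z[lo : lo + length].copy(),
        )

    return cut(a), cut(b)


def align_dyad(record: DyadRecord) -> DyadRecord:
    """Apply the onset/truncation rule to both members of a dyad.

    For a real dyad (shared onset and length) this just drops the shared
    pre-onset segment; for a pseudo dyad it is the full alignment rule.
    """
    if record.aligned:
        return record
    handler, grasper = align_pseudo(record.handler, record.grasper)
    return DyadRecord(handler=handler, grasper=grasper, kind=record.kind, aligned=True)


def extract_axis(series: TrajectorySeries, axis: str) -> np.ndarray:
    """Post-onset coordinate sequence (mm) along one axis.

    The analysis of nutation uses the horizontal axes x and z; requesting
    the vertical axis y is allowed but triggers a warning because vertical
    drift is growth, not oscillation.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
    if axis == "y":
        warnings.warn(
            "axis 'y' is the vertical growth axis, outside the default "
            "synchrony analysis (x and z)",
            UserWarning,
            stacklevel=2,
        )
    return np.asarray(getattr(series, axis)[series.onset_index :], dtype=float)


# ---------------------------------------------------------------------------
# Dyad manifest


def write_manifest(records: Iterable[dict], path: str | Path) -> None:
    """Write a dyad manifest: list of {dyad_id, kind, handler_file, grasper_file}."""
    entries = list(records)
    for e in entries:
        missing = {"dyad_id", "kind", "handler_file", "grasper_file"} - e.keys()
        if missing:
            raise ValueError(f"manifest entry {e} missing {sorted(missing)}")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"{path}: manifest must be a list of dyad entries")
    return entries


def load_dyads_from_manifest(path: str | Path) -> list[DyadRecord]:
    """Read every dyad listed in a manifest, resolving paths relative to it."""
    base = Path(path).parent
    records = []
    for entry in read_manifest(path):
        handler = read_trajectory_csv(base / entry["handler_file"])
        grasper = read_trajectory_csv(base / entry["grasper_file"])
        records.append(DyadRecord(handler=handler, grasper=grasper, kind=entry["kind"]))
    return records
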
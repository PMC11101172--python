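"""Track containers and tidy-CSV I/O.

A *track* is the time-ordered 2D trajectory of one labelled structure
(nucleus or centrosome) of one migrating cell, expressed in micrometres
and minutes.  Tracks are exchanged as tidy CSV tables with columns
``cell_id, role, frame, t_min, x_um, y_um`` (MTrackJ-style manual-tracking
exports are converted upstream into this dialect).

Coordinates are consumed as given: pixel-size calibration happens before
this package, and only x,y are tracked (no z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, TrackFormatError, TrackValidationError

logger = logging.getLogger("saltmig")

ROLES = ("nucleus", "centrosome")
REQUIRED_COLUMNS = ("cell_id", "role", "frame", "t_min", "x_um", "y_um")

#: tolerance (minutes) when checking that sampling times sit on the dt grid
GRID_TOL = 1e-6


@dataclass(frozen=True)
class Track:
    """Trajectory of one structure of one cell.

    Parameters
    ----------
    cell_id : str
        Opaque cell identifier.
    role : {"nucleus", "centrosome"}
    t : ndarray, shape (n,)
        Sampling times in minutes, strictly increasing, each interval a
        positive multiple of ``dt_nominal`` (missing frames are allowed
        here; use :func:`split_at_gaps` before kinematic analysis).
    xy : ndarray, shape (n, 2)
        Positions in micrometres.
    dt_nominal : float
        Nominal frame interval in minutes (3 min in the reference
        acquisition protocol).
    """

    cell_id: str
    role: str
    t: np.ndarray
    xy: np.ndarray
    dt_nominal: float = 3.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)
        if self.role not in ROLES:
            raise TrackValidationError(
                f"track {self.cell_id!r}: role must be one of {ROLES}, got {self.role!r}"
            )
        if t.ndim != 1 or xy.shape != (t.size, 2):
            raise TrackValidationError(
                f"track {self.cell_id!r}: t must be (n,) and xy (n, 2); "
                f"got {t.shape} and {xy.shape}"
            )
        if t.size == 0:
            raise TrackValidationError(f"track {self.cell_id!r}: empty track")
        if not (np.isfinite(t).all() and np.isfinite(xy).all()):
            raise TrackValidationError(f"track {self.cell_id!r}: non-finite coordinate")
        if t[0] < 0:
            raise TrackValidationError(f"track {self.cell_id!r}: negative time")
        if self.dt_nominal <= 0:
            raise TrackValidationError(f"track {self.cell_id!r}: dt_nominal must be > 0")
        dt = np.diff(t)
        if (dt <= 0).any():
            raise TrackValidationError(
                f"track {self.cell_id!r}: timepoints not strictly increasing"
            )
        ratio = dt / self.dt_nominal
        if np.abs(ratio - np.round(ratio)).max(initial=0.0) > GRID_TOL:
            raise TrackValidationError(
                f"track {self.cell_id!r}: inter-point interval not a multiple "
                f"of dt_nominal={self.dt_nominal} min"
            )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration_min(self) -> float:
        """Tracked duration in minutes (last minus first timepoint)."""
        return float(self.t[-1] - self.t[0])

    @property
    def has_gaps(self) -> bool:
        return bool((np.diff(self.t) > self.dt_nominal + GRID_TOL).any())


@dataclass(frozen=True)
class CellRecord:
    """One cell: its nucleus track, optional centrosome track and context."""

    cell_id: str
    nucleus: Track
    centrosome: Track | None = None
    group: str = ""
    dataset_id: str = ""
    reference_vector: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0])
    )

    def __post_init__(self) -> None:
        if self.nucleus.role != "nucleus":
            raise TrackValidationError(f"cell {self.cell_id!r}: nucleus track has wrong role")
        if self.centrosome is not None:
            if self.centrosome.role != "centrosome":
                raise TrackValidationError(
                    f"cell {self.cell_id!r}: centrosome track has wrong role"
                )
            if self.centrosome.cell_id != self.nucleus.cell_id:
                raise TrackValidationError(
                    f"cell {self.cell_id!r}: centrosome cell_id "
                    f"{self.centrosome.cell_id!r} != nucleus cell_id"
                )
        ref = np.asarray(self.reference_vector, dtype=float)
        norm = float(np.hypot(*ref))
        if ref.shape != (2,) or not np.isfinite(norm) or norm == 0.0:
            raise TrackValidationError(
                f"cell {self.cell_id!r}: reference_vector must be a nonzero 2-vector"
            )
        object.__setattr__(self, "reference_vector", ref / norm)


def read_tracks(
    path: str | Path, dialect: str = "tidy_csv", dt_nominal: float = 3.0
) -> list[Track]:
    """Read a tidy track table into one :class:`Track` per (cell_id, role).

    ``t_min`` takes precedence where present; empty ``t_min`` cells fall
    back to ``frame * dt_nominal`` (frames are 0-based).  Rows may appear
    in any order; points are sorted by time.  Duplicate
    (cell_id, role, t) rows are rejected.
    """
    if dialect != "tidy_csv":
        raise TrackFormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise TrackFormatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"cell_id": str, "role": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrackFormatError(f"{path}: missing required column {col!r}")
    for col in ("frame", "t_min", "x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 0- vs 1-based numbering
            line = int(bad.idxmax()) + 2
            raise TrackFormatError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        df[col] = coerced
    if df["x_um"].isna().any() or df["y_um"].isna().any():
        line = int(df[["x_um", "y_um"]].isna().any(axis=1).idxmax()) + 2
        raise TrackFormatError(f"{path}: missing coordinate at line {line}")

    t = df["t_min"].to_numpy(dtype=float)
    missing_t = np.isnan(t)
    if missing_t.any():
        frames = df["frame"].to_numpy(dtype=float)
        if np.isnan(frames[missing_t]).any():
            raise TrackFormatError(f"{path}: rows with neither t_min nor frame")
        t[missing_t] = frames[missing_t] * dt_nominal
    df = df.assign(t_min=t)

    tracks: list[Track] = []
    for (cell_id, role), sub in df.groupby(["cell_id", "role"], sort=True):
        sub = sub.sort_values("t_min")
        tt = sub["t_min"].to_numpy()
        if np.unique(np.round(tt / GRID_TOL)).size != tt.size:
            raise TrackValidationError(
                f"{path}: duplicate timepoint for cell {cell_id!r} role {role!r}"
            )
        if len(sub) < 2:
            raise TrackValidationError(
                f"{path}: track {cell_id!r}/{role!r} has fewer than 2 points"
            )
        tracks.append(
            Track(
                cell_id=str(cell_id),
                role=str(role),
                t=tt,
                xy=sub[["x_um", "y_um"]].to_numpy(),
                dt_nominal=dt_nominal,
            )
        )
    return tracks


def tracks_to_frame(tracks: Iterable[Track]) -> pd.DataFrame:
    """Flatten tracks back into the tidy table (inverse of :func:`read_tracks`)."""
    rows = []
    for tr in tracks:
        frame = np.round(tr.t / tr.dt_nominal).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "role": tr.role,
                    "frame": frame,
                    "t_min": tr.t,
                    "x_um": tr.xy[:, 0],
                    "y_um": tr.xy[:, 1],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return pd.concat(rows, ignore_index=True)


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks as tidy CSV, coordinates at 6 decimal places (lossless round-trip)."""
    df = tracks_to_frame(tracks)
    df.to_csv(path, index=False, float_format="%.6f")


def split_at_gaps(track: Track, max_gap: float | None = None) -> list[Track]:
    """Split a track into maximal sub-tracks with all intervals <= ``max_gap``.

    ``max_gap`` defaults to ``dt_nominal``: thresholded per-interval
    displacement tests (6 um per 3 min) are undefined over longer
    intervals, so gapped tracks are segmented rather than interpolated.
    Sub-track ids are suffixed ``/1``, ``/2``, ... in time order; a
    gap-free track is returned unchanged (single element, original id).
    Single-point segments are kept so that the output point sets
    partition the input.
    """
    if max_gap is None:
        max_gap = track.dt_nominal
    if max_gap < track.dt_nominal - GRID_TOL:
        raise ParameterError(
            f"max_gap={max_gap} min is smaller than dt_nominal={track.dt_nominal} min"
        )
    breaks = np.flatnonzero(np.diff(track.t) > max_gap + GRID_TOL)
    if breaks.size == 0:
        return [track]
    bounds = np.concatenate([[0], breaks + 1, [len(track)]])
    out = []
    for k in range(bounds.size - 1):
        lo, hi = bounds[k], bounds[k + 1]
        out.append(
            replace(
                track,
                cell_id=f"{track.cell_id}/{k + 1}",
                t=track.t[lo:hi],
                xy=track.xy[lo:hi],
            )
        )
    return out


def pair_cells(
    tracks: Sequence[Track],
    group: str = "",
    reference_vector: Sequence[float] = (1.0, 0.0),
    dataset_id: str = "",
) -> list[CellRecord]:
    """Pair nucleus and centrosome tracks into per-cell records.

    Every nucleus track yields a record; a centrosome track is attached
    when one shares the cell_id.  Centrosome-only cell_ids are logged and
    dropped.  Two tracks with the same (cell_id, role) are an error.
    """
    by_id: dict[str, dict[str, Track]] = {}
    for tr in tracks:
        slot = by_id.setdefault(tr.cell_id, {})
        if tr.role in slot:
            raise TrackValidationError(
                f"two {tr.role} tracks share cell_id {tr.cell_id!r}"
            )
        slot[tr.role] = tr
    records = []
    for cell_id in sorted(by_id):
        slot = by_id[cell_id]
        if "nucleus" not in slot:
            logger.warning(
                "cell %r has a centrosome track but no nucleus track; dropped", cell_id
            )
            continue
        records.append(
            CellRecord(
                cell_id=cell_id,
                nucleus=slot["nucleus"],
                centrosome=slot.get("centrosome"),
                group=group,
                dataset_id=dataset_id,
                reference_vector=np.asarray(reference_vector, dtype=float),
            )
        )
    return records
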
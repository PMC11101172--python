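"""Event detection and per-cell migration metrics for saltatory migration.

Migrating neuroblasts of the postnatal rostral migratory stream move in a
cyclic "two-stroke" fashion: the centrosome first advances into a swelling
of the leading process (*centrokinesis*, CK), then the nucleus jumps
forward (*nucleokinesis*, NK), then the cell pauses.  At a 3-min frame
interval these strokes are operationalised as:

* **NK** — an inter-frame nuclear displacement strictly greater than
  6 μm.  Consecutive supra-threshold steps are merged into one event
  (the per-event distance is then the path length of the run).
* **CK** — an increase of the centrosome–nucleus separation strictly
  greater than 2 μm followed by a decrease strictly greater than 2 μm.
  A CK is *efficient* when a subsequent NK follows it (before the next
  CK begins), *inefficient* otherwise.

All per-cell metrics (speed, pausing time, sinuosity, migration angle,
NK/CK statistics) are computed from raw tracked coordinates; no smoothing
or interpolation is applied.  Cells tracked for less than 30 min or
performing no NK at all are excluded by :func:`qc_filter`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tracks import CellRecord, Track, GRID_TOL

logger = logging.getLogger("saltmig")

NK_THRESHOLD_UM = 6.0   #: nuclear step above which a movement is an NK
CK_THRESHOLD_UM = 2.0   #: forward/backward centrosome excursion threshold
MIN_DURATION_MIN = 30.0  #: QC: minimum tracked duration


# ---------------------------------------------------------------------------
# events

@dataclass(frozen=True)
class NKEvent:
    """One nucleokinesis: a maximal run of consecutive supra-threshold steps."""

    start_t: float
    end_t: float
    n_steps: int
    path_distance: float  # μm, sum of step displacements in the run
    net_distance: float   # μm, straight-line start→end of the run

    def __post_init__(self):
        if not (self.path_distance >= self.net_distance >= 0.0 or
                math.isclose(self.path_distance, self.net_distance)):
            raise ValueError("NK event: path_distance < net_distance")


@dataclass(frozen=True)
class CKEvent:
    """One centrokinesis: a rise/fall excursion of the separation series."""

    onset_t: float
    peak_t: float
    end_t: float
    forward_amplitude: float   # μm, peak − onset baseline
    backward_amplitude: float  # μm, peak − value at closing point
    ck_speed: float            # μm/hr, centrosome path over [onset, end] / duration
    efficient: bool | None = None  # None until classified


@dataclass(frozen=True)
class RadarCounts:
    """Cell counts per angular dial of a migration radar."""

    dial_edges: tuple[tuple[float, float], ...]
    labels: tuple[str, ...]
    counts: tuple[int, ...]

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def percentages(self) -> tuple[float, ...]:
        n = self.n
        if n == 0:
            return tuple(float("nan") for _ in self.counts)
        return tuple(100.0 * c / n for c in self.counts)


@dataclass
class CellMetrics:
    """Per-cell summary row; NaN marks undefined quantities."""

    cell_id: str
    group: str
    dataset_id: str
    duration_hr: float
    speed: float          # μm/hr, pauses included
    pausing_pct: float    # % of time slots below the NK threshold
    sinuosity: float      # path / net straight-line distance (≥ 1)
    angle_deg: float      # [0, 360), 0 = toward the OB reference direction
    nk_count: int
    nk_freq: float        # NK events per hour
    nk_mean_distance: float  # μm, mean per-event path distance
    ck_count: int | None = None
    ck_freq: float | None = None
    ck_speed_median: float | None = None
    ck_efficiency_pct: float | None = None
    qc_pass: bool = True
    qc_reason: str = ""


# ---------------------------------------------------------------------------
# elementary kinematics

def step_displacements(track: Track) -> np.ndarray:
    """Per-interval Euclidean displacements, one per consecutive point pair.

    Returns a structured view as an ndarray of shape (n-1,); interval start
    times are ``track.t[:-1]``.
    """
    if len(track) < 2:
        raise ParameterError(f"track {track.cell_id!r}: need >= 2 points")
    return np.hypot(*np.diff(track.xy, axis=0).T)


def _require_gap_free(track: Track) -> None:
    if track.has_gaps:
        raise ParameterError(
            f"track {track.cell_id!r} has missing frames; split_at_gaps first "
            "(per-interval thresholds are undefined over longer intervals)"
        )


def detect_nk_events(
    track: Track, nk_threshold: float = NK_THRESHOLD_UM, merge: bool = True
) -> list[NKEvent]:
    """Detect nucleokineses as maximal runs of steps strictly > ``nk_threshold``.

    With ``merge=False`` every supra-threshold step becomes its own
    single-step event (sensitivity variant; the default merges runs, which
    is what makes per-event distances exceed the single-step threshold).
    """
    if nk_threshold <= 0:
        raise ParameterError(f"nk_threshold must be > 0, got {nk_threshold}")
    _require_gap_free(track)
    steps = step_displacements(track)
    supra = steps > nk_threshold
    events: list[NKEvent] = []
    i = 0
    n = steps.size
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and supra[j + 1] and merge:
            j += 1
        net = float(np.hypot(*(track.xy[j + 1] - track.xy[i])))
        events.append(
            NKEvent(
                start_t=float(track.t[i]),
                end_t=float(track.t[j + 1]),
                n_steps=j - i + 1,
                path_distance=float(steps[i : j + 1].sum()),
                net_distance=net,
            )
        )
        i = j + 1
    return events


def migration_speed(track: Track) -> float:
    """Total path length / total time, in μm/hr, pauses included."""
    if track.duration_min <= 0:
        raise ParameterError(f"track {track.cell_id!r}: zero duration")
    return float(step_displacements(track).sum() / (track.duration_min / 60.0))


def pausing_fraction(track: Track, nk_threshold: float = NK_THRESHOLD_UM) -> float:
    """Percentage of time slots in which the nucleus moves less than the NK cutoff.

    A step of exactly the threshold counts as a pause (an NK requires a
    movement strictly above it).
    """
    _require_gap_free(track)
    steps = step_displacements(track)
    return float(100.0 * np.count_nonzero(steps <= nk_threshold) / steps.size)


def sinuosity(track: Track) -> float:
    """Path length over straight-line start→end distance; NaN if the net is 0."""
    path = float(step_displacements(track).sum())
    net = float(np.hypot(*(track.xy[-1] - track.xy[0])))
    if net == 0.0:
        logger.warning("track %r: zero net displacement, sinuosity undefined", track.cell_id)
        return float("nan")
    return path / net


def migration_angle(track: Track, reference_vector: Sequence[float]) -> float:
    """Angle (degrees in [0, 360)) from the SVZ→OB reference to the net displacement.

    Counter-clockwise positive; 0° means migration exactly toward the OB.
    NaN if the cell ends where it started.
    """
    ref = np.asarray(reference_vector, dtype=float)
    norm = np.hypot(*ref)
    if ref.shape != (2,) or norm == 0.0:
        raise ParameterError("reference_vector must be a nonzero 2-vector")
    disp = track.xy[-1] - track.xy[0]
    if disp[0] == 0.0 and disp[1] == 0.0:
        logger.warning("track %r: zero net displacement, angle undefined", track.cell_id)
        return float("nan")
    ang = math.degrees(
        math.atan2(ref[0] * disp[1] - ref[1] * disp[0], ref[0] * disp[0] + ref[1] * disp[1])
    )
    return ang % 360.0


def radar_bin(angles: Iterable[float], n_dials: int = 4) -> RadarCounts:
    """Bin migration angles into ``n_dials`` equal dials centred on 0°, 90°, ...

    Dial *i* covers [i·w − w/2, i·w + w/2) with w = 360/n_dials; a boundary
    angle belongs to the dial it opens.  For the canonical 4-dial radar the
    dials are labelled forward [315°,45°), left [45°,135°), backward
    [135°,225°), right [225°,315°).
    """
    if n_dials < 2:
        raise ParameterError("n_dials must be >= 2")
    angles = np.asarray(list(angles), dtype=float)
    if angles.size and ((angles < 0) | (angles >= 360)).any():
        raise ParameterError("angles must lie in [0, 360)")
    width = 360.0 / n_dials
    idx = (np.floor((angles + width / 2.0) / width).astype(int)) % n_dials
    counts = np.bincount(idx, minlength=n_dials)
    edges = tuple(
        ((i * width - width / 2.0) % 360.0, (i * width + width / 2.0) % 360.0)
        for i in range(n_dials)
    )
    labels = (
        ("forward", "left", "backward", "right")
        if n_dials == 4
        else tuple(f"dial_{i}" for i in range(n_dials))
    )
    return RadarCounts(dial_edges=edges, labels=labels, counts=tuple(int(c) for c in counts))


# ---------------------------------------------------------------------------
# centrosome dynamics

def centrosome_separation_series(cell: CellRecord) -> tuple[np.ndarray, np.ndarray]:
    """(t, separation) over the timepoints shared by nucleus and centrosome tracks.

    Separation is the Euclidean centrosome→nucleus distance.  The
    centrosome track may cover only part of the nucleus track; CK analysis
    is restricted to the overlap.
    """
    if cell.centrosome is None:
        raise ParameterError(f"cell {cell.cell_id!r}: no centrosome track")
    tn = np.round(cell.nucleus.t / GRID_TOL).astype(np.int64)
    tc = np.round(cell.centrosome.t / GRID_TOL).astype(np.int64)
    common, ia, ib = np.intersect1d(tn, tc, return_indices=True)
    t = cell.nucleus.t[ia]
    sep = np.hypot(*(cell.centrosome.xy[ib] - cell.nucleus.xy[ia]).T)
    return t, sep


def _scan_rise_fall(s: np.ndarray, threshold: float) -> list[tuple[int, int, int]]:
    """Greedy left-to-right rise/fall excursion scan on a scalar series.

    An event opens at the running minimum (baseline; last occurrence, so
    flat pre-baseline stretches are not swallowed into the event), is
    armed once the series has risen more than ``threshold`` above that
    baseline, and closes at the first point more than ``threshold`` below
    the running maximum reached since the onset.  Returns
    (onset, peak, close) index triples; the closing index can serve as
    the next baseline.
    """
    events: list[tuple[int, int, int]] = []
    n = s.size
    start = 0
    while start < n - 1:
        min_idx = start
        armed = False
        peak_idx = -1
        closed = False
        for m in range(start + 1, n):
            if not armed:
                if s[m] - s[min_idx] > threshold:
                    armed = True
                    peak_idx = m
                elif s[m] <= s[min_idx]:
                    min_idx = m
            if armed:
                if s[m] > s[peak_idx]:
                    peak_idx = m
                if s[peak_idx] - s[m] > threshold:
                    events.append((min_idx, peak_idx, m))
                    start = m
                    closed = True
                    break
        if not closed:
            break
    return events


def detect_ck_events(
    cell: CellRecord,
    ck_threshold: float = CK_THRESHOLD_UM,
    frame: str = "relative",
) -> list[CKEvent] | None:
    """Detect centrokineses on the centrosome–nucleus separation series.

    ``frame="relative"`` (default) scans the scalar separation — forward
    means the centrosome moving away from the nucleus.  ``frame="absolute"``
    is a sensitivity variant scanning the centrosome's signed displacement
    along the SVZ→OB reference axis instead.

    Returns ``None`` (missing data, not an error) when the cell has no
    centrosome track or fewer than 3 shared timepoints.
    """
    if ck_threshold <= 0:
        raise ParameterError(f"ck_threshold must be > 0, got {ck_threshold}")
    if frame not in ("relative", "absolute"):
        raise ParameterError(f"frame must be 'relative' or 'absolute', got {frame!r}")
    if cell.centrosome is None:
        return None
    t, sep = centrosome_separation_series(cell)
    if t.size < 3:
        return None
    if frame == "relative":
        series = sep
    else:
        tn = np.round(cell.centrosome.t / GRID_TOL).astype(np.int64)
        mask = np.isin(tn, np.round(t / GRID_TOL).astype(np.int64))
        series = (cell.centrosome.xy[mask] - cell.centrosome.xy[mask][0]) @ cell.reference_vector
    # centrosome positions on the shared grid, for the per-event speed
    tc = np.round(cell.centrosome.t / GRID_TOL).astype(np.int64)
    keep = np.isin(tc, np.round(t / GRID_TOL).astype(np.int64))
    cxy = cell.centrosome.xy[keep]
    events = []
    for i, j, k in _scan_rise_fall(np.asarray(series, dtype=float), ck_threshold):
        dur_hr = (t[k] - t[i]) / 60.0
        path = float(np.hypot(*np.diff(cxy[i : k + 1], axis=0).T).sum())
        events.append(
            CKEvent(
                onset_t=float(t[i]),
                peak_t=float(t[j]),
                end_t=float(t[k]),
                forward_amplitude=float(series[j] - series[i]),
                backward_amplitude=float(series[j] - series[k]),
                ck_speed=path / dur_hr,
            )
        )
    return events


def classify_ck_efficiency(
    cks: Sequence[CKEvent], nks: Sequence[NKEvent], track_end_t: float | None = None
) -> list[CKEvent]:
    """Flag each CK efficient iff an NK starts after its peak and before the next CK.

    The matching window for CK *k* is ``(peak_t(k), onset_t(k+1)]`` — for
    the last CK it extends to the end of the track.  Each NK validates at
    most one CK (the earliest still-unmatched one).
    """
    cks = sorted(cks, key=lambda e: e.onset_t)
    nk_starts = sorted(e.start_t for e in nks)
    used = [False] * len(nk_starts)
    out = []
    for idx, ck in enumerate(cks):
        lo = ck.peak_t
        if idx + 1 < len(cks):
            hi = cks[idx + 1].onset_t
        else:
            hi = track_end_t if track_end_t is not None else math.inf
        efficient = False
        for m, s in enumerate(nk_starts):
            if used[m]:
                continue
            if lo < s <= hi:
                used[m] = True
                efficient = True
                break
            if s > hi:
                break
        out.append(
            CKEvent(
                onset_t=ck.onset_t,
                peak_t=ck.peak_t,
                end_t=ck.end_t,
                forward_amplitude=ck.forward_amplitude,
                backward_amplitude=ck.backward_amplitude,
                ck_speed=ck.ck_speed,
                efficient=efficient,
            )
        )
    return out


# ---------------------------------------------------------------------------
# QC and aggregation

def qc_filter(
    cells: Iterable[CellRecord],
    min_duration: float = MIN_DURATION_MIN,
    nk_threshold: float = NK_THRESHOLD_UM,
) -> tuple[list[CellRecord], list[tuple[str, str]]]:
    """Exclude cells tracked < ``min_duration`` min or with no NK at all.

    Returns (kept, excluded) where each exclusion is a (cell_id, reason)
    pair with reason ``too_short`` or ``no_nk``.
    """
    kept, excluded = [], []
    for cell in cells:
        if cell.nucleus.duration_min < min_duration:
            excluded.append((cell.cell_id, "too_short"))
        elif not detect_nk_events(cell.nucleus, nk_threshold):
            excluded.append((cell.cell_id, "no_nk"))
        else:
            kept.append(cell)
    return kept, excluded


def compute_cell_metrics(
    cell: CellRecord,
    nk_threshold: float = NK_THRESHOLD_UM,
    ck_threshold: float = CK_THRESHOLD_UM,
    min_duration: float = MIN_DURATION_MIN,
    nk_merge: bool = True,
    ck_frame: str = "relative",
) -> tuple[CellMetrics, list[NKEvent], list[CKEvent]]:
    """All per-cell metrics plus the underlying NK and CK event lists.

    CK fields are ``None`` when the cell has no usable centrosome track;
    ``ck_efficiency_pct`` is ``None`` when no CK was detected.
    """
    nucleus = cell.nucleus
    nks = detect_nk_events(nucleus, nk_threshold, merge=nk_merge)
    duration_hr = nucleus.duration_min / 60.0
    qc_reason = ""
    if nucleus.duration_min < min_duration:
        qc_reason = "too_short"
    elif not nks:
        qc_reason = "no_nk"
    cks = detect_ck_events(cell, ck_threshold, frame=ck_frame)
    if cks is not None:
        cks = classify_ck_efficiency(cks, nks, track_end_t=float(nucleus.t[-1]))
    metrics = CellMetrics(
        cell_id=cell.cell_id,
        group=cell.group,
        dataset_id=cell.dataset_id,
        duration_hr=duration_hr,
        speed=migration_speed(nucleus),
        pausing_pct=pausing_fraction(nucleus, nk_threshold),
        sinuosity=sinuosity(nucleus),
        angle_deg=migration_angle(nucleus, cell.reference_vector),
        nk_count=len(nks),
        nk_freq=len(nks) / duration_hr,
        nk_mean_distance=(
            float(np.mean([e.path_distance for e in nks])) if nks else float("nan")
        ),
        qc_pass=qc_reason == "",
        qc_reason=qc_reason,
    )
    if cks is not None:
        metrics.ck_count = len(cks)
        metrics.ck_freq = len(cks) / duration_hr
        metrics.ck_speed_median = (
            float(np.median([e.ck_speed for e in cks])) if cks else float("nan")
        )
        metrics.ck_efficiency_pct = (
            100.0 * sum(e.efficient for e in cks) / len(cks) if cks else None
        )
    return metrics, nks, (cks if cks is not None else [])


def metrics_table(metrics: Iterable[CellMetrics]) -> pd.DataFrame:
    """Stack per-cell metrics into a tidy DataFrame (one row per cell)."""
    rows = [vars(m).copy() for m in metrics]
    df = pd.DataFrame(rows)
    return df
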
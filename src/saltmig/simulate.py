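"""Synthetic saltatory-migration tracks with known ground truth.

The generator embodies the two-stroke migration cycle on the exact
acquisition grid (3-min frames, 2–3 hr tracks): the cell pauses (slow
directed crawl plus sub-threshold positional jitter), the centrosome
advances into the leading process and retreats (a rise/fall excursion of
the centrosome–nucleus separation), and — for efficient cycles — the
nucleus then jumps forward by a lognormally distributed path distance
along a von Mises heading.  Genotype presets reproduce the published
control / Fmr1-null / Map1b-rescue regimes: the mutant moves with fewer
and shorter nucleokineses, pauses more, and is less directionally
persistent; the rescue restores the rates but not the persistence.

Positional jitter is modelled as whole-cell-body noise shared by nucleus
and centrosome, with a much smaller centrosome-specific component on top;
see the methods note for what this does and does not emulate about
manual-tracking noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tracks import CellRecord, Track

#: NK path distances are resampled until they exceed this floor (μm) so that
#: generated events remain detectable at the 6 μm / 3 min criterion even
#: under frame-to-frame jitter.
NK_STEP_FLOOR_UM = 7.2


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the saltatory-migration simulator.

    Rates are per hour, lengths in μm, times in minutes.  ``cycle_rate``
    is the expected *nucleokinesis* rate; migration cycles (each carrying
    a CK) are scheduled at ``cycle_rate / p_efficient_ck + extra_ck_rate``
    so that a fraction ``p_efficient_ck`` of CKs is followed by an NK.
    """

    dt: float = 3.0
    duration_min: float = 120.0
    duration_max: float = 180.0
    cycle_rate: float = 2.5          # expected NK events / hr
    p_efficient_ck: float = 0.54     # P(a cycle's CK is followed by an NK)
    extra_ck_rate: float = 0.0       # additional NK-free CKs / hr
    nk_step_median: float = 11.5     # μm, median NK path distance
    nk_step_logsd: float = 0.25      # log-scale SD of NK path distance
    nk_steps_max: int = 2            # frames an NK may span (split when large)
    ck_amplitude_median: float = 4.5  # μm, median separation excursion
    ck_amplitude_logsd: float = 0.25
    baseline_separation: float = 2.5  # μm, resting centrosome–nucleus distance
    pause_drift: float = 1.5         # μm/frame, directed crawl during pauses
    jitter_sd: float = 0.8           # μm/frame/axis, shared cell-body noise
    centrosome_jitter_sd: float = 0.25  # μm, centrosome-specific noise
    heading_kappa: float = 8.0       # von Mises concentration of headings
    name: str = "custom"

    def validate(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.duration_min < 2 * self.dt or self.duration_max < self.duration_min:
            raise ParameterError("degenerate duration range (need >= 2 frames)")
        for attr in ("cycle_rate", "extra_ck_rate", "jitter_sd",
                     "centrosome_jitter_sd", "pause_drift"):
            if getattr(self, attr) < 0:
                raise ParameterError(f"{attr} must be >= 0")
        if not 0.0 <= self.p_efficient_ck <= 1.0:
            raise ParameterError("p_efficient_ck must be in [0, 1]")
        if self.cycle_rate > 0 and self.p_efficient_ck == 0:
            raise ParameterError("cycle_rate > 0 requires p_efficient_ck > 0")
        if self.cycle_rate > 0 and self.nk_step_median <= 6.0:
            raise ParameterError("nk_step_median must exceed 6 μm (detectability)")
        if self.nk_steps_max not in (1, 2):
            raise ParameterError("nk_steps_max must be 1 or 2")
        # a single jitter step is Rayleigh(jitter_sd * sqrt(2));
        # require P(step > 6 μm) < 1e-4 so jitter alone never mimics an NK
        if self.jitter_sd > 0:
            p_big = math.exp(-9.0 / self.jitter_sd**2)
            if p_big >= 1e-4:
                raise ParameterError(
                    f"jitter_sd={self.jitter_sd} gives P(jitter step > 6 μm)="
                    f"{p_big:.2e} >= 1e-4"
                )


PRESETS: dict[str, SimParams] = {
    # Anchored to the published per-genotype medians: control ~2.5 NK/hr,
    # ~11.5 μm per NK, 54% efficient CKs, tight forward headings; the
    # Fmr1-null regime ~1.2 NK/hr, ~9.3 μm, 33% efficient, scattered
    # headings and a slower pause crawl; the Map1b-knockdown rescue keeps
    # the control rates but the mutant's poor directional persistence
    # (sinuosity and directionality are not rescued).
    "control": SimParams(
        name="control", cycle_rate=2.5, p_efficient_ck=0.54,
        nk_step_median=11.5, nk_step_logsd=0.25, ck_amplitude_median=4.5,
        pause_drift=1.5, heading_kappa=8.0,
    ),
    "fmr1_null": SimParams(
        name="fmr1_null", cycle_rate=1.2, p_efficient_ck=0.33,
        nk_step_median=9.3, nk_step_logsd=0.20, ck_amplitude_median=3.5,
        pause_drift=0.7, heading_kappa=2.5,
    ),
    "fmr1_null_mirMap1b": SimParams(
        name="fmr1_null_mirMap1b", cycle_rate=2.5, p_efficient_ck=0.54,
        nk_step_median=11.5, nk_step_logsd=0.25, ck_amplitude_median=4.5,
        pause_drift=1.5, heading_kappa=2.5,
    ),
}


def preset(name: str) -> SimParams:
    """Return the generative parameter preset for a genotype regime."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


@dataclass
class CellGroundTruth:
    """Events a simulated cell actually performed, for recovery studies."""

    cell_id: str
    heading_deg: float                         # true cell heading vs reference
    nk_events: list[tuple[float, float, int]] = field(default_factory=list)
    # (start_t of first jump interval, total path distance μm, frames spanned)
    ck_events: list[tuple[float, float, bool]] = field(default_factory=list)
    # (onset_t, amplitude μm, efficient)


def _von_mises(rng: np.random.Generator, mu: float, kappa: float) -> float:
    if kappa <= 0:
        return float(rng.uniform(-math.pi, math.pi))
    return float(rng.vonmises(mu, kappa))


def _lognormal_above(
    rng: np.random.Generator, median: float, logsd: float, floor: float
) -> float:
    """Lognormal(ln median, logsd) conditioned to exceed ``floor`` (rejection)."""
    mu = math.log(median)
    for _ in range(1000):
        x = float(rng.lognormal(mu, logsd))
        if x > floor:
            return x
    return floor  # pathological parameters; keep the guarantee


def simulate_cell(
    params: SimParams,
    reference_vector: Sequence[float] = (1.0, 0.0),
    rng: np.random.Generator | None = None,
    cell_id: str = "sim_0",
    group: str | None = None,
    dataset_id: str = "sim",
) -> tuple[CellRecord, CellGroundTruth]:
    """Simulate one cell (nucleus + centrosome tracks) on the exact dt grid.

    The cell alternates pause stretches and migration cycles.  A cycle is:
    a one-frame separation rise to the CK peak, a one-frame plateau just
    below the peak, then a fall back to baseline over 1–2 frames, during
    which — for efficient cycles — the nucleus performs its NK jump(s).
    Fully reproducible given ``rng``.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(0)
    ref = np.asarray(reference_vector, dtype=float)
    ref = ref / np.hypot(*ref)
    ref_angle = math.atan2(ref[1], ref[0])

    duration = float(
        params.duration_min
        + rng.integers(0, int(round((params.duration_max - params.duration_min) / params.dt)) + 1)
        * params.dt
    )
    n_frames = int(round(duration / params.dt)) + 1

    heading = _von_mises(rng, 0.0, params.heading_kappa) + ref_angle
    e_head = np.array([math.cos(heading), math.sin(heading)])

    # --- schedule cycles -------------------------------------------------
    frames_per_hr = 60.0 / params.dt
    cycle_lambda = (
        (params.cycle_rate / params.p_efficient_ck if params.cycle_rate > 0 else 0.0)
        + params.extra_ck_rate
    )
    p_nk = params.cycle_rate / cycle_lambda if cycle_lambda > 0 else 0.0
    # mean block: rise (1) + plateau (1) + fall (1.5) frames
    block_mean = 3.5
    if cycle_lambda > 0:
        period_frames = frames_per_hr / cycle_lambda
        gap_mean = max(1.0, period_frames - block_mean)
        p_gap = min(1.0, 1.0 / gap_mean)
    else:
        p_gap = 0.0

    # base nucleus path (noise-free), separation profile, event log
    base = np.zeros((n_frames, 2))
    sep = np.full(n_frames, params.baseline_separation)
    truth = CellGroundTruth(
        cell_id=cell_id, heading_deg=math.degrees(heading - ref_angle) % 360.0
    )

    pos = np.zeros(2)
    f = 0

    def advance_pause(k: int, f: int) -> int:
        nonlocal pos
        for _ in range(k):
            if f >= n_frames - 1:
                return n_frames - 1
            pos = pos + params.pause_drift * e_head
            f += 1
            base[f] = pos
        return f

    while f < n_frames - 1 and p_gap > 0:
        gap = int(rng.geometric(p_gap))
        f = advance_pause(gap, f)
        if f >= n_frames - 1:
            break
        # cycle block: one-frame rise to the peak, one-frame plateau, fall
        rise_f = 1
        fall_f = int(rng.integers(1, 3))
        do_nk = bool(rng.random() < p_nk)
        amp = _lognormal_above(
            rng, params.ck_amplitude_median, params.ck_amplitude_logsd, 2.5
        )
        nk_dist = 0.0
        nk_frames = 0
        if do_nk:
            nk_dist = _lognormal_above(
                rng, params.nk_step_median, params.nk_step_logsd, NK_STEP_FLOOR_UM
            )
            nk_frames = (
                2 if (params.nk_steps_max >= 2 and nk_dist > 2 * NK_STEP_FLOOR_UM) else 1
            )
            fall_f = max(fall_f, nk_frames)
        # need the rise, the plateau and (for NK cycles) every jump frame;
        # trailing fall frames may truncate at the end of the track
        needed = rise_f + 1 + (nk_frames if do_nk else 1)
        if f + needed > n_frames - 1:
            break
        onset_t = f * params.dt
        # rise
        for r in range(rise_f):
            f = advance_pause(1, f)
            sep[f] = params.baseline_separation + amp * (r + 1) / rise_f
        # plateau one frame just below the peak (keeps the detected peak
        # strictly before the NK onset, matching the efficiency window)
        f = advance_pause(1, f)
        sep[f] = params.baseline_separation + amp - 1.2
        nk_heading = _von_mises(rng, heading, params.heading_kappa)
        e_nk = np.array([math.cos(nk_heading), math.sin(nk_heading)])
        if do_nk:
            truth.nk_events.append((f * params.dt, nk_dist, nk_frames))
        for d in range(fall_f):
            if f >= n_frames - 1:
                break
            if do_nk and d < nk_frames:
                pos = pos + (nk_dist / nk_frames) * e_nk
            else:
                pos = pos + params.pause_drift * e_head
            f += 1
            base[f] = pos
            frac = 1.0 - (d + 1) / fall_f
            sep[f] = params.baseline_separation + max(0.0, amp - 1.2) * frac
        truth.ck_events.append((onset_t, amp, do_nk))

    # fill any remaining frames with pause crawl
    f = advance_pause(n_frames, f)

    # --- emit noisy tracks ----------------------------------------------
    shared = rng.normal(0.0, params.jitter_sd, size=(n_frames, 2))
    own = rng.normal(0.0, params.centrosome_jitter_sd, size=(n_frames, 2))
    t = np.arange(n_frames) * params.dt
    nuc_xy = base + shared
    cen_xy = base + shared + sep[:, None] * e_head + own
    group_label = group if group is not None else params.name
    record = CellRecord(
        cell_id=cell_id,
        nucleus=Track(cell_id, "nucleus", t, nuc_xy, params.dt),
        centrosome=Track(cell_id, "centrosome", t, cen_xy, params.dt),
        group=group_label,
        dataset_id=dataset_id,
        reference_vector=ref,
    )
    return record, truth


def simulate_cohort(
    params: SimParams,
    n_cells: int,
    seed: int,
    reference_vector: Sequence[float] = (1.0, 0.0),
    group: str | None = None,
    dataset_id: str = "sim",
) -> tuple[list[CellRecord], list[CellGroundTruth]]:
    """Simulate independent cells via deterministic per-cell substreams.

    One master seed spawns one child stream per cell, so cohorts are
    reproducible regardless of generation order.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_cells)
    records, truths = [], []
    for i, child in enumerate(children):
        rec, tru = simulate_cell(
            params,
            reference_vector=reference_vector,
            rng=np.random.default_rng(child),
            cell_id=f"{params.name}_{i:04d}",
            group=group,
            dataset_id=dataset_id,
        )
        records.append(rec)
        truths.append(tru)
    return records, truths


def nk_recovery(
    records: Sequence[CellRecord],
    truths: Sequence[CellGroundTruth],
    nk_threshold: float = 6.0,
) -> dict:
    """Match detected NK events against the ground-truth event log.

    A true NK is *recovered* when a detected event overlaps its jump
    interval; a detected event is *spurious* when it overlaps no true NK.
    Returns recovery and spurious fractions with the underlying counts.
    """
    from .kinematics import detect_nk_events

    by_id = {t.cell_id: t for t in truths}
    n_true = n_matched = n_detected = n_spurious = 0
    for rec in records:
        truth = by_id[rec.cell_id]
        dt = rec.nucleus.dt_nominal
        windows = [(s, s + frames * dt) for s, _, frames in truth.nk_events]
        used = [False] * len(windows)
        events = detect_nk_events(rec.nucleus, nk_threshold)
        n_true += len(windows)
        n_detected += len(events)
        for e in events:
            hit = False
            for i, (a, b) in enumerate(windows):
                if e.start_t < b and e.end_t > a:
                    hit = True
                    if not used[i]:
                        used[i] = True
                        n_matched += 1
                    break
            if not hit:
                n_spurious += 1
    return {
        "recovery": n_matched / n_true if n_true else float("nan"),
        "spurious": n_spurious / n_detected if n_detected else 0.0,
        "n_true": n_true,
        "n_detected": n_detected,
    }


def ground_truth_table(truths: Sequence[CellGroundTruth]) -> pd.DataFrame:
    """Tidy per-event ground-truth table (one row per true NK or CK event)."""
    rows = []
    for tru in truths:
        for start_t, dist, frames in tru.nk_events:
            rows.append(
                dict(cell_id=tru.cell_id, event="nk", t_min=start_t,
                     magnitude_um=dist, n_frames=frames, efficient=None,
                     heading_deg=tru.heading_deg)
            )
        for onset_t, amp, eff in tru.ck_events:
            rows.append(
                dict(cell_id=tru.cell_id, event="ck", t_min=onset_t,
                     magnitude_um=amp, n_frames=None, efficient=eff,
                     heading_deg=tru.heading_deg)
            )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "event", "t_min", "magnitude_um", "n_frames",
                 "efficient", "heading_deg"],
    )
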
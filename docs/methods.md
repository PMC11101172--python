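# Methods

This note documents the models, conventions and numerical choices behind
`saltmig`, in the spirit of a methods section for the package itself.

## 1. Data model

A *track* is a time-ordered sequence of 2D positions (μm) of one labelled
structure — nucleus or centrosome — of one cell, sampled on a nominal
frame grid (Δt = 3 min by default). Coordinates are consumed as given:
pixel-size calibration and the tracking itself happen upstream, and only
x,y are used (the source acquisitions are 2D projections). Timepoints
must sit on the Δt grid (tolerance 10⁻⁶ min); tracks with missing frames
are **split at the gaps rather than interpolated**, because the
per-interval displacement thresholds below (6 μm per 3 min) are undefined
over longer intervals. A cell record pairs a nucleus track with an
optional centrosome track (which may cover only part of the nucleus
track; all centrosome analyses are restricted to the shared timepoints)
plus a group label and the per-dataset SVZ→OB unit reference vector,
which must be supplied by the user — the package does not infer anatomy.

## 2. Event definitions and metrics

**Nucleokinesis (NK).** A movement strictly greater than 6 μm between two
consecutive timepoints. Maximal runs of consecutive supra-threshold steps
are merged into a single event whose distance is the path length of the
run. The merge is the package default because observed per-event
distances (median ≈ 11.5 μm in control cohorts) comfortably exceed the
6 μm single-step cutoff, implying that a nuclear translocation can span
two frames; since the raw data do not force this choice, `--no-nk-merge`
counts each supra-threshold step as its own event for sensitivity
analysis. A step of exactly 6 μm is a pause (the definition is strict).

**Centrokinesis (CK).** Measured on the scalar centrosome–nucleus
separation: a forward excursion strictly greater than 2 μm above the
running baseline followed by a backward movement strictly greater than
2 μm below the running peak. The scan is greedy left-to-right: an event
opens at the last point of the running minimum, arms once the rise
threshold is crossed, closes at the first point far enough below the
running maximum, and the closing point can serve as the next baseline.
The nucleus-relative frame is the default because the definition is
computed from centrosome *and* nucleus coordinates; measuring absolute
centrosome motion would conflate CK with NK. `--ck-frame absolute`
instead scans the centrosome's signed displacement along the SVZ→OB axis,
as a sensitivity variant. **CK speed** is the centrosome path length over
the event divided by the event duration (μm/hr) — a pragmatic definition,
reported per cell as the median. **Efficiency**: CK *k* is efficient iff
some NK starts in the window (peak of *k*, onset of *k+1*], the window of
the last CK extending to the end of the track; each NK validates at most
one CK (the earliest unmatched). This is the tightest non-overlapping
reading of "followed by a subsequent NK"; because consecutive windows are
disjoint, the greedy matching is also the unique maximal one.

**Per-cell metrics.** Speed = total path length / total tracked time,
pauses included (μm/hr). Pausing time = % of time slots below the NK
cutoff. Sinuosity = path length / straight-line start-to-end distance;
undefined (NaN, with a warning) for a cell that ends exactly where it
started. Migration angle θ = signed angle from the reference vector to
the net displacement vector, counter-clockwise positive, in [0°, 360°);
radars bin θ into four 90° dials centred on 0°/90°/180°/270°, a boundary
angle belonging to the dial it opens. QC excludes cells tracked less than
30 min and cells with no NK during the whole track, with machine-readable
reasons (`too_short`, `no_nk`).

Useful invariants (all property-tested): speed ≥ net speed, with
sinuosity = speed/net speed; pausing% and supra-threshold% sum to 100;
NK events partition the supra-threshold step set; all metrics are
invariant under joint rotation of coordinates and reference vector, and
behave equivariantly under scaling when thresholds are scaled along.

## 3. Statistics

Group comparisons default to the nonparametric path: Kruskal-Wallis on
ranks (tie-corrected H against χ² with k−1 df), Dunn's post hoc z tests
on mean ranks (tie-corrected, Benjamini-Hochberg adjusted — BH is used
because it is the one correction named alongside the categorical
analyses), two-sided Mann-Whitney (exact enumeration when both n ≤ 20
and there are no ties, normal approximation otherwise), Pearson χ²
without continuity correction, and Fisher's exact test — exact
hypergeometric two-sided p for 2×2 tables, and for R×C tables a
Monte-Carlo test over ≥10⁵ tables sampled from the null conditional
distribution with both margins fixed (label-permutation sampling; the
p estimate (1+hits)/(B+1) is reported with its Monte-Carlo standard
error and seed). A Shapiro-Wilk/Levene report is available but
deliberately does **not** gate the analysis onto parametric tests: the
package reproduces one well-defined analysis path rather than a
data-dependent switch. Summaries are median (IQR) with
linear-interpolation (type-7) quantiles.

## 4. The synthetic-track generator

The simulator is a semi-Markov embodiment of the two-stroke cycle on the
exact Δt grid, used for validation and parameter-recovery studies. Per
cell: a heading ψ ~ von Mises(reference, κ) is drawn once; the cell then
alternates geometric pause stretches and migration cycles. During pauses
the nucleus performs a slow directed crawl (`pause_drift` μm/frame along
ψ) with isotropic Gaussian jitter. A cycle is: one-frame rise of the
separation to baseline + A (A lognormal, resampled to exceed 2.5 μm so
events stay above the CK threshold), a one-frame plateau held 1.2 μm
below the peak, then a fall back to baseline over 1–2 frames. With
probability `p_efficient_ck` the nucleus jumps during the fall: a path
distance d ~ lognormal(median `nk_step_median`, `nk_step_logsd`),
resampled to exceed 7.2 μm so that generated events remain detectable
under frame noise, split over two frames only when d > 14.4 μm, along a
per-event heading ~ von Mises(ψ, κ). Cycles are scheduled at rate
`cycle_rate / p_efficient_ck` (plus `extra_ck_rate` NK-free cycles), with
the geometric gap mean chosen so that the *realised* cycle rate matches
the schedule after accounting for the 3.5-frame mean busy time; the last
cycle may truncate its fall at the track end. Track durations are drawn
uniformly on the 120–180 min grid.

The plateau frame exists so that a detected NK always starts strictly
after the detected CK peak, which is what the efficiency window requires;
its 1.2 μm dip keeps the detected peak on the rise frame with high
probability under noise.

**Noise model.** Frame-to-frame positional jitter (`jitter_sd` = 0.8 μm
per axis) is applied to the *whole cell body* — identically to nucleus
and centrosome — with a much smaller centrosome-specific jitter
(0.25 μm) on top. This keeps the separation series quiet enough for a
2 μm threshold to be meaningful, mirroring the fact that the original
analysis could use that threshold at all. It does **not** emulate fully
independent per-marker tracking error: with two independent 0.8 μm
noises, spurious 2 μm separation excursions would be common and CK
detection on real data would be noisier than on these tracks. Passing
the CK-recovery checks here therefore validates the scanner's logic, not
its robustness to heavy marker noise. Similarly, the generator draws NK
steps above a 7.2 μm floor, so NK-recovery rates quantify detector
correctness, not behaviour on events straddling the 6 μm boundary;
jitter parameters are validated so that P(a pure jitter step > 6 μm)
< 10⁻⁴.

**Genotype presets.** The three regimes are anchored to the published
per-genotype values: control (2.5 NK/hr, 11.5 μm NK median, 54%
efficient CKs, κ = 8), *Fmr1*-null (1.2 NK/hr, 9.3 μm, 33%, κ = 2.5),
and the Map1b-knockdown rescue = control rates with the mutant's κ
(directional persistence and hence sinuosity are not rescued). The
remaining knobs were fixed once by desk calibration against the
published medians and then left alone: `pause_drift` 1.5/0.7/1.5
μm/frame (pause movement in real cells is largely a slow directed crawl
— an isotropic-jitter-only model cannot produce sinuosity ≈ 1.15 at 82%
pausing), CK amplitude medians 4.5/3.5/4.5 μm (which give CK speeds of
roughly 80/57 μm/hr), log-SDs 0.25/0.20/0.25. Published IQRs are matched
only approximately (the sources give medians and IQRs, not
distributions); the mutant's sinuosity in particular overshoots its
published median (≈1.8 vs 1.35) as the price of a heading spread wide
enough to reproduce the directionality defect. Emergent cohort medians
at n = 200 (≈62/86%/1.2/11.9 μm/2.3 hr⁻¹ for control vs
≈41/94%/1.8/9.7/1.1 for the mutant) reproduce all published orderings;
the recovery and ordering checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` compute them at run time.

**Seeding.** One master seed spawns per-cell child streams
(`numpy.random.SeedSequence.spawn`), so cohorts are bit-reproducible and
order-independent.

## 5. Numerical and interface choices

- Problem sizes: validation cohorts use n = 200 cells per preset for
  recovery and n = 150 per arm for ordering contrasts; the
  Kruskal-Wallis size check uses 5,000 null datasets of 3×15 — sizes at
  which the checks are decisive yet run in seconds on one core.
- Exact-grid bookkeeping uses integer frame indices scaled by the 10⁻⁶
  min tolerance, so timepoint joins never depend on float equality.
- Degenerate inputs: zero net displacement → NaN sinuosity/angle with a
  warning, not an exception; a cell without a centrosome track yields
  missing CK fields, not an error; an empty post-QC cohort aborts the
  pipeline with the per-reason exclusion counts.
- Ties: first occurrence wins for CK peaks; the last baseline point
  before the rise is the onset (so flat stretches are not absorbed into
  events).
- Outputs are plain CSV/JSON; every bundle embeds the full configuration
  and the SHA-256 of its input, so any reported number is traceable.
  Radar rendering (matplotlib) is optional and kept out of the analysis
  path.

## 6. Known limitations

- 2D only; no estimation of the SVZ→OB axis from images; no
  morphological (swelling/leading-process) metrics.
- The efficiency window and the NK merge are principled readings of
  under-specified conventions; both are exposed as flags precisely
  because the original description does not pin them down.
- The simulator is phenomenological: it reproduces event statistics and
  their group orderings, not cytoskeletal mechanics, cell–cell
  interactions, or chain migration, and its noise model understates
  independent per-marker tracking error (see §4).
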
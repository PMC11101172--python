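# saltmig

Quantification of **cyclic saltatory neuronal migration** from time-lapse
tracking data.

Neuroblasts travelling along the postnatal rostral migratory stream (RMS)
from the ventricular/subventricular zone (SVZ) to the olfactory bulb (OB)
do not glide smoothly: they move in a discontinuous *two-stroke* cycle in
which the centrosome first advances into a swelling of the leading process
(**centrokinesis, CK**), the nucleus then jumps forward
(**nucleokinesis, NK**), and the cell pauses before the cycle reinitiates.
`saltmig` turns manually tracked x,y,t coordinates of nuclei and
centrosomes (3-min frame interval, 2–3 hr movies, MTrackJ-style exports
converted to a tidy CSV) into the standard per-cell statistics of this
migratory mode, compares experimental groups nonparametrically, and ships
a generative simulator of saltatory tracks with known ground truth so the
whole pipeline can be validated end to end.

It is aimed at labs doing live imaging of neuronal migration in acute
slices or explants who need a reproducible, scriptable version of the
usual spreadsheet analysis.

## Definitions implemented

With positions sampled every Δt = 3 min, and a per-dataset unit vector
pointing from the SVZ toward the OB:

- **NK event** — inter-frame nuclear displacement strictly greater than
  6 μm; consecutive supra-threshold steps are merged into one event whose
  distance is the path length of the run (switchable with `--no-nk-merge`).
- **CK event** — on the scalar centrosome–nucleus separation series, a
  rise of more than 2 μm above the running baseline followed by a fall of
  more than 2 μm below the running peak (greedy left-to-right scan). A CK
  is **efficient** when an NK starts after its peak and before the next
  CK's onset, **inefficient** otherwise. `--ck-frame absolute` instead
  scans the centrosome's displacement along the SVZ→OB axis.
- **speed** — total path length / total time, pauses included (μm/hr).
- **pausing time** — % of time slots with nuclear displacement below the
  NK cutoff.
- **sinuosity** — path length / straight-line start-to-end distance (≥ 1).
- **migration angle θ** — angle in [0°, 360°) between the cell's net
  displacement vector and the SVZ→OB vector (counter-clockwise positive);
  summarised as a four-dial **migration radar**
  (forward [315°,45°), left, backward, right).
- **QC** — cells tracked < 30 min or performing no NK at all are excluded.

Group comparisons follow the nonparametric path used for these metrics:
Kruskal-Wallis on ranks with Dunn's post hoc test (Benjamini-Hochberg
adjusted), Mann-Whitney for two groups, Pearson χ² and Fisher's exact
test (Monte-Carlo for R×C tables) for categorical data, all summarised as
median (IQR).

## Worked example

Simulate a control cohort, analyze it, and print the report:

```bash
$ saltmig simulate --preset control --n-cells 50 --seed 42 -o tracks.csv --truth truth.csv
wrote 50 cells (100 tracks) to tracks.csv

$ saltmig analyze tracks.csv --ref-vector 1,0 -o out/
{
  "tracks_read": 100,
  "cells_paired": 50,
  "excluded_too_short": 0,
  "excluded_no_nk": 0,
  "cells_analyzed": 50
}

$ saltmig report out/
per-cell metrics, median (IQR):
  speed: 60.70 (7.96)
  pausing_pct: 87.23 (4.26)
  sinuosity: 1.18 (0.07)
  nk_mean_distance: 11.93 (2.02)
  nk_freq: 2.22 (0.69)
  ck_freq: 4.30 (0.27)
  ck_speed_median: 81.23 (9.84)
  ck_efficiency_pct: 50.00 (16.46)

directionality radar (% of cells):
  forward: 96.0%
  left: 0.0%
  backward: 0.0%
  right: 4.0%
```

The cohort pauses ~87% of the time and performs ~2.2 NK/hr of ~12 μm
each — the pause-dominated, jump-driven signature of saltatory migration —
and 96% of cells travel in the forward dial toward the OB. Comparing it
against a simulated *Fmr1*-null cohort:

```bash
$ saltmig simulate --preset fmr1_null --n-cells 50 --seed 43 -o null.csv
$ saltmig analyze null.csv --group fmr1_null -o out_null/
$ saltmig compare out/cell_metrics.csv out_null/cell_metrics.csv --metric speed --out stats.json
mann_whitney: statistic=2426 p=4.399e-17
```

The mutant preset migrates at ~41 μm/hr median versus ~61 μm/hr for
control — the slowed-down, more erratic regime the presets emulate.

Everything is also available as a library (`saltmig.detect_nk_events`,
`saltmig.compute_cell_metrics`, `saltmig.simulate_cohort`, …); CSV in,
DataFrames out.

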
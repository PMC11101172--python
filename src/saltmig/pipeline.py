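"""End-to-end analysis pipeline: read → split → pair → QC → metrics → radar.

Every run emits a self-describing bundle: per-cell metrics CSV, per-event
CSVs, radar JSON and a ``report.json`` carrying the full configuration,
the SHA-256 of the input table and the cell counts at every stage, so
each number in the outputs is traceable to a config + input hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import tracks as tio
from .config import RunConfig
from .errors import SaltmigError

logger = logging.getLogger("saltmig")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def analyze_records(records, config: RunConfig):
    """Compute per-cell metrics, event tables and the radar for one cohort.

    Metrics rows are emitted only for QC-passing cells; exclusions are
    returned as (cell_id, reason) pairs.
    """
    kept, excluded = kin.qc_filter(
        records, min_duration=config.min_duration, nk_threshold=config.nk_threshold
    )
    metrics_rows, nk_rows, ck_rows = [], [], []
    for cell in kept:
        metrics, nks, cks = kin.compute_cell_metrics(
            cell,
            nk_threshold=config.nk_threshold,
            ck_threshold=config.ck_threshold,
            min_duration=config.min_duration,
            nk_merge=config.nk_merge,
            ck_frame=config.ck_frame,
        )
        metrics_rows.append(metrics)
        for e in nks:
            nk_rows.append(dict(cell_id=cell.cell_id, **asdict(e)))
        for e in cks:
            ck_rows.append(dict(cell_id=cell.cell_id, **asdict(e)))
    metrics_df = kin.metrics_table(metrics_rows) if metrics_rows else pd.DataFrame()
    nk_df = pd.DataFrame(nk_rows)
    ck_df = pd.DataFrame(ck_rows)
    angles = (
        metrics_df["angle_deg"].dropna().to_numpy() if len(metrics_df) else np.array([])
    )
    radar = kin.radar_bin(angles, n_dials=config.n_dials)
    return metrics_df, nk_df, ck_df, radar, excluded


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline per ``config`` and write the output bundle.

    Raises :class:`SaltmigError` when no cell survives QC, reporting how
    many exclusions were ``too_short`` vs ``no_nk``.
    """
    if not config.input:
        raise SaltmigError("config.input is required")
    outdir = Path(config.outdir or ".")
    outdir.mkdir(parents=True, exist_ok=True)

    raw_tracks = tio.read_tracks(config.input, dt_nominal=config.dt)
    n_read = len(raw_tracks)
    split_tracks = []
    for tr in raw_tracks:
        split_tracks.extend(tio.split_at_gaps(tr))
    split_tracks = [tr for tr in split_tracks if len(tr) >= 2]
    records = tio.pair_cells(
        split_tracks,
        group=config.group,
        reference_vector=config.reference_vector,
    )
    logger.info("read %d tracks → %d cells", n_read, len(records))

    metrics_df, nk_df, ck_df, radar, excluded = analyze_records(records, config)
    reasons = [r for _, r in excluded]
    if len(metrics_df) == 0:
        raise SaltmigError(
            "no cell passed QC: "
            f"{reasons.count('too_short')} excluded as too_short, "
            f"{reasons.count('no_nk')} excluded as no_nk"
        )

    metrics_df.to_csv(outdir / "cell_metrics.csv", index=False, float_format="%.6f")
    nk_df.to_csv(outdir / "nk_events.csv", index=False, float_format="%.6f")
    ck_df.to_csv(outdir / "ck_events.csv", index=False, float_format="%.6f")

    radar_payload = {
        "labels": list(radar.labels),
        "dial_edges_deg": [list(e) for e in radar.dial_edges],
        "counts": list(radar.counts),
        "percentages": list(radar.percentages),
        "n_cells": radar.n,
    }
    (outdir / "radar.json").write_text(json.dumps(radar_payload, indent=2))

    report = {
        "config": config.to_dict(),
        "input_sha256": _sha256(config.input),
        "counts": {
            "tracks_read": n_read,
            "cells_paired": len(records),
            "excluded_too_short": reasons.count("too_short"),
            "excluded_no_nk": reasons.count("no_nk"),
            "cells_analyzed": int(len(metrics_df)),
        },
        "exclusions": [{"cell_id": c, "reason": r} for c, r in excluded],
        "outputs": ["cell_metrics.csv", "nk_events.csv", "ck_events.csv", "radar.json"],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    config.save(outdir / "config.yaml")
    logger.info(
        "analyzed %d cells (%d excluded)", len(metrics_df), len(excluded)
    )
    return report


def format_report(outdir: str | Path) -> str:
    """Human-readable summary of a previously written bundle."""
    outdir = Path(outdir)
    report = json.loads((outdir / "report.json").read_text())
    radar = json.loads((outdir / "radar.json").read_text())
    metrics = pd.read_csv(outdir / "cell_metrics.csv")
    lines = [
        f"saltmig analysis bundle: {outdir}",
        f"input sha256: {report['input_sha256'][:16]}…",
        "",
        "stage counts:",
    ]
    for k, v in report["counts"].items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("per-cell metrics, median (IQR):")
    for col in ("speed", "pausing_pct", "sinuosity", "nk_mean_distance", "nk_freq",
                "ck_freq", "ck_speed_median", "ck_efficiency_pct"):
        if col in metrics.columns and metrics[col].notna().any():
            q1, med, q3 = np.nanpercentile(metrics[col].astype(float), [25, 50, 75])
            lines.append(f"  {col}: {med:.2f} ({q3 - q1:.2f})")
    lines.append("")
    lines.append("directionality radar (% of cells):")
    for lab, pct in zip(radar["labels"], radar["percentages"]):
        lines.append(f"  {lab}: {pct:.1f}%")
    return "\n".join(lines)
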
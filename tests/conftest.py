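"""Shared fixtures and track-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from saltmig import CellRecord, Track


def make_track(xy, cell_id="c1", role="nucleus", dt=3.0, t=None):
    xy = np.asarray(xy, dtype=float)
    if t is None:
        t = np.arange(len(xy)) * dt
    return Track(cell_id=cell_id, role=role, t=np.asarray(t, float), xy=xy, dt_nominal=dt)


def make_cell(nuc_xy, cen_xy=None, dt=3.0, ref=(1.0, 0.0), cell_id="c1", group="g"):
    nucleus = make_track(nuc_xy, cell_id=cell_id, role="nucleus", dt=dt)
    centrosome = (
        make_track(cen_xy, cell_id=cell_id, role="centrosome", dt=dt)
        if cen_xy is not None
        else None
    )
    return CellRecord(
        cell_id=cell_id, nucleus=nucleus, centrosome=centrosome,
        group=group, reference_vector=np.asarray(ref, float),
    )


def random_track(rng, n_steps=None, big_step_rate=0.3, cell_id="r"):
    """Random walk mixing sub- and supra-threshold steps, for oracle tests."""
    if n_steps is None:
        n_steps = int(rng.integers(2, 31))
    sizes = np.where(
        rng.random(n_steps) < big_step_rate,
        rng.uniform(6.0, 15.0, n_steps),   # includes near-threshold values
        rng.uniform(0.0, 6.5, n_steps),
    )
    angles = rng.uniform(0, 2 * np.pi, n_steps)
    steps = sizes[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return make_track(xy, cell_id=cell_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
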
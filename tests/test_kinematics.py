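"""Per-cell kinematics: metric definitions, events and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import saltmig as sm
from conftest import make_cell, make_track, random_track

# ---------------------------------------------------------------------------
# elementary metrics


def test_step_displacements_345():
    tr = make_track([[0, 0], [3, 4]])
    assert sm.step_displacements(tr) == pytest.approx([5.0])


def test_step_displacements_stationary():
    tr = make_track(np.zeros((10, 2)))
    assert np.array_equal(sm.step_displacements(tr), np.zeros(9))


def test_step_displacements_matches_pairwise(rng):
    tr = random_track(rng, n_steps=25)
    expected = [math.dist(tr.xy[i], tr.xy[i + 1]) for i in range(len(tr) - 1)]
    assert sm.step_displacements(tr) == pytest.approx(expected)


def test_migration_speed_examples():
    # 10 μm over 6 min → 100 μm/hr
    tr = make_track([[0, 0], [5, 0], [10, 0]])
    assert sm.migration_speed(tr) == pytest.approx(100.0)
    assert sm.migration_speed(make_track(np.zeros((10, 2)))) == 0.0


def test_pausing_fraction_examples():
    assert sm.pausing_fraction(make_track(np.zeros((13, 2)))) == 100.0
    all_big = make_track(np.cumsum(np.tile([8.0, 0.0], (13, 1)), axis=0))
    assert sm.pausing_fraction(all_big) == 0.0
    # 3 of 12 steps above threshold → 75 % pausing
    sizes = [1.0] * 9 + [8.0] * 3
    xy = np.vstack([[0, 0], np.cumsum([[s, 0] for s in sizes], axis=0)])
    assert sm.pausing_fraction(make_track(xy)) == pytest.approx(75.0)


def test_pausing_boundary_step_exactly_threshold_is_pause():
    tr = make_track([[0, 0], [6, 0], [12, 0]])
    assert sm.pausing_fraction(tr) == 100.0
    assert sm.detect_nk_events(tr) == []


def test_sinuosity_examples(caplog):
    straight = make_track([[0, 0], [1, 0], [2, 0], [3, 0]])
    assert sm.sinuosity(straight) == pytest.approx(1.0)
    out_and_back = make_track([[0, 0], [10, 0], [5, 0]])
    assert sm.sinuosity(out_and_back) == pytest.approx(3.0)
    with caplog.at_level("WARNING", logger="saltmig"):
        assert math.isnan(sm.sinuosity(make_track([[0, 0], [1, 0], [0, 0]])))
    assert "undefined" in caplog.text


def test_migration_angle_reference_frame():
    fwd = make_track([[0, 0], [5, 0]])
    back = make_track([[0, 0], [-5, 0]])
    left = make_track([[0, 0], [0, 5]])
    assert sm.migration_angle(fwd, (1, 0)) == pytest.approx(0.0)
    assert sm.migration_angle(back, (1, 0)) == pytest.approx(180.0)
    # counter-clockwise positive: +y is 90° to the left of +x
    assert sm.migration_angle(left, (1, 0)) == pytest.approx(90.0)
    # the reference vector rotates the frame
    assert sm.migration_angle(left, (0, 1)) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# NK events


def test_nk_single_isolated_step():
    xy = np.vstack([[0, 0], np.cumsum([[1, 0], [8, 0], [1, 0]], axis=0)])
    (event,) = sm.detect_nk_events(make_track(xy))
    assert event.n_steps == 1
    assert event.path_distance == pytest.approx(8.0)
    assert event.start_t == 3.0 and event.end_t == 6.0


def test_nk_run_merging_and_off_switch():
    xy = np.vstack([[0, 0], np.cumsum([[1, 0], [7, 0], [0, 7], [1, 0]], axis=0)])
    tr = make_track(xy)
    (event,) = sm.detect_nk_events(tr)
    assert event.n_steps == 2
    assert event.path_distance == pytest.approx(14.0)
    assert event.net_distance == pytest.approx(math.hypot(7, 7))
    unmerged = sm.detect_nk_events(tr, merge=False)
    assert [e.n_steps for e in unmerged] == [1, 1]
    assert sum(e.path_distance for e in unmerged) == pytest.approx(14.0)


def test_nk_threshold_validation():
    with pytest.raises(sm.ParameterError):
        sm.detect_nk_events(make_track(np.zeros((5, 2))), nk_threshold=0.0)


def test_nk_gapped_track_rejected():
    tr = make_track(np.zeros((3, 2)), t=[0.0, 3.0, 12.0])
    with pytest.raises(sm.ParameterError, match="split_at_gaps"):
        sm.detect_nk_events(tr)


def test_nk_union_of_event_steps_is_supra_threshold_set(rng):
    for _ in range(30):
        tr = random_track(rng)
        steps = sm.step_displacements(tr)
        events = sm.detect_nk_events(tr)
        covered = set()
        for e in events:
            i0 = int(round(e.start_t / 3.0))
            covered.update(range(i0, i0 + e.n_steps))
        assert covered == set(np.flatnonzero(steps > 6.0).tolist())


# ---------------------------------------------------------------------------
# QC


def test_qc_filter_reasons():
    too_short = make_cell(np.vstack([[0, 0], [[8, 0]], [[16, 0]]]))  # 6 min
    no_nk = make_cell(np.zeros((21, 2)), cell_id="b")  # 60 min, still
    xy = np.zeros((21, 2))
    xy[11:, 0] = 8.0  # one 8 μm step at 30 min
    good = make_cell(xy, cell_id="c")
    kept, excluded = sm.qc_filter([too_short, no_nk, good])
    assert [c.cell_id for c in kept] == ["c"]
    assert dict(excluded) == {"c1": "too_short", "b": "no_nk"}


def test_qc_boundary_30min_kept():
    xy = np.zeros((11, 2))
    xy[5:, 0] = 7.0
    cell = make_cell(xy)  # exactly 30 min
    kept, excluded = sm.qc_filter([cell])
    assert kept and not excluded


# ---------------------------------------------------------------------------
# radar


def test_radar_cardinal_angles_one_per_dial():
    radar = sm.radar_bin([0.0, 90.0, 180.0, 270.0])
    assert radar.counts == (1, 1, 1, 1)
    assert radar.labels == ("forward", "left", "backward", "right")


def test_radar_all_forward():
    radar = sm.radar_bin([10.0] * 7)
    assert radar.counts == (7, 0, 0, 0)
    assert radar.percentages[0] == pytest.approx(100.0)


def test_radar_boundary_belongs_to_opening_dial():
    radar = sm.radar_bin([315.0, 45.0, 135.0, 225.0])
    assert radar.counts == (1, 1, 1, 1)


def test_radar_uniform_matches_bruteforce(rng):
    from oracles import radar_bruteforce

    angles = rng.uniform(0, 360, size=1000)
    radar = sm.radar_bin(angles)
    assert list(radar.counts) == radar_bruteforce(angles)
    assert sum(radar.percentages) == pytest.approx(100.0, abs=0.01)


# ---------------------------------------------------------------------------
# centrosome series and CK events


def test_separation_series_trivial_cases():
    n = np.zeros((5, 2))
    cell = make_cell(n, cen_xy=n.copy())
    t, sep = sm.centrosome_separation_series(cell)
    assert np.allclose(sep, 0.0)
    cell5 = make_cell(n, cen_xy=n + [3.0, 4.0])
    _, sep5 = sm.centrosome_separation_series(cell5)
    assert np.allclose(sep5, 5.0)


def test_separation_restricted_to_overlap(rng):
    nuc = rng.normal(size=(10, 2))
    cen = rng.normal(size=(4, 2))
    nucleus = make_track(nuc, cell_id="c1", role="nucleus")
    centrosome = sm.Track("c1", "centrosome", np.arange(3, 7) * 3.0, cen, 3.0)
    cell = sm.CellRecord(cell_id="c1", nucleus=nucleus, centrosome=centrosome)
    t, sep = sm.centrosome_separation_series(cell)
    assert np.allclose(t, [9.0, 12.0, 15.0, 18.0])
    expected = [math.dist(cen[k], nuc[3 + k]) for k in range(4)]
    assert sep == pytest.approx(expected)


def _cell_with_separation(sep, nuc_xy=None):
    """Nucleus at rest (or given), centrosome offset by `sep` along +x."""
    sep = np.asarray(sep, dtype=float)
    n = len(sep)
    nuc = np.zeros((n, 2)) if nuc_xy is None else np.asarray(nuc_xy, float)
    cen = nuc + np.column_stack([sep, np.zeros(n)])
    return make_cell(nuc, cen_xy=cen)


def test_ck_simple_excursion():
    cell = _cell_with_separation([1, 1, 4, 1, 1])
    (event,) = sm.detect_ck_events(cell)
    assert event.forward_amplitude == pytest.approx(3.0)
    assert event.backward_amplitude == pytest.approx(3.0)
    assert (event.onset_t, event.peak_t, event.end_t) == (3.0, 6.0, 9.0)


def test_ck_monotone_rise_gives_nothing():
    cell = _cell_with_separation(np.linspace(1, 10, 8))
    assert sm.detect_ck_events(cell) == []


def test_ck_missing_centrosome_is_missing_data():
    cell = make_cell(np.zeros((5, 2)))
    assert sm.detect_ck_events(cell) is None


def test_ck_speed_from_centrosome_path():
    # centrosome walks +1 μm/frame in x while separation rises and falls
    sep = np.array([1.0, 1.0, 4.0, 1.0, 1.0])
    nuc = np.column_stack([np.arange(5.0), np.zeros(5)])
    cell = _cell_with_separation(sep, nuc_xy=nuc)
    (event,) = sm.detect_ck_events(cell)
    # centrosome x over the event: 2 → 6 → 4, path 4 + 2 = 6 μm in 6 min
    assert event.ck_speed == pytest.approx(6.0 / (6.0 / 60.0))


def test_ck_efficiency_windows():
    ck = sm.CKEvent(onset_t=3, peak_t=9, end_t=15, forward_amplitude=3,
                    backward_amplitude=3, ck_speed=10.0)
    nk = sm.NKEvent(start_t=12, end_t=15, n_steps=1, path_distance=8, net_distance=8)
    (flagged,) = sm.classify_ck_efficiency([ck], [nk], track_end_t=60.0)
    assert flagged.efficient is True
    (flagged,) = sm.classify_ck_efficiency([ck], [], track_end_t=60.0)
    assert flagged.efficient is False
    # NK at the peak itself is not "subsequent"
    nk_at_peak = sm.NKEvent(start_t=9, end_t=12, n_steps=1, path_distance=8, net_distance=8)
    (flagged,) = sm.classify_ck_efficiency([ck], [nk_at_peak], track_end_t=60.0)
    assert flagged.efficient is False
    # one NK cannot validate two CKs
    ck2 = sm.CKEvent(onset_t=30, peak_t=33, end_t=39, forward_amplitude=3,
                     backward_amplitude=3, ck_speed=10.0)
    nk_mid = sm.NKEvent(start_t=20, end_t=23, n_steps=1, path_distance=8, net_distance=8)
    flagged = sm.classify_ck_efficiency([ck, ck2], [nk_mid], track_end_t=60.0)
    assert [e.efficient for e in flagged] == [True, False]


# ---------------------------------------------------------------------------
# aggregation


def test_compute_cell_metrics_constructed_example():
    """Two NK events of 8 and 12 μm over one hour → 2 NK/hr, mean 10 μm."""
    xy = np.zeros((21, 2))
    xy[5:, 0] += 8.0
    xy[15:, 0] += 12.0
    cell = make_cell(xy)
    metrics, nks, cks = sm.compute_cell_metrics(cell)
    assert metrics.duration_hr == pytest.approx(1.0)
    assert metrics.nk_count == 2
    assert metrics.nk_freq == pytest.approx(2.0)
    assert metrics.nk_mean_distance == pytest.approx(10.0)
    assert metrics.speed == pytest.approx(20.0)
    assert metrics.pausing_pct == pytest.approx(100.0 * 18 / 20)
    assert metrics.sinuosity == pytest.approx(1.0)
    assert metrics.angle_deg == pytest.approx(0.0)
    assert metrics.qc_pass
    assert metrics.ck_count is None  # no centrosome track


# ---------------------------------------------------------------------------
# properties


@st.composite
def _tracks(draw):
    n = draw(st.integers(min_value=3, max_value=20))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    rng = np.random.default_rng(seed)
    return random_track(rng, n_steps=n - 1)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(_tracks(), st.floats(min_value=0.1, max_value=8.0),
       st.floats(min_value=0.0, max_value=2 * math.pi))
def test_scale_and_rotation_equivariance(track, scale, theta):
    """Doubling coordinates doubles lengths; rotating with the reference
    vector changes nothing."""
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    scaled = sm.Track(track.cell_id, "nucleus", track.t, track.xy * scale, 3.0)
    rotated = sm.Track(track.cell_id, "nucleus", track.t, track.xy @ rot.T, 3.0)
    assert sm.migration_speed(scaled) == pytest.approx(scale * sm.migration_speed(track))
    assert sm.migration_speed(rotated) == pytest.approx(sm.migration_speed(track))
    net = math.dist(track.xy[0], track.xy[-1])
    if net > 1e-9:
        assert sm.sinuosity(scaled) == pytest.approx(sm.sinuosity(track))
        assert sm.sinuosity(rotated) == pytest.approx(sm.sinuosity(track))
        ref = np.array([1.0, 0.0])
        a0 = sm.migration_angle(track, ref)
        a1 = sm.migration_angle(rotated, rot @ ref)
        assert math.isclose(a0, a1, abs_tol=1e-6) or math.isclose(abs(a0 - a1), 360, abs_tol=1e-6)
    # thresholds scale with the coordinates
    ev0 = sm.detect_nk_events(track, 6.0)
    ev1 = sm.detect_nk_events(scaled, 6.0 * scale)
    assert len(ev0) == len(ev1)
    assert [e.n_steps for e in ev0] == [e.n_steps for e in ev1]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(_tracks())
def test_pausing_complements_supra_fraction(track):
    steps = sm.step_displacements(track)
    supra = 100.0 * np.count_nonzero(steps > 6.0) / steps.size
    assert sm.pausing_fraction(track) + supra == pytest.approx(100.0)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(_tracks())
def test_speed_dominates_net_speed_and_sinuosity_consistency(track):
    speed = sm.migration_speed(track)
    net = math.dist(track.xy[0], track.xy[-1])
    net_speed = net / (track.duration_min / 60.0)
    assert speed >= net_speed - 1e-9
    if net > 1e-9:
        assert sm.sinuosity(track) == pytest.approx(speed / net_speed)
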
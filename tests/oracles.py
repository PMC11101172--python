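"""Independent brute-force reference implementations used only by tests.

These re-derive event detection from the definitions with the simplest
possible mechanics (python loops, slice-wide min/max recomputed from
scratch), deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math
from itertools import groupby

import numpy as np


def nk_events_bruteforce(xy: np.ndarray, t: np.ndarray, threshold: float, merge: bool = True):
    """Maximal runs of consecutive steps strictly above ``threshold``.

    Returns tuples (start_t, end_t, n_steps, path_distance, net_distance).
    """
    steps = [
        math.dist(xy[i], xy[i + 1]) for i in range(len(xy) - 1)
    ]
    flags = [s > threshold for s in steps]
    events = []
    idx = 0
    for flag, run in groupby(flags):
        run = list(run)
        if flag:
            if merge:
                chunks = [(idx, idx + len(run))]
            else:
                chunks = [(k, k + 1) for k in range(idx, idx + len(run))]
            for i, j in chunks:
                events.append(
                    (
                        float(t[i]),
                        float(t[j]),
                        j - i,
                        float(sum(steps[i:j])),
                        float(math.dist(xy[i], xy[j])),
                    )
                )
        idx += len(run)
    return events


def ck_events_bruteforce(s: np.ndarray, threshold: float):
    """Greedy left-to-right rise/fall excursions, via slice-wide min/max.

    Returns (onset_idx, peak_idx, close_idx) triples: the onset is the
    first running-minimum point before the series has risen more than
    ``threshold`` above it (last occurrence of that minimum), the close
    is the first later point more than ``threshold`` below the maximum
    since onset, the peak is that maximum (first occurrence).
    """
    s = np.asarray(s, dtype=float)
    n = s.size
    events = []
    p0 = 0
    while p0 < n - 1:
        rise_at = None
        for m in range(p0 + 1, n):
            if s[m] - s[p0:m + 1].min() > threshold:
                rise_at = m
                break
        if rise_at is None:
            break
        window = s[p0:rise_at + 1]
        onset = p0 + (window.size - 1 - int(np.argmin(window[::-1])))  # last min
        close = None
        for m in range(rise_at, n):
            if s[onset:m + 1].max() - s[m] > threshold:
                close = m
                break
        if close is None:
            break
        peak = onset + int(np.argmax(s[onset:close + 1]))
        events.append((onset, peak, close))
        p0 = close
    return events


def efficiency_bruteforce(ck_windows, nk_starts):
    """CK k is efficient iff any NK start lies in its (peak, next-onset] window.

    ``ck_windows`` are (peak_t, window_end_t) pairs in time order; windows
    of consecutive CKs are disjoint by construction, so existence is
    equivalent to the one-NK-per-CK greedy matching.
    """
    return [any(lo < s <= hi for s in nk_starts) for lo, hi in ck_windows]


def radar_bruteforce(angles, n_dials=4):
    """Count angles per dial by direct interval membership tests."""
    width = 360.0 / n_dials
    counts = [0] * n_dials
    for a in angles:
        for i in range(n_dials):
            lo = (i * width - width / 2.0) % 360.0
            hi = (i * width + width / 2.0) % 360.0
            inside = (lo <= a < hi) if lo < hi else (a >= lo or a < hi)
            if inside:
                counts[i] += 1
                break
    return counts


def kruskal_h_closed_form(groups):
    """H = 12/(N(N+1)) Σ n_i R̄_i² − 3(N+1), for tie-free data."""
    pooled = sorted(x for g in groups for x in g)
    assert len(set(pooled)) == len(pooled), "closed form assumes no ties"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(pooled)
    h = 0.0
    for g in groups:
        r_mean = sum(rank[v] for v in g) / len(g)
        h += len(g) * r_mean**2
    return 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)


def chi2_2x2_closed_form(a, b, c, d):
    """(ad − bc)² N / (row and column product) for a 2x2 table."""
    n = a + b + c + d
    return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
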
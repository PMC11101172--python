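"""Nonparametric group statistics for per-cell migration metrics.

The reported analysis path for every migration comparison is
nonparametric: Kruskal-Wallis ANOVA on ranks followed by Dunn's post hoc
test (Benjamini-Hochberg adjusted), Mann-Whitney rank-sum tests for
two-group comparisons, Pearson's chi-square and Fisher's exact test for
categorical tables, with results summarised as median (IQR).  A
Shapiro-Wilk / Levene normality report is available but does not switch
the pipeline onto parametric tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError


@dataclass
class GroupComparison:
    """Result of one statistical comparison."""

    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    posthoc: pd.DataFrame | None = None
    summaries: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def _as_groups(groups: Sequence[Sequence[float]], labels=None):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if labels is None:
        labels = [f"group_{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ParameterError("labels must match the number of groups")
    if any(a.size == 0 for a in arrays):
        raise ParameterError("every group needs at least one non-missing value")
    return arrays, list(labels)


def summarize(groups: Sequence[Sequence[float]], labels=None) -> pd.DataFrame:
    """Per-group n, median, Q1, Q3 and IQR (linear-interpolation quantiles)."""
    arrays, labels = _as_groups(groups, labels)
    rows = []
    for lab, a in zip(labels, arrays):
        q1, med, q3 = np.percentile(a, [25, 50, 75])
        rows.append(dict(group=lab, n=a.size, median=med, q1=q1, q3=q3, iqr=q3 - q1))
    return pd.DataFrame(rows)


def kruskal_wallis(groups: Sequence[Sequence[float]], labels=None) -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) against a chi-square with k−1 df."""
    arrays, labels = _as_groups(groups, labels)
    if len(arrays) < 2:
        raise ParameterError("need at least 2 groups")
    h, p = sps.kruskal(*arrays)
    return GroupComparison(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        df=len(arrays) - 1,
        summaries=summarize(arrays, labels),
    )


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels=None,
    adjust: str = "benjamini_hochberg",
) -> pd.DataFrame:
    """Dunn's post hoc z tests on mean ranks, with tie correction.

    For groups i, j the statistic is

        z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) (1/n_i + 1/n_j)),

    where T = Σ(t³ − t) / (12(N − 1)) sums over tied values in the pooled
    sample.  Two-sided p-values are adjusted with Benjamini-Hochberg.
    """
    if adjust not in ("benjamini_hochberg", "none"):
        raise ParameterError(f"unknown adjustment {adjust!r}")
    arrays, labels = _as_groups(groups, labels)
    if len(arrays) < 2:
        raise ParameterError("need at least 2 groups")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(dict(group_a=labels[i], group_b=labels[j], z=z, p_raw=min(p, 1.0)))
    table = pd.DataFrame(rows)
    if adjust == "benjamini_hochberg":
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    else:
        table["p_adj"] = table["p_raw"]
    return table


def mann_whitney(a: Sequence[float], b: Sequence[float], labels=None) -> GroupComparison:
    """Two-sided Mann-Whitney U.

    Exact enumeration for small samples (both n ≤ 20, no ties); otherwise
    the normal approximation with tie correction.
    """
    (xa, xb), labels = _as_groups([a, b], labels)
    pooled = np.concatenate([xa, xb])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(xa.size, xb.size) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return GroupComparison(
        test_name="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summaries=summarize([xa, xb], labels),
        extras={"method": method},
    )


def chi2_contingency(table: Sequence[Sequence[float]]) -> GroupComparison:
    """Pearson chi-square on an RxC count table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ParameterError("need an RxC table with R, C >= 2")
    if (tab < 0).any():
        raise ParameterError("counts must be non-negative")
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
    return GroupComparison(
        test_name="chi2_pearson", statistic=float(chi2), p_value=float(p), df=int(df)
    )


def _log_table_prob(tab: np.ndarray) -> float:
    """log multivariate hypergeometric probability of a table given its margins."""
    r = tab.sum(axis=1)
    c = tab.sum(axis=0)
    n = tab.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(tab + 1).sum()
    )


def fisher_exact(
    table: Sequence[Sequence[float]],
    mode: str = "auto",
    n_mc: int = 100_000,
    seed: int = 0,
) -> GroupComparison:
    """Fisher's exact test on an RxC table.

    2x2 tables use the exact two-sided hypergeometric test (sum of tables
    at most as probable as the observed one).  Larger tables — or
    ``mode="montecarlo"`` — use a Monte-Carlo test over tables sampled
    from the null conditional distribution with both margins fixed; the
    p-value estimate ``(1 + #{P(T) <= P(obs)}) / (n_mc + 1)`` is reported
    with its Monte-Carlo standard error in ``extras``.
    """
    tab = np.asarray(table)
    if not np.allclose(tab, np.round(tab)):
        raise ParameterError("Fisher's exact test needs integer counts")
    tab = np.round(tab).astype(np.int64)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ParameterError("need an RxC table with R, C >= 2")
    if (tab < 0).any():
        raise ParameterError("counts must be non-negative")
    if mode not in ("auto", "exact_2x2", "montecarlo"):
        raise ParameterError(f"unknown mode {mode!r}")
    if mode == "exact_2x2" and tab.shape != (2, 2):
        raise ParameterError("exact_2x2 mode needs a 2x2 table")
    use_exact = tab.shape == (2, 2) and mode in ("auto", "exact_2x2")
    if use_exact:
        _, p = sps.fisher_exact(tab, alternative="two-sided")
        return GroupComparison(test_name="fisher_exact", statistic=float("nan"),
                               p_value=float(p))
    if n_mc < 1000:
        raise ParameterError("n_mc must be >= 1000")
    rng = np.random.default_rng(seed)
    r, c = tab.shape
    row_labels = np.repeat(np.arange(r), tab.sum(axis=1))
    col_labels = np.repeat(np.arange(c), tab.sum(axis=0))
    log_p_obs = _log_table_prob(tab)
    hits = 0
    chunk = 20_000
    done = 0
    flat_bins = r * c
    while done < n_mc:
        b = min(chunk, n_mc - done)
        # b independent permutations of the column labels via random keys
        keys = rng.random((b, col_labels.size))
        perm = col_labels[np.argsort(keys, axis=1)]
        cell = row_labels[None, :] * c + perm
        counts = np.zeros((b, flat_bins), dtype=np.int64)
        np.add.at(counts, (np.repeat(np.arange(b), col_labels.size), cell.ravel()), 1)
        log_p = (
            gammaln(tab.sum(axis=1) + 1).sum()
            + gammaln(tab.sum(axis=0) + 1).sum()
            - gammaln(tab.sum() + 1)
            - gammaln(counts + 1).sum(axis=1)
        )
        hits += int((log_p <= log_p_obs + 1e-9).sum())
        done += b
    p_hat = (1.0 + hits) / (n_mc + 1.0)
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_mc))
    return GroupComparison(
        test_name="fisher_montecarlo",
        statistic=float("nan"),
        p_value=float(p_hat),
        extras={"mc_se": se, "n_mc": n_mc, "seed": seed},
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normality_report(groups: Sequence[Sequence[float]], labels=None) -> pd.DataFrame:
    """Shapiro-Wilk per group plus a pooled Levene test (informational only).

    The pipeline always reports nonparametric statistics; this mirrors the
    gating tests without letting them switch the analysis path.
    """
    arrays, labels = _as_groups(groups, labels)
    rows = []
    for lab, a in zip(labels, arrays):
        if a.size >= 3 and np.unique(a).size > 1:
            w, p = sps.shapiro(a)
        else:
            w, p = float("nan"), float("nan")
        rows.append(dict(group=lab, shapiro_w=w, shapiro_p=p))
    df = pd.DataFrame(rows)
    if len(arrays) >= 2 and all(a.size >= 2 for a in arrays):
        stat, p = sps.levene(*arrays, center="median")
        df.attrs["levene_stat"] = float(stat)
        df.attrs["levene_p"] = float(p)
    return df


def compare_metric(
    groups: Sequence[Sequence[float]], labels=None, mc_seed: int = 0
) -> GroupComparison:
    """Canonical comparison for one metric across >= 2 groups.

    Two groups: Mann-Whitney.  More: Kruskal-Wallis with Dunn/BH post hoc.
    """
    arrays, labels = _as_groups(groups, labels)
    if len(arrays) == 2:
        return mann_whitney(arrays[0], arrays[1], labels)
    result = kruskal_wallis(arrays, labels)
    result.posthoc = dunn_posthoc(arrays, labels)
    return result
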
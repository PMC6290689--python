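"""Cohort-level statistics for the inter-team variability analysis.

Dispersion is summarized nonparametrically: median, interquartile range
(Q1-Q3) and the quartile coefficient of dispersion CoD = (Q3-Q1)/(Q3+Q1),
extended to the 10th/90th percentiles since the IQR by construction covers
only half the cohort.  Hypothesis testing follows the nonparametric route:
D'Agostino-Pearson omnibus normality screening, then Kruskal-Wallis with
Dunn's post hoc comparisons at alpha = 0.05.

The default quantile estimator is linear interpolation at rank p*(n+1)
(the "exclusive" method used by GraphPad Prism); the estimator is an
argument so alternatives can be compared.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .io_formats import MetricsTable

__all__ = [
    "SummaryStats",
    "RankConsensus",
    "quantile",
    "summary",
    "cod",
    "case_average",
    "percent_diff",
    "dagostino_pearson",
    "kruskal_wallis_dunn",
    "DunnResult",
    "rank_cases",
    "consensus",
    "ols_check",
]

_QUANTILE_METHODS = {"exclusive": "weibull", "inclusive": "median_unbiased",
                     "linear": "linear"}


def quantile(values: np.ndarray, p: float, method: str = "exclusive") -> float:
    """Quantile by linear interpolation at rank p*(n+1), clamped to [1, n].

    ``method='exclusive'`` (default) matches GraphPad Prism's percentile
    convention; 'linear' is the numpy default (rank 1 + p*(n-1));
    'inclusive' is the median-unbiased estimator.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise InsufficientDataError("no values")
    if method == "exclusive":
        r = np.clip(p * (n + 1), 1.0, float(n)) - 1.0
        lo = int(np.floor(r))
        hi = min(lo + 1, n - 1)
        frac = r - lo
        return float(x[lo] * (1 - frac) + x[hi] * frac)
    try:
        np_method = _QUANTILE_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown quantile method {method!r}") from None
    return float(np.quantile(x, p, method=np_method))


def cod(q1: float, q3: float) -> float:
    """Quartile coefficient of dispersion (Q3-Q1)/(Q3+Q1), dimensionless."""
    return (q3 - q1) / (q3 + q1)


@dataclass
class SummaryStats:
    """Nonparametric dispersion summary of one parameter over one grouping.

    ``cod`` is NaN (with ``cod_defined=False``) when Q1+Q3 = 0.
    """

    n: int
    median: float
    q1: float
    q3: float
    cod: float
    p10: float
    p90: float
    cod_defined: bool = True


def summary(values: Iterable[float], method: str = "exclusive") -> SummaryStats:
    """Median, quartiles, CoD and 10th/90th percentiles of a sample (n >= 3)."""
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 finite values, got {len(x)}")
    q1 = quantile(x, 0.25, method)
    q3 = quantile(x, 0.75, method)
    denom = q1 + q3
    defined = denom != 0
    return SummaryStats(
        n=len(x),
        median=quantile(x, 0.5, method),
        q1=q1, q3=q3,
        cod=cod(q1, q3) if defined else float("nan"),
        p10=quantile(x, 0.10, method),
        p90=quantile(x, 0.90, method),
        cod_defined=bool(defined),
    )


def case_average(table: MetricsTable, parameter: str) -> pd.Series:
    """Per-team mean of a parameter across cases ("case-average" statistic).

    A team missing the parameter for *any* case is excluded entirely — the
    Challenge's missing-data rule, which is why velocity-derived and
    WSS-derived case-average N differ in an incomplete cohort.
    """
    wide = table.pivot(parameter)
    all_cases = table.cases
    wide = wide.reindex(columns=all_cases)
    complete = wide.dropna(axis=0, how="any")
    return complete.mean(axis=1)


def percent_diff(a: float, b: float) -> float:
    """Symmetric percent difference 200*|b-a|/(a+b): |b-a| over mean(a, b)."""
    if a + b <= 0:
        raise ValueError("percent_diff requires a + b > 0")
    return 200.0 * abs(b - a) / (a + b)


def dagostino_pearson(values: Iterable[float]) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test: (K^2, p).

    K^2 combines the skewness and kurtosis z-scores; p comes from a chi^2
    distribution with 2 df.  Requires n >= 8.
    """
    x = np.asarray(list(values), dtype=float)
    if len(x) < 8:
        raise InsufficientDataError(
            f"omnibus test needs n >= 8, got {len(x)}")
    k2, p = stats.normaltest(x)
    return float(k2), float(p)


@dataclass
class DunnResult:
    """Kruskal-Wallis H and p with Dunn's pairwise post hoc comparisons.

    ``pairwise`` maps (group_i, group_j) -> (z, p_unadjusted, p_adjusted).
    """

    h: float
    p: float
    pairwise: dict[tuple, tuple[float, float, float]]
    adjustment: str


def _dunn_pairwise(groups: Sequence[np.ndarray], labels: Sequence,
                   adjustment: str) -> dict:
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + len(g)].mean()))
        start += len(g)
    pairs = list(itertools.combinations(range(len(groups)), 2))
    raw = {}
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_un = 2.0 * stats.norm.sf(abs(z))
        raw[(labels[i], labels[j])] = (float(z), float(p_un))
    m = len(pairs)
    keys = list(raw)
    p_un = np.array([raw[k][1] for k in keys])
    if adjustment == "bonferroni":
        p_adj = np.minimum(p_un * m, 1.0)
    elif adjustment == "holm":
        order = np.argsort(p_un)
        p_adj = np.empty_like(p_un)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * p_un[idx])
            p_adj[idx] = min(running, 1.0)
    elif adjustment == "none":
        p_adj = p_un
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return {k: (raw[k][0], raw[k][1], float(pa)) for k, pa in zip(keys, p_adj)}


def kruskal_wallis_dunn(groups: Mapping | Sequence[Sequence[float]],
                        adjustment: str = "bonferroni") -> DunnResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's post hoc z-tests.

    ``groups`` is a mapping label -> values or a sequence of samples.
    Dunn p-values are familywise-adjusted over all pairwise comparisons
    (Bonferroni by default, Prism's convention; 'holm' and 'none' are
    available).  A degenerate input in which every value is identical
    returns H = 0, p = 1 rather than an error.
    """
    if isinstance(groups, Mapping):
        labels = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = list(range(len(data)))
    if len(data) < 2 or any(len(g) < 1 for g in data):
        raise InsufficientDataError("need >= 2 non-empty groups")
    if sum(len(g) for g in data) < 5:
        raise InsufficientDataError("need total n >= 5")
    pooled = np.concatenate(data)
    if np.all(pooled == pooled[0]):
        pairwise = {(labels[i], labels[j]): (0.0, 1.0, 1.0)
                    for i, j in itertools.combinations(range(len(data)), 2)}
        return DunnResult(h=0.0, p=1.0, pairwise=pairwise,
                          adjustment=adjustment)
    h, p = stats.kruskal(*data)
    pairwise = _dunn_pairwise(data, labels, adjustment)
    return DunnResult(h=float(h), p=float(p), pairwise=pairwise,
                      adjustment=adjustment)


@dataclass
class RankConsensus:
    """Team rank-ordering consensus for one parameter.

    ``counts`` is a (case x rank) table of how many teams put each case at
    each rank (rank 1 = lowest value).  ``majority`` maps rank -> case label
    when strictly more than half of the ranked teams agree, else None.
    ``experience_counts`` maps (case, rank, experience) -> count when team
    metadata is available.
    """

    counts: pd.DataFrame
    majority: dict[int, str | None]
    n_teams: int
    experience_counts: dict[tuple, int]
    ties: dict[str, bool]


def rank_cases(table: MetricsTable, parameter: str) -> pd.DataFrame:
    """Per-team rank permutation of cases (1 = lowest value of parameter).

    Teams missing the parameter for any case are excluded.  Ties are broken
    deterministically by case label order; tied teams are flagged in the
    ``_tie`` column.
    """
    wide = table.pivot(parameter).reindex(columns=table.cases)
    wide = wide.dropna(axis=0, how="any")
    out = {}
    ties = {}
    for team, row in wide.iterrows():
        vals = row.values.astype(float)
        order = np.lexsort((np.arange(len(vals)), vals))
        ranks = np.empty(len(vals), dtype=int)
        ranks[order] = np.arange(1, len(vals) + 1)
        out[team] = ranks
        ties[team] = bool(len(np.unique(vals)) < len(vals))
    df = pd.DataFrame.from_dict(out, orient="index", columns=wide.columns)
    df["_tie"] = pd.Series(ties)
    return df


def consensus(ranks: pd.DataFrame, meta=None) -> RankConsensus:
    """Aggregate per-team rank permutations into a consensus table.

    Each team contributes exactly one case per rank, so row and column sums
    of ``counts`` all equal the number of ranked teams.  Majority at a rank
    requires *strictly* more than half of the ranked teams.
    """
    tie_flags = ranks["_tie"].to_dict() if "_tie" in ranks else {}
    rk = ranks.drop(columns=["_tie"], errors="ignore")
    cases = list(rk.columns)
    n_teams = len(rk)
    n_ranks = len(cases)
    counts = pd.DataFrame(0, index=cases, columns=range(1, n_ranks + 1))
    exp_counts: dict[tuple, int] = {}
    for team, row in rk.iterrows():
        exp = None
        if meta is not None and team in meta:
            exp = meta[team].experience
        for case_label, rank in row.items():
            counts.loc[case_label, int(rank)] += 1
            if exp is not None:
                key = (case_label, int(rank), exp)
                exp_counts[key] = exp_counts.get(key, 0) + 1
    majority: dict[int, str | None] = {}
    for rank in counts.columns:
        col = counts[rank]
        top = col.idxmax()
        majority[int(rank)] = top if col[top] * 2 > n_teams else None
    return RankConsensus(counts=counts, majority=majority, n_teams=n_teams,
                         experience_counts=exp_counts, ties=tie_flags)


def ols_check(x: Iterable[float], y: Iterable[float]) -> tuple[float, float, float]:
    """Ordinary least squares y = slope*x + intercept; returns (slope,
    intercept, R^2) with R^2 the squared Pearson correlation.

    Used as the reported-vs-computed quality-assurance regression.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if len(xa) < 3:
        raise InsufficientDataError("need n >= 3")
    if np.var(xa) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(xa, ya)
    r2 = 0.0 if np.var(ya) == 0 else float(res.rvalue) ** 2
    return float(res.slope), float(res.intercept), r2
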
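"""Nonparametric statistical layer.

Continuous morphometric measurements are summarized as median and
interquartile range, normalized as percent of the control-group median, and
compared with the Kruskal-Wallis rank-sum test followed by Dunn's pairwise
post-hoc z-tests.  Categorical covariates are compared with Pearson's
chi-square test, Bonferroni-corrected over the requested pairwise
comparisons.  Dual-observer agreement is scored with Cohen's kappa on
categorized readings, banded as poor / fair / moderate / substantial /
almost perfect.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, NormalizationError

ALPHA = 0.05

#: Agreement bands for Cohen's kappa (upper-inclusive interval edges).
KAPPA_BANDS = (
    (0.80, "almost_perfect"),
    (0.60, "substantial"),
    (0.40, "moderate"),
    (0.20, "fair"),
)


@dataclass
class GroupSummary:
    group: str | None
    n: int
    median: float
    iqr: tuple[float, float]
    percent_of_control_median: float


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    post_hoc: list[PairwiseResult] = field(default_factory=list)
    alpha: float = ALPHA
    method: str = ""
    warnings: list[str] = field(default_factory=list)


@dataclass
class KappaResult:
    kappa: float
    ci95: tuple[float, float]
    band: str
    p_observed: float
    p_expected: float
    n: int
    flagged: bool = False


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize(
    values: Sequence[float], control_values: Sequence[float], group: str | None = None
) -> GroupSummary:
    """Median, IQR (linear-interpolation quartiles) and percent-of-control.

    The control median is pegged to 100%, so passing the control group's own
    values yields exactly 100.
    """
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if values.size == 0 or control.size == 0:
        raise ConfigurationError("summarize requires non-empty value lists")
    control_median = float(np.median(control))
    if control_median == 0:
        raise NormalizationError("control median is zero; percent-of-control undefined")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return GroupSummary(
        group=group,
        n=int(values.size),
        median=float(med),
        iqr=(float(q1), float(q3)),
        percent_of_control_median=100.0 * float(med) / control_median,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


def _kw_statistic(ranks: np.ndarray, sizes: Sequence[int], tie_correction: float) -> float:
    n = ranks.size
    h = 0.0
    start = 0
    for ni in sizes:
        h += ranks[start : start + ni].sum() ** 2 / ni
        start += ni
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_correction if tie_correction > 0 else 0.0


def _tie_correction(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    n = pooled.size
    return 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n)) if n > 1 else 1.0


def _exact_kw_pvalue(groups_values: list[np.ndarray]) -> float:
    """Exact permutation p-value: the fraction of distinct assignments of the
    pooled values to the group sizes with H at least the observed H."""
    pooled = np.concatenate(groups_values)
    sizes = [len(g) for g in groups_values]
    ranks = sps.rankdata(pooled)
    tie_c = _tie_correction(pooled)
    observed = _kw_statistic(
        np.concatenate([ranks[_indices_of(groups_values, pooled)[i]] for i in range(len(sizes))]),
        sizes,
        tie_c,
    )

    n = pooled.size
    indices = list(range(n))
    count = 0
    total = 0
    for assignment in _partitions(indices, sizes):
        perm_ranks = np.concatenate([ranks[list(part)] for part in assignment])
        h = _kw_statistic(perm_ranks, sizes, tie_c)
        total += 1
        if h >= observed - 1e-12:
            count += 1
    return count / total


def _indices_of(groups_values: list[np.ndarray], pooled: np.ndarray) -> list[list[int]]:
    out = []
    start = 0
    for g in groups_values:
        out.append(list(range(start, start + len(g))))
        start += len(g)
    return out


def _partitions(indices: list[int], sizes: Sequence[int]):
    """All ways to split ``indices`` into ordered parts of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    first, rest = sizes[0], sizes[1:]
    for chosen in itertools.combinations(indices, first):
        chosen_set = set(chosen)
        remaining = [i for i in indices if i not in chosen_set]
        for tail in _partitions(remaining, rest):
            yield (chosen,) + tail


def kruskal_wallis_dunn(
    groups: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
    exact_max_n: int = 10,
    alpha: float = ALPHA,
) -> TestResult:
    """Kruskal-Wallis rank-sum test with Dunn's pairwise post-hoc z-tests.

    Tie-corrected H against the chi-square reference; when the pooled sample
    size is at most ``exact_max_n`` the global p-value is computed by exact
    enumeration of all distinct group assignments instead.  Dunn z statistics
    compare mean ranks with the pooled-variance tie correction; pairwise
    p-values are adjusted by ``bonferroni`` (default), ``holm`` or ``none``.
    """
    if adjust not in ("bonferroni", "holm", "none"):
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    names = list(groups)
    if len(names) < 2:
        raise ConfigurationError("need at least 2 groups")
    values = [np.asarray(groups[g], dtype=float) for g in names]
    if any(v.size < 2 for v in values):
        raise ConfigurationError("each group needs at least 2 values")
    sizes = [v.size for v in values]
    pooled = np.concatenate(values)
    n = pooled.size
    df = len(names) - 1

    if np.all(pooled == pooled[0]):
        post = [
            PairwiseResult(pair=(a, b), statistic=0.0, p_raw=1.0, p_adjusted=1.0)
            for a, b in itertools.combinations(names, 2)
        ]
        return TestResult(statistic=0.0, p_value=1.0, df=df, post_hoc=post, alpha=alpha,
                          method="kruskal-wallis (degenerate: all values identical)")

    ranks = sps.rankdata(pooled)
    tie_c = _tie_correction(pooled)
    h = _kw_statistic(ranks, sizes, tie_c)
    if n <= exact_max_n:
        p = _exact_kw_pvalue(values)
        method = "kruskal-wallis (exact permutation)"
    else:
        # cross-checkable against scipy.stats.kruskal
        p = float(sps.chi2.sf(h, df))
        method = "kruskal-wallis (chi-square approximation)"

    # Dunn's test on mean ranks
    mean_ranks = {}
    start = 0
    for name, ni in zip(names, sizes):
        mean_ranks[name] = ranks[start : start + ni].mean()
        start += ni
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        se = math.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        raw.append((z, 2.0 * float(sps.norm.sf(abs(z)))))

    adjusted = _adjust_pvalues([p_ for _, p_ in raw], adjust)
    post = [
        PairwiseResult(pair=pair, statistic=z, p_raw=p_raw, p_adjusted=p_adj)
        for pair, (z, p_raw), p_adj in zip(pairs, raw, adjusted)
    ]
    return TestResult(statistic=float(h), p_value=p, df=df, post_hoc=post, alpha=alpha, method=method)


def _adjust_pvalues(pvalues: Sequence[float], method: str) -> list[float]:
    m = len(pvalues)
    if method == "none" or m == 0:
        return list(pvalues)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvalues]
    # holm step-down
    order = np.argsort(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


# ---------------------------------------------------------------------------
# chi-square with Bonferroni
# ---------------------------------------------------------------------------


def chi_square_bonferroni(
    table: np.ndarray | Mapping[str, Sequence[int]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    alpha: float = ALPHA,
) -> TestResult:
    """Pearson chi-square tests with Bonferroni correction over comparisons.

    ``table`` maps group -> category counts (or is a 2-D count array, rows as
    groups).  Each comparison extracts the two groups' rows and tests the
    2 x C subtable without continuity correction; adjusted p = min(1, raw * m).
    Comparisons whose subtable has an all-zero row or column are excluded
    with a warning.  The headline statistic/p are for the full table.
    """
    if isinstance(table, Mapping):
        names = list(table)
        counts = np.asarray([table[g] for g in names], dtype=float)
    else:
        counts = np.asarray(table, dtype=float)
        names = [str(i) for i in range(counts.shape[0])]
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ConfigurationError("need at least a 2x2 contingency table")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ConfigurationError("counts must be non-negative integers")

    # headline statistic on the table restricted to informative rows/columns
    full_warnings: list[str] = []
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    trimmed = counts[row_keep][:, col_keep]
    if trimmed.shape != counts.shape:
        msg = "all-zero rows/columns dropped from the overall chi-square table"
        warnings.warn(msg, stacklevel=2)
        full_warnings.append(msg)
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        chi2, p, df = float("nan"), float("nan"), 0
        full_warnings.append("overall test undefined after dropping empty rows/columns")
    else:
        chi2, p, df, _ = sps.chi2_contingency(trimmed, correction=False)
    result = TestResult(statistic=float(chi2), p_value=float(p), df=int(df),
                        alpha=alpha, method="pearson chi-square", warnings=full_warnings)

    if comparisons:
        valid = []
        for a, b in comparisons:
            sub = counts[[names.index(a), names.index(b)], :]
            sub = sub[:, sub.sum(axis=0) > 0]  # drop empty categories
            if sub.shape[1] < 2 or np.any(sub.sum(axis=1) == 0):
                msg = f"comparison {a} vs {b} excluded: all-zero row/column"
                warnings.warn(msg, stacklevel=2)
                result.warnings.append(msg)
                continue
            c2, praw, _, _ = sps.chi2_contingency(sub, correction=False)
            valid.append(((a, b), float(c2), float(praw)))
        m = len(valid)
        for pair, c2, praw in valid:
            result.post_hoc.append(
                PairwiseResult(pair=pair, statistic=c2, p_raw=praw, p_adjusted=min(1.0, praw * m))
            )
    return result


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------


def kappa_band(kappa: float) -> str:
    for edge, name in KAPPA_BANDS:
        if kappa > edge:
            return name
    return "poor"


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> KappaResult:
    """Cohen's kappa between two raters with a large-sample 95% CI.

    kappa = (p_o - p_e) / (1 - p_e); SE = sqrt(p_o (1 - p_o) / (n (1-p_e)^2)).
    When both raters are constant and identical (p_e = 1, kappa undefined)
    the agreement is reported as 1.0 and flagged.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size != b.size or a.size < 2:
        raise ConfigurationError("need two equal-length rating lists with >= 2 items")
    categories = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in categories)
    )
    if p_e >= 1.0 - 1e-12:
        return KappaResult(kappa=1.0, ci95=(1.0, 1.0), band=kappa_band(1.0),
                           p_observed=p_o, p_expected=p_e, n=n, flagged=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(max(p_o * (1.0 - p_o), 0.0) / (n * (1.0 - p_e) ** 2))
    lo, hi = max(-1.0, kappa - 1.96 * se), min(1.0, kappa + 1.96 * se)
    return KappaResult(kappa=float(kappa), ci95=(lo, hi), band=kappa_band(kappa),
                       p_observed=p_o, p_expected=p_e, n=n)


def bin_by_quantiles(
    values_a: Sequence[float], values_b: Sequence[float], n_bins: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize two raters' continuous readings into pooled-quantile bins
    (tertiles by default) with common edges, for kappa on continuous data."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(a, edges), np.digitize(b, edges)
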
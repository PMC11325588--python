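"""Alpha/beta diversity and the univariate group tests.

Alpha diversity uses Hill numbers (effective species numbers)

    D_q = (sum_i p_i^q)^(1/(1-q)),   D_1 = exp(-sum_i p_i ln p_i),

so q=0 is richness, q=1 the exponential of Shannon entropy and q=2 the
inverse Simpson concentration.  Beta diversity is Bray-Curtis
dissimilarity, BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i).  Group
contrasts use the Wilcoxon rank-sum test and one-way ANOVA followed by
Duncan's multiple range test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import relative_abundance

__all__ = [
    "hill_number",
    "alpha_table",
    "bray_curtis",
    "wilcoxon_rank_sum",
    "anova_duncan",
    "DuncanResult",
    "write_distance_matrix",
]


def hill_number(counts: np.ndarray, q: float) -> float:
    """Effective number of species of order ``q`` for one sample.

    ``q=0`` counts taxa, ``q=1`` is exp(Shannon entropy), ``q=2`` the
    inverse Simpson index.  Invariant to rescaling all counts by a
    positive constant and to taxon order.
    """
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no diversity")
    p = x[x > 0] / total
    if q == 0:
        return float(p.size)
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def alpha_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Hill numbers at q = 0, 1, 2.

    Columns: ``richness`` (q=0), ``shannon_hill`` (q=1, the
    effective-species form of Shannon entropy) and ``inv_simpson``
    (q=2).  For any sample richness >= shannon_hill >= inv_simpson >= 1.
    """
    rows = {
        s: {
            "richness": hill_number(row.to_numpy(), 0),
            "shannon_hill": hill_number(row.to_numpy(), 1),
            "inv_simpson": hill_number(row.to_numpy(), 2),
        }
        for s, row in table.iterrows()
    }
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.index]


def bray_curtis(table: pd.DataFrame, use_relative: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix between samples.

    By default profiles are converted to per-sample relative abundances
    first, so unequal sequencing depth does not masquerade as community
    turnover; set ``use_relative=False`` to use raw counts.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least two samples")
    data = relative_abundance(table) if use_relative else table.astype(float)
    if not use_relative and (table.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(data.to_numpy(), metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in table.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Square symmetric TSV layout with a sample-id header."""
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def wilcoxon_rank_sum(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(W, p)`` where W is the rank sum of ``x`` in the pooled
    midrank ordering.  The p-value is exact (full enumeration) when
    n_x + n_y <= 20 and the pooled data has no ties, otherwise a normal
    approximation with tie and continuity corrections is used.  If the
    pooled data is constant the test is degenerate and p = 1 is
    returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if np.ptp(pooled) == 0:
        warnings.warn("constant pooled data: rank-sum test degenerate, p = 1")
        return w, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return w, float(res.pvalue)


@dataclass
class DuncanResult:
    """One-way ANOVA with Duncan's multiple range letters."""

    f_statistic: float
    p_value: float
    means: pd.Series
    letters: dict[str, str]
    alpha: float


def _duncan_letters(ordered: list[str], ns_range) -> dict[str, str]:
    # maximal runs of mutually non-separated groups share a letter
    k = len(ordered)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and ns_range(i, j + 1):
            j += 1
        if not intervals or j > intervals[-1][1]:
            intervals.append((i, j))
    letters = {g: "" for g in ordered}
    for letter_idx, (i, j) in enumerate(intervals):
        letter = chr(ord("a") + letter_idx)
        for g in ordered[i : j + 1]:
            letters[g] += letter
    return letters


def anova_duncan(
    values, groups, alpha: float = 0.05
) -> DuncanResult:
    """One-way ANOVA plus Duncan's multiple range test.

    Duncan's test orders the group means and compares each pair spanning
    ``p`` ordered means against the studentized-range critical value at
    the protected level 1 - (1 - alpha)^(p-1); with unbalanced groups
    the harmonic mean of the group sizes enters the standard error.
    Groups sharing a letter are not separated at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = {g: values[groups == g] for g in labels}
    if any(s.size < 2 for s in samples.values()):
        raise ValueError("every group needs at least two observations")
    f_stat, p_val = stats.f_oneway(*samples.values())

    n_total = values.size
    a = len(labels)
    df_err = n_total - a
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples.values()) / df_err
    if mse <= 0:
        raise ValueError("zero within-group variance in every group")

    means = pd.Series({g: s.mean() for g, s in samples.items()})
    ordered = list(means.sort_values(ascending=False).index)
    n_h = a / sum(1.0 / samples[g].size for g in labels)
    se = np.sqrt(mse / n_h)

    def critical_range(span: int) -> float:
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        q_crit = stats.studentized_range.ppf(1.0 - alpha_p, span, df_err)
        return float(q_crit) * se

    # protected step-down: a range is significant only if its difference
    # exceeds the critical range AND no enclosing range was declared NS
    k = len(ordered)
    ns = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        r_p = critical_range(span)
        for i in range(0, k - span + 1):
            j = i + span - 1
            diff = means[ordered[i]] - means[ordered[j]]
            if diff <= r_p or (i > 0 and ns[i - 1, j]) or (j < k - 1 and ns[i, j + 1]):
                ns[i, j] = True
    letters = _duncan_letters(ordered, lambda i, j: bool(ns[i, j]))
    return DuncanResult(float(f_stat), float(p_val), means, letters, alpha)
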
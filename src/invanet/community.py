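"""Multivariate habitat contrasts on distance matrices.

NMDS (non-metric multidimensional scaling, Kruskal stress-1), ANOSIM,
PERMANOVA (Adonis), within-group beta-dispersion extraction and
taxon-covariate Spearman correlation tables.

Permutation tests report p = (1 + #{permuted statistic >= observed}) /
(1 + n_perm) so p is never zero; whenever the number of distinct label
assignments is at most 10,000 the full set is enumerated instead and p
is the exact proportion of assignments (the observed one included) with
a statistic at least as large.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from sklearn.manifold import smacof
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "OrdinationResult",
    "PermTestResult",
    "nmds",
    "anosim",
    "permanova",
    "within_group_dissimilarities",
    "taxa_covariate_correlations",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool


@dataclass
class PermTestResult:
    method: str
    statistic: float
    p_value: float
    permutations: int
    exhaustive: bool
    effect_size: float | None = None  # R^2 for PERMANOVA
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "permutations": self.permutations,
            "exhaustive": self.exhaustive,
            "effect_size": self.effect_size,
            "seed": self.seed,
        }


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling used as the metric start for NMDS."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(w)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-12,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Runs ``n_restarts`` random starts plus one classical (metric)
    scaling start through SMACOF with isotonic regression of the fitted
    distances on dissimilarity ranks, and keeps the lowest-stress
    configuration.  Deterministic under ``seed``.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < k + 2:
        raise ValueError("need at least k + 2 samples for NMDS")
    off = d[np.triu_indices(n, 1)]
    if np.ptp(off) == 0:
        warnings.warn(
            "all dissimilarities equal: NMDS degenerate, returning metric "
            "configuration with stress 0"
        )
        coords = _classical_mds(d, k)
        return OrdinationResult(
            pd.DataFrame(coords, index=list(dm.ids)), 0.0, 0, False
        )
    rng = np.random.default_rng(seed)
    inits = [rng.uniform(-1, 1, size=(n, k)) for _ in range(n_restarts)]
    inits.append(_classical_mds(d, k))
    best_coords, best_stress = None, np.inf
    for init in inits:
        coords, stress = smacof(
            d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
        )
        if stress < best_stress:
            best_stress, best_coords = stress, coords
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        pd.DataFrame(best_coords, index=list(dm.ids), columns=cols),
        float(best_stress),
        len(inits),
        True,
    )


def _group_codes(labels) -> tuple[np.ndarray, np.ndarray]:
    codes, uniques = pd.factorize(np.asarray(labels))
    counts = np.bincount(codes)
    if len(uniques) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    return codes, counts


def _n_assignments(counts: np.ndarray) -> int:
    n = int(counts.sum())
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _label_matrix(
    codes: np.ndarray, counts: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """All distinct assignments if few enough, else sampled permutations.

    The observed labelling occupies row 0 in the sampled case only; in
    the exhaustive case every row is a distinct assignment.
    """
    if _n_assignments(counts) <= EXHAUSTIVE_LIMIT:
        mat = np.array(list(multiset_permutations(sorted(codes))), dtype=np.int64)
        return mat, True
    mat = np.empty((n_perm, codes.size), dtype=np.int64)
    for i in range(n_perm):
        mat[i] = rng.permutation(codes)
    return mat, False


def _quadratic_within(mat_sq: np.ndarray, labelmat: np.ndarray, g: int) -> np.ndarray:
    z = (labelmat == g).astype(float)
    return np.einsum("pi,ij,pj->p", z, mat_sq, z) / 2.0


def _permanova_f(d2: np.ndarray, labelmat: np.ndarray, counts: np.ndarray):
    n = d2.shape[0]
    a = counts.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(labelmat.shape[0])
    for g in range(a):
        ss_within += _quadratic_within(d2, labelmat, g) / counts[g]
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):  # zero within-group SS -> F = inf
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def _anosim_r(rank_mat: np.ndarray, labelmat: np.ndarray, counts: np.ndarray):
    n = rank_mat.shape[0]
    m = n * (n - 1) // 2
    w = int(sum(c * (c - 1) // 2 for c in counts))
    b = m - w
    total = rank_mat.sum() / 2.0
    within = np.zeros(labelmat.shape[0])
    for g in range(counts.size):
        within += _quadratic_within(rank_mat, labelmat, g)
    r_within = within / w
    r_between = (total - within) / b
    return (r_between - r_within) / (m / 2.0)


def _perm_p(stats_all: np.ndarray, observed: float, exhaustive: bool, n_perm: int):
    hits = int(np.sum(stats_all >= observed - 1e-12))
    if exhaustive:
        return hits / stats_all.size, stats_all.size
    return (1 + hits) / (1 + n_perm), n_perm


def anosim(
    dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0
) -> PermTestResult:
    """ANOSIM: rank-based contrast of between- vs within-group distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 and midranks for tied dissimilarities; R is 1 when
    every between-group distance exceeds every within-group distance and
    0 when grouping is irrelevant.
    """
    d = np.asarray(dm.data, dtype=float)
    codes, counts = _group_codes(labels)
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(d[iu])
    rank_mat = np.zeros_like(d)
    rank_mat[iu] = ranks
    rank_mat += rank_mat.T

    observed = float(_anosim_r(rank_mat, codes[None, :], counts)[0])
    rng = np.random.default_rng(seed)
    labelmat, exhaustive = _label_matrix(codes, counts, n_perm, rng)
    stats_all = _anosim_r(rank_mat, labelmat, counts)
    p, used = _perm_p(stats_all, observed, exhaustive, n_perm)
    return PermTestResult("ANOSIM", observed, float(p), used, exhaustive, None, seed)


def permanova(
    dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0
) -> PermTestResult:
    """PERMANOVA (Adonis): permutational partitioning of squared distances.

    SS_total = sum_{i<j} d_ij^2 / n, SS_within from within-group pairs
    scaled by group size, pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)),
    effect size R^2 = SS_between / SS_total.
    """
    d = np.asarray(dm.data, dtype=float)
    codes, counts = _group_codes(labels)
    d2 = d**2
    f_obs, r2_obs = _permanova_f(d2, codes[None, :], counts)
    rng = np.random.default_rng(seed)
    labelmat, exhaustive = _label_matrix(codes, counts, n_perm, rng)
    f_all, _ = _permanova_f(d2, labelmat, counts)
    p, used = _perm_p(f_all, float(f_obs[0]), exhaustive, n_perm)
    return PermTestResult(
        "PERMANOVA", float(f_obs[0]), float(p), used, exhaustive, float(r2_obs[0]), seed
    )


def within_group_dissimilarities(dm: DistanceMatrix, labels) -> dict[str, np.ndarray]:
    """All within-group pairwise dissimilarities, per group.

    The habitat beta-dispersion contrast is a Wilcoxon rank-sum test on
    the two returned lists.
    """
    d = np.asarray(dm.data, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")
        sub = d[np.ix_(idx, idx)]
        out[str(g)] = sub[np.triu_indices(idx.size, 1)]
    return out


def taxa_covariate_correlations(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman correlations of taxa (rows of the result) vs covariates.

    Returns (rho, p, q) DataFrames, with Benjamini-Hochberg q-values
    computed across the whole matrix as one family.  Constant covariates
    yield undefined correlations, reported as NaN with a warning.
    """
    if covariates is None:
        covariates = [
            c for c in metadata.columns if pd.api.types.is_numeric_dtype(metadata[c])
        ]
    common = [s for s in abundance.index if s in metadata.index]
    if len(common) < 5:
        raise ValueError("need at least five samples with metadata")
    ab = abundance.loc[common]
    md = metadata.loc[common]
    taxa = list(ab.columns)
    rho = pd.DataFrame(np.nan, index=taxa, columns=covariates)
    pval = pd.DataFrame(np.nan, index=taxa, columns=covariates)
    for cov in covariates:
        y = md[cov].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"covariate {cov!r} is constant; correlations undefined")
            continue
        for t in taxa:
            r, p = stats.spearmanr(ab[t].to_numpy(), y)
            rho.loc[t, cov] = r
            pval.loc[t, cov] = p
    qval = pval.copy()
    flat = pval.to_numpy().ravel()
    mask = ~np.isnan(flat)
    if mask.any():
        q = np.full(flat.shape, np.nan)
        q[mask] = multipletests(flat[mask], method="fdr_bh")[1]
        qval.iloc[:, :] = q.reshape(pval.shape)
    return rho, pval, qval
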
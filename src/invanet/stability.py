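"""Network stability: natural connectivity and community cohesion.

Natural connectivity is the spectral robustness measure

    nc = ln( (1/N) sum_i exp(lambda_i) )

over the eigenvalues of the unsigned, unweighted adjacency matrix; it
decreases monotonically as edges are removed and is tracked here under
random node removal.

Cohesion quantifies how strongly a community's members covary.  Each
taxon's *connectedness* is its mean positive (or negative) pairwise
correlation after subtracting a null expectation from "taxon shuffle"
randomisations that independently permute every partner taxon's
abundances across samples.  A sample's positive cohesion is the
abundance-weighted sum of positive connectedness, C+ = sum_j a_j c+_j
(and analogously C- <= 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigvalsh
from scipy.special import logsumexp
from scipy.stats import rankdata

from .tables import relative_abundance

__all__ = [
    "natural_connectivity",
    "robustness_curve",
    "connectedness",
    "cohesion",
]

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.0, 0.8001, 0.05), 10))
_EXHAUSTIVE_MAX = 8  # 8! = 40,320 permutations


def natural_connectivity(net: nx.Graph, normalized: bool = False) -> float:
    """ln of the mean eigen-exponential of the adjacency spectrum.

    Uses the unsigned, unweighted adjacency and a log-sum-exp so large
    leading eigenvalues cannot overflow.  An edgeless graph scores 0.
    With ``normalized=True`` the value is divided by (N - ln N).
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined for an empty node set")
    a = np.abs(np.sign(nx.to_numpy_array(net, weight="weight")))
    w = eigvalsh(a)
    nc = float(logsumexp(w) - math.log(n))
    if normalized:
        nc /= n - math.log(n)
    return nc


@dataclass
class RobustnessCurve:
    """Mean +/- SD natural connectivity vs fraction of nodes removed."""

    table: pd.DataFrame  # columns: fraction, mean, sd, n_ok
    n_reps: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "fractions": self.table["fraction"].tolist(),
            "mean": self.table["mean"].tolist(),
            "sd": self.table["sd"].tolist(),
            "n_ok": self.table["n_ok"].tolist(),
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


def robustness_curve(
    net: nx.Graph,
    fractions=DEFAULT_FRACTIONS,
    n_reps: int = 50,
    seed: int = 0,
) -> RobustnessCurve:
    """Natural connectivity under random node removal.

    For each fraction f, ``floor(f * N)`` uniformly chosen nodes are
    deleted and natural connectivity recomputed on the induced subgraph,
    ``n_reps`` times; replicates whose subgraph is empty are recorded as
    missing.  Deterministic under ``seed``.
    """
    fractions = np.asarray(list(fractions), dtype=float)
    if np.any((fractions < 0) | (fractions >= 1)):
        raise ValueError("removal fractions must lie in [0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    nodes = list(net.nodes())
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        m = int(math.floor(f * n))
        vals = []
        for _ in range(n_reps):
            if m == 0:
                vals.append(natural_connectivity(net))
                continue
            drop = set(rng.choice(n, size=m, replace=False).tolist())
            keep = [nodes[i] for i in range(n) if i not in drop]
            if not keep:
                vals.append(np.nan)
                continue
            vals.append(natural_connectivity(net.subgraph(keep)))
        vals = np.asarray(vals, dtype=float)
        ok = ~np.isnan(vals)
        rows.append(
            {
                "fraction": float(f),
                "mean": float(np.mean(vals[ok])) if ok.any() else np.nan,
                "sd": float(np.std(vals[ok], ddof=0)) if ok.any() else np.nan,
                "n_ok": int(ok.sum()),
            }
        )
    return RobustnessCurve(pd.DataFrame(rows), n_reps, seed)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    return (x - mu) / sd


def connectedness(
    table: pd.DataFrame,
    n_null: int = 200,
    corr_method: str = "pearson",
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Null-corrected positive/negative connectedness per taxon.

    Correlations are computed on per-sample relative abundances.  The
    null for focal taxon i and partner j is the mean correlation of i's
    observed profile with j's profile permuted across samples; each of
    the ``n_null`` randomisations permutes every partner column
    independently.  With ``exhaustive=True`` all n! sample permutations
    are enumerated instead (only feasible for n <= 8 samples).

    Returns a DataFrame indexed by taxon with columns ``pos`` (mean of
    the positive null-corrected correlations with its partners, 0 if
    none) and ``neg`` (mean of the negative ones, 0 if none).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if corr_method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {corr_method!r}")
    rel = relative_abundance(table)
    x = rel.to_numpy(dtype=float)
    n, t = x.shape
    if t == 1:
        return pd.DataFrame({"pos": [0.0], "neg": [0.0]}, index=table.columns)
    if n < 5 and not exhaustive:
        raise ValueError("need at least five samples (or exhaustive mode)")
    if corr_method == "spearman":
        x = rankdata(x, axis=0)
    var = x.std(axis=0, ddof=0)
    keep = var > 0
    if not keep.all():
        import warnings

        warnings.warn(
            f"{int((~keep).sum())} zero-variance taxa excluded from connectedness"
        )
    z = _standardize(x[:, keep])
    obs = z.T @ z / n

    if exhaustive:
        if n > _EXHAUSTIVE_MAX:
            raise ValueError(
                f"exhaustive null infeasible for n = {n} samples (max {_EXHAUSTIVE_MAX})"
            )
        null_sum = np.zeros_like(obs)
        count = 0
        for perm in permutations(range(n)):
            null_sum += z.T @ z[list(perm)] / n
            count += 1
        null_mean = null_sum / count
    else:
        rng = np.random.default_rng(seed)
        null_sum = np.zeros_like(obs)
        col_idx = np.arange(z.shape[1])
        for _ in range(n_null):
            perm_rows = rng.permuted(
                np.broadcast_to(np.arange(n)[:, None], z.shape).copy(), axis=0
            )
            zp = z[perm_rows, col_idx]
            null_sum += z.T @ zp / n
        null_mean = null_sum / n_null

    corrected = obs - null_mean
    np.fill_diagonal(corrected, 0.0)
    k = corrected.shape[0]
    pos = np.zeros(k)
    neg = np.zeros(k)
    for i in range(k):
        row = np.delete(corrected[i], i)
        p = row[row > 0]
        m = row[row < 0]
        pos[i] = p.mean() if p.size else 0.0
        neg[i] = m.mean() if m.size else 0.0
    out = pd.DataFrame(0.0, index=table.columns, columns=["pos", "neg"])
    kept_ids = table.columns[keep]
    out.loc[kept_ids, "pos"] = pos
    out.loc[kept_ids, "neg"] = neg
    return out


def cohesion(table: pd.DataFrame, conn: pd.DataFrame) -> pd.DataFrame:
    """Per-sample positive and negative cohesion.

    C+ = sum_j a_j c+_j and C- = sum_j a_j c-_j with a_j the taxon's
    relative abundance in the sample, so C+ >= 0 >= C- and both are
    invariant to rescaling a sample's counts.
    """
    if set(table.columns) != set(conn.index):
        raise ValueError("taxon sets of count table and connectedness differ")
    rel = relative_abundance(table)
    conn = conn.loc[rel.columns]
    cpos = rel.to_numpy() @ conn["pos"].to_numpy()
    cneg = rel.to_numpy() @ conn["neg"].to_numpy()
    return pd.DataFrame(
        {"pos_cohesion": cpos, "neg_cohesion": cneg}, index=table.index
    )
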
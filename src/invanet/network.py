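"""Co-occurrence network construction and complexity metrics.

The construction rule: keep ASVs present in (by default) every sample of
a habitat and ranked in the top 200 by relative abundance, correlate all
pairs with Spearman's rho, Benjamini-Hochberg adjust the two-sided
p-values, and draw an edge wherever |rho| > 0.7 and q < 0.05 (both
strict).  Edges carry the correlation as weight and its sign; network
complexity is summarised by node/link counts, average degree, density,
and mean shortest-path length over reachable pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import relative_abundance

__all__ = [
    "CorrelationResult",
    "NetworkMetrics",
    "select_core_taxa",
    "spearman_matrix",
    "bh_adjust",
    "build_network",
    "network_metrics",
]


@dataclass
class CorrelationResult:
    """Taxon x taxon Spearman rho with matching p and BH q matrices.

    ``rho`` is symmetric with unit diagonal; diagonal entries of ``p``
    and ``q`` are NaN (self-correlation is not a test).
    """

    taxon_ids: list[str]
    rho: np.ndarray
    p: np.ndarray
    q: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        ids = self.taxon_ids
        return (
            pd.DataFrame(self.rho, index=ids, columns=ids),
            pd.DataFrame(self.p, index=ids, columns=ids),
            pd.DataFrame(self.q, index=ids, columns=ids),
        )


@dataclass
class NetworkMetrics:
    n_nodes: int  # nodes with at least one edge
    n_taxa_retained: int  # all taxa that entered the correlation step
    n_links: int
    average_degree: float
    average_path_length: float
    density: float
    positive_edge_fraction: float
    edgeless: bool

    def to_dict(self) -> dict:
        return asdict(self)


def select_core_taxa(
    table: pd.DataFrame, top_k: int = 200, prevalence: float = 1.0
) -> pd.DataFrame:
    """Keep prevalent taxa, then the ``top_k`` most abundant of them.

    A taxon qualifies when it has a nonzero count in at least
    ``prevalence`` (fraction) of the samples — the default 1.0 demands
    presence in every sample.  Qualifying taxa are ranked by summed
    per-sample relative abundance and the top ``top_k`` retained; fewer
    are returned if fewer qualify.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("empty count table")
    present = (table > 0).mean(axis=0) >= prevalence
    n_prev = int(present.sum())
    if n_prev == 0:
        raise ValueError(
            f"no taxa pass the prevalence filter ({prevalence:.2f}) in "
            f"{table.shape[0]} samples; most prevalent taxon occurs in "
            f"{int((table > 0).sum(axis=0).max())} samples"
        )
    rel = relative_abundance(table)
    scores = rel.loc[:, present].sum(axis=0)
    keep = scores.sort_values(ascending=False, kind="stable").index[:top_k]
    # preserve original column order for determinism of downstream output
    keep_ordered = [t for t in table.columns if t in set(keep)]
    return table[keep_ordered]


def spearman_matrix(table: pd.DataFrame, use_relative: bool = True) -> CorrelationResult:
    """All-pairs Spearman correlation with t-approximation p-values.

    rho is the Pearson correlation of per-taxon midranks; the two-sided
    p-value uses t = rho sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom, with p = 0 at |rho| = 1 (the limiting case).  q-values are
    Benjamini-Hochberg over the off-diagonal upper triangle.  Constant
    taxa give undefined correlations, masked as NaN with a warning.
    """
    n = table.shape[0]
    if n < 4:
        raise ValueError("need at least four samples for correlation p-values")
    data = relative_abundance(table) if use_relative else table.astype(float)
    x = data.to_numpy(dtype=float)
    ranks = stats.rankdata(x, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa: correlations undefined (NaN)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0 - 1e-13] = 0.0  # limiting case of the t-approximation
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, np.nan)

    q = np.full_like(p, np.nan)
    iu = np.triu_indices(rho.shape[0], 1)
    pv = p[iu]
    mask = ~np.isnan(pv)
    if mask.any():
        qv = np.full(pv.shape, np.nan)
        qv[mask] = bh_adjust(pv[mask])
        q[iu] = qv
        q.T[iu] = qv
    return CorrelationResult(list(map(str, table.columns)), rho, p, q)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def build_network(
    corr: CorrelationResult, r_threshold: float = 0.7, q_threshold: float = 0.05
) -> nx.Graph:
    """Edge iff |rho| > r_threshold and q < q_threshold (both strict).

    Every retained taxon appears as a node, so isolated nodes record
    taxa that passed filtering but formed no significant association.
    Edge attributes: ``rho``, ``weight`` (=rho), ``sign`` (+1/-1), ``q``.
    """
    g = nx.Graph(r_threshold=float(r_threshold), q_threshold=float(q_threshold))
    g.add_nodes_from(corr.taxon_ids)
    ids = corr.taxon_ids
    iu = np.triu_indices(len(ids), 1)
    for i, j in zip(*iu):
        r = corr.rho[i, j]
        qv = corr.q[i, j]
        if np.isnan(r) or np.isnan(qv):
            continue
        if abs(r) > r_threshold and qv < q_threshold:
            g.add_edge(
                ids[i],
                ids[j],
                rho=float(r),
                weight=float(r),
                sign=1 if r > 0 else -1,
                q=float(qv),
            )
    return g


def network_metrics(net: nx.Graph) -> NetworkMetrics:
    """Complexity summary of a co-occurrence network.

    ``n_nodes`` counts non-isolated nodes (the convention of network
    viewers that drop unconnected taxa); ``n_taxa_retained`` counts all
    nodes.  Average path length is the mean unweighted shortest-path
    length over all connected (reachable) pairs across components.  An
    edgeless network reports zeros with ``edgeless=True``.
    """
    n_total = net.number_of_nodes()
    n_links = net.number_of_edges()
    active = [v for v, d in net.degree() if d > 0]
    n_act = len(active)
    if n_links == 0:
        return NetworkMetrics(0, n_total, 0, 0.0, 0.0, 0.0, 0.0, True)
    sub = net.subgraph(active)
    avg_degree = 2.0 * n_links / n_act
    density = n_links / (n_act * (n_act - 1) / 2.0) if n_act > 1 else 0.0
    pos = sum(1 for _, _, d in net.edges(data=True) if d.get("sign", 1) > 0)
    total_len = 0
    total_pairs = 0
    for comp in nx.connected_components(sub):
        cg = sub.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(cg):
            total_len += sum(lengths.values())
        total_pairs += len(comp) * (len(comp) - 1)
    apl = total_len / total_pairs if total_pairs else 0.0
    return NetworkMetrics(
        n_act,
        n_total,
        n_links,
        float(avg_degree),
        float(apl),
        float(density),
        pos / n_links,
        False,
    )
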
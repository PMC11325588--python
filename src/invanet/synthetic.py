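"""Synthetic habitat-contrasted ASV tables with known ground truth.

The generator emulates the field design the pipeline is aimed at: an
invaded habitat sampled at five sites and a native habitat at three
adjacent sites, three replicates per site.  Counts arise from a latent
Gaussian copula whose correlation matrix carries a habitat-specific
signed Erdos-Renyi "backbone" (denser in the native habitat), quantile-
mapped through negative-binomial marginals with log-normal mean
abundances; the invaded habitat loses a fixed fraction of taxa outright
(structural zeros), making the alpha-diversity ground truth exact.
Soil covariates are Gaussian per habitat with directional contrasts
matching field observations (higher ammonium, lower salinity and pH in
the invaded habitat).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import export_network

__all__ = [
    "SyntheticConfig",
    "TaxonNetworkTruth",
    "make_backbone",
    "simulate_counts",
    "simulate_soil_covariates",
    "write_synthetic_dataset",
    "DEFAULT_COVARIATE_EFFECTS",
]

INVADED = "invaded"
NATIVE = "native"

# (mean_native, mean_invaded, sd): directional contrasts follow field
# measurements under invasive vs native vegetation — ammonium up,
# salinity and pH down after invasion; the rest near-unchanged.
DEFAULT_COVARIATE_EFFECTS: dict[str, tuple[float, float, float]] = {
    "SWC": (0.25, 0.27, 0.01),
    "SOC": (3.51, 3.36, 0.5),
    "TN": (0.63, 0.54, 0.1),
    "TP": (0.43, 0.45, 0.05),
    "NH4": (6.62, 8.05, 0.3),
    "NO3": (1.26, 1.42, 0.1),
    "AP": (35.63, 35.49, 5.0),
    "pH": (8.56, 8.27, 0.08),
    "salt": (13.05, 8.8, 1.2),
    "EC": (2.93, 2.37, 0.2),
}


@dataclass
class SyntheticConfig:
    """Study-design parameters of the simulated dataset.

    ``backbone_density`` and ``n_sites`` are per-habitat mappings; the
    defaults encode the unequal design (5 invaded vs 3 native sites,
    3 replicates each) and a denser native correlation backbone.
    ``dispersion`` is the negative-binomial size parameter (smaller =
    more overdispersed); ``site_sd`` scales a shared random intercept
    per site on the latent means.
    """

    n_sites: dict[str, int] = field(
        default_factory=lambda: {INVADED: 5, NATIVE: 3}
    )
    n_reps_per_site: int = 3
    n_taxa: int = 300
    backbone_density: dict[str, float] = field(
        default_factory=lambda: {NATIVE: 0.08, INVADED: 0.03}
    )
    corr_strength: float = 0.6
    frac_negative_edges: float = 0.2
    richness_ratio: float = 0.75
    depth_range: tuple[int, int] = (20_000, 50_000)
    dispersion: float = 1.0
    site_sd: float = 0.25
    abundance_sigma: float = 1.2
    covariate_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be >= 10")
        for h, d in self.backbone_density.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"backbone density for {h!r} outside [0, 1]")
        if not 0.0 < self.corr_strength < 1.0:
            raise ValueError("corr_strength must lie in (0, 1)")
        if not 0.0 <= self.frac_negative_edges <= 1.0:
            raise ValueError("frac_negative_edges outside [0, 1]")
        if not 0.0 < self.richness_ratio <= 1.0:
            raise ValueError("richness_ratio must lie in (0, 1]")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] <= 0:
            raise ValueError("invalid depth_range")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    @property
    def habitats(self) -> list[str]:
        return list(self.n_sites)


@dataclass
class TaxonNetworkTruth:
    """Signed ground-truth backbone for one habitat."""

    habitat: str
    graph: nx.Graph  # edge attribute ``sign`` in {+1, -1}
    density: float  # realised edges / possible pairs

    def edges_signed(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)]


def _taxon_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"ASV{i + 1:0{width}d}" for i in range(n)]


def make_backbone(
    n_taxa: int, density: float, frac_negative: float, seed: int
) -> TaxonNetworkTruth:
    """Signed Erdos-Renyi backbone over taxon identifiers."""
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density outside [0, 1]")
    g = nx.gnp_random_graph(n_taxa, density, seed=int(seed))
    rng = np.random.default_rng(seed)
    mapping = dict(enumerate(_taxon_ids(n_taxa)))
    for u, v in g.edges():
        g.edges[u, v]["sign"] = -1 if rng.random() < frac_negative else 1
    g = nx.relabel_nodes(g, mapping)
    possible = n_taxa * (n_taxa - 1) / 2
    return TaxonNetworkTruth("", g, g.number_of_edges() / possible)


def _nearest_correlation(r: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue clipping followed by rescaling to unit diagonal."""
    w, v = np.linalg.eigh(r)
    w = np.clip(w, eps, None)
    r2 = (v * w) @ v.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    np.fill_diagonal(r2, 1.0)
    w_min = np.linalg.eigvalsh(r2).min()
    if w_min <= 0:
        raise RuntimeError(
            f"correlation repair failed: minimum eigenvalue {w_min:.3e} after clipping"
        )
    return r2


def _latent_correlation(
    truth: TaxonNetworkTruth, taxa: list[str], strength: float
) -> np.ndarray:
    n = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    r = np.eye(n)
    for u, v, sign in truth.edges_signed():
        r[idx[u], idx[v]] = r[idx[v], idx[u]] = sign * strength
    return _nearest_correlation(r)


def _rescale_to_depth(raw: np.ndarray, depth: int) -> np.ndarray:
    """Scale overdispersed draws to an exact library size.

    Largest-remainder rounding of ``raw * depth / sum(raw)``: keeps the
    sample's composition (hence cross-sample rank correlations) while
    pinning the library size inside the configured depth range.  Taxa
    with a zero draw stay zero, so structural absences are preserved.
    """
    total = raw.sum()
    if total <= 0:
        raise RuntimeError("sample with all-zero latent counts; increase depth")
    t = raw * (depth / total)
    base = np.floor(t).astype(np.int64)
    remainder = int(depth - base.sum())
    if remainder > 0:
        frac = t - base
        # only taxa with a positive draw can absorb the remainder
        frac[raw <= 0] = -1.0
        top = np.argsort(-frac, kind="stable")[:remainder]
        base[top] += 1
    return base


def simulate_counts(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, TaxonNetworkTruth]]:
    """Simulate the count table, metadata and per-habitat backbone truth.

    Latent multivariate-normal draws per habitat carry the backbone
    correlation (after nearest-correlation repair); a shared scalar site
    intercept induces the site-nested replicate structure; the normal
    CDF of each latent value is quantile-mapped through a negative-
    binomial marginal whose mean is the taxon's log-normal relative
    abundance times the sample's library size.  In the invaded habitat a
    random fraction (1 - richness_ratio) of taxa is structurally zeroed.
    Byte-identical outputs under identical config (same seed).
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["abundance", "zeros", "latent", "depth", "covariates", "signs"],
            ss.spawn(6),
        )
    }
    taxa = _taxon_ids(config.n_taxa)

    # log-normal mean relative abundances, shared across habitats
    log_mean = seeds["abundance"].normal(0.0, config.abundance_sigma, config.n_taxa)
    base_abundance = np.exp(log_mean)

    # structural zeros in the invaded habitat
    n_absent = int(np.floor((1.0 - config.richness_ratio) * config.n_taxa))
    absent_idx = seeds["zeros"].choice(config.n_taxa, size=n_absent, replace=False)
    absent = np.zeros(config.n_taxa, dtype=bool)
    absent[absent_idx] = True

    backbone_seeds = {
        h: int(np.random.default_rng(child).integers(2**31))
        for h, child in zip(sorted(config.n_sites), ss.spawn(len(config.n_sites)))
    }
    truths: dict[str, TaxonNetworkTruth] = {}
    frames = []
    meta_rows = []
    site_codes = {INVADED: "Sp", NATIVE: "Su"}
    latent_rng = seeds["latent"]
    depth_rng = seeds["depth"]
    scale = np.sqrt(1.0 + config.site_sd**2)

    for habitat in config.habitats:
        truth = make_backbone(
            config.n_taxa,
            config.backbone_density[habitat],
            config.frac_negative_edges,
            backbone_seeds[habitat],
        )
        truth.habitat = habitat
        truths[habitat] = truth
        corr = _latent_correlation(truth, taxa, config.corr_strength)
        chol = np.linalg.cholesky(corr)

        present = ~absent if habitat == INVADED else np.ones(config.n_taxa, bool)
        rel_mean = np.where(present, base_abundance, 0.0)
        rel_mean = rel_mean / rel_mean.sum()

        code = site_codes.get(habitat, habitat[:2].capitalize())
        for site in range(config.n_sites[habitat]):
            site_intercept = latent_rng.normal(0.0, config.site_sd)
            for rep in range(config.n_reps_per_site):
                z = chol @ latent_rng.standard_normal(config.n_taxa) + site_intercept
                u = np.clip(stats.norm.cdf(z / scale), 1e-12, 1.0 - 1e-12)
                depth = int(depth_rng.integers(*config.depth_range, endpoint=True))
                mu = rel_mean * depth
                k = config.dispersion
                with np.errstate(divide="ignore", invalid="ignore"):
                    raw = stats.nbinom.ppf(u, k, k / (k + mu))
                raw = np.where(mu > 0, raw, 0.0)
                counts = _rescale_to_depth(raw, depth)
                sample_id = f"{code}{site + 1}-{rep + 1}"
                frames.append(pd.Series(counts, index=taxa, name=sample_id))
                meta_rows.append(
                    {"sample_id": sample_id, "habitat": habitat, "site": f"{code}{site + 1}"}
                )

    table = pd.DataFrame(frames)
    table.index.name = "sample_id"
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = simulate_soil_covariates(
        metadata,
        config.covariate_effects,
        seed=int(seeds["covariates"].integers(2**31)),
    )
    return table, metadata, truths


def simulate_soil_covariates(
    metadata: pd.DataFrame,
    effects: dict[str, tuple[float, float, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Add Gaussian soil covariates per habitat at the stated means/SDs.

    ``effects`` maps covariate name to (mean_native, mean_invaded, sd);
    an empty mapping returns the metadata unchanged.
    """
    if "habitat" not in metadata.columns:
        raise ValueError("metadata must carry a habitat column")
    if not effects:
        return metadata
    rng = np.random.default_rng(seed)
    out = metadata.copy()
    is_invaded = (out["habitat"] == INVADED).to_numpy()
    n = len(out)
    for name, (mean_native, mean_invaded, sd) in effects.items():
        if sd < 0:
            raise ValueError(f"negative SD for covariate {name!r}")
        means = np.where(is_invaded, mean_invaded, mean_native)
        out[name] = means + rng.normal(0.0, 1.0, n) * sd
    return out


def write_synthetic_dataset(
    config: SyntheticConfig, outdir: str | Path
) -> dict[str, Path]:
    """Write counts TSV, metadata TSV and one truth GraphML per habitat."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, metadata, truths = simulate_counts(config)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    table.to_csv(paths["counts"], sep="\t", index_label="sample_id")
    metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    for habitat, truth in truths.items():
        p = outdir / f"truth_{habitat}.graphml"
        export_network(truth.graph, p, "graphml")
        paths[f"truth_{habitat}"] = p
    return paths
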
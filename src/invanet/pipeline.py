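"""One-command habitat-contrast pipeline.

Runs, in order: load-or-simulate -> alpha diversity + covariate tests ->
Bray-Curtis + NMDS + ANOSIM/PERMANOVA + beta-dispersion contrast ->
per-habitat core-taxa filter -> Spearman/FDR correlation -> network +
complexity metrics -> cohesion + natural-connectivity robustness ->
taxon-covariate correlation table -> structured JSON report.  Every
stage writes its intermediate artifact to the output directory and every
seed and threshold is echoed into the report, so two runs with the same
configuration are byte-identical (no timestamps are recorded).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, community, diversity, network, stability, tables
from .synthetic import SyntheticConfig, simulate_counts

__all__ = ["PipelineConfig", "run_pipeline", "compare_habitats", "load_config"]


@dataclass
class PipelineConfig:
    """All thresholds, seeds and paths of a pipeline run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    mapping_path: str | None = None
    synthetic: bool = False
    synthetic_config: SyntheticConfig | None = None
    habitat_col: str = "habitat"
    reference_habitat: str = "native"
    top_k: int = 200
    prevalence: float = 1.0
    r_threshold: float = 0.7
    q_threshold: float = 0.05
    alpha: float = 0.05
    n_perm: int = 999
    n_null: int = 200
    removal_fractions: tuple = stability.DEFAULT_FRACTIONS
    removal_reps: int = 50
    nmds_restarts: int = 20
    use_relative: bool = True
    seed: int = 0
    outdir: str = "invanet_out"

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence outside [0, 1]")
        if not 0.0 <= self.r_threshold <= 1.0:
            raise ValueError("r_threshold outside [0, 1]")
        if not 0.0 < self.q_threshold <= 1.0:
            raise ValueError("q_threshold outside (0, 1]")
        if self.top_k < 1 or self.n_perm < 1 or self.n_null < 1:
            raise ValueError("top_k, n_perm and n_null must be positive")
        if not self.synthetic and self.counts_path is None:
            raise ValueError("either synthetic=True or counts/metadata paths required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["removal_fractions"] = [float(f) for f in self.removal_fractions]
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic_config", None)
    cfg = PipelineConfig(**raw)
    if syn is not None:
        if "n_sites" in syn:
            syn["n_sites"] = {str(k): int(v) for k, v in syn["n_sites"].items()}
        if "depth_range" in syn:
            syn["depth_range"] = tuple(syn["depth_range"])
        cfg.synthetic_config = SyntheticConfig(**syn)
    return cfg


def _summary(series: pd.Series) -> dict:
    return {
        "mean": float(series.mean()),
        "sd": float(series.std(ddof=1)) if len(series) > 1 else 0.0,
        "median": float(series.median()),
        "n": int(len(series)),
    }


def _alpha_stage(table, metadata, habitat_col, outdir):
    alpha = diversity.alpha_table(table)
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    habitats = metadata[habitat_col]
    out = {"summary": {}, "tests": {}}
    for h in sorted(habitats.unique()):
        sub = alpha.loc[habitats[habitats == h].index]
        out["summary"][h] = {c: _summary(sub[c]) for c in alpha.columns}
    if habitats.nunique() == 2:
        h1, h2 = sorted(habitats.unique())
        for c in alpha.columns:
            w, p = diversity.wilcoxon_rank_sum(
                alpha.loc[habitats[habitats == h1].index, c],
                alpha.loc[habitats[habitats == h2].index, c],
            )
            res = diversity.anova_duncan(alpha[c].to_numpy(), habitats.to_numpy())
            out["tests"][c] = {
                "wilcoxon_W": w,
                "wilcoxon_p": p,
                "anova_F": res.f_statistic,
                "anova_p": res.p_value,
                "duncan_letters": res.letters,
            }
    return alpha, out


def _covariate_stage(metadata, habitat_col):
    habitats = metadata[habitat_col]
    covs = [
        c
        for c in metadata.columns
        if c != habitat_col and pd.api.types.is_numeric_dtype(metadata[c])
    ]
    out = {}
    if habitats.nunique() != 2 or not covs:
        return out
    h1, h2 = sorted(habitats.unique())
    pvals = []
    for c in covs:
        x = metadata.loc[habitats == h1, c].to_numpy(dtype=float)
        y = metadata.loc[habitats == h2, c].to_numpy(dtype=float)
        w, p = diversity.wilcoxon_rank_sum(x, y)
        try:
            res = diversity.anova_duncan(
                metadata[c].to_numpy(dtype=float), habitats.to_numpy()
            )
            anova = {
                "anova_F": res.f_statistic,
                "anova_p": res.p_value,
                "duncan_letters": res.letters,
            }
        except ValueError:
            anova = {"anova_F": None, "anova_p": None, "duncan_letters": None}
        out[c] = {
            "mean": {h1: float(np.mean(x)), h2: float(np.mean(y))},
            "wilcoxon_W": w,
            "wilcoxon_p": p,
            **anova,
        }
        pvals.append(p)
    qvals = network.bh_adjust(pvals)
    for c, q in zip(out, qvals):
        out[c]["wilcoxon_q"] = float(q)
    return out


def _beta_stage(table, metadata, habitat_col, cfg, outdir):
    dm = diversity.bray_curtis(table, use_relative=cfg.use_relative)
    diversity.write_distance_matrix(dm, outdir / "bray_curtis.tsv")
    habitats = metadata.loc[list(dm.ids), habitat_col]
    ord_res = community.nmds(dm, n_restarts=cfg.nmds_restarts, seed=cfg.seed)
    ord_res.coordinates.to_csv(
        outdir / "nmds_coordinates.tsv", sep="\t", index_label="sample_id"
    )
    out = {"nmds_stress": ord_res.stress, "nmds_converged": ord_res.converged}
    if habitats.nunique() >= 2:
        an = community.anosim(dm, habitats.to_numpy(), n_perm=cfg.n_perm, seed=cfg.seed)
        pe = community.permanova(
            dm, habitats.to_numpy(), n_perm=cfg.n_perm, seed=cfg.seed
        )
        out["anosim"] = an.to_dict()
        out["permanova"] = pe.to_dict()
        within = community.within_group_dissimilarities(dm, habitats.to_numpy())
        if len(within) == 2:
            (g1, v1), (g2, v2) = sorted(within.items())
            w, p = diversity.wilcoxon_rank_sum(v1, v2)
            out["beta_dispersion"] = {
                "groups": [g1, g2],
                "median": {g1: float(np.median(v1)), g2: float(np.median(v2))},
                "wilcoxon_W": w,
                "wilcoxon_p": p,
            }
    return dm, out


def _network_stage(table, metadata, habitat_col, cfg, outdir, rng):
    habitats = metadata[habitat_col]
    nets, out = {}, {}
    for h in sorted(habitats.unique()):
        sub = table.loc[habitats[habitats == h].index]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        core = network.select_core_taxa(sub, top_k=cfg.top_k, prevalence=cfg.prevalence)
        corr = network.spearman_matrix(core, use_relative=cfg.use_relative)
        net = network.build_network(corr, cfg.r_threshold, cfg.q_threshold)
        tables.export_network(net, outdir / f"network_{h}.graphml", "graphml")
        tables.export_network(net, outdir / f"network_{h}_edges.tsv", "edgelist")
        metrics = network.network_metrics(net)
        # stability is evaluated on the connected part of the network,
        # matching the reported (non-isolated) node counts
        active = [v for v, d in net.degree() if d > 0]
        sub_net = net.subgraph(active).copy()
        seed_h = int(rng.integers(2**31))
        if sub_net.number_of_nodes() > 0:
            nc = stability.natural_connectivity(sub_net)
            curve = stability.robustness_curve(
                sub_net,
                fractions=cfg.removal_fractions,
                n_reps=cfg.removal_reps,
                seed=seed_h,
            )
            curve.table.to_csv(outdir / f"robustness_{h}.tsv", sep="\t", index=False)
            curve_dict = curve.to_dict()
        else:
            nc, curve_dict = 0.0, None
        # cohesion on all taxa present in the habitat
        conn_seed = int(rng.integers(2**31))
        conn = stability.connectedness(sub, n_null=cfg.n_null, seed=conn_seed)
        coh = stability.cohesion(sub, conn)
        coh.to_csv(outdir / f"cohesion_{h}.tsv", sep="\t", index_label="sample_id")
        nets[h] = net
        out[h] = {
            "n_samples": int(sub.shape[0]),
            "n_core_taxa": int(core.shape[1]),
            "metrics": metrics.to_dict(),
            "natural_connectivity": float(nc),
            "robustness": curve_dict,
            "cohesion": {
                "pos": _summary(coh["pos_cohesion"]),
                "neg": _summary(coh["neg_cohesion"]),
                "n_null": cfg.n_null,
                "seed": conn_seed,
            },
        }
    return nets, out


def _heatmap_stage(table, metadata, habitat_col, taxonomy, outdir):
    covs = [
        c
        for c in metadata.columns
        if c != habitat_col and pd.api.types.is_numeric_dtype(metadata[c])
    ]
    if not covs:
        return None
    if taxonomy is not None:
        agg = tables.aggregate_by_rank(table, taxonomy, "phylum")
    else:
        agg = table
    rel = tables.relative_abundance(agg)
    top = rel.mean(axis=0).sort_values(ascending=False).index[:10]
    rho, p, q = community.taxa_covariate_correlations(rel[list(top)], metadata, covs)
    for name, df in [("rho", rho), ("p", p), ("q", q)]:
        df.to_csv(outdir / f"taxa_covariate_{name}.tsv", sep="\t", index_label="taxon")
    return {
        "taxa": list(map(str, top)),
        "covariates": covs,
        "n_significant_q05": int((q.to_numpy() < 0.05).sum()),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written
    to ``<outdir>/report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2045]))

    taxonomy = None
    if config.synthetic:
        syn = config.synthetic_config or SyntheticConfig(seed=config.seed)
        table, metadata, truths = simulate_counts(syn)
        tables.write_count_table(table, outdir / "counts.tsv")
        tables.write_metadata(metadata, outdir / "metadata.tsv")
        for h, truth in truths.items():
            tables.export_network(truth.graph, outdir / f"truth_{h}.graphml")
    else:
        metadata = tables.read_metadata(config.metadata_path, config.habitat_col)
        table = tables.read_count_table(
            config.counts_path, sample_ids=list(metadata.index)
        )
        table = table.loc[[s for s in table.index if s in metadata.index]]
        metadata = metadata.loc[table.index]
        if config.taxonomy_path:
            taxonomy = tables.read_taxonomy(config.taxonomy_path)

    if config.habitat_col not in metadata.columns:
        warnings.warn(
            f"metadata has no {config.habitat_col!r} column: running as a single "
            "community, habitat contrasts skipped"
        )
        metadata = metadata.copy()
        metadata[config.habitat_col] = "all"
    n_habitats = metadata[config.habitat_col].nunique()

    report: dict = {
        "provenance": {
            "software": "invanet",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        }
    }

    _, report["alpha"] = _alpha_stage(table, metadata, config.habitat_col, outdir)
    report["covariates"] = _covariate_stage(metadata, config.habitat_col)
    _, report["beta"] = _beta_stage(table, metadata, config.habitat_col, config, outdir)
    _, report["habitats"] = _network_stage(
        table, metadata, config.habitat_col, config, outdir, rng
    )
    report["taxa_covariate_heatmap"] = _heatmap_stage(
        table, metadata, config.habitat_col, taxonomy, outdir
    )
    if n_habitats == 2:
        report["contrasts"] = compare_habitats(
            report, reference=config.reference_habitat
        )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def compare_habitats(report: dict, reference: str = "native") -> dict:
    """Per-metric habitat contrast with percent change vs the reference.

    Percent change is 100 * (other - reference) / reference, matching
    the convention "metric decreased by X% after invasion" when the
    native habitat is the reference.
    """
    habs = report.get("habitats", {})
    if len(habs) != 2:
        raise ValueError(
            "compare_habitats needs exactly two habitats; run pairwise otherwise"
        )
    names = sorted(habs)
    if reference not in names:
        reference = names[0]
    other = next(h for h in names if h != reference)

    def metric_pairs():
        for key in (
            "n_nodes",
            "n_links",
            "average_degree",
            "average_path_length",
            "density",
            "positive_edge_fraction",
        ):
            yield key, {h: habs[h]["metrics"][key] for h in names}
        yield "natural_connectivity", {
            h: habs[h]["natural_connectivity"] for h in names
        }
        yield "positive_cohesion_median", {
            h: habs[h]["cohesion"]["pos"]["median"] for h in names
        }
        yield "negative_cohesion_median", {
            h: habs[h]["cohesion"]["neg"]["median"] for h in names
        }

    out = {"reference": reference, "other": other, "metrics": {}}
    for key, vals in metric_pairs():
        ref_v, oth_v = float(vals[reference]), float(vals[other])
        pct = 100.0 * (oth_v - ref_v) / ref_v if ref_v != 0 else None
        out["metrics"][key] = {
            reference: ref_v,
            other: oth_v,
            "difference": oth_v - ref_v,
            "percent_change": pct,
        }
    return out
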
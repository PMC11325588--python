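# invanet

Habitat-contrast analysis of soil microbial communities from ASV-level
amplicon count tables.

`invanet` is aimed at microbial ecologists comparing two habitats — the
motivating case is a coastal wetland where an invasive cordgrass
displaces native halophyte vegetation — who want a single reproducible
pipeline from a samples × taxa count table and sample metadata to the
standard battery of community contrasts:

- **Alpha diversity** as Hill numbers,
  `D_q = (Σᵢ pᵢ^q)^{1/(1−q)}`, reporting richness (q = 0),
  exp-Shannon (q = 1) and inverse Simpson (q = 2), compared between
  habitats with Wilcoxon rank-sum tests and one-way ANOVA with Duncan's
  multiple range letters.
- **Beta diversity** as Bray–Curtis dissimilarity
  `BC(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ)`, ordinated by non-metric MDS
  (Kruskal stress-1) and tested with ANOSIM
  (`R = (r̄_between − r̄_within)/(M/2)`) and PERMANOVA (pseudo-F from the
  permutational partition of squared distances), with exhaustive label
  enumeration whenever it is feasible.
- **Co-occurrence networks** per habitat: ASVs present in every sample
  and ranked in the top 200 by relative abundance are correlated with
  Spearman's ρ; an edge is drawn iff |ρ| > 0.7 and the
  Benjamini–Hochberg q < 0.05 (both strict). Complexity is summarised
  by node/link counts, average degree, density and mean shortest-path
  length; networks export to GraphML/GEXF/TSV.
- **Stability**: natural connectivity
  `λ̄ = ln((1/N) Σᵢ e^{λᵢ})` over the adjacency spectrum, tracked under
  random node removal, and community **cohesion** — per-sample
  `C± = Σⱼ aⱼ c±ⱼ`, where a taxon's connectedness `c±ⱼ` is its mean
  positive/negative pairwise correlation after subtracting a
  taxon-shuffle null expectation.
- A **synthetic-data generator** that emulates the field design (5
  invaded + 3 native sites × 3 replicates) with known signed correlation
  backbones of differing density, an exact richness deficit, variable
  library sizes and habitat-contrasted soil covariates — so every
  pipeline stage can be validated against ground truth.

## Worked example

Run the whole analysis on a simulated dataset (or pass `--counts` /
`--metadata` TSVs for real data):

```bash
invanet run --synthetic --seed 1 --outdir demo_out
```

which writes every intermediate table (alpha diversity, Bray–Curtis
matrix, NMDS coordinates, per-habitat GraphML networks, cohesion and
robustness tables) plus `report.json`, and prints the habitat contrast:

```
metric                             native      invaded   % change
n_nodes                                 6            2     -66.7%
n_links                                 3            1     -66.7%
average_degree                          1            1      +0.0%
average_path_length                     1            1      +0.0%
density                               0.2            1    +400.0%
positive_edge_fraction                  1            0    -100.0%
natural_connectivity               0.4338       0.4338      -0.0%
positive_cohesion_median           0.3204       0.2357     -26.4%
negative_cohesion_median          -0.2843       -0.215     -24.4%
```

Reading this: the native habitat's network retains more significant
associations (3 links over 6 nodes vs 1 over 2) and its samples are more
cohesive (positive cohesion median 0.32 vs 0.24, a 26% drop with
invasion), mirroring the expected simplification of microbial
association structure in the invaded habitat.  Note that with only 9–15
samples per habitat the FDR-corrected |ρ| > 0.7 rule admits very few
edges, so node-level network metrics sit near their floor — see
`docs/methods.md` for why this is an honest property of the design, not
an artifact.  The report also contains the ANOSIM/PERMANOVA contrast
(here R = 0.55, pseudo-F = 4.43, both p = 0.001 with 999 permutations)
and the alpha-diversity deficit (mean richness 294 native vs 221
invaded, by construction ~75%).

`invanet simulate` writes a synthetic dataset with its ground-truth
backbones; `invanet report` pretty-prints an existing `report.json`.
YAML configuration files (see `invanet.pipeline.PipelineConfig`) expose
every threshold, grid and seed.

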
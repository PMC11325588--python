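"""I/O and aggregation for count, metadata, taxonomy and mapping tables.

The in-memory convention throughout the package is a pandas DataFrame of
non-negative integer counts with **samples as rows** and taxa (ASVs) as
columns.  Sample metadata is a DataFrame indexed by sample id with a
categorical habitat column plus numeric soil covariates.  All tables are
exchanged as UTF-8 tab-separated files with a header row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

UNCLASSIFIED = "Unclassified"

__all__ = [
    "validate_count_table",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "read_group_mapping",
    "relative_abundance",
    "aggregate_by_rank",
    "aggregate_by_group",
    "export_network",
]


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check count-table invariants; return the validated table.

    Raises ``ValueError`` on duplicate identifiers, negative or
    non-integer cells, naming the offending row/column where possible.
    """
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon ids: {dup}")
    arr = table.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count table contains non-numeric cells")
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at sample {table.index[i]!r}, taxon {table.columns[j]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"non-integer count at sample {table.index[i]!r}, taxon {table.columns[j]!r}"
        )
    return table.astype(np.int64)


def read_count_table(
    path: str | Path,
    orientation: str = "auto",
    sample_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read a TSV count table and normalise it to samples x taxa.

    Parameters
    ----------
    orientation
        ``"samples"`` if rows are samples, ``"taxa"`` if rows are taxa,
        or ``"auto"``: when ``sample_ids`` (e.g. from a metadata table)
        is supplied the orientation is detected by matching them against
        the row or column labels; without ``sample_ids`` rows are
        assumed to be samples.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) < len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate taxon ids: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation not in ("auto", "samples", "taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "taxa":
        df = df.T
    elif orientation == "auto" and sample_ids is not None:
        ids = set(sample_ids)
        in_rows = len(ids & set(df.index))
        in_cols = len(ids & set(df.columns))
        if in_cols > in_rows:
            df = df.T
        elif in_rows == 0:
            raise ValueError(
                "none of the supplied sample ids match the table's rows or columns"
            )
    df.index.name = None
    df.columns.name = None
    return validate_count_table(df)


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_count_table(table).to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path, habitat_col: str = "habitat") -> pd.DataFrame:
    """Read a sample metadata TSV indexed by sample id."""
    md = pd.read_csv(path, sep="\t", index_col=0)
    if md.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    if habitat_col in md.columns:
        md[habitat_col] = md[habitat_col].astype(str)
    return md


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV: taxon id index, one column per rank."""
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if tax.index.duplicated().any():
        raise ValueError("duplicate taxon ids in taxonomy")
    return tax


def read_group_mapping(path: str | Path) -> pd.DataFrame:
    """Read a taxon -> functional-group mapping (two columns, one-to-many)."""
    mp = pd.read_csv(path, sep="\t", dtype=str)
    if mp.shape[1] < 2:
        raise ValueError("group mapping needs at least two columns (taxon_id, group)")
    mp = mp.iloc[:, :2]
    mp.columns = ["taxon_id", "group"]
    if (mp["group"].str.len() == 0).any() or mp["group"].isna().any():
        raise ValueError("group labels must be non-empty strings")
    return mp


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; every row sums to one.

    Raises ``ValueError`` naming any sample with a zero library size.
    """
    totals = table.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"samples with zero total count: {zero}")
    return table.div(totals, axis=0)


def aggregate_by_rank(
    table: pd.DataFrame, taxonomy: pd.DataFrame, rank: str = "phylum"
) -> pd.DataFrame:
    """Sum counts into taxonomy labels at ``rank`` (e.g. phylum).

    Taxa missing from the taxonomy, or with a null label, are pooled
    into ``"Unclassified"`` so per-sample totals are conserved.
    """
    if rank not in taxonomy.columns:
        raise ValueError(f"rank {rank!r} not present in taxonomy columns")
    labels = taxonomy[rank].reindex(table.columns)
    labels = labels.where(labels.notna() & (labels != ""), UNCLASSIFIED)
    out = table.T.groupby(labels.to_numpy()).sum().T
    out.index = table.index
    return out


def aggregate_by_group(
    table: pd.DataFrame, mapping: pd.DataFrame, weighted: bool = True
) -> pd.DataFrame:
    """Relative abundance per functional group (overlapping guilds allowed).

    Each taxon contributes its full per-sample relative abundance to
    *every* group it maps to, so group columns are each in [0, 1] but do
    not sum to one.  With ``weighted=False`` the presence/absence
    indicator is averaged over a group's member taxa instead.
    """
    if mapping.empty:
        raise ValueError("empty group mapping")
    rel = relative_abundance(table)
    groups = sorted(mapping["group"].unique())
    out = pd.DataFrame(0.0, index=table.index, columns=groups)
    for group, sub in mapping.groupby("group"):
        taxa = [t for t in sub["taxon_id"] if t in table.columns]
        if not taxa:
            continue
        if weighted:
            out[group] = rel[taxa].sum(axis=1)
        else:
            out[group] = (table[taxa] > 0).mean(axis=1)
    return out


def export_network(net: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML, GEXF or an edge-list TSV.

    Node attributes (degree and any taxon annotations) and edge
    attributes (rho, sign, q) are preserved in the XML formats; the
    edge-list TSV carries source, target, rho, sign and q columns.
    """
    fmt = fmt.lower()
    g = net.copy()
    for node, deg in g.degree():
        g.nodes[node]["degree"] = int(deg)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt in ("edgelist", "tsv", "edge-list"):
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d.get("rho", d.get("weight", np.nan)),
                "sign": d.get("sign", int(np.sign(d.get("rho", 0))) or 1),
                "q": d.get("q", np.nan),
            }
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "q"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {fmt!r}")
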
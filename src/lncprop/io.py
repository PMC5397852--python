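"""Readers and writers for the package's interchange formats.

All tabular formats are UTF-8 tab-delimited text with one header row and no
quoting: expression matrices (gene id, biotype, then one column per
sample), network edge/node tables, per-dataset and consensus co-expression
edge tables, and the enrichment results table.  Pathways use the GMT
format; seed lists are plain text (one id per line, ``#`` comments);
run manifests are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpr import BIOTYPES, ConsensusEdge, ExpressionDataset, PairCorrelation
from .enrichment import EnrichmentResult, PathwayGeneSet
from .network import CNCNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_seeds",
    "write_seeds",
    "read_network",
    "write_network",
    "read_ppi",
    "write_pair_correlations",
    "write_consensus_edges",
    "read_consensus_edges",
    "write_results",
    "read_results",
    "write_manifest",
    "read_manifest",
]

RESULT_COLUMNS = [
    "pathway_id", "name", "size", "es", "p_value", "fdr",
    "peak_index", "core_genes",
]


def read_expression(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    """Read an FPKM matrix: gene_id, biotype, then sample columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected gene_id, biotype and sample columns")
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        gene_ids=df.iloc[:, 0].tolist(),
        biotypes=df.iloc[:, 1].tolist(),
        values=df.iloc[:, 2:].to_numpy(dtype=float),
    )


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    df = pd.DataFrame(dataset.values)
    df.columns = [f"sample_{i + 1}" for i in range(dataset.n_samples)]
    df.insert(0, "biotype", dataset.biotypes)
    df.insert(0, "gene_id", dataset.gene_ids)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[PathwayGeneSet]:
    """Read pathways in GMT format: id, description, member genes."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"({len(fields)} tab fields, need >= 3)"
                )
            pw_id, name, genes = fields[0], fields[1], fields[2:]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "%s:%d: duplicate gene id(s) in pathway %s deduplicated",
                    path, lineno, pw_id,
                )
            if not unique:
                raise ValueError(f"{path}:{lineno}: pathway {pw_id!r} has no genes")
            out.append(PathwayGeneSet(pw_id, name, frozenset(unique)))
    return out


def write_gmt(pathways: Iterable[PathwayGeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


def read_seeds(path: str | Path) -> list[str]:
    """One identifier per line; ``#`` comments and blank lines ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_seeds(seeds: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in seeds), encoding="utf-8")


def read_network(edge_path: str | Path, node_path: str | Path) -> CNCNetwork:
    """Read a network from its edge and node tables.

    Unknown biotype strings and edges referencing undeclared nodes are
    errors.
    """
    nodes = pd.read_csv(node_path, sep="\t", dtype=str)
    biotypes: dict[str, str] = {}
    for _, row in nodes.iterrows():
        if row["biotype"] not in BIOTYPES:
            raise ValueError(
                f"{node_path}: unknown biotype {row['biotype']!r} "
                f"for node {row['gene_id']!r}"
            )
        biotypes[row["gene_id"]] = row["biotype"]
    edges = pd.read_csv(edge_path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    records = []
    for _, row in edges.iterrows():
        for node in (row["gene_a"], row["gene_b"]):
            if node not in biotypes:
                raise ValueError(
                    f"{edge_path}: edge references node {node!r} "
                    "absent from the node table"
                )
        sign = row.get("sign")
        sign = None if pd.isna(sign) else int(sign)
        records.append((row["gene_a"], row["gene_b"], row["provenance"], sign))
    return CNCNetwork.from_edges(records, biotypes)


def write_network(net: CNCNetwork, edge_path: str | Path, node_path: str | Path) -> None:
    recs = net.edge_records()
    pd.DataFrame(
        {
            "gene_a": [r[0] for r in recs],
            "gene_b": [r[1] for r in recs],
            "provenance": [r[2] for r in recs],
            "sign": [("" if r[3] is None else r[3]) for r in recs],
        }
    ).to_csv(edge_path, sep="\t", index=False)
    nodes = sorted(net.graph.nodes)
    pd.DataFrame(
        {"gene_id": nodes, "biotype": [net.biotype(n) for n in nodes]}
    ).to_csv(node_path, sep="\t", index=False)


def read_ppi(path: str | Path) -> list[tuple[str, str]]:
    """Two-column protein interaction pair list (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False)]


def write_pair_correlations(calls: Sequence[PairCorrelation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_a": [c.gene_a for c in calls],
            "gene_b": [c.gene_b for c in calls],
            "r": [c.r for c in calls],
            "z": [c.z for c in calls],
            "p_adj": [c.p_adj for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def write_consensus_edges(edges: Sequence[ConsensusEdge], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_a": [e.gene_a for e in edges],
            "gene_b": [e.gene_b for e in edges],
            "sign": [e.sign for e in edges],
            "support": [e.support for e in edges],
        }
    ).to_csv(path, sep="\t", index=False)


def read_consensus_edges(path: str | Path) -> list[ConsensusEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return [
        ConsensusEdge(r.gene_a, r.gene_b, int(r.sign), int(r.support))
        for r in df.itertuples(index=False)
    ]


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Deterministic results table: descending ES, ties by pathway id."""
    rows = sorted(results, key=lambda r: (-r.es, r.pathway_id))
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in rows],
            "name": [r.name for r in rows],
            "size": [r.size for r in rows],
            "es": [r.es for r in rows],
            "p_value": [r.p_value for r in rows],
            "fdr": [r.fdr for r in rows],
            "peak_index": [r.peak_index for r in rows],
            "core_genes": [";".join(r.core_genes) for r in rows],
        }
    )


def write_results(results: Sequence[EnrichmentResult] | pd.DataFrame, path: str | Path) -> None:
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"pathway_id": str, "name": str},
        keep_default_na=False,
        na_values={"p_value": [""], "fdr": [""]},
    )
    df["core_genes"] = df["core_genes"].astype(str)
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    df["fdr"] = pd.to_numeric(df["fdr"], errors="coerce")
    return df


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o).__name__)

    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_default) + "\n",
        encoding="utf-8",
    )


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
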
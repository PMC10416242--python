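"""Readers and writers for the pipeline's on-disk formats.

Abundance tables travel as TSV in the QIIME dialect (taxa as rows, a
``#OTU ID`` header sentinel, samples as columns) or as BIOM 1.0 JSON;
internally everything is samples x taxa. Taxonomy is a two-column TSV
with semicolon-joined seven-rank lineages carrying ``d__``-style
prefixes. Networks are written as GraphML plus a three-column edge list.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .netinfer import AssociationNetwork
from .taxonomy import RANKS, TaxonomyRecord

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_taxonomy",
    "write_taxonomy",
    "write_network",
    "read_network_edgelist",
    "write_edge_supports",
]

_OTU_SENTINEL = "#OTU ID"
_RANK_PREFIX = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


# -- abundance tables ---------------------------------------------------

def read_abundance(
    path, format: str = "tsv", orientation: str | None = None
) -> AbundanceTable:
    """Read an abundance table from TSV or BIOM 1.0 JSON.

    TSV orientation is auto-detected via the ``#OTU ID`` header sentinel
    (taxa-as-rows, QIIME convention); without the sentinel an explicit
    ``orientation`` of ``"taxa_rows"`` or ``"samples_rows"`` is required.
    """
    path = Path(path)
    if format == "biom":
        return _read_biom(path)
    if format != "tsv":
        raise ValueError(f"format must be 'tsv' or 'biom', got {format!r}")
    with open(path) as fh:
        header = fh.readline()
    first_cell = header.split("\t", 1)[0].strip()
    if first_cell == _OTU_SENTINEL:
        orientation = "taxa_rows"
    elif orientation is None:
        raise ValueError(
            f"no {_OTU_SENTINEL!r} sentinel in {path}; pass orientation explicitly"
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "taxa_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return AbundanceTable(df)


def write_abundance(table: AbundanceTable, path, format: str = "tsv") -> None:
    """Write a table as QIIME-dialect TSV (taxa rows) or BIOM 1.0 JSON."""
    path = Path(path)
    if format == "biom":
        _write_biom(table, path)
        return
    if format != "tsv":
        raise ValueError(f"format must be 'tsv' or 'biom', got {format!r}")
    out = table.data.T
    out.index.name = _OTU_SENTINEL
    out.to_csv(path, sep="\t")


def _read_biom(path: Path) -> AbundanceTable:
    """Minimal BIOM 1.0 (JSON) reader: dense and sparse matrix types."""
    doc = json.loads(Path(path).read_text())
    rows = [r["id"] for r in doc["rows"]]       # observations = taxa
    cols = [c["id"] for c in doc["columns"]]    # samples
    n_rows, n_cols = doc["shape"]
    mat = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    df = pd.DataFrame(mat.T, index=cols, columns=rows)
    return AbundanceTable(df)


def _write_biom(table: AbundanceTable, path: Path) -> None:
    values = table.counts().T  # taxa x samples
    data = [
        [int(i), int(j), float(values[i, j])]
        for i, j in zip(*np.nonzero(values))
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "umbranet",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [len(table.taxon_ids), len(table.sample_ids)],
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    Path(path).write_text(json.dumps(doc))


# -- taxonomy -----------------------------------------------------------

def read_taxonomy(path) -> list[TaxonomyRecord]:
    """Read two-column TSV (taxon_id, semicolon-joined lineage).

    Missing trailing ranks are padded with the empty label, which the MDM
    relabeler treats as unassigned.
    """
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            taxon_id, lineage = parts
            labels = [s.strip() for s in lineage.split(";")]
            labels = (labels + [""] * 7)[:7]
            records.append(TaxonomyRecord(taxon_id=taxon_id, ranks=tuple(labels)))
    return records


def write_taxonomy(records, path, with_prefixes: bool = True) -> None:
    with open(path, "w") as fh:
        for rec in records:
            labels = rec.display_ranks()
            if with_prefixes:
                labels = tuple(p + l for p, l in zip(_RANK_PREFIX, labels))
            fh.write(f"{rec.taxon_id}\t{'; '.join(labels)}\n")


# -- networks -----------------------------------------------------------

def write_network(network: AssociationNetwork, graphml_path=None, edgelist_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(network.to_networkx(), graphml_path)
    if edgelist_path is not None:
        with open(edgelist_path, "w") as fh:
            fh.write("node_i\tnode_j\tsign\n")
            for i, j in sorted(network.edges):
                fh.write(f"{i}\t{j}\t{network.signs.get((i, j), 0)}\n")


def read_network_edgelist(path, nodes=None) -> AssociationNetwork:
    edges = set()
    signs = {}
    seen = set()
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            i, j, sign = line.rstrip("\n").split("\t")
            e = (i, j) if i <= j else (j, i)
            edges.add(e)
            signs[e] = int(sign)
            seen.update(e)
    return AssociationNetwork(
        nodes=list(nodes) if nodes is not None else sorted(seen),
        edges=edges,
        signs=signs,
    )


def write_edge_supports(supports, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tcount\tretained\n")
        for s in sorted(supports, key=lambda s: s.edge):
            i, j = s.edge
            fh.write(f"{i}\t{j}\t{s.bootstrap_count}\t{str(s.retained).lower()}\n")
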
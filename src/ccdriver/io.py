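"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices, group maps, annotation tables, DEG tables and Ct plates
travel as TSV; interactomes as SIF ("A pp B") or two-column TSV; reports and
ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .deg import AnnotationTable, DEGRecord, ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_group_map",
    "write_group_map",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_edge_list",
    "write_sif",
    "deg_records_to_frame",
    "write_deg_table",
    "read_deg_table",
    "write_json",
]


def read_expression_tsv(
    matrix_path: str | Path,
    groups_path: str | Path,
    *,
    annotation: AnnotationTable | None = None,
) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    group_map = read_group_map(groups_path)
    symbols = {}
    if annotation is not None:
        symbols = dict(
            zip(annotation.table["gene_id"], annotation.table["symbol"].fillna(""))
        )
    return ExpressionMatrix(values=values, group_map=group_map, symbols=symbols)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_group_map(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return dict(zip(frame["sample"].astype(str), frame["group"].astype(str)))


def write_group_map(group_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in group_map.items():
            fh.write(f"{sample}\t{group}\n")


def read_annotation_tsv(path: str | Path) -> AnnotationTable:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    frame["symbol"] = frame["symbol"].fillna("")
    frame["protein_annotated"] = frame["protein_annotated"].astype(bool)
    return AnnotationTable(table=frame)


def write_annotation_tsv(ann: AnnotationTable, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read SIF ("A pp B", one interaction type) or two-column TSV edges.

    Single-token SIF lines (isolated nodes) carry no edge and are skipped
    here; use :func:`read_network` to keep them.
    """
    edges: list[tuple[str, str]] = []
    for parts in _sif_lines(path):
        if len(parts) >= 3:  # SIF: source, type, target(s)
            src, _, *targets = parts
            edges.extend((src, t) for t in targets if t)
        elif len(parts) == 2:
            edges.append((parts[0], parts[1]))
    return edges


def read_network(path: str | Path) -> nx.Graph:
    """Read a SIF or two-column edge file as a graph, keeping isolated nodes."""
    g = nx.Graph()
    for parts in _sif_lines(path):
        if len(parts) == 1:
            g.add_node(parts[0])
        elif len(parts) == 2:
            g.add_edge(parts[0], parts[1])
        else:
            src, _, *targets = parts
            for t in targets:
                if t:
                    g.add_edge(src, t)
    return g


def _sif_lines(path: str | Path):
    with open(path) as fh:
        for line in fh:
            parts = [p for p in line.rstrip("\n").split("\t") if p != ""]
            if parts:
                yield parts


def write_sif(
    edges: Iterable[tuple[str, str]] | nx.Graph,
    path: str | Path,
    *,
    interaction: str = "pp",
) -> None:
    if isinstance(edges, nx.Graph):
        isolated = sorted((str(v) for v in nx.isolates(edges)))
        pairs = sorted((sorted((str(u), str(v))) for u, v in edges.edges()))
    else:
        isolated = []
        pairs = sorted(sorted((str(u), str(v))) for u, v in edges)
    with open(path, "w") as fh:
        for u, v in pairs:
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for v in isolated:
            fh.write(f"{v}\n")


def deg_records_to_frame(records: Iterable[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "symbol": r.symbol,
                "log2fc": r.log2fc,
                "signed_fc": r.signed_fc,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "direction": r.direction,
                "is_deg": r.is_deg,
            }
            for r in records
        ],
        columns=[
            "gene_id",
            "symbol",
            "log2fc",
            "signed_fc",
            "p_raw",
            "p_adj",
            "direction",
            "is_deg",
        ],
    )


def write_deg_table(records: Iterable[DEGRecord], path: str | Path) -> None:
    deg_records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    return [
        DEGRecord(
            gene_id=row.gene_id,
            symbol=row.symbol,
            log2fc=float(row.log2fc),
            signed_fc=float(row.signed_fc),
            p_raw=float(row.p_raw),
            p_adj=float(row.p_adj),
            direction=row.direction,
            is_deg=bool(row.is_deg),
        )
        for row in frame.itertuples()
    ]


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(map(str, o))
        if hasattr(o, "item"):
            return o.item()
        if hasattr(o, "tolist"):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
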
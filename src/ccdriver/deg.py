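"""Differential-expression calling and bookkeeping.

Genes are compared between two sample groups on log2 intensities. A gene is a
DEG when its linear fold change exceeds the threshold (|signed FC| > 2 by
default) and its one-way ANOVA p-value clears alpha. Fold changes follow the
Transcriptome Analysis Console sign convention: the signed FC is ``2**log2fc``
for up-regulated genes and ``-2**(-log2fc)`` for down-regulated ones, so its
magnitude is never inside (-1, 1).

Benjamini-Hochberg adjusted p-values are always computed and carried on each
record; gating on them is optional (``use_adjusted``). The default gate is the
raw ANOVA p, which is the filter that defines the DEG tables this pipeline
starts from.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DEGRecord",
    "AnnotationTable",
    "DEGSummary",
    "call_degs",
    "filter_annotated",
    "summarize_deg_table",
    "signed_fold_change",
]


def signed_fold_change(log2fc: float) -> float:
    """Linear fold change with the TAC sign convention (never in (-1, 1))."""
    if log2fc >= 0:
        return float(2.0 ** log2fc)
    return float(-(2.0 ** (-log2fc)))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression of genes across grouped samples.

    Parameters
    ----------
    values
        genes x samples DataFrame of log2 intensities; the index holds unique
        gene ids, the columns unique sample ids. No missing values.
    group_map
        sample id -> group label; every sample column must be mapped and every
        group must contain at least two samples.
    symbols
        optional gene id -> symbol map (defaults to the gene id itself).
    """

    values: pd.DataFrame
    group_map: dict[str, str]
    symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise ValueError("gene ids are not unique")
        if self.values.columns.has_duplicates:
            raise ValueError("sample ids are not unique")
        unmapped = [s for s in self.values.columns if s not in self.group_map]
        if unmapped:
            raise ValueError(f"samples without group label: {unmapped}")
        counts: dict[str, int] = {}
        for s in self.values.columns:
            g = self.group_map[s]
            counts[g] = counts.get(g, 0) + 1
        if len(counts) < 2:
            raise ValueError("need at least two groups")
        low = [g for g, c in counts.items() if c < 2]
        if low:
            raise ValueError(
                f"groups with fewer than two replicates (variance undefined): {low}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns if self.group_map[s] == group]
        if not cols:
            raise KeyError(f"group not present: {group!r}")
        return cols

    def symbol_of(self, gene_id: str) -> str:
        return self.symbols.get(gene_id, gene_id)


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    symbol: str
    log2fc: float
    signed_fc: float
    p_raw: float
    p_adj: float
    direction: str  # "up" or "down"
    is_deg: bool


@dataclass(frozen=True)
class AnnotationTable:
    """Per-gene annotation: symbol (may be empty), biotype, protein flag."""

    table: pd.DataFrame  # columns: gene_id, symbol, biotype, protein_annotated

    def __post_init__(self) -> None:
        required = {"gene_id", "symbol", "biotype", "protein_annotated"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("annotation gene_id not unique")

    def lookup(self, gene_id: str) -> dict | None:
        rows = self.table[self.table["gene_id"] == gene_id]
        if rows.empty:
            return None
        return rows.iloc[0].to_dict()


@dataclass(frozen=True)
class DEGSummary:
    total_genes: int
    n_deg: int
    n_up: int
    n_down: int
    pct_deg: float
    pct_up: float | None
    pct_down: float | None
    pct_unchanged: float
    decimals: int


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def call_degs(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    *,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> list[DEGRecord]:
    """Call DEGs for ``group_a`` versus ``group_b``.

    ``log2fc = mean(group_a) - mean(group_b)``; the p-value is a one-way ANOVA
    across the two groups (identical to a pooled-variance t-test there), and
    BH adjustment is applied over all genes of the matrix. A gene is a DEG
    when ``|signed_fc| > fc_threshold`` and the gating p-value is below
    ``alpha``.

    Degenerate variance is handled explicitly: a gene with zero within-group
    variance and a nonzero group difference gets p = 0 (logged); one with zero
    variance and no difference gets p = 1, so an all-identical matrix yields
    no DEGs.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    a = matrix.values[matrix.samples_in(group_a)].to_numpy(float)
    b = matrix.values[matrix.samples_in(group_b)].to_numpy(float)

    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p_raw = stats.f_oneway(a, b, axis=1)
    p_raw = np.asarray(p_raw, float)

    within_var = a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)
    degenerate = within_var == 0
    n_forced = 0
    for i in np.flatnonzero(degenerate):
        if log2fc[i] != 0:
            p_raw[i] = 0.0
            n_forced += 1
        else:
            p_raw[i] = 1.0
    if n_forced:
        logger.warning(
            "%d gene(s) with zero within-group variance and nonzero difference; "
            "p set to 0",
            n_forced,
        )
    p_raw = np.nan_to_num(p_raw, nan=1.0)

    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    gate = p_adj if use_adjusted else p_raw
    records: list[DEGRecord] = []
    for i, gid in enumerate(matrix.gene_ids):
        lfc = float(log2fc[i])
        sfc = signed_fold_change(lfc)
        records.append(
            DEGRecord(
                gene_id=gid,
                symbol=matrix.symbol_of(gid),
                log2fc=lfc,
                signed_fc=sfc,
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                direction="up" if lfc >= 0 else "down",
                is_deg=bool(abs(sfc) > fc_threshold and gate[i] < alpha),
            )
        )
    return records


def filter_annotated(
    degs: Sequence[DEGRecord], ann: AnnotationTable
) -> tuple[list[DEGRecord], list[DEGRecord]]:
    """Split DEG records into (kept, removed) by the annotation predicate.

    A record is removed when its symbol is empty, its biotype is lncRNA, or it
    lacks a protein annotation. Gene ids absent from the annotation table are
    treated as uncharacterized (and logged). Input order is preserved.
    """
    table = ann.table.set_index("gene_id")
    kept: list[DEGRecord] = []
    removed: list[DEGRecord] = []
    n_missing = 0
    for rec in degs:
        if rec.gene_id not in table.index:
            n_missing += 1
            removed.append(rec)
            continue
        row = table.loc[rec.gene_id]
        symbol = row["symbol"]
        bad = (
            symbol is None
            or (isinstance(symbol, float) and math.isnan(symbol))
            or str(symbol).strip() == ""
            or row["biotype"] == "lncRNA"
            or not bool(row["protein_annotated"])
        )
        (removed if bad else kept).append(rec)
    if n_missing:
        logger.warning(
            "%d DEG gene id(s) missing from annotation; treated as uncharacterized",
            n_missing,
        )
    return kept, removed


def summarize_deg_table(
    total_genes: int,
    degs: Iterable[DEGRecord],
    *,
    decimals_pct: int = 1,
) -> DEGSummary:
    """Count/percentage bookkeeping for a DEG table.

    ``pct_deg`` and ``pct_unchanged`` are percentages of ``total_genes``;
    ``pct_up``/``pct_down`` are percentages of the DEG count. Rounding is
    half-up at ``decimals_pct`` decimals. With no DEGs the up/down
    percentages are undefined (None), not zero.
    """
    if decimals_pct not in (0, 1):
        raise ValueError("decimals_pct must be 0 or 1")
    deg_list = [d for d in degs if d.is_deg]
    n_deg = len(deg_list)
    if n_deg > total_genes:
        raise ValueError("n_deg exceeds total_genes")
    n_up = sum(1 for d in deg_list if d.direction == "up")
    n_down = n_deg - n_up
    pct = lambda num, den: _round_half_up(100.0 * num / den, decimals_pct)
    return DEGSummary(
        total_genes=total_genes,
        n_deg=n_deg,
        n_up=n_up,
        n_down=n_down,
        pct_deg=pct(n_deg, total_genes),
        pct_up=pct(n_up, n_deg) if n_deg else None,
        pct_down=pct(n_down, n_deg) if n_deg else None,
        pct_unchanged=pct(total_genes - n_deg, total_genes),
        decimals=decimals_pct,
    )
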
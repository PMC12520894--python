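"""Driver-gene identification and cross-comparison bookkeeping.

"Highly modulated" drivers are fold-change outliers: genes whose log2 fold
change falls outside the Tukey fences (quartiles by linear interpolation,
1.5 x IQR) AND deviates significantly from the Gaussian of the non-outlier
body (an iterative, externally studentized Grubbs-style test at alpha).
Detection runs on the signed log2 scale, where a Gaussian reference is
meaningful.

"Highly interconnected" drivers (hubs) come from the centrality consensus;
this module partitions both kinds of drivers into shared and distinctive sets
across pairwise comparisons (Venn regions), assembles the driver panel, pulls
first-neighbor context from the network, and handles the small-DEG endpoint
comparison, where network stages are not applicable and a per-gene marker
table is emitted instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .deg import AnnotationTable, DEGRecord, filter_annotated

__all__ = [
    "OutlierCall",
    "VennPartition",
    "DriverPanel",
    "NeighborContext",
    "detect_outliers",
    "venn_partition",
    "assemble_driver_panel",
    "neighbor_context",
    "endpoint_marker_path",
]

QUARTILE_CONVENTION = "linear interpolation (type 7)"


@dataclass(frozen=True)
class OutlierCall:
    gene: str
    log2fc: float
    fence_low: float
    fence_high: float
    outside_fence: bool
    deviation_p: float
    is_outlier: bool


@dataclass(frozen=True)
class VennPartition:
    labels: tuple[str, ...]
    regions: dict  # frozenset(labels) -> frozenset(members), nonempty regions only

    def exclusive(self, label: str) -> frozenset:
        return self.regions.get(frozenset([label]), frozenset())

    def shared(self) -> frozenset:
        """Members present in at least two input sets."""
        out: set = set()
        for key, members in self.regions.items():
            if len(key) >= 2:
                out |= members
        return frozenset(out)


@dataclass(frozen=True)
class DriverPanel:
    distinctive_outliers: dict  # label -> frozenset
    shared_outliers: frozenset
    distinctive_hubs: dict
    shared_hubs: frozenset
    panel_size: int


@dataclass(frozen=True)
class NeighborContext:
    driver: str
    neighbors: tuple  # (symbol, direction) pairs, sorted by symbol
    neighbor_count: int


def _deviation_p(x: float, reference: np.ndarray) -> float:
    """Two-sided p for x against the Gaussian fitted to ``reference``.

    Externally studentized: t = |x - mean| / (s * sqrt(1 + 1/n)), df = n - 1.
    This is the Grubbs statistic with the candidate held out of the sample.
    """
    n = reference.size
    if n < 3:
        return 1.0
    s = reference.std(ddof=1)
    if s == 0:
        return 0.0 if x != reference[0] else 1.0
    t = abs(x - reference.mean()) / (s * np.sqrt(1.0 + 1.0 / n))
    return float(min(1.0, 2.0 * stats.t.sf(t, df=n - 1)))


def detect_outliers(
    degs: Sequence[DEGRecord],
    *,
    alpha: float = 0.05,
    fence_mult: float = 1.5,
    require_fence: bool = True,
    require_deviation: bool = True,
) -> list[OutlierCall]:
    """Flag highly modulated DEGs on the log2 fold-change distribution.

    Quartiles use linear interpolation; fences are Q1 - fence_mult*IQR and
    Q3 + fence_mult*IQR of the full log2fc sample. Fence candidates are then
    tested most-extreme-first against the remaining (non-flagged) values and
    removed while significant at ``alpha``. By default a gene is an outlier
    only when it is outside the fences AND deviates significantly
    (``require_*`` flags expose each criterion alone).
    """
    records = list(degs)
    if len(records) < 5:
        raise ValueError(
            "need at least 5 DEGs for quartiles; use endpoint_marker_path for "
            "small comparisons"
        )
    if not (require_fence or require_deviation):
        raise ValueError("at least one outlier criterion must be required")
    values = np.array([r.log2fc for r in records], dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - fence_mult * iqr, q3 + fence_mult * iqr
    outside = (values < lo) | (values > hi)

    # iterative Grubbs-style pruning, most extreme candidate first
    if require_fence:
        excess = np.maximum(lo - values, values - hi)
        candidates = sorted(np.flatnonzero(outside), key=lambda i: -excess[i])
    else:
        med = np.median(values)
        candidates = sorted(range(len(values)), key=lambda i: -abs(values[i] - med))
    remaining = set(range(len(values)))
    flagged: set = set()
    for i in candidates:
        ref = np.array([values[j] for j in remaining if j != i])
        if _deviation_p(values[i], ref) < alpha:
            flagged.add(i)
            remaining.discard(i)
        else:
            break

    body = np.array([values[j] for j in remaining])
    calls = []
    for i, rec in enumerate(records):
        ref = np.array([values[j] for j in remaining if j != i]) if i in remaining else body
        p = _deviation_p(values[i], ref)
        is_out = (outside[i] if require_fence else True) and (
            i in flagged if require_deviation else True
        )
        calls.append(
            OutlierCall(
                gene=rec.symbol,
                log2fc=float(values[i]),
                fence_low=float(lo),
                fence_high=float(hi),
                outside_fence=bool(outside[i]),
                deviation_p=p,
                is_outlier=bool(is_out),
            )
        )
    return calls


def venn_partition(sets: Mapping[str, set]) -> VennPartition:
    """Enumerate every nonempty intersection/exclusive region of 2-4 sets."""
    labels = tuple(sets)
    if not 2 <= len(labels) <= 4:
        raise ValueError("venn_partition supports 2-4 sets")
    regions: dict = {}
    for r in range(1, len(labels) + 1):
        for inside in itertools.combinations(labels, r):
            members = set.intersection(*(set(sets[l]) for l in inside))
            for other in labels:
                if other not in inside:
                    members -= set(sets[other])
            if members:
                regions[frozenset(inside)] = frozenset(members)
    return VennPartition(labels=labels, regions=regions)


def assemble_driver_panel(
    outliers_by_comparison: Mapping[str, set],
    hubs_by_comparison: Mapping[str, set],
) -> DriverPanel:
    """Partition outliers and hubs into shared/distinctive sets per comparison.

    Distinctive = exclusive Venn region of one comparison; shared = members of
    any multi-set region. The panel size is the size of the union of all
    distinctive outliers and distinctive hubs (a gene appearing in both
    categories counts once).
    """
    if set(outliers_by_comparison) != set(hubs_by_comparison):
        raise ValueError("outlier and hub maps must share comparison labels")
    labels = list(outliers_by_comparison)
    if len(labels) == 1:
        label = labels[0]
        d_out = {label: frozenset(outliers_by_comparison[label])}
        d_hub = {label: frozenset(hubs_by_comparison[label])}
        panel = set(d_out[label]) | set(d_hub[label])
        return DriverPanel(d_out, frozenset(), d_hub, frozenset(), len(panel))
    v_out = venn_partition(outliers_by_comparison)
    v_hub = venn_partition(hubs_by_comparison)
    d_out = {l: v_out.exclusive(l) for l in labels}
    d_hub = {l: v_hub.exclusive(l) for l in labels}
    panel = set()
    for l in labels:
        panel |= d_out[l] | d_hub[l]
    return DriverPanel(
        distinctive_outliers=d_out,
        shared_outliers=v_out.shared(),
        distinctive_hubs=d_hub,
        shared_hubs=v_hub.shared(),
        panel_size=len(panel),
    )


def neighbor_context(net: nx.Graph, driver: str) -> NeighborContext:
    """First neighbors of a driver with their regulation direction."""
    if driver not in net:
        raise KeyError(f"driver not in network: {driver!r}")
    nbrs = sorted(net.neighbors(driver), key=str)
    pairs = tuple((str(v), net.nodes[v].get("direction", "")) for v in nbrs)
    return NeighborContext(driver=str(driver), neighbors=pairs, neighbor_count=len(pairs))


def endpoint_marker_path(
    degs: Sequence[DEGRecord],
    ann: AnnotationTable,
    *,
    min_for_network: int = 20,
) -> dict:
    """Small-DEG endpoint handling.

    When the comparison yields fewer DEGs than ``min_for_network``, dense-
    module clustering and driver filtering are not applicable; the annotation
    filter is applied and a per-gene marker table (sorted by |log2fc|, with
    direction) is returned instead. Larger comparisons are delegated to the
    full network path (``fallback`` False, no table).
    """
    deg_list = [d for d in degs if d.is_deg]
    if len(deg_list) >= min_for_network:
        return {"fallback": False, "markers": None, "n_deg": len(deg_list)}
    kept, removed = filter_annotated(deg_list, ann)
    rows = [
        {
            "gene_id": d.gene_id,
            "symbol": d.symbol,
            "log2fc": d.log2fc,
            "signed_fc": d.signed_fc,
            "p_raw": d.p_raw,
            "p_adj": d.p_adj,
            "direction": d.direction,
        }
        for d in sorted(kept, key=lambda d: (-abs(d.log2fc), d.symbol))
    ]
    markers = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "symbol",
            "log2fc",
            "signed_fc",
            "p_raw",
            "p_adj",
            "direction",
        ],
    )
    return {
        "fallback": True,
        "markers": markers,
        "n_deg": len(deg_list),
        "n_removed_unannotated": len(removed),
    }
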
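"""End-to-end per-comparison analysis with a machine-readable report.

For every pairwise comparison: DEG calling and Table-1-style summary, the
annotation filter, then either the full network path (induced network,
topology and scale-free check, dense-module detection and retention,
centrality-consensus hubs, fold-change outliers) or — when the comparison
yields too few DEGs for network analysis — the per-gene endpoint marker
table. Across comparisons the outlier and hub sets are partitioned into
shared and distinctive drivers (Venn regions), assembled into the driver
panel, and each distinctive driver gets its first-neighbor context.

Hub candidates default to the members of retained modules (the dense-module
workflow); set ``hub_scope="network"`` to rank every node. When ground truth
is supplied, recovery metrics (DEG sensitivity/FDP, hub and outlier
precision/recall, per-module best Jaccard) are embedded in the report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx

from . import drivers as drv
from . import mcode
from .centrality import call_hubs, compute_centralities, top_k_sets
from .deg import AnnotationTable, ExpressionMatrix, call_degs, filter_annotated, summarize_deg_table
from .network import build_network, scale_free_fit, topology_report
from .simulate import GroundTruth, StudyBundle

__all__ = ["PipelineConfig", "run_pairwise_analysis", "run_fixture_study"]


@dataclass(frozen=True)
class PipelineConfig:
    comparisons: tuple  # (label, group_a, group_b)
    fc_threshold: float = 2.0
    alpha: float = 0.05
    use_adjusted: bool = False
    decimals_pct: int = 1
    vwp: float = 0.2
    haircut: bool = True
    kcore_min_exclusive: int = 5
    degree_min_exclusive: float = 5.0
    degree_statistic: str = "mean"
    hub_k: int = 10
    hub_min_metrics: int = 5
    hub_scope: str = "modules"  # or "network"
    epc_realizations: int = 1000
    epc_retention: float = 0.5
    outlier_alpha: float = 0.05
    fence_mult: float = 1.5
    min_for_network: int = 20
    seed: int = 0

    def validate(self) -> None:
        labels = [c[0] for c in self.comparisons]
        if len(labels) != len(set(labels)):
            raise ValueError("comparison labels must be unique")
        if self.hub_scope not in ("modules", "network"):
            raise ValueError("hub_scope must be 'modules' or 'network'")


def _recovery(called: set, truth: set) -> dict:
    tp = len(called & truth)
    return {
        "n_called": len(called),
        "n_true": len(truth),
        "tp": tp,
        "precision": tp / len(called) if called else None,
        "recall": tp / len(truth) if truth else None,
    }


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a or b) else 0.0


def _analyze_comparison(
    label: str,
    group_a: str,
    group_b: str,
    matrix: ExpressionMatrix,
    annotation: AnnotationTable,
    interactome_edges: list,
    cfg: PipelineConfig,
    seed_offset: int,
) -> dict:
    degs_all = call_degs(
        matrix,
        group_a,
        group_b,
        fc_threshold=cfg.fc_threshold,
        alpha=cfg.alpha,
        use_adjusted=cfg.use_adjusted,
    )
    called = [d for d in degs_all if d.is_deg]
    summary = summarize_deg_table(
        len(matrix.gene_ids), degs_all, decimals_pct=cfg.decimals_pct
    )
    out: dict = {
        "label": label,
        "group_a": group_a,
        "group_b": group_b,
        "summary": asdict(summary),
        "called_symbols": sorted(d.symbol for d in called),
    }

    endpoint = drv.endpoint_marker_path(
        degs_all, annotation, min_for_network=cfg.min_for_network
    )
    if endpoint["fallback"]:
        markers = endpoint["markers"]
        out.update(
            fallback=True,
            markers=markers.to_dict(orient="records"),
            n_markers=len(markers),
            n_removed_unannotated=endpoint["n_removed_unannotated"],
            marker_directions={
                "up": int((markers["direction"] == "up").sum()),
                "down": int((markers["direction"] == "down").sum()),
            },
        )
        return out

    kept, removed = filter_annotated(called, annotation)
    out["fallback"] = False
    out["annotation_filter"] = {
        "n_input": len(called),
        "n_kept": len(kept),
        "n_removed": len(removed),
    }
    net = build_network(kept, interactome_edges)
    out["_network"] = net  # stripped before serialization
    out["topology"] = topology_report(net).to_dict()
    fit = scale_free_fit(net, strict=False)
    out["scale_free"] = asdict(fit)

    weights = mcode.mcode_vertex_weights(net)
    complexes = mcode.mcode_find_complexes(net, weights, vwp=cfg.vwp, haircut=cfg.haircut)
    retained = mcode.filter_modules(
        complexes,
        kcore_min_exclusive=cfg.kcore_min_exclusive,
        degree_min_exclusive=cfg.degree_min_exclusive,
        degree_statistic=cfg.degree_statistic,
    )
    out["_complexes"] = complexes
    out["modules"] = [
        {
            "seed": str(c.seed_node),
            "n_nodes": c.size,
            "mcode_score": c.mcode_score,
            "kcore_max": c.kcore_max,
            "avg_within_degree": c.avg_within_degree,
            "retained": c in retained,
            "nodes": sorted(map(str, c.node_set)),
        }
        for c in complexes
    ]

    table = compute_centralities(
        net,
        epc_realizations=cfg.epc_realizations,
        epc_retention=cfg.epc_retention,
        seed=cfg.seed + seed_offset,
    )
    candidates = None
    if cfg.hub_scope == "modules" and retained:
        candidates = set().union(*(c.node_set for c in retained))
        candidates = {str(v) for v in candidates}
    tops = top_k_sets(table, k=cfg.hub_k, candidates=candidates)
    hub_calls = call_hubs(tops, min_metrics=cfg.hub_min_metrics)
    out["hub_calls"] = [
        {
            "node": h.node,
            "n_top_memberships": h.n_top_memberships,
            "is_hub": h.is_hub,
        }
        for h in hub_calls
    ]
    out["hubs"] = sorted(h.node for h in hub_calls if h.is_hub)

    if len(kept) >= 5:
        outlier_calls = drv.detect_outliers(
            kept, alpha=cfg.outlier_alpha, fence_mult=cfg.fence_mult
        )
        out["outliers"] = sorted(c.gene for c in outlier_calls if c.is_outlier)
        out["outlier_fences"] = [outlier_calls[0].fence_low, outlier_calls[0].fence_high]
    else:
        out["outliers"] = []
        out["outlier_fences"] = None
    return out


def run_pairwise_analysis(
    matrix: ExpressionMatrix,
    annotation: AnnotationTable,
    interactome: nx.Graph | list,
    config: PipelineConfig,
    *,
    truth: dict | None = None,
) -> dict:
    """Run every configured comparison and assemble the study report."""
    config.validate()
    edges = (
        [(str(u), str(v)) for u, v in interactome.edges()]
        if isinstance(interactome, nx.Graph)
        else list(interactome)
    )
    report: dict = {"parameters": asdict(config), "comparisons": {}}
    results = {}
    for i, (label, a, b) in enumerate(config.comparisons):
        results[label] = _analyze_comparison(
            label, a, b, matrix, annotation, edges, config, seed_offset=i
        )

    network_labels = [l for l, r in results.items() if not r["fallback"]]
    if len(network_labels) >= 2:
        panel = drv.assemble_driver_panel(
            {l: set(results[l]["outliers"]) for l in network_labels},
            {l: set(results[l]["hubs"]) for l in network_labels},
        )
        report["driver_panel"] = {
            "distinctive_outliers": {
                l: sorted(panel.distinctive_outliers[l]) for l in network_labels
            },
            "shared_outliers": sorted(panel.shared_outliers),
            "distinctive_hubs": {
                l: sorted(panel.distinctive_hubs[l]) for l in network_labels
            },
            "shared_hubs": sorted(panel.shared_hubs),
            "panel_size": panel.panel_size,
        }
        context: dict = {}
        for l in network_labels:
            net = results[l]["_network"]
            drivers_here = set(panel.distinctive_outliers[l]) | set(
                panel.distinctive_hubs[l]
            )
            context[l] = {}
            for d in sorted(drivers_here):
                if d in net:
                    ctx = drv.neighbor_context(net, d)
                    context[l][d] = {
                        "neighbor_count": ctx.neighbor_count,
                        "neighbors": [list(p) for p in ctx.neighbors],
                    }
        report["neighbor_context"] = context

    if truth is not None:
        report["recovery"] = _recovery_report(results, truth)

    for label, r in results.items():
        r.pop("_network", None)
        r.pop("_complexes", None)
        report["comparisons"][label] = r
    return report


def _recovery_report(results: dict, truth: dict) -> dict:
    rec: dict = {"per_comparison": {}}
    hub_tp = hub_called = hub_true = 0
    out_tp = out_called = out_true = 0
    jaccards: list[float] = []
    for label, r in results.items():
        t: GroundTruth = truth.get(label)
        if t is None:
            continue
        called = set(r["called_symbols"])
        true_degs = set(t.true_deg_ids)
        entry = {
            "deg_sensitivity": len(called & true_degs) / len(true_degs)
            if true_degs
            else None,
            "deg_fdp": len(called - true_degs) / len(called) if called else None,
        }
        if not r["fallback"]:
            hubs = set(r["hubs"])
            th = set(t.true_hub_ids)
            outs = set(r["outliers"])
            to = set(t.true_outlier_ids)
            entry["hubs"] = _recovery(hubs, th)
            entry["outliers"] = _recovery(outs, to)
            hub_tp += len(hubs & th)
            hub_called += len(hubs)
            hub_true += len(th)
            out_tp += len(outs & to)
            out_called += len(outs)
            out_true += len(to)
            mods = []
            for ms in t.true_module_nodesets:
                best = max(
                    (_jaccard(set(map(str, ms)), set(map(str, c.node_set)))
                     for c in r["_complexes"]),
                    default=0.0,
                )
                mods.append(best)
            entry["module_best_jaccard"] = mods
            jaccards.extend(mods)
        rec["per_comparison"][label] = entry
    rec["hub_precision"] = hub_tp / hub_called if hub_called else None
    rec["hub_recall"] = hub_tp / hub_true if hub_true else None
    rec["outlier_precision"] = out_tp / out_called if out_called else None
    rec["outlier_recall"] = out_tp / out_true if out_true else None
    rec["module_jaccard_min"] = min(jaccards) if jaccards else None
    return rec


def run_fixture_study(
    sim_config=None,
    *,
    pipeline_overrides: dict | None = None,
) -> tuple[StudyBundle, dict]:
    """Generate the bundled study fixture and run the full analysis on it."""
    from .simulate import make_fixture_study

    bundle = make_fixture_study(sim_config)
    overrides = pipeline_overrides or {}
    cfg = PipelineConfig(
        comparisons=bundle.comparisons, seed=bundle.config.seed, **overrides
    )
    report = run_pairwise_analysis(
        bundle.matrix,
        bundle.annotation,
        bundle.interactome,
        cfg,
        truth=bundle.truth,
    )
    return bundle, report
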
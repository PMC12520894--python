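"""Outlier drivers, Venn partitioning, the driver panel and the endpoint path."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ccdriver.deg import AnnotationTable, DEGRecord, signed_fold_change
from ccdriver.drivers import (
    assemble_driver_panel,
    detect_outliers,
    endpoint_marker_path,
    neighbor_context,
    venn_partition,
)

import networkx as nx


def rec(gene, log2fc, is_deg=True):
    return DEGRecord(
        gene_id=gene,
        symbol=gene,
        log2fc=log2fc,
        signed_fc=signed_fold_change(log2fc),
        p_raw=0.01,
        p_adj=0.02,
        direction="up" if log2fc >= 0 else "down",
        is_deg=is_deg,
    )


def recs(values):
    return [rec(f"g{i}", v) for i, v in enumerate(values)]


class TestDetectOutliers:
    def test_single_extreme_value_flagged(self):
        calls = detect_outliers(recs([1.1, 1.2, -1.1, 1.3, -1.2, 5.3]))
        flagged = [c.gene for c in calls if c.is_outlier]
        assert flagged == ["g5"]
        c5 = calls[5]
        assert c5.outside_fence and c5.deviation_p < 0.05
        # fences from type-7 quartiles: Q1=-0.55, Q3=1.275
        assert c5.fence_low == pytest.approx(-0.55 - 1.5 * 1.825)
        assert c5.fence_high == pytest.approx(1.275 + 1.5 * 1.825)

    def test_constant_vector_no_outliers(self):
        calls = detect_outliers(recs([2.0] * 8))
        assert not any(c.is_outlier for c in calls)

    def test_too_few_values_error_mentions_fallback(self):
        with pytest.raises(ValueError, match="endpoint"):
            detect_outliers(recs([1, 2, 3, 4]))

    def test_conjunction_invariant(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 40), [9.0, -8.5]])
        for c in detect_outliers(recs(vals)):
            if c.is_outlier:
                assert c.outside_fence and c.deviation_p < 0.05

    def test_criterion_flags(self):
        vals = [1.1, 1.2, -1.1, 1.3, -1.2, 5.3]
        fence_only = detect_outliers(recs(vals), require_deviation=False)
        grubbs_only = detect_outliers(recs(vals), require_fence=False)
        assert [c.gene for c in fence_only if c.is_outlier] == ["g5"]
        assert [c.gene for c in grubbs_only if c.is_outlier] == ["g5"]
        with pytest.raises(ValueError):
            detect_outliers(recs(vals), require_fence=False, require_deviation=False)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(st.floats(-3, 3), min_size=8, max_size=25),
        st.floats(0.5, 4),
        st.floats(-5, 5),
    )
    def test_affine_equivariance(self, body, a, b):
        vals = np.round(np.array(body + [20.0]), 3)  # one clear outlier
        base = [c.is_outlier for c in detect_outliers(recs(vals))]
        moved = [c.is_outlier for c in detect_outliers(recs(a * vals + b))]
        assert base == moved

    def test_planted_outlier_recovery_over_seeds(self):
        rng = np.random.default_rng(17)
        fp = 0
        for _ in range(50):
            n = 1000
            vals = rng.uniform(-1.5, 1.5, n)
            planted = rng.choice(n, 5, replace=False)
            vals[planted] = rng.choice([-1, 1], 5) * rng.uniform(4, 6, 5)
            calls = detect_outliers(recs(vals))
            flagged = {int(c.gene[1:]) for c in calls if c.is_outlier}
            assert set(planted.tolist()) <= flagged  # sensitivity 1.0
            fp += len(flagged - set(planted.tolist()))
        assert fp / 50 <= 1.0  # <= 1 false positive per 1,000 genes on average


class TestVennPartition:
    def test_two_sets(self):
        part = venn_partition({"L": {"A", "B", "C"}, "R": {"B", "C", "D"}})
        assert part.exclusive("L") == {"A"}
        assert part.exclusive("R") == {"D"}
        assert part.shared() == {"B", "C"}

    def test_study_hub_sets(self):
        n1 = {"KIF11", "CDC6", "CDCA8", "CCNA2", "PLK1"}
        n2 = {"CASP3", "CDCA8", "CCNA2", "PLK1"}
        part = venn_partition({"network1": n1, "network2": n2})
        assert part.shared() == {"CDCA8", "CCNA2", "PLK1"}
        assert part.exclusive("network1") == {"KIF11", "CDC6"}
        assert part.exclusive("network2") == {"CASP3"}

    def test_identical_sets_single_region(self):
        part = venn_partition({"a": {"X", "Y"}, "b": {"X", "Y"}})
        assert part.regions == {frozenset({"a", "b"}): frozenset({"X", "Y"})}

    def test_regions_partition_the_union(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            sets = {
                f"s{i}": set(rng.choice(30, size=rng.integers(0, 15), replace=False).tolist())
                for i in range(k)
            }
            part = venn_partition(sets)
            union = set().union(*sets.values())
            seen = []
            for members in part.regions.values():
                seen.extend(members)
            assert len(seen) == len(set(seen))  # disjoint
            assert set(seen) == union

    @pytest.mark.parametrize("k", [1, 5])
    def test_arity_limits(self, k):
        with pytest.raises(ValueError):
            venn_partition({f"s{i}": {"x"} for i in range(k)})


class TestDriverPanel:
    def test_study_panel_of_twelve(self):
        outliers = {
            "network1": {"EFHD1", "HS6ST2", "SLC35G1"},
            "network2": {"HBA1", "SLC39A8", "ERO1A", "TKDP5", "CALCRL", "ELOVL6"},
        }
        hubs = {"network1": {"KIF11", "CDC6"}, "network2": {"CASP3"}}
        panel = assemble_driver_panel(outliers, hubs)
        assert panel.panel_size == 12
        assert panel.distinctive_hubs["network1"] == {"KIF11", "CDC6"}
        assert panel.shared_outliers == frozenset()

    def test_empty_sets(self):
        panel = assemble_driver_panel({"a": set(), "b": set()}, {"a": set(), "b": set()})
        assert panel.panel_size == 0

    def test_union_semantics_across_categories(self):
        panel = assemble_driver_panel(
            {"a": {"X"}, "b": set()}, {"a": {"X"}, "b": set()}
        )
        assert panel.panel_size == 1  # same gene in both categories counts once

    def test_shared_members_not_distinctive(self):
        panel = assemble_driver_panel(
            {"a": {"X", "Y"}, "b": {"X"}}, {"a": set(), "b": set()}
        )
        assert panel.shared_outliers == {"X"}
        assert panel.distinctive_outliers["a"] == {"Y"}
        assert panel.panel_size == 1

    def test_order_invariance(self):
        o = {"a": {"P", "Q"}, "b": {"Q", "R"}}
        h = {"a": {"H1"}, "b": set()}
        p1 = assemble_driver_panel(o, h)
        p2 = assemble_driver_panel(
            {"b": o["b"], "a": o["a"]}, {"b": h["b"], "a": h["a"]}
        )
        assert p1.panel_size == p2.panel_size
        assert p1.shared_outliers == p2.shared_outliers

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError):
            assemble_driver_panel({"a": set()}, {"b": set()})


class TestNeighborContext:
    def test_isolated_driver_has_no_partners(self):
        g = nx.Graph()
        g.add_node("HBA1", direction="up")
        ctx = neighbor_context(g, "HBA1")
        assert ctx.neighbor_count == 0 and ctx.neighbors == ()

    def test_star_center_returns_all_leaves(self):
        g = nx.star_graph(4)
        nx.set_node_attributes(g, "down", "direction")
        ctx = neighbor_context(g, 0)
        assert ctx.neighbor_count == 4
        assert [n for n, _ in ctx.neighbors] == ["1", "2", "3", "4"]

    def test_matches_adjacency(self, study_run):
        bundle, report = study_run
        g = bundle.interactome
        driver = sorted(bundle.interactome_truth.true_hub_ids)[0]
        ctx = neighbor_context(g, driver)
        assert set(n for n, _ in ctx.neighbors) == set(map(str, g.neighbors(driver)))

    def test_unknown_driver(self):
        with pytest.raises(KeyError):
            neighbor_context(nx.path_graph(3), "missing")


def annotation(rows):
    return AnnotationTable(
        table=pd.DataFrame(rows, columns=["gene_id", "symbol", "biotype", "protein_annotated"])
    )


class TestEndpointMarkerPath:
    def test_small_comparison_eleven_markers(self):
        # 13 DEGs, 2 uncharacterized, exactly one upregulated among the kept
        values = [0.8 + 0.1 * i for i in range(13)]
        degs = [rec(f"g{i}", -v) for i, v in enumerate(values)]
        degs[5] = rec("g5", +1.7)
        rows = [(f"g{i}", "" if i in (0, 1) else f"S{i}", "protein_coding", i >= 2) for i in range(13)]
        result = endpoint_marker_path(degs, annotation(rows))
        assert result["fallback"]
        markers = result["markers"]
        assert len(markers) == 11
        assert (markers["direction"] == "up").sum() == 1
        assert (markers["direction"] == "down").sum() == 10
        assert list(markers["log2fc"].abs()) == sorted(
            markers["log2fc"].abs(), reverse=True
        )

    def test_large_comparison_delegates(self):
        degs = [rec(f"g{i}", 1.5) for i in range(500)]
        rows = [(f"g{i}", f"S{i}", "protein_coding", True) for i in range(500)]
        result = endpoint_marker_path(degs, annotation(rows))
        assert result["fallback"] is False and result["markers"] is None

    def test_no_degs_empty_table(self):
        result = endpoint_marker_path([], annotation([]))
        assert result["fallback"] and len(result["markers"]) == 0
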
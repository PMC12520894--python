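"""Synthetic expression matrices, interactomes and bundled study fixtures.

The generator emulates the shape of a cumulus-cell microarray study: a few
tens of thousands of transcripts measured in three biological replicates per
group on the log2 scale, a minority (~6%) of genes carrying a planted linear
fold change above 2, a scale-free interactome grown by preferential
attachment with planted dense modules and planted high-centrality hubs, and a
handful of extreme-fold-change outlier genes. Every draw is governed by one
seed, so identical configurations reproduce bit-identical outputs.

Planted effect magnitudes are lognormal on the linear-FC scale (median 2.8,
shape 0.5 by default), resampled below FC 2, so most planted DEGs clear the
FC>2 gate while only a deliberately separated extreme tail (the planted
outliers) reaches outlier magnitude.

``make_fixture_study`` bundles a three-group study (baseline plus two
endpoint groups) in which most planted effects are shared by both endpoint
groups and a small set is endpoint-specific — so the two endpoint-vs-baseline
comparisons yield full-size DEG sets with shared and distinctive drivers,
while the endpoint-vs-endpoint comparison yields only the handful of
specific genes and exercises the small-DEG marker path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .deg import AnnotationTable, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyBundle",
    "simulate_expression",
    "simulate_interactome",
    "make_fixture_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    ``log2fc_effect`` is (median linear FC, lognormal shape). ``noise_sd`` is
    the per-observation Gaussian SD in log2 units. ``planted_outliers`` is
    (count, |log2FC| floor); outlier magnitudes are drawn as
    floor + |N(0, 0.5)| so they sit clear of the Tukey fences implied by the
    body of planted effects. ``planted_modules`` lists (size, within-density)
    pairs; ``planted_hubs`` nodes are each wired to ``hub_wiring_fraction``
    of all network nodes.
    """

    n_genes: int = 1000
    groups: tuple = (("MII_end", 3), ("GV_start", 3))
    deg_fraction: float = 0.06
    log2fc_effect: tuple = (2.8, 0.5)
    noise_sd: float = 0.25
    down_fraction: float = 0.54
    network_size: int = 500
    attachment_m: int = 2
    planted_modules: tuple = ((14, 1.0), (6, 1.0))
    planted_hubs: int = 12
    hub_wiring_fraction: float = 0.2
    planted_outliers: tuple = (11, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.network_size <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must lie in [0, 1]")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for label, reps in self.groups:
            if reps < 2:
                raise ValueError(
                    f"group {label!r} has {reps} replicate(s); at least 2 required "
                    "(within-group variance undefined otherwise)"
                )
        n_outliers = self.planted_outliers[0]
        if round(self.deg_fraction * self.n_genes) < n_outliers:
            raise ValueError("more planted outliers than planted DEGs")
        if self.network_size <= self.attachment_m:
            raise ValueError("network_size must exceed attachment_m")
        for size, density in self.planted_modules:
            if size > self.network_size:
                raise ValueError("planted module larger than the network")
            if density > 1.0:
                raise ValueError("within-density cannot exceed 1")


@dataclass(frozen=True)
class GroundTruth:
    true_deg_ids: frozenset = frozenset()
    true_directions: dict = field(default_factory=dict)
    true_module_nodesets: tuple = ()
    true_hub_ids: frozenset = frozenset()
    true_outlier_ids: frozenset = frozenset()


@dataclass(frozen=True)
class StudyBundle:
    config: SimulationConfig
    matrix: ExpressionMatrix
    annotation: AnnotationTable
    interactome: nx.Graph
    interactome_truth: GroundTruth
    truth: dict  # comparison label -> GroundTruth
    comparisons: tuple  # (label, group_a, group_b)


def _symbol(i: int) -> str:
    return f"G{i + 1:06d}"


def _gene_id(i: int) -> str:
    return f"TC{i + 1:06d}"


def _draw_body_magnitudes(
    rng: np.random.Generator, n: int, effect: tuple, *, min_linear_fc: float = 2.0
) -> np.ndarray:
    """|log2FC| of ordinary planted DEGs: lognormal linear FC, resampled below
    the floor (FC 2 by default, so every planted DEG clears the DEG gate)."""
    median, shape = effect
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(np.log(median), shape, size=max(2 * (n - filled), 8))
        draw = draw[draw >= min_linear_fc]
        take = min(n - filled, draw.size)
        out[filled : filled + take] = draw[:take]
        filled += take
    return np.log2(out)


def _draw_outlier_magnitudes(
    rng: np.random.Generator, n: int, floor: float
) -> np.ndarray:
    return floor + np.abs(rng.normal(0.0, 0.5, size=n))


def _build_matrix(
    config: SimulationConfig,
    offsets: np.ndarray,  # n_genes x n_groups group-mean log2 offsets
    rng: np.random.Generator,
) -> ExpressionMatrix:
    n = config.n_genes
    base = rng.normal(7.0, 1.0, size=n)
    columns: dict[str, np.ndarray] = {}
    group_map: dict[str, str] = {}
    for gi, (label, reps) in enumerate(config.groups):
        for r in range(reps):
            sample = f"{label}_r{r + 1}"
            noise = (
                rng.normal(0.0, config.noise_sd, size=n)
                if config.noise_sd > 0
                else np.zeros(n)
            )
            columns[sample] = base + offsets[:, gi] + noise
            group_map[sample] = label
    values = pd.DataFrame(columns, index=[_gene_id(i) for i in range(n)])
    symbols = {_gene_id(i): _symbol(i) for i in range(n)}
    return ExpressionMatrix(values=values, group_map=group_map, symbols=symbols)


def simulate_expression(
    config: SimulationConfig,
    *,
    planted_effects: dict | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Two-or-more-group expression matrix with planted DEGs.

    Planted DEGs carry a group-mean log2 difference (first listed group vs
    all others) drawn from the configured effect distribution, always with
    |difference| >= 1 (linear FC >= 2); other genes have no group difference.
    ``planted_effects`` maps gene symbols to exact log2 differences and
    overrides/extends the random planting (handy for closed-form checks).
    Returns the matrix and the ground truth of the first-vs-rest contrast.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_deg = round(config.deg_fraction * n)
    deg_idx = np.sort(rng.choice(n, size=n_deg, replace=False))
    n_out, floor = config.planted_outliers
    out_idx = (
        np.sort(rng.choice(deg_idx, size=n_out, replace=False)) if n_out else np.array([], int)
    )
    out_set = set(out_idx.tolist())

    delta = np.zeros(n)
    body = [i for i in deg_idx if i not in out_set]
    mags = _draw_body_magnitudes(rng, len(body), config.log2fc_effect)
    signs = np.where(rng.random(len(body)) < config.down_fraction, -1.0, 1.0)
    for j, i in enumerate(body):
        delta[i] = signs[j] * mags[j]
    omags = _draw_outlier_magnitudes(rng, len(out_idx), floor)
    osigns = np.where(rng.random(len(out_idx)) < config.down_fraction, -1.0, 1.0)
    for j, i in enumerate(out_idx):
        delta[i] = osigns[j] * omags[j]

    symbol_to_idx = {_symbol(i): i for i in range(n)}
    extra = set()
    if planted_effects:
        for sym, d in planted_effects.items():
            i = symbol_to_idx[sym]
            delta[i] = d
            extra.add(i)

    offsets = np.zeros((n, len(config.groups)))
    offsets[:, 0] = delta
    matrix = _build_matrix(config, offsets, rng)

    deg_all = sorted(set(deg_idx.tolist()) | {i for i in extra if delta[i] != 0})
    truth = GroundTruth(
        true_deg_ids=frozenset(_symbol(i) for i in deg_all),
        true_directions={
            _symbol(i): ("up" if delta[i] >= 0 else "down") for i in deg_all
        },
        true_outlier_ids=frozenset(_symbol(i) for i in out_idx),
    )
    return matrix, truth


def _plant_module(
    g: nx.Graph, nodes: list, density: float, rng: np.random.Generator
) -> None:
    size = len(nodes)
    target = round(density * size * (size - 1) / 2)
    missing = [
        (nodes[i], nodes[j])
        for i in range(size)
        for j in range(i + 1, size)
        if not g.has_edge(nodes[i], nodes[j])
    ]
    have = size * (size - 1) // 2 - len(missing)
    need = max(0, target - have)
    if need:
        pick = rng.choice(len(missing), size=need, replace=False)
        for k in pick:
            g.add_edge(*missing[k])


def simulate_interactome(
    config: SimulationConfig,
    *,
    node_symbols: list | None = None,
    module_nodes: list | None = None,
    hub_nodes: list | None = None,
) -> tuple[nx.Graph, GroundTruth]:
    """Scale-free backbone with planted dense modules and planted hubs.

    The backbone grows by preferential attachment (``attachment_m`` edges per
    new node). Each planted module is realized by adding edges among a chosen
    node subset until the requested within-density is reached; each planted
    hub is wired to a random ``hub_wiring_fraction`` of all nodes. Node
    labels are gene symbols consistent with ``simulate_expression`` output
    (overridable via ``node_symbols``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = config.network_size
    backbone_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(n, config.attachment_m, seed=backbone_seed)
    symbols = node_symbols if node_symbols is not None else [_symbol(i) for i in range(n)]
    if len(symbols) != n:
        raise ValueError("node_symbols length must equal network_size")
    g = nx.relabel_nodes(g, dict(enumerate(symbols)))

    used: set = set()
    module_sets: list[frozenset] = []
    specs = list(config.planted_modules)
    if module_nodes is not None:
        if len(module_nodes) != len(specs):
            raise ValueError("module_nodes must match planted_modules")
    for mi, (size, density) in enumerate(specs):
        if module_nodes is not None:
            nodes = list(module_nodes[mi])
            if len(nodes) != size:
                raise ValueError("module node list size mismatch")
        else:
            free = [s for s in symbols if s not in used]
            nodes = [free[k] for k in rng.choice(len(free), size=size, replace=False)]
        used.update(nodes)
        _plant_module(g, nodes, density, rng)
        module_sets.append(frozenset(nodes))

    if hub_nodes is not None:
        hubs = list(hub_nodes)
    else:
        free = [s for s in symbols if s not in used]
        hubs = [
            free[k]
            for k in rng.choice(len(free), size=config.planted_hubs, replace=False)
        ]
    # hubs wire into the backbone, avoiding planted-module nodes, so the two
    # planted motifs (dense modules, global hubs) stay separable ground truth
    n_wire = round(config.hub_wiring_fraction * n)
    module_members = set().union(*module_sets) if module_sets else set()
    for h in hubs:
        others = [s for s in symbols if s != h and s not in module_members]
        take = min(n_wire, len(others))
        targets = rng.choice(len(others), size=take, replace=False)
        for k in targets:
            g.add_edge(h, others[k])

    truth = GroundTruth(
        true_module_nodesets=tuple(module_sets),
        true_hub_ids=frozenset(hubs),
    )
    return g, truth


# ---------------------------------------------------------------------------
# bundled three-group study fixture
# ---------------------------------------------------------------------------

_STUDY_GROUPS = (("GV_start", 3), ("MII_end", 3), ("GV_end", 3))


def make_fixture_study(
    config: SimulationConfig | None = None,
    *,
    uncharacterized_fraction: float = 0.16,
) -> StudyBundle:
    """Full study fixture: matrix, annotation, interactome and ground truth.

    Layout (counts fixed by the study design, magnitudes/wiring from
    ``config``): of the planted DEGs, a large shared block responds
    identically in both endpoint groups and a small block is
    endpoint-specific, so pairwise 3 (endpoint vs endpoint) stays below the
    network threshold. Planted hubs (12: 9 shared, 2 MII-specific, 1
    GV-specific) sit in one dense 14-node module together with two plain
    members; a second 6-node module is planted below the k-core retention
    cutoff. Planted outliers: 3 MII-specific (down), 6 GV-specific (5 up, 1
    down), 2 shared. One gene per endpoint-specific block is left
    uncharacterized in the annotation table; the remaining uncharacterized
    genes (up to ``uncharacterized_fraction`` of all genes) are drawn from
    the unplanted pool, mimicking annotation gaps that do not touch the
    driver panel.
    """
    if config is None:
        config = SimulationConfig(groups=_STUDY_GROUPS)
    if len(config.groups) != 3:
        raise ValueError("the study fixture needs exactly 3 groups (baseline + 2)")
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_genes
    n_deg = round(config.deg_fraction * n)
    # fixed layout counts
    n_mii = 6  # 3 outliers + 2 hubs + 1 uncharacterized
    n_gv = 8  # 6 outliers + 1 hub + 1 uncharacterized
    n_shared_min = 9 + 2 + 6 + 2  # hubs + module plain + minor module + outliers
    if n_deg < n_mii + n_gv + n_shared_min:
        raise ValueError(f"deg_fraction too small for the study layout (need >= "
                         f"{n_mii + n_gv + n_shared_min + 1} planted DEGs)")

    deg_idx = rng.choice(n, size=n_deg, replace=False)
    mii = list(deg_idx[:n_mii])
    gv = list(deg_idx[n_mii : n_mii + n_gv])
    shared = list(deg_idx[n_mii + n_gv :])

    roles = {
        "mii_outliers": mii[0:3],
        "mii_hubs": mii[3:5],
        "mii_unchar": mii[5:6],
        "gv_outliers": gv[0:6],
        "gv_hub": gv[6:7],
        "gv_unchar": gv[7:8],
        "shared_hubs": shared[0:9],
        "module_plain": shared[9:11],
        "minor_module": shared[11:17],
        "shared_outliers": shared[17:19],
        "shared_plain": shared[19:],
    }
    floor = config.planted_outliers[1]

    def body_mag(k):
        return _draw_body_magnitudes(rng, k, config.log2fc_effect)

    delta = np.zeros(n)
    sign = np.zeros(n)
    # outliers: directions follow the study pattern
    for i, m in zip(roles["mii_outliers"], _draw_outlier_magnitudes(rng, 3, floor)):
        delta[i], sign[i] = m, -1.0
    gv_signs = [1.0, 1.0, 1.0, 1.0, 1.0, -1.0]
    for i, m, s in zip(
        roles["gv_outliers"], _draw_outlier_magnitudes(rng, 6, floor), gv_signs
    ):
        delta[i], sign[i] = m, s
    for i, m, s in zip(
        roles["shared_outliers"], _draw_outlier_magnitudes(rng, 2, floor), [1.0, -1.0]
    ):
        delta[i], sign[i] = m, s
    # hubs and module members: down-regulated, solidly above the FC gate
    # (log2FC >= 1.5) so DEG-call noise does not erode the planted structure
    hub_all = roles["shared_hubs"] + roles["mii_hubs"] + roles["gv_hub"]
    structural = hub_all + roles["module_plain"] + roles["minor_module"]
    smags = _draw_body_magnitudes(
        rng, len(structural), config.log2fc_effect, min_linear_fc=2.83
    )
    for i, m in zip(hub_all, smags[: len(hub_all)]):
        delta[i], sign[i] = m, -1.0
    module_rest = roles["module_plain"] + roles["minor_module"]
    # everything else: body magnitudes; the free sign probability is set so
    # the overall expected down-fraction matches config.down_fraction despite
    # the direction-constrained plantings above
    rest = roles["mii_unchar"] + roles["gv_unchar"] + roles["shared_plain"]
    free = len(rest) + len(module_rest)
    fixed_down = len(hub_all) + 3 + 1 + 1  # hubs + mii outliers + 1 gv + 1 shared
    p_down = np.clip(
        (config.down_fraction * (n_deg) - fixed_down) / free, 0.05, 0.95
    )
    mdirs = np.where(rng.random(len(module_rest)) < p_down, -1.0, 1.0)
    for j, i in enumerate(module_rest):
        delta[i], sign[i] = smags[len(hub_all) + j], mdirs[j]
    mags = body_mag(len(rest))
    dirs = np.where(rng.random(len(rest)) < p_down, -1.0, 1.0)
    for j, i in enumerate(rest):
        delta[i], sign[i] = mags[j], dirs[j]

    signed = delta * sign
    mii_set = set(mii)
    gv_set = set(gv)
    offsets = np.zeros((n, 3))  # columns: GV_start, MII_end, GV_end
    for i in np.flatnonzero(signed):
        if i in mii_set:
            offsets[i, 1] = signed[i]
        elif i in gv_set:
            offsets[i, 2] = signed[i]
        else:
            offsets[i, 1] = signed[i]
            offsets[i, 2] = signed[i]
    matrix = _build_matrix(config, offsets, rng)

    # annotation: planted drivers always annotated; designated genes plus a
    # random slice of the unplanted pool are uncharacterized
    planted = set(int(i) for i in deg_idx)
    if uncharacterized_fraction > 0:
        unchar = set(roles["mii_unchar"]) | set(roles["gv_unchar"])
        n_unchar = round(uncharacterized_fraction * n)
        pool = np.array(sorted(set(range(n)) - planted))
        extra = rng.choice(pool, size=max(0, n_unchar - len(unchar)), replace=False)
        unchar |= set(int(i) for i in extra)
    else:
        unchar = set()
    rows = []
    for i in range(n):
        if i in unchar:
            mode = i % 3
            rows.append(
                {
                    "gene_id": _gene_id(i),
                    "symbol": "" if mode == 0 else _symbol(i),
                    "biotype": "lncRNA" if mode == 1 else "other",
                    "protein_annotated": False,
                }
            )
        else:
            rows.append(
                {
                    "gene_id": _gene_id(i),
                    "symbol": _symbol(i),
                    "biotype": "protein_coding",
                    "protein_annotated": True,
                }
            )
    annotation = AnnotationTable(table=pd.DataFrame(rows))

    # interactome over all planted DEG genes plus unplanted filler
    filler_pool = np.array(sorted(set(range(n)) - planted))
    n_filler = config.network_size - n_deg
    if n_filler < 0:
        raise ValueError("network_size smaller than the planted DEG count")
    filler = rng.choice(filler_pool, size=n_filler, replace=False)
    node_idx = [int(i) for i in deg_idx] + [int(i) for i in filler]
    perm = rng.permutation(len(node_idx))
    node_symbols = [_symbol(node_idx[k]) for k in perm]

    hub_module = [_symbol(i) for i in hub_all + roles["module_plain"]]
    minor_module = [_symbol(i) for i in roles["minor_module"]]
    net_config = replace(config, planted_hubs=len(hub_all))
    interactome, net_truth = simulate_interactome(
        net_config,
        node_symbols=node_symbols,
        module_nodes=[hub_module, minor_module][: len(config.planted_modules)],
        hub_nodes=[_symbol(i) for i in hub_all],
    )

    sym = _symbol
    def dirmap(idx_list, flip=False):
        out = {}
        for i in idx_list:
            s = -sign[i] if flip else sign[i]
            out[sym(i)] = "up" if s >= 0 else "down"
        return out

    shared_l = list(shared)
    truth = {
        "pairwise1": GroundTruth(
            true_deg_ids=frozenset(sym(i) for i in shared_l + mii),
            true_directions={**dirmap(shared_l), **dirmap(mii)},
            true_module_nodesets=tuple(
                frozenset(s for s in ms if s in {sym(i) for i in shared_l + mii})
                for ms in net_truth.true_module_nodesets
            ),
            true_hub_ids=frozenset(sym(i) for i in roles["shared_hubs"] + roles["mii_hubs"]),
            true_outlier_ids=frozenset(
                sym(i) for i in roles["shared_outliers"] + roles["mii_outliers"]
            ),
        ),
        "pairwise2": GroundTruth(
            true_deg_ids=frozenset(sym(i) for i in shared_l + gv),
            true_directions={**dirmap(shared_l), **dirmap(gv)},
            true_module_nodesets=tuple(
                frozenset(s for s in ms if s in {sym(i) for i in shared_l + gv})
                for ms in net_truth.true_module_nodesets
            ),
            true_hub_ids=frozenset(sym(i) for i in roles["shared_hubs"] + roles["gv_hub"]),
            true_outlier_ids=frozenset(
                sym(i) for i in roles["shared_outliers"] + roles["gv_outliers"]
            ),
        ),
        "pairwise3": GroundTruth(
            true_deg_ids=frozenset(sym(i) for i in mii + gv),
            true_directions={**dirmap(mii), **dirmap(gv, flip=True)},
            true_outlier_ids=frozenset(
                sym(i) for i in roles["mii_outliers"] + roles["gv_outliers"]
            ),
        ),
    }
    comparisons = (
        ("pairwise1", "MII_end", "GV_start"),
        ("pairwise2", "GV_end", "GV_start"),
        ("pairwise3", "MII_end", "GV_end"),
    )
    return StudyBundle(
        config=config,
        matrix=matrix,
        annotation=annotation,
        interactome=interactome,
        interactome_truth=net_truth,
        truth=truth,
        comparisons=comparisons,
    )
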
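"""Synthetic data generation and the evaluation protocol.

This module provides everything needed to benchmark the enrichment and key
driver analyses without external data: positive/negative control gene-set
collections built to a size plan, GWAS-like association tables with planted
signal in designated gene sets, weighted random networks with a planted hub
module, an edge-rewiring noise model, and the performance metrics
(sensitivity, specificity, positive likelihood ratio, ROC, Jaccard
reproducibility of key drivers).

The default size plan is 100 sets each of sizes 25, 100 and 250, for 300
positive and 300 matched negative control sets.  Background association
values are -log10 of Uniform(0, 1] P-values (a calibrated null); markers of
planted genes receive an additional exponential bump with mean equal to the
effect size, so effect 0 reproduces the pure null exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    GeneSetCollection,
    MarkerAssociationTable,
    MarkerGeneMap,
    ValidationError,
    WeightedNetwork,
)
from .util import jaccard_index
from .wkda import WkdaParams, run_wkda

__all__ = [
    "SizePlan",
    "DEFAULT_SIZE_PLAN",
    "PerformanceReport",
    "generate_control_sets",
    "synthetic_marker_gene_map",
    "simulate_association_study",
    "synthetic_network",
    "node_labels",
    "rewire_network",
    "evaluate_performance",
    "jaccard_index",
    "kd_reproducibility",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SizePlan:
    """How many control sets to build at each size."""

    sizes: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for size, count in self.sizes:
            if size < 1 or count < 1:
                raise ValueError(f"invalid plan entry (size={size}, count={count})")

    @property
    def total_sets(self) -> int:
        return sum(count for _, count in self.sizes)

    @property
    def max_size(self) -> int:
        return max(size for size, _ in self.sizes)


DEFAULT_SIZE_PLAN = SizePlan(((25, 100), (100, 100), (250, 100)))


@dataclass(frozen=True)
class PerformanceReport:
    """Detection performance of an enrichment run on labelled control sets.

    sensitivity: positives called at FDR < cutoff / all positives.
    specificity: negatives rejected at FDR >= cutoff / all negatives.
    plr: sensitivity / (1 - specificity), inf when specificity is 1.
    roc: (fpr, tpr) points from sweeping the call threshold; auc by trapezoid.
    """

    sensitivity: float
    specificity: float
    plr: float
    roc: tuple[tuple[float, float], ...]
    auc: float
    fdr_cutoff: float


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_control_sets(
    positive_pool: Collection[str],
    negative_pool: Collection[str],
    plan: SizePlan = DEFAULT_SIZE_PLAN,
    seed: int | None = None,
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Sample positive and negative control gene sets to the same size plan.

    Genes are drawn without replacement within a set and independently (with
    replacement) across sets; the pools must be disjoint and at least as
    large as the biggest requested set.
    """
    pos = sorted(set(str(g) for g in positive_pool))
    neg = sorted(set(str(g) for g in negative_pool))
    if set(pos) & set(neg):
        raise ValidationError("positive and negative pools must be disjoint")
    rng = np.random.default_rng(seed)

    def build(pool: list[str], label: str) -> GeneSetCollection:
        if plan.max_size > len(pool):
            raise ValidationError(
                f"{label} pool ({len(pool)} genes) smaller than the largest "
                f"requested set size ({plan.max_size})"
            )
        sets: dict[str, frozenset[str]] = {}
        for size, count in plan.sizes:
            for j in range(count):
                picked = rng.choice(len(pool), size=size, replace=False)
                sets[f"{label}_{size}_{j + 1:03d}"] = frozenset(pool[i] for i in picked)
        return GeneSetCollection.from_dict(sets)

    return build(pos, "POS"), build(neg, "NEG")


def synthetic_marker_gene_map(
    n_genes: int = 500,
    mean_markers: float = 3.0,
    seed: int | None = None,
    gene_prefix: str = "G",
    marker_prefix: str = "M",
) -> MarkerGeneMap:
    """A synthetic genome: each gene carries 1 + Poisson(mean - 1) markers.

    Variable marker counts per gene are what make the hierarchical
    permutation matter; marker ids are unique across genes.
    """
    if n_genes < 1 or mean_markers < 1:
        raise ValueError("need n_genes >= 1 and mean_markers >= 1")
    rng = np.random.default_rng(seed)
    counts = 1 + rng.poisson(mean_markers - 1.0, size=n_genes)
    pairs = []
    marker = 0
    for i, c in enumerate(counts):
        gene = f"{gene_prefix}{i:04d}"
        for _ in range(int(c)):
            pairs.append((gene, f"{marker_prefix}{marker:06d}"))
            marker += 1
    return MarkerGeneMap.from_pairs(pairs)


def simulate_association_study(
    mgmap: MarkerGeneMap,
    planted_sets: GeneSetCollection | None = None,
    effect: float = 0.0,
    seed: int | None = None,
) -> MarkerAssociationTable:
    """GWAS-like association table with optional planted signal.

    Background values are -log10 of Uniform(0, 1] P-values.  Markers of
    genes belonging to any planted set receive an additional
    Exponential(mean = effect) bump; effect 0 leaves planted and background
    markers identically distributed.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    markers = mgmap.markers
    values = -np.log10(1.0 - rng.random(len(markers)))
    if planted_sets is not None and effect > 0:
        planted_genes = frozenset().union(*(g for _, g in planted_sets.items()))
        gene_markers = mgmap.gene_markers
        planted_markers = {
            m for g in planted_genes for m in gene_markers.get(g, ())
        }
        mask = np.fromiter((m in planted_markers for m in markers), dtype=bool)
        values[mask] += rng.exponential(scale=effect, size=int(mask.sum()))
    return MarkerAssociationTable(pd.Series(values, index=pd.Index(markers)))


def node_labels(n_nodes: int, prefix: str = "G") -> list[str]:
    """The node names used by :func:`synthetic_network`."""
    return [f"{prefix}{i:04d}" for i in range(n_nodes)]


def synthetic_network(
    n_nodes: int = 300,
    topology: str = "scale_free",
    planted_module: tuple[str, Sequence[str]] | None = None,
    attachment: int = 3,
    edge_prob: float = 0.02,
    weight_range: tuple[float, float] = (0.25, 1.0),
    planted_weight: float = 1.0,
    seed: int | None = None,
    node_prefix: str = "G",
) -> WeightedNetwork:
    """Random weighted network with an optional planted hub module.

    The base graph is Barabasi-Albert ("scale_free", preferential attachment
    ``attachment``) or Erdos-Renyi ("erdos_renyi", edge probability
    ``edge_prob``); background weights are Uniform over ``weight_range``.
    The planted module wires its hub to every member with weight
    ``planted_weight`` (overriding any background edge), so the hub's degree
    is at least the module size.
    """
    rng = np.random.default_rng(seed)
    graph_seed = int(rng.integers(2**31))
    if topology == "scale_free":
        base = nx.barabasi_albert_graph(n_nodes, attachment, seed=graph_seed)
    elif topology == "erdos_renyi":
        base = nx.gnp_random_graph(n_nodes, edge_prob, seed=graph_seed)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    names = node_labels(n_nodes, node_prefix)
    lo, hi = weight_range
    if not (0 < lo <= hi):
        raise ValueError("weight_range must be positive and ordered")
    edges: dict[tuple[str, str], float] = {}
    for u, v in sorted(base.edges()):
        a, b = names[u], names[v]
        key = (a, b) if a <= b else (b, a)
        edges[key] = float(rng.uniform(lo, hi))
    if planted_module is not None:
        hub, members = planted_module
        unknown = (set(members) | {hub}) - set(names)
        if unknown:
            raise ValueError(f"planted nodes not in the network: {sorted(unknown)}")
        if hub in members:
            raise ValueError("planted hub cannot be its own member")
        for m in members:
            key = (hub, m) if hub <= m else (m, hub)
            edges[key] = float(planted_weight)
    net = WeightedNetwork.from_edges((u, v, w) for (u, v), w in edges.items())
    # keep isolated nodes so the network order N is exactly n_nodes
    net.graph.add_nodes_from(names)
    return net


def rewire_network(
    net: WeightedNetwork,
    fraction: float,
    mode: str = "uniform",
    seed: int | None = None,
) -> WeightedNetwork:
    """Topological-noise model: randomly rewire a fraction of the edges.

    "uniform" resamples both endpoints of the selected edges uniformly
    (avoiding self-loops and duplicates, weights carried along);
    "degree_preserving" performs double-edge swaps until the target fraction
    of edges has been touched.  Node set, edge count and the weight multiset
    are preserved in both modes.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    nodes = net.nodes
    edges = [
        (min(u, v), max(u, v), d["weight"])
        for u, v, d in net.graph.edges(data=True)
    ]
    edges.sort()
    m = len(edges)
    n_target = round(fraction * m)
    edge_set = {(u, v) for u, v, _ in edges}

    def norm(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    if mode == "uniform":
        chosen = rng.choice(m, size=n_target, replace=False) if n_target else []
        for ei in sorted(chosen):
            u, v, w = edges[ei]
            edge_set.discard((u, v))
            for _ in range(1000):
                a, b = rng.choice(len(nodes), size=2, replace=False)
                cand = norm(nodes[a], nodes[b])
                if cand not in edge_set:
                    break
            else:  # pathological density: keep the original edge
                cand = (u, v)
            edge_set.add(cand)
            edges[ei] = (cand[0], cand[1], w)
    elif mode == "degree_preserving":
        n_swaps = math.ceil(n_target / 2)
        done, attempts = 0, 0
        max_attempts = 200 * max(n_swaps, 1)
        while done < n_swaps and attempts < max_attempts:
            attempts += 1
            i, j = rng.choice(m, size=2, replace=False)
            u, v, w1 = edges[i]
            x, y, w2 = edges[j]
            if len({u, v, x, y}) < 4:
                continue
            new1, new2 = norm(u, y), norm(x, v)
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard((u, v))
            edge_set.discard((x, y))
            edge_set.add(new1)
            edge_set.add(new2)
            edges[i] = (new1[0], new1[1], w1)
            edges[j] = (new2[0], new2[1], w2)
            done += 1
        if done < n_swaps:
            log.warning("degree-preserving rewiring reached %d/%d swaps", done, n_swaps)
    else:
        raise ValueError(f"unknown rewiring mode {mode!r}")
    out = WeightedNetwork.from_edges(edges)
    out.graph.add_nodes_from(nodes)
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def evaluate_performance(
    fdrs: Mapping[str, float],
    labels: Mapping[str, bool],
    fdr_cutoff: float = 0.25,
) -> PerformanceReport:
    """Sensitivity/specificity/PLR of labelled control results at an FDR cut.

    ``labels`` maps each result id to True for positive controls.  The ROC
    sweeps the call threshold over the observed FDR values.
    """
    ids = sorted(fdrs)
    missing = [i for i in ids if i not in labels]
    if missing:
        raise ValidationError(f"unlabelled result(s): {missing[:3]}")
    pos = np.array([fdrs[i] for i in ids if labels[i]], dtype=float)
    neg = np.array([fdrs[i] for i in ids if not labels[i]], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("need at least one positive and one negative control")
    sensitivity = float(np.mean(pos < fdr_cutoff))
    specificity = float(np.mean(neg >= fdr_cutoff))
    plr = math.inf if specificity == 1.0 else sensitivity / (1.0 - specificity)
    thresholds = np.concatenate(
        [[0.0], np.unique(np.concatenate([pos, neg])), [math.inf]]
    )
    points = [
        (float(np.mean(neg < t)), float(np.mean(pos < t))) for t in thresholds
    ]
    points = sorted(set(points))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return PerformanceReport(
        sensitivity, specificity, plr, tuple(points), auc, fdr_cutoff
    )


def kd_reproducibility(
    net_a: WeightedNetwork,
    net_b: WeightedNetwork,
    sets: GeneSetCollection,
    params: WkdaParams | None = None,
    top_k: int | None = None,
    fdr_cutoff: float | None = None,
) -> float:
    """Jaccard overlap of the key drivers found on two independent networks.

    Key drivers are the independent hubs selected either at an FDR cutoff or
    as the top-k by adjusted significance (exactly one criterion must be
    given), pooled over all sets.  Identical networks give 1; fully rewired
    networks give ~0.
    """
    if (top_k is None) == (fdr_cutoff is None):
        raise ValueError("give exactly one of top_k or fdr_cutoff")

    def kd_ids(results) -> set[str]:
        independent = [r for r in results if r.is_independent]
        if fdr_cutoff is not None:
            return {r.hub_id for r in independent if r.fdr < fdr_cutoff}
        ranked = sorted(independent, key=lambda r: (r.p_bonf, r.p, r.hub_id))
        out: set[str] = set()
        for r in ranked:
            out.add(r.hub_id)
            if len(out) >= top_k:
                break
        return out

    return jaccard_index(
        kd_ids(run_wkda(net_a, sets, params)),
        kd_ids(run_wkda(net_b, sets, params)),
    )
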
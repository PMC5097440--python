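"""Weighted key driver analysis (wKDA).

A key driver is a network hub whose 1-hop neighbourhood is over-represented
with members of a disease-associated gene set.  Edge weights enter through
local node strengths: within a hub's neighbourhood, each neighbour's
strength is the sum of its edge weights to other members of the
neighbourhood (hub included), and the hub itself -- whose raw strength would
dominate by construction -- is assigned the neighbourhood-average strength.
The observed score O is the strength-weighted fraction of disease genes in
the neighbourhood scaled by the hub degree N_k, so that it is commensurate
with the expected count E = N_k * N_p / N under the isotropy assumption
(N_p disease genes on a network of N nodes).  The test statistic is

    chi = (O - E) / (sqrt(E) + kappa)

with kappa = 1 stabilising small expected counts.  Significance comes from
permuting node labels (equivalently, drawing random member sets of size N_p)
with the (b+1)/(nperm+1) pseudocount rule, followed by a two-tier
correction: within each gene set, P-values of independent hubs are
Bonferroni-multiplied by the number of independent hubs and values above 1
are discarded; the surviving P-values are pooled across sets and converted
to FDRs with Benjamini-Hochberg.  Hubs whose neighbourhoods largely overlap
an already-accepted hub are reported as co-hubs of that hub rather than
tested independently, which preserves power and flags topological
redundancy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, ValidationError, WeightedNetwork
from .util import jaccard_index

__all__ = [
    "HubNeighbourhood",
    "KeyDriverResult",
    "WkdaParams",
    "screen_hubs",
    "classify_cohubs",
    "local_strengths",
    "effective_membership",
    "wkda_statistic",
    "score_hubs",
    "run_wkda",
    "two_tier_adjust",
    "bonferroni_threshold",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HubNeighbourhood:
    """A hub, its adjacent genes and their local strengths."""

    hub_id: str
    neighbours: frozenset[str]
    strengths: Mapping[str, float]
    hub_strength: float

    @property
    def degree(self) -> int:
        return len(self.neighbours)

    @property
    def total_strength(self) -> float:
        return sum(self.strengths.values()) + self.hub_strength


@dataclass(frozen=True)
class KeyDriverResult:
    hub_id: str
    set_id: str
    is_independent: bool
    cohubs: tuple[str, ...]
    parent_hub: str
    O: float
    E: float
    chi: float
    p: float
    p_bonf: float
    fdr: float


@dataclass(frozen=True)
class WkdaParams:
    """Tunable parameters of a wKDA run.

    degree_quantile: hubs are nodes in the top (1 - quantile) of the degree
        distribution (default: top 25%).  overlap_cutoff: neighbourhood
        Jaccard overlap at or above which a hub becomes a co-hub of an
        already-accepted independent hub.  denominator: "plus" uses
        sqrt(E) + kappa; "minus" reproduces the alternative sqrt(E) - kappa
        form (unstable near E = 1 and not recommended).
    """

    degree_quantile: float = 0.75
    overlap_cutoff: float = 0.25
    kappa: float = 1.0
    nperm: int = 10_000
    seed: int | None = None
    denominator: str = "plus"


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-adjusted significance level on the -log10 P scale.

    E.g. alpha 0.05 over 1346 pathway tests gives -log10(0.05/1346) = 4.43.
    """
    if not (0 < alpha < 1) or n_tests < 1:
        raise ValueError("need 0 < alpha < 1 and n_tests >= 1")
    return float(-math.log10(alpha / n_tests))


def screen_hubs(net: WeightedNetwork, degree_quantile: float = 0.75) -> list[str]:
    """Nodes whose degree reaches the given quantile of all node degrees.

    Ties at the quantile are included, so a regular graph yields every node.
    When the quantile collapses onto the minimum degree while other degrees
    exist (a degenerate, minimum-dominated degree distribution such as a
    star), the cutoff moves up to the smallest degree above the minimum so
    that low-connectivity nodes are still ignored.
    """
    graph = net.graph
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot screen hubs in an empty network")
    deg = dict(graph.degree())
    degrees = np.array(list(deg.values()))
    threshold = float(np.quantile(degrees, degree_quantile))
    dmin = degrees.min()
    if threshold <= dmin and degrees.max() > dmin:
        threshold = float(degrees[degrees > dmin].min())
    return sorted(n for n, d in deg.items() if d >= threshold and d > 0)


def classify_cohubs(
    hubs: Sequence[str], net: WeightedNetwork, overlap_cutoff: float = 0.25
) -> tuple[list[str], dict[str, list[str]]]:
    """Split screened hubs into independent hubs and their co-hubs.

    Hubs are processed in descending degree (ties by id).  A hub is accepted
    as independent when its neighbourhood Jaccard overlap with every
    already-accepted independent hub stays below ``overlap_cutoff``;
    otherwise it becomes a co-hub of the independent hub it overlaps most.
    Every screened hub ends up as exactly one of the two.
    """
    graph = net.graph
    nbrs = {h: frozenset(graph[h]) for h in hubs}
    order = sorted(hubs, key=lambda h: (-len(nbrs[h]), h))
    independent: list[str] = []
    cohub_map: dict[str, list[str]] = {}
    for hub in order:
        best, best_overlap = None, 0.0
        for accepted in independent:
            overlap = jaccard_index(nbrs[hub], nbrs[accepted])
            if overlap > best_overlap:
                best, best_overlap = accepted, overlap
        if best is None or best_overlap < overlap_cutoff:
            independent.append(hub)
            cohub_map[hub] = []
        else:
            cohub_map[best].append(hub)
    return independent, cohub_map


def local_strengths(net: WeightedNetwork, hub: str) -> HubNeighbourhood:
    """Collapse the edges inside a hub's neighbourhood into node strengths.

    A neighbour's strength sums the weights of its edges to other nodes of
    {hub} union neighbours; edges leaving the neighbourhood are ignored.  The
    hub receives the arithmetic mean of the neighbour strengths.
    """
    graph = net.graph
    if hub not in graph:
        raise KeyError(f"hub {hub!r} not in network")
    neighbours = set(graph[hub])
    if not neighbours:
        raise ValidationError(f"node {hub!r} has degree 0 and cannot be a hub")
    nodes = neighbours | {hub}
    strengths = {
        v: sum(d["weight"] for u, d in graph[v].items() if u in nodes)
        for v in sorted(neighbours)
    }
    hub_strength = sum(strengths.values()) / len(strengths)
    return HubNeighbourhood(hub, frozenset(neighbours), strengths, hub_strength)


def effective_membership(
    nb: HubNeighbourhood, member_genes: Iterable[str]
) -> tuple[float, float]:
    """Strength-weighted disease-gene share of a neighbourhood.

    Returns (ratio, O): ratio is the sum of member-node strengths over the
    total neighbourhood strength (the hub participates through its average
    strength), and O = ratio * N_k is the effective member count that is
    commensurate with E = N_k * N_p / N.
    """
    members = set(member_genes)
    total = nb.total_strength
    if total <= 0:
        raise ValidationError("neighbourhood has zero total strength")
    member_sum = sum(nb.strengths[v] for v in nb.neighbours if v in members)
    if nb.hub_id in members:
        member_sum += nb.hub_strength
    ratio = member_sum / total
    return ratio, ratio * nb.degree


def wkda_statistic(O: float, E: float, kappa: float = 1.0,
                   denominator: str = "plus") -> float:
    """chi = (O - E) / (sqrt(E) +/- kappa); negative chi means depletion."""
    if E <= 0:
        raise ValueError(f"expected count must be positive, got {E}")
    if denominator == "plus":
        denom = math.sqrt(E) + kappa
    elif denominator == "minus":
        denom = math.sqrt(E) - kappa
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return (O - E) / denom


def _null_chis(
    base: np.ndarray,
    idx: np.ndarray,
    strengths: np.ndarray,
    total: float,
    n_k: int,
    expected: float,
    denom: float,
    nperm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null chi values from random node relabelings, computed in chunks."""
    out = np.empty(nperm)
    done = 0
    chunk = max(1, min(nperm, 4_000_000 // max(base.size, 1)))
    while done < nperm:
        block = min(chunk, nperm - done)
        mat = np.tile(base, (block, 1))
        rng.permuted(mat, axis=1, out=mat)
        member = mat[:, idx].astype(float)
        o_null = member @ strengths / total * n_k
        out[done:done + block] = (o_null - expected) / denom
        done += block
    return out


def score_hubs(
    net: WeightedNetwork,
    member_genes: Iterable[str],
    hubs: Sequence[str] | None = None,
    *,
    kappa: float = 1.0,
    nperm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    denominator: str = "plus",
) -> list[KeyDriverResult]:
    """Score hubs against one member gene set with raw permutation P-values.

    The null permutes node labels over the whole network with cached
    strengths, so only the member indicator moves.  Returned records carry
    the unadjusted p; the Bonferroni/FDR fields are filled by
    :func:`two_tier_adjust`.
    """
    graph = net.graph
    nodes = sorted(graph)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    members = sorted(set(member_genes) & set(nodes))
    if not members:
        raise ValidationError("member set does not intersect the network")
    n_p = len(members)
    base = np.zeros(n, dtype=np.int8)
    base[[index[m] for m in members]] = 1
    if rng is None:
        rng = np.random.default_rng(seed)
    if hubs is None:
        hubs = screen_hubs(net)
    out: list[KeyDriverResult] = []
    for hub in hubs:
        nb = local_strengths(net, hub)
        ordered = sorted(nb.neighbours)
        idx = np.array([index[v] for v in ordered] + [index[hub]], dtype=np.intp)
        strengths = np.array([nb.strengths[v] for v in ordered] + [nb.hub_strength])
        total = float(strengths.sum())
        n_k = nb.degree
        expected = n_k * n_p / n
        _, observed = effective_membership(nb, members)
        chi = wkda_statistic(observed, expected, kappa, denominator)
        denom = (
            math.sqrt(expected) + kappa
            if denominator == "plus"
            else math.sqrt(expected) - kappa
        )
        null = _null_chis(base, idx, strengths, total, n_k, expected, denom, nperm, rng)
        b = int(np.count_nonzero(null >= chi))
        p = (b + 1) / (nperm + 1)
        out.append(
            KeyDriverResult(
                hub_id=hub, set_id="", is_independent=True, cohubs=(),
                parent_hub="", O=observed, E=expected, chi=chi, p=p,
                p_bonf=float("nan"), fdr=float("nan"),
            )
        )
    return out


def run_wkda(
    net: WeightedNetwork,
    sets: GeneSetCollection,
    params: WkdaParams | None = None,
) -> list[KeyDriverResult]:
    """Full wKDA: screen hubs, classify co-hubs, score every (hub, set) pair
    by permutation and apply the two-tier multiple-testing correction.

    Gene sets that do not intersect the network are skipped with a warning.
    Co-hubs are reported alongside their independent hub with their own chi
    and unadjusted p.
    """
    params = params or WkdaParams()
    hubs = screen_hubs(net, params.degree_quantile)
    independent, cohub_map = classify_cohubs(hubs, net, params.overlap_cutoff)
    owner = {
        cohub: indep for indep, cohubs in cohub_map.items() for cohub in cohubs
    }
    ordered_hubs = [h for indep in independent for h in (indep, *cohub_map[indep])]
    base_seed = (
        params.seed
        if params.seed is not None
        else int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    )
    node_set = set(net.graph)
    results: list[KeyDriverResult] = []
    for k, set_id in enumerate(sorted(sets.ids())):
        members = sets[set_id] & node_set
        if not members:
            log.warning("set %s skipped: no genes present in the network", set_id)
            continue
        rng = np.random.default_rng([base_seed, 29, k])
        scored = score_hubs(
            net, members, ordered_hubs, kappa=params.kappa, nperm=params.nperm,
            rng=rng, denominator=params.denominator,
        )
        for record in scored:
            if record.hub_id in owner:
                record = replace(
                    record, set_id=set_id, is_independent=False,
                    parent_hub=owner[record.hub_id],
                )
            else:
                record = replace(
                    record, set_id=set_id, is_independent=True,
                    cohubs=tuple(cohub_map[record.hub_id]),
                )
            results.append(record)
    return two_tier_adjust(results)


def two_tier_adjust(results: Sequence[KeyDriverResult]) -> list[KeyDriverResult]:
    """Bonferroni within each set over its independent hubs, then BH across.

    Within a set, each independent hub's p is multiplied by the number of
    independent hubs tested for that set; adjusted values above 1 are
    discarded (the truncated remainder behaves like uniform P-values under
    the null).  The surviving values are pooled across sets and converted to
    FDRs by Benjamini-Hochberg.  Co-hub records are reported unadjusted,
    attached to a surviving independent hub.
    """
    independent = [r for r in results if r.is_independent]
    cohubs = [r for r in results if not r.is_independent]
    counts: dict[str, int] = {}
    for r in independent:
        counts[r.set_id] = counts.get(r.set_id, 0) + 1
    retained = []
    for r in independent:
        p_bonf = r.p * counts[r.set_id]
        if p_bonf <= 1.0:
            retained.append(replace(r, p_bonf=p_bonf))
    if retained:
        fdrs = multipletests([r.p_bonf for r in retained], method="fdr_bh")[1]
        retained = [replace(r, fdr=float(f)) for r, f in zip(retained, fdrs)]
    surviving = {(r.set_id, r.hub_id) for r in retained}
    kept_cohubs = [r for r in cohubs if (r.set_id, r.parent_hub) in surviving]
    out = retained + kept_cohubs
    out.sort(key=lambda r: (r.set_id, not r.is_independent, r.p, r.hub_id))
    return out
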
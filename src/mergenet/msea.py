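"""Marker Set Enrichment Analysis (MSEA).

MSEA asks whether the distinct markers mapped to a gene set carry more
strong association signals than the markers of equally many random genes.
The test statistic sums observed-minus-expected counts of markers exceeding
a ladder of study-wide quantile cutoffs,

    chi = sum_i (O_i - E_i) / (sqrt(E_i) + kappa),

where O_i is the number of the set's distinct markers at or above cutoff i,
E_i = m * p_i with m the number of distinct member markers and p_i the
study-wide tail fraction at that cutoff, and kappa (default 1) stabilises
small expected counts.  Because the statistic only compares values with
study-wide quantiles, it adapts to any association scale and is invariant
under monotone transforms of the values.

The null distribution is built by a hierarchical gene-based permutation:
random gene sets of the same gene count are drawn from the mapped universe
and each gene carries its full marker list, which preserves gene size and
shared-marker structure.  Shuffling marker labels instead is available as an
alternative.  Permutation P-values use the (b+1)/(nperm+1) pseudocount rule
so they are never zero; when no permutation exceeds the observation, the
P-value falls back to the upper tail of a Gaussian fitted to the null, which
also supplies the Z-scores that the Stouffer meta-analysis combines.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import (
    GeneSetCollection,
    MarkerAssociationTable,
    MarkerGeneMap,
    ValidationError,
)
from .util import jaccard_index

__all__ = [
    "QuantileScheme",
    "EnrichmentResult",
    "MetaResult",
    "MseaParams",
    "build_quantile_scheme",
    "background_tail_fractions",
    "enrichment_statistic",
    "hierarchical_null",
    "marker_label_null",
    "null_tail_p",
    "run_msea",
    "stouffer_meta",
    "meta_msea",
    "merge_significant_sets",
]

log = logging.getLogger(__name__)

#: floor for the smallest upper-tail probability of the quantile ladder
MIN_TAIL_PROB = 1e-4
#: exhaustive enumeration is used when C(universe, set size) stays below this
DEFAULT_EXHAUSTIVE_LIMIT = 100_000


@dataclass(frozen=True)
class QuantileScheme:
    """Strictly increasing association-value cutoffs (-log10 P units)."""

    cutoffs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cutoffs, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("scheme needs at least one cutoff")
        if np.any(np.diff(c) <= 0):
            raise ValueError("cutoffs must be strictly increasing")
        object.__setattr__(self, "cutoffs", c)

    @property
    def n(self) -> int:
        return int(self.cutoffs.size)


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    n_genes: int
    n_markers: int
    chi: float
    p_freq: float
    z: float
    p_norm: float
    p_final: float
    fdr: float


@dataclass(frozen=True)
class MetaResult:
    set_id: str
    z_by_study: tuple[float, ...]
    z_meta: float
    p_meta: float


@dataclass(frozen=True)
class MseaParams:
    """Tunable parameters of an MSEA run.

    nperm: permutations per null distribution (one null is cached per
        distinct set size).  n_quantiles: number of quantile cutoffs, placed
        at upper-tail probabilities log-spaced from 0.5 down to
        max(10/n_markers, 1e-4).  null_mode: "gene" for the hierarchical
        gene-label permutation (default) or "marker" for marker-label
        shuffling.  Exhaustive enumeration replaces sampling automatically
        when the number of possible gene sets is small.
    """

    nperm: int = 10_000
    n_quantiles: int = 10
    kappa: float = 1.0
    null_mode: str = "gene"
    seed: int | None = None
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT


class TailP(NamedTuple):
    p_freq: float
    z: float
    p_norm: float
    p_final: float


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------


def _as_values(assoc) -> np.ndarray:
    if isinstance(assoc, MarkerAssociationTable):
        return assoc.values
    return np.asarray(assoc, dtype=float)


def _counts_at_least(values: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    """Number of values >= each cutoff (closed threshold)."""
    sv = np.sort(values)
    return values.size - np.searchsorted(sv, cutoffs, side="left")


def build_quantile_scheme(assoc, n_points: int = 10) -> QuantileScheme:
    """Empirical quantile cutoffs of the study-wide value distribution.

    Upper-tail probabilities are log-spaced from 0.5 (the bulk) down to
    max(10/n_markers, 1e-4), so the ladder covers both moderate and extreme
    signals while keeping expected counts stable.  Duplicate cutoffs (tied
    or constant data) collapse, so the scheme may end up shorter.
    """
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    values = _as_values(assoc)
    if values.size == 0:
        raise ValidationError("cannot build a quantile scheme from an empty table")
    lo = 0.5
    hi = min(lo, max(10.0 / values.size, MIN_TAIL_PROB))
    tail_probs = np.geomspace(lo, hi, n_points)
    cutoffs = np.unique(np.quantile(values, 1.0 - tail_probs))
    return QuantileScheme(cutoffs)


def background_tail_fractions(assoc, scheme: QuantileScheme) -> np.ndarray:
    """Fraction of all study markers at or above each cutoff."""
    values = _as_values(assoc)
    return _counts_at_least(values, scheme.cutoffs) / values.size


def enrichment_statistic(
    member_values: Sequence[float] | np.ndarray,
    scheme: QuantileScheme,
    background_tail_probs: Sequence[float] | np.ndarray,
    kappa: float = 1.0,
) -> float:
    """The adaptive multi-quantile statistic chi for one gene set.

    ``member_values`` are the association values of the set's *distinct*
    markers; ``background_tail_probs`` come from the same study via
    :func:`background_tail_fractions`.
    """
    vals = np.asarray(member_values, dtype=float)
    if vals.size == 0:
        raise ValidationError("cannot score a set with no mapped markers")
    p = np.asarray(background_tail_probs, dtype=float)
    if p.shape != scheme.cutoffs.shape:
        raise ValueError("background_tail_probs must match the scheme cutoffs")
    observed = _counts_at_least(vals, scheme.cutoffs)
    expected = vals.size * p
    return float(np.sum((observed - expected) / (np.sqrt(expected) + kappa)))


# ---------------------------------------------------------------------------
# null distributions
# ---------------------------------------------------------------------------


class _Universe:
    """Marker values and per-gene marker index lists, restricted to markers
    that carry an association value."""

    def __init__(self, mgmap: MarkerGeneMap, assoc: MarkerAssociationTable) -> None:
        series = assoc.series
        pairs = mgmap.data
        present = pairs["MARKER"].isin(series.index)
        use = pairs[present]
        if use.empty:
            raise ValidationError("no mapped marker has an association value")
        marker_ids = np.sort(use["MARKER"].unique())
        index = {m: i for i, m in enumerate(marker_ids)}
        self.values: np.ndarray = series.loc[marker_ids].to_numpy(dtype=float)
        gene_idx: dict[str, np.ndarray] = {}
        for gene, grp in use.groupby("GENE", sort=True):
            gene_idx[str(gene)] = np.fromiter(
                sorted(index[m] for m in grp["MARKER"]), dtype=np.intp
            )
        self.gene_ids: list[str] = list(gene_idx)
        self.gene_marker_idx: list[np.ndarray] = [gene_idx[g] for g in self.gene_ids]
        n_dropped = mgmap.n_genes - len(self.gene_ids)
        if n_dropped:
            log.info("%d gene(s) had no scored markers and were dropped", n_dropped)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def union_values(self, positions: Iterable[int]) -> np.ndarray:
        idx = np.unique(np.concatenate([self.gene_marker_idx[i] for i in positions]))
        return self.values[idx]


def _check_nperm(nperm: int) -> None:
    if nperm < 100:
        warnings.warn(
            f"nperm={nperm} permutations give an unstable null distribution",
            UserWarning,
            stacklevel=3,
        )


def _gene_null(
    universe: _Universe,
    set_size: int,
    scheme: QuantileScheme,
    tail_probs: np.ndarray,
    kappa: float,
    nperm: int,
    rng: np.random.Generator,
    exhaustive: bool | None,
    exhaustive_limit: int,
) -> tuple[np.ndarray, bool]:
    n = universe.n_genes
    if set_size > n:
        raise ValueError(f"set size {set_size} exceeds the gene universe ({n})")
    total = math.comb(n, set_size)
    if exhaustive is None:
        exhaustive = total <= exhaustive_limit
    if exhaustive:
        chis = np.fromiter(
            (
                enrichment_statistic(universe.union_values(pos), scheme, tail_probs, kappa)
                for pos in combinations(range(n), set_size)
            ),
            dtype=float,
            count=total,
        )
        return chis, True
    _check_nperm(nperm)
    chis = np.empty(nperm)
    for i in range(nperm):
        pos = rng.choice(n, size=set_size, replace=False)
        chis[i] = enrichment_statistic(
            universe.union_values(pos), scheme, tail_probs, kappa
        )
    return chis, False


def hierarchical_null(
    mgmap: MarkerGeneMap,
    assoc: MarkerAssociationTable,
    set_size_genes: int,
    scheme: QuantileScheme,
    kappa: float = 1.0,
    nperm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
    background_tail_probs: np.ndarray | None = None,
) -> np.ndarray:
    """Null chi values from the hierarchical gene-based permutation.

    Each permutation draws ``set_size_genes`` genes uniformly without
    replacement from the mapped universe, takes the union of their marker
    lists (distinct markers) and scores it.  With ``exhaustive=True`` (or
    automatically when the number of combinations is small) every possible
    gene set is enumerated exactly once.
    """
    universe = _Universe(mgmap, assoc)
    if background_tail_probs is None:
        background_tail_probs = background_tail_fractions(universe.values, scheme)
    rng = np.random.default_rng(seed)
    chis, _ = _gene_null(
        universe, set_size_genes, scheme, np.asarray(background_tail_probs),
        kappa, nperm, rng, exhaustive, DEFAULT_EXHAUSTIVE_LIMIT,
    )
    return chis


def marker_label_null(
    assoc: MarkerAssociationTable,
    member_marker_count: int,
    scheme: QuantileScheme,
    kappa: float = 1.0,
    nperm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
    background_tail_probs: np.ndarray | None = None,
) -> np.ndarray:
    """Null chi values from marker-label shuffling: each permutation samples
    ``member_marker_count`` markers uniformly from all study markers."""
    values = _as_values(assoc)
    k = int(member_marker_count)
    if k < 1 or k > values.size:
        raise ValueError(f"member_marker_count {k} outside [1, {values.size}]")
    if background_tail_probs is None:
        background_tail_probs = background_tail_fractions(values, scheme)
    tail_probs = np.asarray(background_tail_probs)
    total = math.comb(values.size, k)
    if exhaustive is None:
        exhaustive = total <= DEFAULT_EXHAUSTIVE_LIMIT
    if exhaustive:
        return np.fromiter(
            (
                enrichment_statistic(values[list(pos)], scheme, tail_probs, kappa)
                for pos in combinations(range(values.size), k)
            ),
            dtype=float,
            count=total,
        )
    _check_nperm(nperm)
    rng = np.random.default_rng(seed)
    chis = np.empty(nperm)
    for i in range(nperm):
        chis[i] = enrichment_statistic(
            rng.choice(values, size=k, replace=False), scheme, tail_probs, kappa
        )
    return chis


def null_tail_p(
    chi_obs: float,
    null: np.ndarray | Sequence[float],
    nperm: int | None = None,
    *,
    exhaustive: bool = False,
) -> TailP:
    """Frequency P, Gaussian Z and the combined final P for one observation.

    p_freq is (b+1)/(nperm+1) with b the number of null values >= chi_obs
    (exact b/n for an exhaustive null, which already contains the observed
    configuration); a Gaussian fitted to the null by its sample moments gives
    z and p_norm, and p_final falls back to p_norm only when b = 0.  All
    returned probabilities are strictly positive, which keeps the results
    convertible to Z-scores for meta-analysis.
    """
    null = np.asarray(null, dtype=float)
    n = null.size if nperm is None else int(nperm)
    if null.size == 0:
        raise ValueError("empty null distribution")
    b = int(np.count_nonzero(null >= chi_obs))
    p_freq = b / null.size if exhaustive else (b + 1) / (n + 1)
    mu = float(null.mean())
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    if sd == 0.0:
        if np.isclose(chi_obs, mu):
            return TailP(max(p_freq, np.finfo(float).tiny), 0.0, 0.5, 1.0)
        raise ValidationError(
            "degenerate null distribution (zero variance) cannot be scored"
        )
    z = (chi_obs - mu) / sd
    p_norm = float(stats.norm.sf(z))
    p_norm = max(p_norm, np.nextafter(0.0, 1.0))
    p_final = p_norm if b == 0 else max(p_freq, np.finfo(float).tiny)
    return TailP(max(p_freq, np.finfo(float).tiny), z, p_norm, p_final)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def _membership_positions(
    universe: _Universe, genes: frozenset[str]
) -> list[int]:
    """Positions of universe genes belonging to a set.

    Supergene ids created by shared-marker merging join their members with
    ';'; a supergene belongs to a set when any member does.
    """
    positions = []
    for i, gid in enumerate(universe.gene_ids):
        if gid in genes or any(part in genes for part in gid.split(";")):
            positions.append(i)
    return positions


def run_msea(
    sets: GeneSetCollection,
    mgmap: MarkerGeneMap,
    assoc: MarkerAssociationTable,
    params: MseaParams | None = None,
) -> list[EnrichmentResult]:
    """Score every gene set and correct across sets with Benjamini-Hochberg.

    The quantile scheme and background tail fractions are computed on the
    analysis universe (mapped markers with association values).  One null
    distribution is simulated per distinct set size and cached.  Sets with no
    mapped genes are skipped with a log message.  Results are sorted by
    ascending final P, ties by set id.
    """
    params = params or MseaParams()
    universe = _Universe(mgmap, assoc)
    scheme = build_quantile_scheme(universe.values, params.n_quantiles)
    tail_probs = background_tail_fractions(universe.values, scheme)
    base_seed = (
        params.seed
        if params.seed is not None
        else int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    )
    null_cache: dict[tuple[str, int], tuple[np.ndarray, bool]] = {}
    results: list[EnrichmentResult] = []
    for set_id in sorted(sets.ids()):
        positions = _membership_positions(universe, sets[set_id])
        if not positions:
            log.info("set %s skipped: no mapped genes", set_id)
            continue
        member_values = universe.union_values(positions)
        chi = enrichment_statistic(member_values, scheme, tail_probs, params.kappa)
        if params.null_mode == "gene":
            key = ("gene", len(positions))
            if key not in null_cache:
                rng = np.random.default_rng([base_seed, 101, key[1]])
                null_cache[key] = _gene_null(
                    universe, key[1], scheme, tail_probs, params.kappa,
                    params.nperm, rng, None, params.exhaustive_limit,
                )
        elif params.null_mode == "marker":
            key = ("marker", member_values.size)
            if key not in null_cache:
                null = marker_label_null(
                    universe.values, key[1], scheme, params.kappa, params.nperm,
                    seed=np.random.default_rng([base_seed, 211, key[1]]).integers(2**31),
                    background_tail_probs=tail_probs,
                )
                exhaustive = math.comb(universe.values.size, key[1]) <= params.exhaustive_limit
                null_cache[key] = (null, exhaustive)
        else:
            raise ValueError(f"unknown null_mode {params.null_mode!r}")
        null, exhaustive = null_cache[key]
        tp = null_tail_p(chi, null, exhaustive=exhaustive)
        results.append(
            EnrichmentResult(
                set_id=set_id,
                n_genes=len(positions),
                n_markers=int(member_values.size),
                chi=chi,
                p_freq=tp.p_freq,
                z=tp.z,
                p_norm=tp.p_norm,
                p_final=tp.p_final,
                fdr=float("nan"),
            )
        )
    if results:
        fdrs = multipletests([r.p_final for r in results], method="fdr_bh")[1]
        results = [replace(r, fdr=float(f)) for r, f in zip(results, fdrs)]
    results.sort(key=lambda r: (r.p_final, r.set_id))
    return results


# ---------------------------------------------------------------------------
# meta-analysis and set merging
# ---------------------------------------------------------------------------


def stouffer_meta(
    z_values: Sequence[float], weights: Sequence[float] | None = None
) -> tuple[float, float]:
    """Stouffer combination: z_meta = sum(w z) / sqrt(sum w^2)."""
    z = np.asarray(list(z_values), dtype=float)
    if z.size == 0:
        raise ValueError("need at least one study")
    if weights is None:
        w = np.ones_like(z)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != z.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match the z list")
    z_meta = float((w * z).sum() / math.sqrt((w**2).sum()))
    return z_meta, float(stats.norm.sf(z_meta))


def meta_msea(
    results_by_study: Sequence[Sequence[EnrichmentResult]],
    weights: Sequence[float] | None = None,
) -> list[MetaResult]:
    """Gene-set level meta-analysis across studies.

    Each study's final P is converted to a Z-score through the inverse of the
    Gaussian upper tail (P clipped just below 1 to keep Z finite), and the
    per-set Z-scores are combined with Stouffer's method.  Only sets scored
    in every study are combined.
    """
    if not results_by_study:
        raise ValueError("need at least one study")
    maps = [{r.set_id: r for r in study} for study in results_by_study]
    shared = sorted(set.intersection(*(set(m) for m in maps)))
    out: list[MetaResult] = []
    for sid in shared:
        ps = np.clip([m[sid].p_final for m in maps], np.finfo(float).tiny, 1.0 - 1e-16)
        zs = stats.norm.isf(ps)
        z_meta, p_meta = stouffer_meta(zs, weights)
        out.append(MetaResult(sid, tuple(float(z) for z in zs), z_meta, p_meta))
    out.sort(key=lambda r: (r.p_meta, r.set_id))
    return out


def merge_significant_sets(
    sets: GeneSetCollection,
    pvals: Mapping[str, float],
    fdr_cutoff: float = 0.05,
    jaccard_cutoff: float = 0.2,
) -> GeneSetCollection:
    """Merge overlapping significant sets into non-overlapping subnetworks.

    Significant sets (p/FDR below ``fdr_cutoff``) are connected whenever
    their gene-level Jaccard overlap reaches ``jaccard_cutoff``; each
    connected component becomes one merged set (the union of genes) named by
    the ';'-joined member ids.  By construction no two merged sets overlap at
    the cutoff.  Enrichment is typically re-run on the merged sets.
    """
    sig = sorted(s for s in sets.ids() if pvals.get(s, math.inf) < fdr_cutoff)
    graph = nx.Graph()
    graph.add_nodes_from(sig)
    for a, b in combinations(sig, 2):
        if jaccard_index(sets[a], sets[b]) >= jaccard_cutoff:
            graph.add_edge(a, b)
    merged: dict[str, frozenset[str]] = {}
    for component in nx.connected_components(graph):
        members = sorted(component)
        merged[";".join(members)] = frozenset().union(*(sets[s] for s in members))
    return GeneSetCollection.from_dict(merged) if merged else GeneSetCollection({})
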
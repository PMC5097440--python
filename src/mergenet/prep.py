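"""Marker preparation: turn raw association tables into the analysis-ready
marker -> gene hierarchy.

The default pipeline order is: top-fraction filtering of the association
table, window-based (or user-supplied) marker-gene assignment, per-gene
dependency (LD) pruning, then merging of genes with shared markers.  Pruning
runs after assignment so that each gene's own marker list -- the unit the
hierarchical permutation shuffles -- is what gets pruned.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from itertools import combinations

import networkx as nx
import pandas as pd
from intervaltree import IntervalTree

from .io import (
    DependencyTable,
    GeneLocationTable,
    MarkerAssociationTable,
    MarkerGeneMap,
    ValidationError,
)
from .util import jaccard_index

__all__ = [
    "filter_top_fraction",
    "map_markers_by_window",
    "prune_dependent_markers",
    "merge_genes_sharing_markers",
]

log = logging.getLogger(__name__)


def filter_top_fraction(assoc: MarkerAssociationTable, fraction: float) -> MarkerAssociationTable:
    """Keep the ceil(fraction * n) most significant markers.

    Weakly associated markers mostly add noise, so restricting to the top
    half of the association spectrum (fraction=0.5) is the default for GWAS.
    Ties at the cutoff break lexicographically by marker id.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(assoc)
    if n == 0:
        raise ValidationError("association table is empty")
    k = math.ceil(fraction * n)
    df = assoc.to_frame().sort_values(
        ["VALUE", "MARKER"], ascending=[False, True], kind="mergesort"
    )
    kept = df.head(k)
    return MarkerAssociationTable(pd.Series(kept["VALUE"].to_numpy(), index=kept["MARKER"]))


def map_markers_by_window(
    assoc: MarkerAssociationTable | None,
    genes: GeneLocationTable,
    marker_positions: pd.DataFrame,
    window_bp: int = 20_000,
) -> MarkerGeneMap:
    """Assign markers to genes by chromosomal proximity.

    A marker at position p maps to every gene with
    p in [start - window_bp, end + window_bp] (closed interval, 1-based) on
    the same chromosome, so markers may map to multiple overlapping genes.
    Markers on chromosomes absent from the gene table are skipped (counted in
    the log).  When ``assoc`` is given, only markers present in it are mapped.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.data.groupby("CHR", sort=False):
        tree = IntervalTree()
        for gene, start, end in zip(grp["GENE"], grp["START"], grp["END"]):
            tree[start - window_bp: end + window_bp + 1] = gene
        trees[str(chrom)] = tree

    pos = marker_positions
    if assoc is not None:
        pos = pos[pos["MARKER"].astype(str).isin(assoc.markers)]

    pairs: set[tuple[str, str]] = set()
    skipped = 0
    for marker, chrom, p in zip(pos["MARKER"], pos["CHR"], pos["POS"]):
        tree = trees.get(str(chrom))
        if tree is None:
            skipped += 1
            continue
        for iv in tree.at(int(p)):
            pairs.add((iv.data, str(marker)))
    if skipped:
        log.info("window mapping skipped %d marker(s) on unknown chromosomes", skipped)
    return MarkerGeneMap.from_pairs(pairs)


def prune_dependent_markers(
    mgmap: MarkerGeneMap,
    assoc: MarkerAssociationTable,
    deps: DependencyTable,
    r2_cutoff: float = 0.5,
) -> MarkerGeneMap:
    """Greedy per-gene pruning of dependent (e.g. LD-linked) markers.

    Within each gene's marker list, markers are visited in descending
    association value (ties by id) and kept only if their r2 with every
    already-kept marker of the same gene stays below the cutoff.  The top
    marker of each gene is therefore always retained, and a marker can be
    kept in one gene but pruned in another.  Missing pairs count as r2 = 0.
    """
    if not (0.0 < r2_cutoff <= 1.0):
        raise ValueError(f"r2_cutoff must be in (0, 1], got {r2_cutoff}")
    values = assoc.series
    pairs: list[tuple[str, str]] = []
    for gene, markers in mgmap.gene_markers.items():
        ranked = sorted(markers, key=lambda m: (-values.get(m, 0.0), m))
        kept: list[str] = []
        for m in ranked:
            if all(deps.r2(m, k) < r2_cutoff for k in kept):
                kept.append(m)
        pairs.extend((gene, m) for m in kept)
    return MarkerGeneMap.from_pairs(pairs)


def merge_genes_sharing_markers(
    mgmap: MarkerGeneMap, share_cutoff: float = 1.0
) -> MarkerGeneMap:
    """Merge genes whose marker sets overlap into supergenes.

    Genes are connected when the Jaccard overlap of their marker sets is at
    least ``share_cutoff``; each connected component of size > 1 becomes a
    supergene whose id joins the member ids with ';' and whose marker set is
    the union.  The conservative default (1.0) merges only genes with
    identical marker sets.  Downstream, a supergene inherits the gene-set
    memberships of all of its members.
    """
    if not (0.0 < share_cutoff <= 1.0):
        raise ValueError(f"share_cutoff must be in (0, 1], got {share_cutoff}")
    msets = mgmap.marker_sets()
    graph = nx.Graph()
    graph.add_nodes_from(msets)
    by_marker: dict[str, list[str]] = defaultdict(list)
    for gene, markers in msets.items():
        for m in markers:
            by_marker[m].append(gene)
    candidate_pairs = {
        pair
        for genes in by_marker.values()
        if len(genes) > 1
        for pair in combinations(sorted(genes), 2)
    }
    for a, b in candidate_pairs:
        if jaccard_index(msets[a], msets[b]) >= share_cutoff:
            graph.add_edge(a, b)
    pairs: list[tuple[str, str]] = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        gid = ";".join(members)
        union = frozenset().union(*(msets[g] for g in members))
        pairs.extend((gid, m) for m in union)
    return MarkerGeneMap.from_pairs(pairs)
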
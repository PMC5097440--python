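"""Tabular I/O and the validated in-memory containers shared by the pipeline.

Every input is a tab-delimited text file with a header row; column names are
matched case-insensitively (``MARKER``/``VALUE``, ``GENE``/``MARKER``,
``MODULE``/``GENE``, ``TAIL``/``HEAD``/``WEIGHT``, ``MARKERA``/``MARKERB``/
``R2``).  Gene sets may alternatively be supplied in GMT format.

The canonical association unit is -log10 P, so "large" always means "more
significant".  Raw P-values are accepted at the boundary only
(``value_kind="raw_p"``) and converted on load.  Duplicate markers keep the
maximum (most significant) value; duplicate or reciprocal network edges keep
the maximum weight, since weight encodes the reliability of an edge.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, is_dataclass
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "MarkerAssociationTable",
    "MarkerGeneMap",
    "GeneSetCollection",
    "WeightedNetwork",
    "DependencyTable",
    "GeneLocationTable",
    "load_association_table",
    "load_marker_gene_map",
    "load_gene_sets",
    "load_network",
    "load_dependency_table",
    "load_gene_locations",
    "load_marker_positions",
    "load_results_table",
    "write_association_table",
    "write_results_table",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """The file does not have the expected tab-delimited layout."""


class ValidationError(ValueError):
    """The file parsed, but its content violates an invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class MarkerAssociationTable:
    """Per-marker association scores in -log10 P units.

    Marker ids are unique; values are finite and non-negative.  Rows are kept
    in a canonical (marker-sorted) order so that loading is independent of the
    input row order.
    """

    series: pd.Series

    def __post_init__(self) -> None:
        s = self.series
        if not isinstance(s, pd.Series):
            s = pd.Series(s, dtype=float)
        s = s.astype(float)
        s.index = s.index.astype(str)
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise ValidationError(f"duplicate marker id {dup!r} in association table")
        vals = s.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValidationError("association values must be finite")
        if np.any(vals < 0):
            raise ValidationError("association values must be >= 0 (-log10 P scale)")
        s = s.sort_index()
        s.index.name = "MARKER"
        s.name = "VALUE"
        object.__setattr__(self, "series", s)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "MarkerAssociationTable":
        data = list(pairs)
        idx = [str(m) for m, _ in data]
        return cls(pd.Series([v for _, v in data], index=idx, dtype=float))

    def __len__(self) -> int:
        return int(self.series.size)

    @property
    def markers(self) -> pd.Index:
        return self.series.index

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy()

    def subset(self, markers: Iterable[str]) -> "MarkerAssociationTable":
        keep = self.series.index.intersection(pd.Index([str(m) for m in markers]))
        return MarkerAssociationTable(self.series.loc[keep])

    def to_frame(self) -> pd.DataFrame:
        return self.series.reset_index()


@dataclass(eq=False)
class MarkerGeneMap:
    """Many-to-many assignment of markers to genes.

    This is the marker -> gene layer of the marker-gene-set hierarchy; its
    gene list defines the universe N from which null gene sets are drawn.
    (gene, marker) pairs are unique; markers shared between genes are kept,
    since shared markers are a real feature of gene families.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.columns = [str(c).upper() for c in df.columns]
        if list(df.columns) != ["GENE", "MARKER"]:
            df = df.rename(columns={df.columns[0]: "GENE", df.columns[1]: "MARKER"})
        df["GENE"] = df["GENE"].astype(str)
        df["MARKER"] = df["MARKER"].astype(str)
        if df.duplicated().any():
            raise ValidationError("duplicate (gene, marker) pairs in marker-gene map")
        df = df.sort_values(["GENE", "MARKER"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "data", df)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MarkerGeneMap":
        uniq = sorted({(str(g), str(m)) for g, m in pairs})
        return cls(pd.DataFrame(uniq, columns=["GENE", "MARKER"]))

    def __len__(self) -> int:
        return len(self.data)

    @cached_property
    def gene_markers(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, tuple[str, ...]] = {}
        for gene, grp in self.data.groupby("GENE", sort=True):
            out[str(gene)] = tuple(grp["MARKER"])
        return out

    @property
    def genes(self) -> list[str]:
        return list(self.gene_markers)

    @property
    def markers(self) -> list[str]:
        return sorted(self.data["MARKER"].unique())

    @property
    def n_genes(self) -> int:
        return len(self.gene_markers)

    @property
    def n_markers(self) -> int:
        return int(self.data["MARKER"].nunique())

    def marker_sets(self) -> dict[str, frozenset[str]]:
        return {g: frozenset(ms) for g, ms in self.gene_markers.items()}


@dataclass(eq=False)
class GeneSetCollection:
    """Named gene sets ("modules"), each non-empty, with optional metadata."""

    sets: dict[str, frozenset[str]]
    info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for sid in sorted(self.sets):
            genes = frozenset(str(g) for g in self.sets[sid])
            if not genes:
                raise ValidationError(f"gene set {sid!r} is empty")
            clean[str(sid)] = genes
        object.__setattr__(self, "sets", clean)

    @classmethod
    def from_dict(cls, sets: Mapping[str, Iterable[str]],
                  info: pd.DataFrame | None = None) -> "GeneSetCollection":
        return cls({sid: frozenset(genes) for sid, genes in sets.items()}, info)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "GeneSetCollection":
        sets: dict[str, set[str]] = {}
        for sid, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
            sets.setdefault(str(sid), set()).add(str(gene))
        return cls.from_dict(sets)

    def ids(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, sid: str) -> bool:
        return sid in self.sets

    def __getitem__(self, sid: str) -> frozenset[str]:
        return self.sets[sid]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets

    def to_frame(self) -> pd.DataFrame:
        rows = [(sid, g) for sid, genes in self.sets.items() for g in sorted(genes)]
        return pd.DataFrame(rows, columns=["MODULE", "GENE"])


@dataclass(eq=False)
class WeightedNetwork:
    """Undirected simple graph of gene-gene edges with positive weights."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            w = d.get("weight", 1.0)
            if not (np.isfinite(w) and w > 0):
                raise ValidationError(f"non-positive weight on edge ({u!r}, {v!r})")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "WeightedNetwork":
        """Build from (tail, head[, weight]) tuples.

        Self-loops are dropped with a warning; duplicate/reciprocal edges are
        collapsed to one undirected edge keeping the maximum weight.
        """
        g = nx.Graph()
        dropped = 0
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                w = 1.0
            else:
                u, v, w = edge[:3]
            u, v, w = str(u), str(v), float(w)
            if not (np.isfinite(w) and w > 0):
                raise ValidationError(f"non-positive weight {w} on edge ({u!r}, {v!r})")
            if u == v:
                dropped += 1
                continue
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
        if dropped:
            log.warning("dropped %d self-loop edge(s)", dropped)
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = sorted(
            (min(u, v), max(u, v), d["weight"]) for u, v, d in self.graph.edges(data=True)
        )
        return pd.DataFrame(rows, columns=["TAIL", "HEAD", "WEIGHT"])


class DependencyTable:
    """Pairwise marker dependency (e.g. LD r-squared), stored unordered.

    Missing pairs are treated as independent (r2 = 0).
    """

    def __init__(self, entries: Iterable[tuple[str, str, float]] = ()) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in entries:
            r2 = float(r2)
            if not (0.0 <= r2 <= 1.0):
                raise ValidationError(f"r2 {r2} outside [0, 1] for pair ({a!r}, {b!r})")
            a, b = str(a), str(b)
            key = (a, b) if a <= b else (b, a)
            self._r2[key] = max(self._r2.get(key, 0.0), r2)

    def r2(self, a: str, b: str) -> float:
        a, b = str(a), str(b)
        key = (a, b) if a <= b else (b, a)
        return self._r2.get(key, 0.0)

    def __len__(self) -> int:
        return len(self._r2)


@dataclass(eq=False)
class GeneLocationTable:
    """Gene coordinates, 1-based inclusive; window tests use closed intervals.

    Only [start, end] is used -- strand is ignored by design, so window-based
    marker assignment is strand-symmetric.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.columns = [str(c).upper() for c in df.columns]
        df["GENE"] = df["GENE"].astype(str)
        df["CHR"] = df["CHR"].astype(str)
        df["START"] = df["START"].astype(int)
        df["END"] = df["END"].astype(int)
        bad = df["START"] > df["END"]
        if bad.any():
            raise ValidationError(
                f"gene {df.loc[bad, 'GENE'].iloc[0]!r} has start > end"
            )
        df = df.sort_values(["CHR", "START", "GENE"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "data", df[["GENE", "CHR", "START", "END"]])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path, min_cols: int = 2) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] < min_cols:
        raise FormatError(
            f"{path}: expected a tab-delimited table with >= {min_cols} columns, "
            f"found {df.shape[1]}"
        )
    df.columns = [str(c).strip().upper() for c in df.columns]
    return df


def _need(df: pd.DataFrame, path, *cols: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def load_association_table(path, value_kind: str = "neglog10p") -> MarkerAssociationTable:
    """Load a marker association table (columns MARKER, VALUE).

    ``value_kind="raw_p"`` expects P-values in (0, 1] and converts them to
    -log10 P; ``"neglog10p"`` expects non-negative scores.  Duplicate markers
    collapse to the maximum (most significant) value.
    """
    if value_kind not in ("neglog10p", "raw_p"):
        raise ValueError(f"unknown value_kind {value_kind!r}")
    df = _read_table(path)
    _need(df, path, "MARKER", "VALUE")
    vals = pd.to_numeric(df["VALUE"], errors="coerce")
    bad = ~np.isfinite(vals.to_numpy())
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
        raise ValidationError(f"{path}: non-numeric value at row {row}")
    if value_kind == "raw_p":
        out_of_range = (vals <= 0) | (vals > 1)
        if out_of_range.any():
            row = int(np.flatnonzero(out_of_range.to_numpy())[0]) + 2
            raise ValidationError(f"{path}: P-value outside (0, 1] at row {row}")
        vals = -np.log10(vals)
    else:
        neg = vals < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0]) + 2
            raise ValidationError(f"{path}: negative -log10 P at row {row}")
    series = pd.Series(vals.to_numpy(), index=df["MARKER"].astype(str))
    series = series.groupby(level=0).max()
    return MarkerAssociationTable(series)


def load_marker_gene_map(path) -> MarkerGeneMap:
    """Load a (GENE, MARKER) mapping table; duplicate pairs are dropped."""
    df = _read_table(path)
    _need(df, path, "GENE", "MARKER")
    mgmap = MarkerGeneMap.from_pairs(zip(df["GENE"], df["MARKER"]))
    log.info("loaded marker-gene map: %d genes, %d markers, %d pairs",
             mgmap.n_genes, mgmap.n_markers, len(mgmap))
    return mgmap


def load_gene_sets(path, format: str = "module_table") -> GeneSetCollection:
    """Load gene sets from a (MODULE, GENE) table or a GMT file.

    Both formats yield identical in-memory collections.
    """
    if format == "module_table":
        df = _read_table(path)
        _need(df, path, "MODULE", "GENE")
        return GeneSetCollection.from_table(df[["MODULE", "GENE"]])
    if format == "gmt":
        sets: dict[str, set[str]] = {}
        desc: list[tuple[str, str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
                    raise ValidationError(
                        f"{path}: gene set {parts[0]!r} has no genes"
                    )
                sets[parts[0]] = {g for g in parts[2:] if g.strip()}
                desc.append((parts[0], parts[1]))
        if not sets:
            raise FormatError(f"{path}: empty GMT file")
        info = pd.DataFrame(desc, columns=["MODULE", "DESCR"])
        return GeneSetCollection.from_dict(sets, info)
    raise ValueError(f"unknown gene set format {format!r}")


def load_network(path) -> WeightedNetwork:
    """Load a weighted edge list (TAIL, HEAD[, WEIGHT]) as an undirected graph.

    A missing WEIGHT column defaults every edge to 1.0, which makes the key
    driver analysis reduce to its unweighted form.
    """
    df = _read_table(path)
    _need(df, path, "TAIL", "HEAD")
    if "WEIGHT" in df.columns:
        w = pd.to_numeric(df["WEIGHT"], errors="coerce")
        if (~np.isfinite(w.to_numpy()) | (w.to_numpy() <= 0)).any():
            raise ValidationError(f"{path}: edge weights must be positive numbers")
        edges = zip(df["TAIL"], df["HEAD"], w)
    else:
        edges = ((t, h, 1.0) for t, h in zip(df["TAIL"], df["HEAD"]))
    return WeightedNetwork.from_edges(edges)


def load_dependency_table(path) -> DependencyTable:
    """Load pairwise marker dependencies (MARKERA, MARKERB, R2)."""
    df = _read_table(path, min_cols=3)
    _need(df, path, "MARKERA", "MARKERB", "R2")
    r2 = pd.to_numeric(df["R2"], errors="coerce")
    if (~np.isfinite(r2.to_numpy())).any():
        raise ValidationError(f"{path}: non-numeric r2 value")
    return DependencyTable(zip(df["MARKERA"], df["MARKERB"], r2))


def load_gene_locations(path) -> GeneLocationTable:
    """Load gene coordinates (GENE, CHR, START, END), 1-based inclusive."""
    df = _read_table(path, min_cols=4)
    _need(df, path, "GENE", "CHR", "START", "END")
    return GeneLocationTable(df[["GENE", "CHR", "START", "END"]])


def load_marker_positions(path) -> pd.DataFrame:
    """Load marker genomic positions (MARKER, CHR, POS) as a DataFrame."""
    df = _read_table(path, min_cols=3)
    _need(df, path, "MARKER", "CHR", "POS")
    out = df[["MARKER", "CHR", "POS"]].copy()
    out["MARKER"] = out["MARKER"].astype(str)
    out["CHR"] = out["CHR"].astype(str)
    out["POS"] = pd.to_numeric(out["POS"]).astype(int)
    return out


def load_results_table(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_association_table(table: MarkerAssociationTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


_ID_FIELDS = ("set_id", "hub_id")
_P_FIELDS = ("p_final", "p_meta", "p")


def write_results_table(results: Sequence, path, fields_order: Sequence[str] | None = None) -> None:
    """Write result records as a TSV with deterministic row order.

    Rows are sorted by ascending P (``p_final``/``p_meta``/``p``, whichever
    the record carries) with ties broken by id.  Tuple/list fields (co-hub
    lists, per-study z-scores) are serialised as ';'-joined strings.  An
    empty result list with ``fields_order`` given yields a header-only file.
    """
    rows = []
    for r in results:
        d = asdict(r) if is_dataclass(r) else dict(r)
        for k, v in d.items():
            if isinstance(v, (tuple, list)):
                d[k] = ";".join(str(x) for x in v)
        rows.append(d)
    if rows:
        cols = list(rows[0].keys())
    elif fields_order is not None:
        cols = list(fields_order)
    else:
        raise ValueError("empty results require fields_order to emit a header")
    df = pd.DataFrame(rows, columns=cols)
    p_col = next((c for c in _P_FIELDS if c in cols), None)
    id_cols = [c for c in _ID_FIELDS if c in cols]
    sort_by = ([p_col] if p_col else []) + id_cols
    if sort_by and len(df):
        df = df.sort_values(sort_by, kind="mergesort", na_position="last")
    df.to_csv(path, sep="\t", index=False)
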
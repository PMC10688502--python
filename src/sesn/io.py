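"""Input parsing and the shared data model.

All inputs are plain UTF-8 text: a two-column PPI edge list, a TSV
expression matrix (genes x raw sample columns), two-column protein-label
tables for GO terms and subcellular compartments, one-complex-per-line
membership lists, a one-ID-per-line essential gold standard and an
optional two-column ID-mapping table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "AnnotationBundle",
    "RawExpression",
    "SamplePlan",
    "MappingTable",
    "read_ppi",
    "read_expression",
    "read_annotations",
    "read_mapping",
    "apply_mapping",
    "write_ppi",
    "write_annotations",
    "write_expression",
]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Order-insensitive edge key for an undirected interaction."""
    return (u, v) if u <= v else (v, u)


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction graph G = (V, E).

    Stored without self-loops or duplicate edges; every edge endpoint is a
    node. `graph` is the backing :class:`networkx.Graph`.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   extra_nodes: Iterable[str] = ()) -> "PPINetwork":
        g = nx.Graph()
        for u, v in edges:
            if u == v:
                continue
            g.add_edge(u, v)
        g.add_nodes_from(extra_nodes)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {canonical_edge(u, v) for u, v in self.graph.edges}

    def neighbors(self, v: str) -> set[str]:
        return set(self.graph[v]) if v in self.graph else set()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def __contains__(self, v: str) -> bool:
        return v in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass
class AnnotationBundle:
    """GO terms, complexes, subcellular compartments and the gold standard.

    Maps may be partial: a protein absent from a map has the empty set.
    Complexes each contain at least two members.
    """

    go_terms: dict[str, set[str]] = field(default_factory=dict)
    complexes: list[set[str]] = field(default_factory=list)
    subcellular: dict[str, set[str]] = field(default_factory=dict)
    essentials: set[str] = field(default_factory=set)

    def go_of(self, v: str) -> set[str]:
        return self.go_terms.get(v, set())

    def compartments_of(self, v: str) -> set[str]:
        return self.subcellular.get(v, set())

    def complex_count(self, v: str) -> int:
        return sum(1 for c in self.complexes if v in c)


@dataclass(frozen=True)
class SamplePlan:
    """Layout of the raw expression columns.

    ``cycles`` mode: `points` time points per cycle repeated over `cycles`
    cell cycles, columns laid out cycle after cycle (column c*points + i is
    time point i of cycle c).  ``replicates`` mode: `samples` sample points
    each measured `reps` times, columns in consecutive blocks.
    """

    mode: str  # "cycles" | "replicates"
    points: int = 0
    cycles: int = 0
    samples: int = 0
    reps: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("cycles", "replicates"):
            raise ValueError(f"unknown sample-plan mode: {self.mode!r}")
        if self.mode == "cycles" and (self.points < 1 or self.cycles < 1):
            raise ValueError("cycles plan needs points >= 1 and cycles >= 1")
        if self.mode == "replicates" and (self.samples < 1 or self.reps < 1):
            raise ValueError("replicates plan needs samples >= 1 and reps >= 1")

    @property
    def n_columns(self) -> int:
        if self.mode == "cycles":
            return self.points * self.cycles
        return self.samples * self.reps

    @property
    def n_samples(self) -> int:
        """Number of averaged sample points, i.e. of sub-networks."""
        return self.points if self.mode == "cycles" else self.samples

    @classmethod
    def cycles_plan(cls, points: int, cycles: int) -> "SamplePlan":
        return cls(mode="cycles", points=points, cycles=cycles)

    @classmethod
    def replicates_plan(cls, samples: int, reps: int) -> "SamplePlan":
        return cls(mode="replicates", samples=samples, reps=reps)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SamplePlan":
        mode = d.get("mode", "cycles")
        if mode == "cycles":
            return cls.cycles_plan(int(d["points"]), int(d["cycles"]))
        return cls.replicates_plan(int(d["samples"]), int(d["reps"]))


@dataclass
class RawExpression:
    """Raw expression matrix: gene -> vector of raw column values."""

    values: dict[str, list[float]]
    sample_plan: SamplePlan

    def __post_init__(self) -> None:
        want = self.sample_plan.n_columns
        for g, vec in self.values.items():
            if len(vec) != want:
                raise ValueError(
                    f"gene {g!r}: expected {want} expression columns per the "
                    f"sample plan, found {len(vec)}"
                )


@dataclass
class MappingTable:
    """Source-ID -> target-ID translation (many-to-one allowed)."""

    pairs: dict[str, str] = field(default_factory=dict)

    def translate(self, ident: str) -> str:
        return self.pairs.get(ident, ident)


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            # tab-delimited if tabs present (labels may contain spaces)
            yield line.split("\t") if "\t" in line else line.split()


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a whitespace/TSV edge list into a clean undirected graph.

    Self-loops and duplicate edges are dropped with a logged count; a file
    with no surviving edges is an error.
    """
    g = nx.Graph()
    dropped = 0
    n_records = 0
    for fields in _data_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: malformed edge line {' '.join(fields)!r}")
        u, v = fields[0], fields[1]
        n_records += 1
        if u == v or g.has_edge(u, v):
            dropped += 1
            continue
        g.add_edge(u, v)
    if dropped:
        logger.info("read_ppi(%s): dropped %d self-loop/duplicate records", path, dropped)
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no interactions left after cleaning "
                         f"({n_records} records read)")
    return PPINetwork(g)


def read_expression(path: str | Path, sample_plan: SamplePlan) -> RawExpression:
    """Read a TSV expression matrix (header row, first column = gene ID).

    Rows sharing a gene ID (multiple probes) are collapsed by element-wise
    arithmetic mean.  Vector lengths are validated against the plan.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    gene_col = df.columns[0]
    n_cols = df.shape[1] - 1
    if n_cols != sample_plan.n_columns:
        raise ValueError(
            f"{path}: {n_cols} expression columns but the sample plan "
            f"requires {sample_plan.n_columns}"
        )
    for col in df.columns[1:]:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric expression value for gene "
                f"{bad.iloc[0][gene_col]!r} in column {col!r}"
            )
    collapsed = df.groupby(gene_col, sort=False).mean(numeric_only=True)
    values = {str(g): [float(x) for x in row]
              for g, row in zip(collapsed.index, collapsed.to_numpy())}
    for g, vec in values.items():
        if any(math.isnan(x) for x in vec):
            raise ValueError(f"{path}: gene {g!r} has missing values")
    return RawExpression(values=values, sample_plan=sample_plan)


def _read_label_map(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for fields in _data_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: expected two columns, got {fields!r}")
        out.setdefault(fields[0], set()).add(fields[1])
    return out


def read_annotations(
    go_path: str | Path | None,
    complex_path: str | Path | None,
    subcell_path: str | Path | None,
    essential_path: str | Path | None,
) -> AnnotationBundle:
    """Read the four annotation files into one bundle.

    Any individual file may be None/missing (that component stays empty,
    with a warning); all four missing is an error.  Complexes with fewer
    than two distinct members are dropped.
    """
    paths = [go_path, complex_path, subcell_path, essential_path]
    if all(p is None or not Path(p).exists() for p in paths):
        raise ValueError("no annotation file could be read (all four missing)")

    bundle = AnnotationBundle()

    def _exists(p):
        if p is None or not Path(p).exists():
            return False
        return True

    if _exists(go_path):
        bundle.go_terms = _read_label_map(go_path)
    else:
        logger.warning("GO annotation file missing; GO weights will be 0")
    if _exists(subcell_path):
        bundle.subcellular = _read_label_map(subcell_path)
    else:
        logger.warning("subcellular file missing; subcellular weights degenerate")
    if _exists(complex_path):
        n_dropped = 0
        for fields in _data_lines(complex_path):
            members = set(fields)
            if len(members) >= 2:
                bundle.complexes.append(members)
            else:
                n_dropped += 1
        if n_dropped:
            logger.info("dropped %d complexes with < 2 members", n_dropped)
    else:
        logger.warning("complex file missing; complex weights will be 0")
    if _exists(essential_path):
        for fields in _data_lines(essential_path):
            bundle.essentials.add(fields[0])
    else:
        logger.warning("essential gold-standard file missing")
    return bundle


def read_mapping(path: str | Path) -> MappingTable:
    """Read a two-column source -> target ID mapping table."""
    pairs: dict[str, str] = {}
    for fields in _data_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}: expected two columns, got {fields!r}")
        pairs[fields[0]] = fields[1]
    return MappingTable(pairs)


def apply_mapping(obj, mapping: MappingTable):
    """Translate all protein IDs of a data-model object through `mapping`.

    Unmapped IDs are kept verbatim (a count is logged).  Networks are
    re-validated afterwards, so an edge collapsed onto one node becomes a
    self-loop and is dropped.
    """
    t = mapping.translate
    if isinstance(obj, PPINetwork):
        unmapped = sum(1 for v in obj.graph.nodes if v not in mapping.pairs)
        if unmapped:
            logger.info("apply_mapping: %d node IDs not in the table, kept verbatim",
                        unmapped)
        return PPINetwork.from_edges(
            ((t(u), t(v)) for u, v in obj.graph.edges),
            extra_nodes=(t(v) for v in obj.graph.nodes),
        )
    if isinstance(obj, AnnotationBundle):
        go = {}
        for v, terms in obj.go_terms.items():
            go.setdefault(t(v), set()).update(terms)
        sub = {}
        for v, comps in obj.subcellular.items():
            sub.setdefault(t(v), set()).update(comps)
        complexes = []
        for c in obj.complexes:
            mapped = {t(v) for v in c}
            if len(mapped) >= 2:
                complexes.append(mapped)
        return AnnotationBundle(
            go_terms=go,
            complexes=complexes,
            subcellular=sub,
            essentials={t(v) for v in obj.essentials},
        )
    if isinstance(obj, RawExpression):
        values: dict[str, list[float]] = {}
        counts: dict[str, int] = {}
        for g, vec in obj.values.items():
            tg = t(g)
            if tg in values:  # many-to-one collapse: average like probes
                k = counts[tg]
                values[tg] = [(a * k + b) / (k + 1)
                              for a, b in zip(values[tg], vec)]
                counts[tg] = k + 1
            else:
                values[tg] = list(vec)
                counts[tg] = 1
        return RawExpression(values=values, sample_plan=obj.sample_plan)
    raise TypeError(f"apply_mapping: unsupported type {type(obj).__name__}")


# --- writers (used by the synthetic-data module and round-trip tests) ---

def write_ppi(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def write_expression(raw: RawExpression, path: str | Path) -> None:
    n = raw.sample_plan.n_columns
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(f"c{i}" for i in range(n)) + "\n")
        for g in sorted(raw.values):
            fh.write(g + "\t" + "\t".join(f"{x:.6g}" for x in raw.values[g]) + "\n")


def write_annotations(bundle: AnnotationBundle, go_path, complex_path,
                      subcell_path, essential_path) -> None:
    with open(go_path, "w", encoding="utf-8") as fh:
        for v in sorted(bundle.go_terms):
            for term in sorted(bundle.go_terms[v]):
                fh.write(f"{v}\t{term}\n")
    with open(complex_path, "w", encoding="utf-8") as fh:
        for c in bundle.complexes:
            if len(c) >= 2:
                fh.write("\t".join(sorted(c)) + "\n")
    with open(subcell_path, "w", encoding="utf-8") as fh:
        for v in sorted(bundle.subcellular):
            for comp in sorted(bundle.subcellular[v]):
                fh.write(f"{v}\t{comp}\n")
    with open(essential_path, "w", encoding="utf-8") as fh:
        for v in sorted(bundle.essentials):
            fh.write(v + "\n")
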
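"""Per-locus splice graph with inferred transcript boundaries and phasing paths.

The splice graph of a bundle has partial exons as internal vertices (weighted
by mean per-base read coverage), splice junctions and exon adjacencies as
edges (weighted by supporting-read counts), and virtual source/target
vertices. Transcript boundaries are inferred from boundary reads: a run of
at least ``min_boundary_reads`` same-type boundary positions, uninterrupted
by any splice position or different-type boundary and with consecutive
members within ``boundary_allowance``, yields one transcript start or end,
which is wired to the source or target.

Each long read spanning more than two partial exons contributes a phasing
path — the ordered vertex chain it covers — which the decomposition stage is
required to preserve intact.

The graph is stored in genomic coordinate order regardless of strand (edges
always run left to right); the strand flag determines how boundary types map
onto the source/target sides: on the forward strand transcript starts are on
the genomic left, on the reverse strand on the genomic right.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .alignment_io import (
    DEFAULT_MIN_INTRON_SIZE,
    AlignmentRecord,
    Bundle,
    FORWARD,
    REVERSE,
)

log = logging.getLogger(__name__)

DEFAULT_MIN_BOUNDARY_READS = 3
DEFAULT_BOUNDARY_ALLOWANCE = 10

# event kinds
DONOR = "donor"
ACCEPTOR = "acceptor"
START_5P = "start_5p"
END_3P = "end_3p"
_SPLICE_KINDS = (DONOR, ACCEPTOR)


class GraphConsistencyError(RuntimeError):
    """Internal contradiction while assembling a splice graph."""


class Event(NamedTuple):
    pos: int
    kind: str

    @property
    def is_splice(self) -> bool:
        return self.kind in _SPLICE_KINDS


@dataclass(frozen=True)
class BoundaryCall:
    """An inferred transcript start/end supported by concordant boundary reads."""

    kind: str  # START_5P or END_3P
    position: int
    support: int


@dataclass(frozen=True)
class PartialExon:
    """A maximal interval between consecutive splice/boundary/coverage breaks."""

    start: int
    end: int
    weight: float  # mean per-base read coverage

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class PhasingPath:
    """The ordered chain of >2 partial exons covered by identical reads."""

    vertices: tuple[int, ...]
    support: int


@dataclass
class Edge:
    weight: float
    kind: str  # junction | adjacency | source_link | sink_link


class SpliceGraph:
    """Directed acyclic splice graph over partial-exon vertices.

    Internal vertices are indexed ``0..n-1`` in genomic order; the virtual
    source is ``graph.s == -1`` and the target ``graph.t == n``. Every edge
    runs from a lower to a higher index, so the index order is a topological
    order.
    """

    def __init__(self, chrom: str, strand: str, vertices: Sequence[PartialExon]):
        vs = list(vertices)
        for a, b in zip(vs, vs[1:]):
            if b.start < a.end:
                raise GraphConsistencyError(
                    f"partial exons out of order or overlapping: {a} vs {b}"
                )
        self.chrom = chrom
        self.strand = strand
        self.vertices: list[PartialExon] = vs
        self.s = -1
        self.t = len(vs)
        self._succ: dict[int, dict[int, Edge]] = {}
        self._pred: dict[int, dict[int, Edge]] = {}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def add_edge(self, u: int, v: int, weight: float, kind: str) -> Edge:
        if not (self.s <= u < v <= self.t):
            raise GraphConsistencyError(f"edge ({u},{v}) violates topological order")
        edge = Edge(weight=float(weight), kind=kind)
        self._succ.setdefault(u, {})[v] = edge
        self._pred.setdefault(v, {})[u] = edge
        return edge

    def has_edge(self, u: int, v: int) -> bool:
        return v in self._succ.get(u, {})

    def edge(self, u: int, v: int) -> Edge:
        return self._succ[u][v]

    def out_edges(self, u: int) -> list[tuple[int, Edge]]:
        return sorted(self._succ.get(u, {}).items())

    def in_edges(self, v: int) -> list[tuple[int, Edge]]:
        return sorted(self._pred.get(v, {}).items())

    def edges(self) -> Iterator[tuple[int, int, Edge]]:
        for u in sorted(self._succ):
            for v in sorted(self._succ[u]):
                yield u, v, self._succ[u][v]

    def n_edges(self) -> int:
        return sum(len(d) for d in self._succ.values())

    def topological_order(self) -> list[int]:
        return [self.s] + list(range(self.n_vertices)) + [self.t]

    def to_dot(self) -> str:
        """GraphViz-style text dump for debugging."""
        lines = [f'digraph "{self.chrom}{self.strand}" {{']
        for i, v in enumerate(self.vertices):
            lines.append(f'  v{i} [label="[{v.start},{v.end}) w={v.weight:.2f}"];')
        for u, v, e in self.edges():
            lu = "s" if u == self.s else f"v{u}"
            lv = "t" if v == self.t else f"v{v}"
            lines.append(f'  {lu} -> {lv} [label="{e.weight:.2f} {e.kind}"];')
        lines.append("}")
        return "\n".join(lines)


def collect_positions(bundle: Bundle) -> list[Event]:
    """Sort splice positions and boundary-read positions into one event list.

    Donor/acceptor events come from every record's junctions; 5'/3' boundary
    events come only from boundary reads (never non-full-length internal
    reads). At equal coordinates splice events sort before boundary events.
    """
    events: list[Event] = []
    for rec in bundle.records:
        for donor, acceptor in rec.junctions:
            events.append(Event(donor, DONOR))
            events.append(Event(acceptor, ACCEPTOR))
        b5 = rec.boundary_5p
        if b5 is not None:
            events.append(Event(b5, START_5P))
        b3 = rec.boundary_3p
        if b3 is not None:
            events.append(Event(b3, END_3P))
    events.sort(key=lambda ev: (ev.pos, 0 if ev.is_splice else 1))
    return events


def call_boundaries(
    events: Sequence[Event],
    min_boundary_reads: int = DEFAULT_MIN_BOUNDARY_READS,
    boundary_allowance: int = DEFAULT_BOUNDARY_ALLOWANCE,
    strand: str = FORWARD,
) -> list[BoundaryCall]:
    """Scan the sorted event list for transcript boundary signals.

    A maximal run of same-type boundary events — uninterrupted by any splice
    event or different-type boundary event, with consecutive members at most
    ``boundary_allowance`` apart — of size at least ``min_boundary_reads``
    yields one call. A 5' run reports its leftmost position on the forward
    strand (rightmost on the reverse); a 3' run the mirror image.
    """
    if min_boundary_reads < 1:
        raise ValueError("min_boundary_reads must be >= 1")
    if boundary_allowance < 0:
        raise ValueError("boundary_allowance must be >= 0")

    calls: list[BoundaryCall] = []
    run_kind: str | None = None
    run: list[int] = []

    def close() -> None:
        nonlocal run_kind, run
        if run_kind is not None and len(run) >= min_boundary_reads:
            # runs are position-sorted; pick the transcript-outermost member
            if (run_kind == START_5P) == (strand != REVERSE):
                pos = run[0]  # leftmost
            else:
                pos = run[-1]  # rightmost
            calls.append(BoundaryCall(kind=run_kind, position=pos, support=len(run)))
        run_kind = None
        run = []

    for ev in events:
        if ev.is_splice:
            close()
            continue
        if ev.kind != run_kind or (run and ev.pos - run[-1] > boundary_allowance):
            close()
            run_kind = ev.kind
            run = [ev.pos]
        else:
            run.append(ev.pos)
    close()
    calls.sort(key=lambda c: (c.position, c.kind))
    return calls


def segment_partial_exons(
    bundle: Bundle, boundaries: Sequence[BoundaryCall] = ()
) -> list[PartialExon]:
    """Partition the covered genome of a bundle into partial exons.

    Breakpoints are every splice position, every called boundary position and
    every zero-coverage gap; each resulting piece carries its mean per-base
    coverage as weight.
    """
    if not bundle.records:
        return []
    offset = min(r.start for r in bundle.records)
    end = max(r.end for r in bundle.records)
    cov = np.zeros(end - offset, dtype=np.int64)
    breaks: set[int] = set()
    for rec in bundle.records:
        for s, e in rec.segments:
            cov[s - offset : e - offset] += 1
        for donor, acceptor in rec.junctions:
            breaks.add(donor)
            breaks.add(acceptor)
    for call in boundaries:
        breaks.add(call.position)

    # maximal covered runs
    covered = cov > 0
    padded = np.concatenate(([False], covered, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    runs = edges.reshape(-1, 2) + offset

    cut_list = sorted(breaks)
    exons: list[PartialExon] = []
    for run_start, run_end in runs:
        cuts = [run_start] + [p for p in cut_list if run_start < p < run_end] + [run_end]
        for a, b in zip(cuts, cuts[1:]):
            weight = float(cov[a - offset : b - offset].mean())
            exons.append(PartialExon(start=int(a), end=int(b), weight=weight))
    return exons


def build_graph(
    bundle: Bundle,
    partial_exons: Sequence[PartialExon],
    boundaries: Sequence[BoundaryCall] = (),
    min_intron_size: int = DEFAULT_MIN_INTRON_SIZE,
) -> SpliceGraph:
    """Assemble the splice graph of one bundle.

    Junction edges connect the vertex ending at a donor to the vertex
    starting at the matching acceptor, weighted by supporting-read count.
    Adjacency edges connect genomically abutting vertices crossed
    contiguously by at least one read, weighted by crossing-read count.
    Source/sink links come from boundary calls (weighted by their support)
    and, so the graph stays decomposable, from vertices with no incoming or
    outgoing edge (weighted by the vertex coverage).
    """
    graph = SpliceGraph(bundle.chrom, bundle.strand, partial_exons)
    start_idx = {v.start: i for i, v in enumerate(graph.vertices)}
    end_idx = {v.end: i for i, v in enumerate(graph.vertices)}

    junction_census: Counter[tuple[int, int]] = Counter()
    for rec in bundle.records:
        junction_census.update(rec.junctions)

    for (donor, acceptor), count in sorted(junction_census.items()):
        if acceptor - donor < min_intron_size:
            raise GraphConsistencyError(
                f"junction ({donor},{acceptor}) shorter than the intron minimum"
            )
        u = end_idx.get(donor)
        v = start_idx.get(acceptor)
        if u is None or v is None:
            raise GraphConsistencyError(
                f"junction ({donor},{acceptor}) does not match partial-exon borders"
            )
        graph.add_edge(u, v, count, "junction")

    # adjacency edges between abutting vertices crossed by a read segment
    for i in range(graph.n_vertices - 1):
        u, v = graph.vertices[i], graph.vertices[i + 1]
        if u.end != v.start:
            continue
        crossing = sum(
            1
            for rec in bundle.records
            if any(s < u.end < e for s, e in rec.segments)
        )
        if crossing > 0:
            graph.add_edge(i, i + 1, crossing, "adjacency")

    # boundary-derived source/sink links; strand decides which genomic side
    # of a vertex corresponds to a transcript start vs end
    for call in boundaries:
        attach_source = (call.kind == START_5P) == (bundle.strand != REVERSE)
        if attach_source:
            v = start_idx.get(call.position)
            if v is None:
                log.warning(
                    "boundary call at %d matches no partial-exon start", call.position
                )
                continue
            if not graph.has_edge(graph.s, v):
                graph.add_edge(graph.s, v, call.support, "source_link")
        else:
            u = end_idx.get(call.position)
            if u is None:
                log.warning(
                    "boundary call at %d matches no partial-exon end", call.position
                )
                continue
            if not graph.has_edge(u, graph.t):
                graph.add_edge(u, graph.t, call.support, "sink_link")

    # topology-forced links keep every vertex on an s-t path
    for i, vx in enumerate(graph.vertices):
        if not graph.in_edges(i):
            graph.add_edge(graph.s, i, vx.weight, "source_link")
        if not graph.out_edges(i):
            graph.add_edge(i, graph.t, vx.weight, "sink_link")
    return graph


def project_read(rec: AlignmentRecord, graph: SpliceGraph) -> tuple[int, ...] | None:
    """Project a read onto the ordered chain of vertices it covers.

    A read covers a vertex when it overlaps at least one base of it and is
    compatible with the graph around it: consecutive covered vertices must be
    linked either by a junction the read itself carries or, when abutting, be
    crossed contiguously by one read segment; interior vertices of the chain
    must be fully spanned. Returns None for incompatible projections.
    """
    chain = [
        i
        for i, v in enumerate(graph.vertices)
        if any(s < v.end and v.start < e for s, e in rec.segments)
    ]
    if not chain:
        return None
    junctions = set(rec.junctions)
    verts = graph.vertices
    for a, b in zip(chain, chain[1:]):
        u, v = verts[a], verts[b]
        if u.end == v.start:
            if not any(s < u.end < e for s, e in rec.segments):
                return None
        elif (u.end, v.start) not in junctions:
            return None
    for idx in chain[1:-1]:
        v = verts[idx]
        if not any(s <= v.start and v.end <= e for s, e in rec.segments):
            return None
    return tuple(chain)


def extract_phasing_paths(bundle: Bundle, graph: SpliceGraph) -> list[PhasingPath]:
    """Derive phasing paths: vertex chains of reads spanning more than two exons.

    Identical chains are merged with summed support; chains that are
    contiguous subsequences of longer chains are retained as separate
    constraints. Reads whose projection is incompatible with the graph are
    excluded with a warning.
    """
    census: Counter[tuple[int, ...]] = Counter()
    for rec in bundle.records:
        chain = project_read(rec, graph)
        if chain is None:
            log.warning(
                "read %s projects incompatibly onto the splice graph; "
                "excluded from phasing",
                rec.read_id,
            )
            continue
        if len(chain) >= 3:
            census[chain] += 1
    return [PhasingPath(vertices=c, support=n) for c, n in sorted(census.items())]


def dump_phasing_paths(paths: Sequence[PhasingPath]) -> str:
    """TSV dump of phasing paths (vertex chain, support) for debugging."""
    lines = ["vertices\tsupport"]
    for p in paths:
        lines.append(",".join(map(str, p.vertices)) + f"\t{p.support}")
    return "\n".join(lines)
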
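"""Post-assembly single-linkage clustering of nearly redundant transcripts.

Two multi-exon transcripts are "very similar" when they lie on the same
chromosome and strand, have the same number of splice junctions, and every
junction differs by at most an allowance summed over its donor and acceptor
shifts (default 10 bp). Connected components of the similarity graph are
clusters; each is represented by its highest-abundance member, whose
abundance becomes the cluster sum and whose end-exons are extended to span
the whole cluster. Single-exon transcripts pass through untouched — the
similarity predicate is defined on splice positions and a transcript without
junctions has none.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx

DEFAULT_CLUSTER_ALLOWANCE = 10


@dataclass
class Transcript:
    """A strand-aware exon chain with predicted abundance."""

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    abundance: float
    transcript_id: str
    gene_id: str

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon ({s},{e}) in {self.transcript_id}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"unordered/abutting exons in {self.transcript_id}")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """The splice chain: ordered (donor, acceptor) pairs."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def similar(t1: Transcript, t2: Transcript, allowance: int = DEFAULT_CLUSTER_ALLOWANCE) -> bool:
    """Symmetric similarity on splice positions.

    True iff same chromosome and strand, equal junction counts (at least
    one), and for every junction the summed absolute donor and acceptor
    differences are within the allowance.
    """
    if allowance < 0:
        raise ValueError("allowance must be >= 0")
    if t1.chrom != t2.chrom or t1.strand != t2.strand:
        return False
    j1, j2 = t1.junctions, t2.junctions
    if len(j1) != len(j2) or not j1:
        return False
    return all(
        abs(d1 - d2) + abs(a1 - a2) <= allowance
        for (d1, a1), (d2, a2) in zip(j1, j2)
    )


def _representative(members: Sequence[Transcript]) -> Transcript:
    # highest abundance; ties: longer span, then leftmost, then lexicographic id
    return sorted(
        members,
        key=lambda t: (-t.abundance, -(t.end - t.start), t.start, t.transcript_id),
    )[0]


def cluster(
    transcripts: Sequence[Transcript],
    allowance: int = DEFAULT_CLUSTER_ALLOWANCE,
) -> list[Transcript]:
    """Collapse nearly redundant transcripts by single-linkage clustering.

    The all-pairs similarity graph is computed per (chromosome, strand,
    junction count) bucket with a first-junction window prefilter — the
    predicate requires every junction within the allowance, so any similar
    pair's first donors are within it too; semantics equal all-pairs.
    """
    singles = [t for t in transcripts if len(t.exons) == 1]
    multi = [t for t in transcripts if len(t.exons) > 1]

    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(range(len(multi)))
    buckets: dict[tuple[str, str, int], list[int]] = {}
    for i, t in enumerate(multi):
        buckets.setdefault((t.chrom, t.strand, len(t.junctions)), []).append(i)
    for idxs in buckets.values():
        idxs = sorted(idxs, key=lambda i: multi[i].junctions[0][0])
        for a, i in enumerate(idxs):
            di = multi[i].junctions[0][0]
            for j in idxs[a + 1 :]:
                if multi[j].junctions[0][0] - di > allowance:
                    break
                if similar(multi[i], multi[j], allowance):
                    graph.add_edge(i, j)

    merged: list[Transcript] = []
    for component in nx.connected_components(graph):
        members = [multi[i] for i in sorted(component)]
        rep = _representative(members)
        exons = list(rep.exons)
        left = min(t.start for t in members)
        right = max(t.end for t in members)
        # extend the two end-exons to span the cluster; interior junctions
        # of the representative are untouched
        exons[0] = (min(left, exons[0][0]), exons[0][1])
        exons[-1] = (exons[-1][0], max(right, exons[-1][1]))
        merged.append(
            replace(rep, exons=tuple(exons), abundance=sum(t.abundance for t in members))
        )

    out = singles + merged
    out.sort(key=lambda t: (t.chrom, t.start, t.end, t.transcript_id))
    return out
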
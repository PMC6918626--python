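"""Anatomy of a splice graph: the classic two-long-read worked example.

Five partial exons a..e; one read spans (a,c,e), two reads span (b,c,d).
A weight-matching decomposition could explain the graph with three paths
that break both reads' exon chains — phasing-path preservation forbids it.
"""

from isoforge import AlignmentRecord, Bundle, ReadClass
from isoforge.decomposition import decompose
from isoforge.splice_graph import (
    build_graph,
    extract_phasing_paths,
    segment_partial_exons,
)

EXONS = {"a": (100, 200), "b": (300, 400), "c": (500, 600), "d": (700, 800), "e": (900, 1000)}


def read(name, keys):
    return AlignmentRecord(
        read_id=name,
        chrom="chr1",
        strand="+",
        segments=tuple(EXONS[k] for k in keys),
        read_class=ReadClass.FULL_LENGTH,
    )


records = (read("green1", "ace"), read("blue1", "bcd"), read("blue2", "bcd"))
bundle = Bundle(chrom="chr1", strand="+", span=(100, 1000), records=records)

partial_exons = segment_partial_exons(bundle)
graph = build_graph(bundle, partial_exons)
print(graph.to_dot())

phasing = extract_phasing_paths(bundle, graph)
names = "abcde"
for p in phasing:
    chain = ",".join(names[v] for v in p.vertices)
    print(f"phasing path ({chain}) supported by {p.support} read(s)")

result = decompose(graph, phasing)
for tp in result.paths:
    chain = ",".join(names[v] for v in tp.vertices if 0 <= v < 5)
    print(f"transcript path ({chain}) abundance {tp.abundance:.1f}")
print(f"L1 weight deviation: {result.l1_deviation:.4f}")

# Both long reads' chains appear contiguously in the output paths: the
# decomposition recovered exactly the two molecules that generated the data.
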
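"""Shared builders: the worked-example bundle, random loci, planted graphs."""

from __future__ import annotations

import numpy as np
import pytest

from isoforge.alignment_io import (
    AlignmentRecord,
    Bundle,
    ReadClass,
    make_bundles,
    smooth_alignment,
)
from isoforge.splice_graph import PartialExon, PhasingPath, SpliceGraph
from isoforge.synthetic import SimConfig, simulate


def make_record(
    read_id: str,
    segments,
    *,
    chrom: str = "chr1",
    strand: str = "+",
    read_class: ReadClass = ReadClass.NFL_INTERNAL,
) -> AlignmentRecord:
    return AlignmentRecord(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        segments=tuple(tuple(s) for s in segments),
        read_class=read_class,
    )


def make_bundle(records, strand: str = "+") -> Bundle:
    start = min(r.start for r in records)
    end = max(r.end for r in records)
    return Bundle(
        chrom=records[0].chrom, strand=strand, span=(start, end), records=tuple(records)
    )


# The five-partial-exon worked example: exons a..e, one long read spanning
# (a,c,e) and two spanning (b,c,d).
FIG_EXONS = {
    "a": (100, 200),
    "b": (300, 400),
    "c": (500, 600),
    "d": (700, 800),
    "e": (900, 1000),
}


@pytest.fixture
def fig1_bundle() -> Bundle:
    ex = FIG_EXONS
    green = make_record(
        "green1", [ex["a"], ex["c"], ex["e"]], read_class=ReadClass.FULL_LENGTH
    )
    blues = [
        make_record(
            f"blue{i}", [ex["b"], ex["c"], ex["d"]], read_class=ReadClass.FULL_LENGTH
        )
        for i in (1, 2)
    ]
    return make_bundle([green] + blues)


def sim_to_records(result) -> list[AlignmentRecord]:
    """Convert simulated reads into alignment records (trusting the XS tag)."""
    records = [
        AlignmentRecord(
            read_id=r.read_id,
            chrom=r.chrom,
            strand=r.xs_tag if r.xs_tag is not None else ".",
            segments=smooth_alignment(r.cigar, r.pos),
            read_class=r.label,
        )
        for r in result.reads
    ]
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.read_id))
    return records


@pytest.fixture
def sim_bundles() -> list[Bundle]:
    """A handful of realistic bundles from a small simulated dataset."""
    cfg = SimConfig(
        seed=42,
        n_genes=6,
        depth=4,
        indel_rate=0.02,
        p_truncate_5p=lambda L: 0.3,
        p_truncate_3p=lambda L: 0.2,
    )
    return make_bundles(sim_to_records(simulate(cfg)))


def planted_graph(rng: np.random.Generator, max_vertices: int = 7, max_paths: int = 4):
    """Random DAG built by planting weighted s-t paths and summing weights.

    Returns (graph, planted s-t paths, planted abundances, phasing paths);
    phasing paths are contiguous interior subchains of planted paths.
    """
    n0 = int(rng.integers(3, max_vertices + 1))
    k = int(rng.integers(1, max_paths + 1))
    raw_paths = []
    for _ in range(k):
        length = int(rng.integers(1, n0 + 1))
        verts = tuple(sorted(rng.choice(n0, size=length, replace=False).tolist()))
        raw_paths.append(verts)
    used = sorted({v for p in raw_paths for v in p})
    remap = {v: i for i, v in enumerate(used)}
    n = len(used)
    interiors = [tuple(remap[v] for v in p) for p in raw_paths]
    paths = [(-1,) + it + (n,) for it in interiors]
    abundances = rng.integers(1, 10, size=len(paths)).astype(float)

    vertices = [PartialExon(200 * i, 200 * i + 100, 1.0) for i in range(n)]
    graph = SpliceGraph("chrS", "+", vertices)
    weights: dict[tuple[int, int], float] = {}
    for p, x in zip(paths, abundances):
        for uv in zip(p, p[1:]):
            weights[uv] = weights.get(uv, 0.0) + x
    for (u, v), w in sorted(weights.items()):
        kind = "junction"
        if u == graph.s:
            kind = "source_link"
        elif v == graph.t:
            kind = "sink_link"
        graph.add_edge(u, v, w, kind)

    phasing: dict[tuple[int, ...], int] = {}
    for it in interiors:
        if len(it) < 3 or rng.random() < 0.3:
            continue
        m = int(rng.integers(3, len(it) + 1))
        start = int(rng.integers(0, len(it) - m + 1))
        chain = it[start : start + m]
        phasing[chain] = phasing.get(chain, 0) + 1
    phasing_paths = [PhasingPath(c, s) for c, s in sorted(phasing.items())]
    return graph, paths, abundances, phasing_paths
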
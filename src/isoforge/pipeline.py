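"""End-to-end assembly: alignments -> bundles -> splice graphs -> transcripts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

from . import alignment_io, clustering, decomposition, splice_graph, transcript_io
from .alignment_io import AlignmentRecord, Bundle
from .clustering import Transcript

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults."""

    min_boundary_reads: int = 3
    boundary_allowance: int = 10
    min_intron_size: int = 50
    max_cluster_intron_distance: int = 10
    bundle_gap: int = 50
    min_transcript_coverage: float = 1.0
    peel_floor: float = 1.0
    min_mapping_quality: int = 1
    cluster: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def assemble_bundle(
    bundle: Bundle, config: RunConfig, gene_id: str
) -> tuple[list[Transcript], dict]:
    """Assemble one bundle into transcripts (pre-clustering)."""
    events = splice_graph.collect_positions(bundle)
    boundaries = splice_graph.call_boundaries(
        events,
        min_boundary_reads=config.min_boundary_reads,
        boundary_allowance=config.boundary_allowance,
        strand=bundle.strand,
    )
    exons = splice_graph.segment_partial_exons(bundle, boundaries)
    graph = splice_graph.build_graph(
        bundle, exons, boundaries, min_intron_size=config.min_intron_size
    )
    phasing = splice_graph.extract_phasing_paths(bundle, graph)
    result = decomposition.decompose(
        graph,
        phasing,
        min_transcript_coverage=config.min_transcript_coverage,
        peel_floor=config.peel_floor,
    )
    transcripts = []
    for i, tp in enumerate(result.paths):
        exon_chain = _vertices_to_exons(graph, tp.vertices)
        if not exon_chain:
            continue
        transcripts.append(
            Transcript(
                chrom=bundle.chrom,
                strand=bundle.strand,
                exons=exon_chain,
                abundance=tp.abundance,
                transcript_id=f"{gene_id}.{i + 1}",
                gene_id=gene_id,
            )
        )
    stats = {
        "n_phasing_paths": len(phasing),
        "n_paths": len(result.paths),
        "l1_deviation": result.l1_deviation,
    }
    return transcripts, stats


def _vertices_to_exons(
    graph: splice_graph.SpliceGraph, path: Sequence[int]
) -> tuple[tuple[int, int], ...]:
    """Merge genomically abutting partial exons of an s-t path into exons."""
    internal = [v for v in path if 0 <= v < graph.n_vertices]
    exons: list[list[int]] = []
    for v in internal:
        px = graph.vertices[v]
        if exons and exons[-1][1] == px.start:
            exons[-1][1] = px.end
        else:
            exons.append([px.start, px.end])
    return tuple((s, e) for s, e in exons)


def assemble_records(
    records: Sequence[AlignmentRecord], config: RunConfig | None = None
) -> tuple[list[Transcript], dict]:
    """Assemble in-memory alignment records; returns (transcripts, summary)."""
    config = config or RunConfig()
    bundles = alignment_io.make_bundles(records, bundle_gap=config.bundle_gap)
    transcripts: list[Transcript] = []
    n_phasing = 0
    for i, bundle in enumerate(bundles):
        ts, stats = assemble_bundle(bundle, config, gene_id=f"gene.{i + 1}")
        transcripts.extend(ts)
        n_phasing += stats["n_phasing_paths"]
    n_pre = len(transcripts)
    if config.cluster:
        transcripts = clustering.cluster(
            transcripts, allowance=config.max_cluster_intron_distance
        )
    summary = {
        "n_records": len(records),
        "n_bundles": len(bundles),
        "n_graphs": len(bundles),
        "n_phasing_paths": n_phasing,
        "n_transcripts_pre_clustering": n_pre,
        "n_transcripts": len(transcripts),
    }
    return transcripts, summary


def assemble(
    alignments_path,
    classification_path,
    out_gtf,
    config: RunConfig | None = None,
) -> dict:
    """File-level pipeline: SAM/BAM + classification TSV -> GTF.

    Returns the run summary. An empty alignment file yields an empty GTF
    with a warning.
    """
    config = config or RunConfig()
    classes = alignment_io.parse_classification(classification_path)
    records = alignment_io.load_alignments(
        alignments_path,
        classes,
        min_intron_size=config.min_intron_size,
        min_mapping_quality=config.min_mapping_quality,
    )
    if not records:
        log.warning("no usable alignments in %s; writing empty GTF", alignments_path)
    transcripts, summary = assemble_records(records, config)
    transcript_io.write_gtf(transcripts, out_gtf)
    return summary
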
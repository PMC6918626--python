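"""Synthetic genomes, annotations and truncation-modelled long-read alignments.

The generator emulates the data model of single-molecule cDNA sequencing:
multi-isoform genes whose isoforms share splice junctions (exon skipping off
a common scaffold), reads that are complete transcript copies subject to
length-dependent 5'/3' truncation — incomplete cDNA synthesis makes
full-length reads increasingly unlikely for long transcripts, with the
default logistic model centred at 2.5 kb — and indel-dominated alignment
errors injected into the CIGARs (insertions and same-length-budget
deletions inside exons, so reference spans stay exact).

Reads are emitted as pre-aligned SAM records rather than FASTA needing an
aligner, keeping every stage testable offline; a FASTA emitter for the reads
exists as a convenience for optional end-to-end runs with a real aligner.
All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pysam

from .alignment_io import ReadClass, classify_flags
from .clustering import Transcript
from .transcript_io import write_gtf

MIN_READ_LENGTH = 50


class SimulationConfigError(ValueError):
    pass


def logistic_truncation(max_p: float, midpoint: float, scale: float) -> Callable[[int], float]:
    """Monotone non-decreasing truncation probability as a function of length."""

    def p(length: int) -> float:
        return float(max_p / (1.0 + np.exp(-(length - midpoint) / scale)))

    return p


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Truncation probabilities are monotone non-decreasing in transcript
    length; the defaults follow a logistic curve with midpoint 2.5 kb, the
    length beyond which full-length reads become unlikely. 5' loss dominates
    (reverse transcription proceeds from the polyA end), hence the larger 5'
    ceiling. ``indel_rate`` is per exonic base; indels are capped at
    ``max_indel_len`` and never alter reference spans or junctions.
    ``splice_jitter`` emulates indel-induced misalignment around splice
    sites: each junction side of each read is shifted by up to 3 bp with
    this probability, producing the nearly redundant transcripts that
    post-assembly clustering collapses. It is off by default so that exact
    junction recovery can be asserted against the truth annotation.
    """

    seed: int = 0
    n_genes: int = 20
    isoforms_per_gene: tuple[int, int] = (2, 3)
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 400)
    depth: int = 5
    truncation_5p_max: float = 0.6
    truncation_3p_max: float = 0.3
    truncation_midpoint: float = 2500.0
    truncation_scale: float = 300.0
    p_truncate_5p: Callable[[int], float] | None = None
    p_truncate_3p: Callable[[int], float] | None = None
    indel_rate: float = 0.01
    max_indel_len: int = 3
    splice_jitter: float = 0.0  # per-junction-side misalignment probability
    bases_per_chrom: int = 500_000
    gene_gap: tuple[int, int] = (2000, 4000)
    strand_tag_missing_rate: float = 0.0

    def truncate_5p_prob(self, length: int) -> float:
        fn = self.p_truncate_5p or logistic_truncation(
            self.truncation_5p_max, self.truncation_midpoint, self.truncation_scale
        )
        return fn(length)

    def truncate_3p_prob(self, length: int) -> float:
        fn = self.p_truncate_3p or logistic_truncation(
            self.truncation_3p_max, self.truncation_midpoint, self.truncation_scale
        )
        return fn(length)

    def validate(self) -> None:
        if self.n_genes < 1 or self.depth < 1:
            raise SimulationConfigError("n_genes and depth must be >= 1")
        if self.exons_per_gene[0] < 4:
            raise SimulationConfigError(
                "genes need >= 4 exons so isoforms can skip internal exons"
            )
        if not 0 <= self.indel_rate <= 1:
            raise SimulationConfigError("indel_rate must be in [0,1]")
        if self.intron_length[0] < 1 or self.exon_length[0] < 1:
            raise SimulationConfigError("length ranges must be positive")
        span = (
            self.exons_per_gene[1] * self.exon_length[1]
            + (self.exons_per_gene[1] - 1) * self.intron_length[1]
        )
        if span + self.gene_gap[1] > self.bases_per_chrom:
            raise SimulationConfigError(
                "gene geometry infeasible: maximal gene longer than a chromosome"
            )


@dataclass(frozen=True)
class SimRead:
    read_id: str
    chrom: str
    strand: str  # transcript strand of the originating gene
    pos: int  # leftmost aligned position
    cigar: str
    segments: tuple[tuple[int, int], ...]  # truth: post-smoothing intervals
    flags: tuple[bool, bool, bool]  # has_5p, has_3p, has_polyA
    label: ReadClass
    isoform_id: str
    xs_tag: str | None


@dataclass
class SimResult:
    config: SimConfig
    chrom_lengths: dict[str, int]
    transcripts: list[Transcript]  # the truth annotation
    reads: list[SimRead]

    @property
    def classification_rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (r.read_id, int(r.flags[0]), int(r.flags[1]), int(r.flags[2]))
            for r in self.reads
        ]


def _slice_exons(
    exons: Sequence[tuple[int, int]], a: int, b: int
) -> tuple[tuple[int, int], ...]:
    """Genomic segments for sense-left-based transcript interval [a, b)."""
    out = []
    offset = 0
    for s, e in exons:
        length = e - s
        lo, hi = max(a - offset, 0), min(b - offset, length)
        if hi > lo:
            out.append((s + lo, s + hi))
        offset += length
    return tuple(out)


def _segment_ops(m: int, rng: np.random.Generator, rate: float, max_len: int) -> list[tuple[str, int]]:
    """CIGAR ops for one exon segment with injected indels.

    Deletions consume reference bases from the surrounding match run and
    insertions none, so the segment's reference span is exactly ``m``.
    """
    if rate <= 0 or m <= 2 * (max_len + 2):
        return [("M", m)]
    n_events = rng.binomial(m, rate)
    if n_events == 0:
        return [("M", m)]
    sites = np.unique(rng.integers(1, m - max_len - 1, size=n_events))
    ops: list[tuple[str, int]] = []
    cur = 0
    for s in sites:
        if s < cur + 1:
            continue
        ln = int(rng.integers(1, max_len + 1))
        ops.append(("M", int(s) - cur))
        if rng.random() < 0.5:
            ops.append(("I", ln))
            cur = int(s)
        else:
            ops.append(("D", ln))
            cur = int(s) + ln
    if m - cur > 0:
        ops.append(("M", m - cur))
    return ops


def _jitter_junctions(
    segments: Sequence[tuple[int, int]], rng: np.random.Generator, prob: float
) -> tuple[tuple[int, int], ...]:
    """Shift junction sides by up to 3 bp, keeping segments/introns valid."""
    segs = [list(s) for s in segments]
    for i in range(len(segs) - 1):
        if rng.random() < prob:
            segs[i][1] += int(rng.integers(-3, 4))
        if rng.random() < prob:
            segs[i + 1][0] += int(rng.integers(-3, 4))
    valid = all(e > s for s, e in segs) and all(
        segs[i + 1][0] - segs[i][1] >= 50 for i in range(len(segs) - 1)
    )
    if not valid:
        return tuple(tuple(s) for s in segments)
    return tuple((s, e) for s, e in segs)


def _cigar_string(
    segments: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    rate: float,
    max_len: int,
) -> str:
    parts: list[tuple[str, int]] = []
    for i, (s, e) in enumerate(segments):
        if i:
            parts.append(("N", s - segments[i - 1][1]))
        parts.extend(_segment_ops(e - s, rng, rate, max_len))
    return "".join(f"{n}{op}" for op, n in parts)


def simulate(config: SimConfig) -> SimResult:
    """Generate the gene models, truth annotation and simulated read set."""
    config.validate()
    rng = np.random.default_rng([config.seed, 7])

    chrom_lengths: dict[str, int] = {}
    transcripts: list[Transcript] = []
    reads: list[SimRead] = []

    chrom_i = 0
    cursor = 1000
    chrom = f"chr{chrom_i + 1}"
    for g in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
        in_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, n_ex - 1
        )
        span = int(ex_lens.sum() + in_lens.sum())
        if cursor + span + 1000 > config.bases_per_chrom:
            chrom_lengths[chrom] = cursor
            chrom_i += 1
            chrom = f"chr{chrom_i + 1}"
            cursor = 1000
        scaffold: list[tuple[int, int]] = []
        pos = cursor
        for k in range(n_ex):
            scaffold.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        cursor = pos + int(rng.integers(config.gene_gap[0], config.gene_gap[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"simgene.{g + 1}"

        n_iso = int(
            rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1)
        )
        n_iso = min(n_iso, n_ex - 1)  # skipped internal exons must be distinct
        internal = np.arange(1, n_ex - 1)
        skips = rng.choice(internal, size=n_iso - 1, replace=False) if n_iso > 1 else []
        iso_exons: list[tuple[tuple[int, int], ...]] = [tuple(scaffold)]
        for sk in sorted(int(s) for s in skips):
            iso_exons.append(tuple(e for i, e in enumerate(scaffold) if i != sk))
        for j, exons in enumerate(iso_exons):
            transcripts.append(
                Transcript(
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    abundance=float(config.depth),
                    transcript_id=f"{gene_id}.i{j + 1}",
                    gene_id=gene_id,
                )
            )
    chrom_lengths[chrom] = cursor

    read_n = 0
    for t in transcripts:
        length = t.exonic_length
        p5 = config.truncate_5p_prob(length)
        p3 = config.truncate_3p_prob(length)
        for _ in range(config.depth):
            read_n += 1
            lose_5p = bool(rng.random() < p5)
            lose_3p = bool(rng.random() < p3)
            rs, re_ = 0, length
            if lose_5p:
                if length - MIN_READ_LENGTH >= 2:
                    rs = int(rng.integers(1, length - MIN_READ_LENGTH + 1))
                else:
                    lose_5p = False
            if lose_3p:
                if rs + MIN_READ_LENGTH < length:
                    re_ = int(rng.integers(rs + MIN_READ_LENGTH, length))
                else:
                    lose_3p = False
            # sense coordinates -> genomic-left-based coordinates
            if t.strand == "-":
                a, b = length - re_, length - rs
            else:
                a, b = rs, re_
            segments = _slice_exons(t.exons, a, b)
            if config.splice_jitter > 0 and len(segments) > 1:
                segments = _jitter_junctions(segments, rng, config.splice_jitter)
            flags = (not lose_5p, not lose_3p, not lose_3p)
            cigar = _cigar_string(segments, rng, config.indel_rate, config.max_indel_len)
            xs: str | None = t.strand
            if config.strand_tag_missing_rate > 0 and (
                rng.random() < config.strand_tag_missing_rate
            ):
                xs = None
            reads.append(
                SimRead(
                    read_id=f"read.{read_n}.{t.transcript_id}",
                    chrom=t.chrom,
                    strand=t.strand,
                    pos=segments[0][0],
                    cigar=cigar,
                    segments=segments,
                    flags=flags,
                    label=classify_flags(*flags),
                    isoform_id=t.transcript_id,
                    xs_tag=xs,
                )
            )

    return SimResult(
        config=config,
        chrom_lengths=chrom_lengths,
        transcripts=transcripts,
        reads=reads,
    )


def write_sam(result: SimResult, path) -> None:
    """Write the simulated reads as a coordinate-sorted SAM file."""
    names = sorted(result.chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": result.chrom_lengths[n]} for n in names],
    }
    order = {n: i for i, n in enumerate(names)}
    reads = sorted(result.reads, key=lambda r: (order[r.chrom], r.pos, r.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = r.read_id
            aln.reference_name = r.chrom
            aln.reference_start = r.pos
            aln.cigarstring = r.cigar
            aln.flag = 0
            aln.mapping_quality = 60
            if r.xs_tag is not None:
                aln.set_tag("XS", r.xs_tag)
            out.write(aln)


def write_classification(result: SimResult, path) -> None:
    lines = ["read_id\thas_5p\thas_3p\thas_polyA"]
    for row in result.classification_rows:
        lines.append("\t".join(map(str, row)))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_table(result: SimResult, path) -> None:
    """Per-isoform truth: enough to compute expected bundles and phasing."""
    by_iso: dict[str, list[SimRead]] = {}
    for r in result.reads:
        by_iso.setdefault(r.isoform_id, []).append(r)
    lines = [
        "transcript_id\tgene_id\tchrom\tstrand\tn_exons\texonic_length"
        "\tn_reads\tn_full_length"
    ]
    for t in result.transcripts:
        rs = by_iso.get(t.transcript_id, [])
        n_fl = sum(1 for r in rs if r.label is ReadClass.FULL_LENGTH)
        lines.append(
            f"{t.transcript_id}\t{t.gene_id}\t{t.chrom}\t{t.strand}"
            f"\t{len(t.exons)}\t{t.exonic_length}\t{len(rs)}\t{n_fl}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_genome_fasta(result: SimResult, path) -> None:
    """Random genome consistent with the chromosome lengths.

    Sequence content is drawn from a seed-derived stream independent of the
    read stream, so emitting the FASTA never perturbs the read set.
    """
    rng = np.random.default_rng([result.config.seed, 11])
    with open(path, "w") as fh:
        for name in sorted(result.chrom_lengths):
            n = result.chrom_lengths[name]
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)))
            fh.write("\n")


def write_reads_fasta(result: SimResult, path) -> None:
    """Convenience emitter of read sequences (genome slices, without indel
    perturbation) for optional runs through a real aligner."""
    rng = np.random.default_rng([result.config.seed, 11])
    seqs: dict[str, str] = {}
    for name in sorted(result.chrom_lengths):
        n = result.chrom_lengths[name]
        seqs[name] = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    comp = str.maketrans("ACGT", "TGCA")
    with open(path, "w") as fh:
        for r in result.reads:
            seq = "".join(seqs[r.chrom][s:e] for s, e in r.segments)
            if r.strand == "-":
                seq = seq.translate(comp)[::-1]
            fh.write(f">{r.read_id}\n{seq}\n")


def write_outputs(result: SimResult, outdir) -> dict[str, Path]:
    """Write genome FASTA, annotation GTF, alignments SAM, classification TSV
    and the truth table into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "alignments": outdir / "alignments.sam",
        "classification": outdir / "classification.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_genome_fasta(result, paths["genome"])
    write_gtf(result.transcripts, paths["annotation"])
    write_sam(result, paths["alignments"])
    write_classification(result, paths["classification"])
    write_truth_table(result, paths["truth"])
    return paths
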
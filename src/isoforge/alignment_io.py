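"""Ingest spliced long-read alignments and read-completeness classifications.

Long cDNA reads are classified by the presence of the 5' primer, 3' primer and
polyA tail into full-length reads (both primers + polyA: the read represents
its transcript end to end), non-full-length boundary reads (one primer: the
read anchors one transcript end) and non-full-length internal reads (neither
primer: treated like short reads downstream).

Alignments are "smoothed" before graph construction: small indels are ignored
(treated as alignment match, counting toward coverage) and only N gaps at
least ``min_intron_size`` long are kept as splice junctions, so that
indel-dominated sequencing errors do not create spurious vertices.

Coordinates are 0-based half-open throughout; conversion to 1-based inclusive
happens only at the GTF boundary.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

DEFAULT_MIN_INTRON_SIZE = 50
DEFAULT_BUNDLE_GAP = 50
DEFAULT_MIN_MAPQ = 1

FORWARD = "+"
REVERSE = "-"
UNKNOWN = "."

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_CODES = "MIDNSHP=X"


class AlignmentError(ValueError):
    """A record violates the alignment contract (e.g. CIGAR starts with N)."""


class ClassificationError(ValueError):
    """The read-classification table is malformed or self-contradictory."""


class ReadClass(enum.Enum):
    FULL_LENGTH = "full_length"
    NFL_5ONLY = "nfl_5only"
    NFL_3ONLY = "nfl_3only"
    NFL_INTERNAL = "nfl_internal"

    @property
    def has_5p_boundary(self) -> bool:
        return self in (ReadClass.FULL_LENGTH, ReadClass.NFL_5ONLY)

    @property
    def has_3p_boundary(self) -> bool:
        return self in (ReadClass.FULL_LENGTH, ReadClass.NFL_3ONLY)


def classify_flags(has_5p: bool, has_3p: bool, has_polya: bool) -> ReadClass:
    """Map primer/polyA detection flags to a read class.

    Full-length requires the 5' primer, the 3' primer and the polyA tail.
    A read with both primers but no polyA tail is treated as anchoring only
    its 5' end: without the polyA the 3' extremity is not a transcript end.
    """
    if has_5p and has_3p and has_polya:
        return ReadClass.FULL_LENGTH
    if not has_5p and not has_3p:
        return ReadClass.NFL_INTERNAL
    if has_5p and not has_3p:
        return ReadClass.NFL_5ONLY
    if has_3p and not has_5p:
        return ReadClass.NFL_3ONLY
    # both primers, no polyA
    return ReadClass.NFL_5ONLY


@dataclass(frozen=True)
class AlignmentRecord:
    """One long read's smoothed, spliced placement on the genome.

    ``segments`` are the post-smoothing aligned blocks (sorted, disjoint,
    separated by gaps of at least the intron minimum). ``strand`` is the
    transcript strand, '.' when the aligner left it undetermined.
    """

    read_id: str
    chrom: str
    strand: str
    segments: tuple[tuple[int, int], ...]
    read_class: ReadClass

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) pairs: the half-open intron intervals."""
        return tuple(
            (self.segments[i][1], self.segments[i + 1][0])
            for i in range(len(self.segments) - 1)
        )

    @property
    def is_spliced(self) -> bool:
        return len(self.segments) > 1

    @property
    def boundary_5p(self) -> int | None:
        """Transcript-start-side terminal coordinate, if this read anchors it.

        On the forward strand the 5' end is the leftmost aligned coordinate;
        on the reverse strand it is the rightmost.
        """
        if not self.read_class.has_5p_boundary:
            return None
        return self.end if self.strand == REVERSE else self.start

    @property
    def boundary_3p(self) -> int | None:
        if not self.read_class.has_3p_boundary:
            return None
        return self.start if self.strand == REVERSE else self.end


@dataclass(frozen=True)
class Bundle:
    """A maximal chained cluster of alignments on one chromosome strand."""

    chrom: str
    strand: str
    span: tuple[int, int]
    records: tuple[AlignmentRecord, ...]


def parse_classification(source) -> dict[str, ReadClass]:
    """Read the classification TSV (read_id, has_5p, has_3p, has_polyA).

    Duplicate read ids are allowed only when their flags agree; a conflict is
    a hard error naming the read.
    """
    table = pd.read_csv(source, sep="\t", dtype={"read_id": str})
    required = ["read_id", "has_5p", "has_3p", "has_polyA"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ClassificationError(
            f"classification table missing column(s): {', '.join(missing)}"
        )
    classes: dict[str, ReadClass] = {}
    for row in table.itertuples(index=False):
        label = classify_flags(bool(row.has_5p), bool(row.has_3p), bool(row.has_polyA))
        prev = classes.get(row.read_id)
        if prev is not None and prev is not label:
            raise ClassificationError(
                f"conflicting classification for read {row.read_id!r}: "
                f"{prev.value} vs {label.value}"
            )
        classes[row.read_id] = label
    return classes


def _normalize_cigar(cigar) -> list[tuple[str, int]]:
    if isinstance(cigar, str):
        ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]
        if not ops or sum(n for _, n in ops) == 0:
            raise AlignmentError(f"unparseable CIGAR string {cigar!r}")
        return ops
    out = []
    for code, length in cigar:
        if isinstance(code, int):
            code = _CIGAR_CODES[code]
        out.append((code, int(length)))
    return out


def smooth_alignment(
    cigar, ref_start: int, min_intron_size: int = DEFAULT_MIN_INTRON_SIZE
) -> tuple[tuple[int, int], ...]:
    """Turn a CIGAR into indel-smoothed aligned segments.

    Match/mismatch ops extend the current segment. Insertions consume no
    reference and are dropped. Deletions of any length are merged into the
    current segment (counting toward coverage) — spurious junctions from long
    error deletions are instead filtered by the intron minimum: an N op
    shorter than ``min_intron_size`` is merged exactly like a deletion, and
    only N ops at least that long end one segment and open the next.

    Accepts a CIGAR string, pysam ``cigartuples`` or (op-letter, length)
    pairs. Raises :class:`AlignmentError` for a CIGAR whose reference walk
    begins or ends with a kept N, or that would produce an empty segment.
    """
    if min_intron_size < 1:
        raise ValueError("min_intron_size must be >= 1")
    ops = _normalize_cigar(cigar)
    core = [(c, n) for c, n in ops if c in "MDN=X" and n > 0]
    if not core:
        raise AlignmentError("CIGAR consumes no reference bases")
    segments: list[tuple[int, int]] = []
    pos = ref_start
    seg_start = ref_start
    for code, length in core:
        if code == "N" and length >= min_intron_size:
            if pos == seg_start:
                raise AlignmentError(
                    "CIGAR yields a zero-length segment (leading/adjacent N ops)"
                )
            segments.append((seg_start, pos))
            pos += length
            seg_start = pos
        else:
            pos += length
    if pos == seg_start:
        raise AlignmentError("CIGAR ends with an intron (trailing N)")
    segments.append((seg_start, pos))
    return tuple(segments)


def resolve_strand(aln: pysam.AlignedSegment) -> str:
    """Deduce the transcript strand from aligner tags.

    XS carries the strand directly; minimap2's ts tag is relative to the read
    orientation. Absent/ambiguous tags yield '.', a valid outcome — such
    spliced records are later placed in both strand bundles ("attempts both
    strands") rather than discarded.
    """
    if aln.has_tag("XS"):
        xs = aln.get_tag("XS")
        if xs in (FORWARD, REVERSE):
            return xs
    if aln.has_tag("ts"):
        ts = aln.get_tag("ts")
        read_strand = REVERSE if aln.is_reverse else FORWARD
        if ts == "+":
            return read_strand
        if ts == "-":
            return REVERSE if read_strand == FORWARD else FORWARD
    return UNKNOWN


def load_alignments(
    path,
    classes: Mapping[str, ReadClass],
    *,
    min_intron_size: int = DEFAULT_MIN_INTRON_SIZE,
    min_mapping_quality: int = DEFAULT_MIN_MAPQ,
) -> list[AlignmentRecord]:
    """Parse a SAM/BAM file into smoothed alignment records.

    Only primary alignments are used (one phasing path per molecule);
    unmapped, secondary, supplementary and low-MAPQ records are skipped.
    Reads absent from ``classes`` default to non-full-length internal.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapping_quality:
                continue
            if not aln.cigartuples:
                continue
            try:
                segments = smooth_alignment(
                    aln.cigartuples, aln.reference_start, min_intron_size
                )
            except AlignmentError as exc:
                log.warning("skipping read %s: %s", aln.query_name, exc)
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    strand=resolve_strand(aln),
                    segments=segments,
                    read_class=classes.get(aln.query_name, ReadClass.NFL_INTERNAL),
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.read_id))
    return records


def make_bundles(
    records: Sequence[AlignmentRecord], bundle_gap: int = DEFAULT_BUNDLE_GAP
) -> list[Bundle]:
    """Group records into per-(chrom, strand) single-linkage bundles.

    A record joins the open bundle iff its start lies within ``bundle_gap``
    of the bundle's current end. Records with unknown transcript strand are
    copied into both strands' bundles.
    """
    if bundle_gap < 0:
        raise ValueError("bundle_gap must be >= 0")
    by_key: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in records:
        if rec.strand == UNKNOWN:
            targets = (FORWARD, REVERSE)
        else:
            targets = (rec.strand,)
        for strand in targets:
            stranded = rec if rec.strand == strand else replace(rec, strand=strand)
            by_key.setdefault((rec.chrom, strand), []).append(stranded)

    bundles: list[Bundle] = []
    for (chrom, strand) in sorted(by_key):
        group = sorted(by_key[(chrom, strand)], key=lambda r: (r.start, r.end, r.read_id))
        open_recs: list[AlignmentRecord] = []
        open_end = None
        for rec in group:
            if open_recs and rec.start >= open_end + bundle_gap:
                bundles.append(_close_bundle(chrom, strand, open_recs))
                open_recs = []
                open_end = None
            open_recs.append(rec)
            open_end = rec.end if open_end is None else max(open_end, rec.end)
        if open_recs:
            bundles.append(_close_bundle(chrom, strand, open_recs))
    bundles.sort(key=lambda b: (b.chrom, b.span, b.strand))
    return bundles


def _close_bundle(chrom: str, strand: str, recs: list[AlignmentRecord]) -> Bundle:
    start = min(r.start for r in recs)
    end = max(r.end for r in recs)
    return Bundle(chrom=chrom, strand=strand, span=(start, end), records=tuple(recs))


_HEADER_FLAG_RE = re.compile(r"(fiveseen|threeseen|polyAseen)=(\d)")


def headers_to_classification(headers: Iterable[str]) -> pd.DataFrame:
    """Convenience converter from Iso-Seq-style FASTA headers to the TSV schema.

    Recognises ``fiveseen=``/``threeseen=``/``polyAseen=`` key-value pairs in
    each header. This is a convenience, not a contract: the supported input
    format for classification is the four-column TSV.
    """
    rows = []
    for header in headers:
        header = header.lstrip(">").strip()
        read_id = header.split()[0]
        flags = dict(_HEADER_FLAG_RE.findall(header))
        rows.append(
            {
                "read_id": read_id,
                "has_5p": int(flags.get("fiveseen", "0")),
                "has_3p": int(flags.get("threeseen", "0")),
                "has_polyA": int(flags.get("polyAseen", "0")),
            }
        )
    return pd.DataFrame(rows, columns=["read_id", "has_5p", "has_3p", "has_polyA"])
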
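"""GTF input/output for transcripts.

GTF2.2 is the single interchange dialect: one ``transcript`` line followed by
one ``exon`` line per exon, 1-based inclusive coordinates, attributes
``gene_id``, ``transcript_id`` and ``cov`` (predicted abundance, four decimal
places). Output ordering is deterministic by (chrom, start, transcript_id).
Reading is gzip-transparent and tolerates both quoted and unquoted attribute
values.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Sequence

from .clustering import Transcript

log = logging.getLogger(__name__)

SOURCE_TAG = "isoforge"

_ATTR_RE = re.compile(r'(\w+)\s+"?([^";]+)"?\s*;?')


class GtfFormatError(ValueError):
    pass


def _sorted(transcripts: Sequence[Transcript]) -> list[Transcript]:
    return sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))


def format_gtf(transcripts: Sequence[Transcript]) -> str:
    lines: list[str] = []
    for t in _sorted(transcripts):
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'cov "{t.abundance:.4f}";'
        )
        lines.append(
            "\t".join(
                [
                    t.chrom,
                    SOURCE_TAG,
                    "transcript",
                    str(t.start + 1),
                    str(t.end),
                    ".",
                    t.strand,
                    ".",
                    attrs,
                ]
            )
        )
        for k, (s, e) in enumerate(t.exons, start=1):
            lines.append(
                "\t".join(
                    [
                        t.chrom,
                        SOURCE_TAG,
                        "exon",
                        str(s + 1),
                        str(e),
                        ".",
                        t.strand,
                        ".",
                        attrs + f' exon_number "{k}";',
                    ]
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


def write_gtf(transcripts: Sequence[Transcript], destination) -> None:
    """Write transcripts as GTF (path or text file handle)."""
    text = format_gtf(transcripts)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def _open_text(source):
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gtf(source) -> list[Transcript]:
    """Read exon features grouped by transcript_id into Transcript objects.

    Coordinates are converted to the internal 0-based half-open convention.
    Transcripts that have no exon features are skipped with a warning.
    Raises :class:`GtfFormatError` on malformed lines, naming the line
    number.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    seen_transcript_ids: set[str] = set()

    if hasattr(source, "read"):
        fh = source
        close = False
    else:
        fh = _open_text(source)
        close = True
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfFormatError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            attributes = dict(_ATTR_RE.findall(attrs))
            tid = attributes.get("transcript_id")
            if tid is None:
                continue
            seen_transcript_ids.add(tid)
            if feature != "exon":
                if tid not in meta:
                    meta[tid] = _meta(chrom, strand, attributes)
                continue
            try:
                interval = (int(start) - 1, int(end))
            except ValueError as exc:
                raise GtfFormatError(f"line {lineno}: bad coordinates") from exc
            exons.setdefault(tid, []).append(interval)
            if tid not in meta:
                meta[tid] = _meta(chrom, strand, attributes)
    finally:
        if close:
            fh.close()

    for tid in seen_transcript_ids - exons.keys():
        log.warning("transcript %s has no exon features; skipped", tid)

    transcripts = []
    for tid, ivals in exons.items():
        m = meta[tid]
        transcripts.append(
            Transcript(
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(sorted(ivals)),
                abundance=m["cov"],
                transcript_id=tid,
                gene_id=m["gene_id"],
            )
        )
    return _sorted(transcripts)


def _meta(chrom: str, strand: str, attributes: dict) -> dict:
    cov = attributes.get("cov", attributes.get("coverage", "0"))
    try:
        cov = float(cov)
    except ValueError:
        cov = 0.0
    return {
        "chrom": chrom,
        "strand": strand,
        "gene_id": attributes.get("gene_id", "unknown"),
        "cov": cov,
    }
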
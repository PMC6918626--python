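"""Score predicted transcripts against a reference annotation.

A correctly predicted known transcript has an exact intron-chain match with a
reference transcript: identical ordered junction coordinates on the same
chromosome and strand, with the outer boundaries of the end exons ignored.
Sensitivity is the fraction of (multi-exon) reference transcripts matched by
at least one prediction; precision the fraction of (multi-exon) predictions
matching at least one reference. Sweeping an abundance threshold over the
predictions produces a precision-recall curve whose area (PR-AUC) summarises
overall performance.

Base-level fraction metrics complement intron-chain matching: the matched
fraction of a prediction is the best share of its exonic bases covered by a
single reference transcript, the assembled fraction of a reference the best
share of its exonic bases covered by a single prediction; both are binned
into 0-50 / 50-75 / 75-95 / 95-100 percent ranges. Single-exon transcripts
are excluded from intron-chain metrics (the chain is empty) but participate
in the fraction metrics.

Predictions that share at least one junction with the reference without a
full chain match are counted as potential novel isoforms and subclassified:
novel-in-catalog (NIC) when every novel junction reuses annotated donors and
acceptors (including new combinations of entirely known junctions),
novel-not-in-catalog (NNC) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import Transcript

FRACTION_BINS = ("0-50", "50-75", "75-95", "95-100")


@dataclass
class EvalReport:
    n_reference_known: int
    n_predicted: int
    n_correct: int  # reference transcripts matched by >=1 prediction
    n_predicted_correct: int  # predictions matching >=1 reference
    sensitivity: float
    precision: float
    pr_auc: float
    matched_fraction_bins: dict[str, int]
    assembled_fraction_bins: dict[str, int]
    n_potential_novel: int = 0
    n_nic: int = 0
    n_nnc: int = 0

    def to_dict(self) -> dict:
        return {
            "n_reference_known": self.n_reference_known,
            "n_predicted": self.n_predicted,
            "n_correct": self.n_correct,
            "n_predicted_correct": self.n_predicted_correct,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "pr_auc": self.pr_auc,
            "matched_fraction_bins": dict(self.matched_fraction_bins),
            "assembled_fraction_bins": dict(self.assembled_fraction_bins),
            "n_potential_novel": self.n_potential_novel,
            "n_nic": self.n_nic,
            "n_nnc": self.n_nnc,
        }

    def to_tsv(self) -> str:
        d = self.to_dict()
        rows = [
            (k, v) for k, v in d.items() if not isinstance(v, dict)
        ]
        for name in ("matched_fraction_bins", "assembled_fraction_bins"):
            for b, n in d[name].items():
                rows.append((f"{name}[{b}%]", n))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def _chain_key(t: Transcript) -> tuple:
    return (t.chrom, t.strand, t.junctions)


def intron_chain_match(pred: Transcript, ref: Transcript) -> bool:
    """Exact intron-chain equality; end-exon outer boundaries are ignored."""
    if len(pred.exons) < 2 or len(ref.exons) < 2:
        raise ValueError("intron-chain matching requires multi-exon transcripts")
    return _chain_key(pred) == _chain_key(ref)


def _multi(ts: Sequence[Transcript]) -> list[Transcript]:
    return [t for t in ts if len(t.exons) > 1]


def _match_counts(
    preds: Sequence[Transcript], refs: Sequence[Transcript]
) -> tuple[int, int]:
    """(#refs matched by >=1 pred, #preds matching >=1 ref); multi-exon only."""
    ref_chains = {_chain_key(t) for t in refs}
    pred_chains = {_chain_key(t) for t in preds}
    n_ref_matched = sum(1 for t in refs if _chain_key(t) in pred_chains)
    n_pred_correct = sum(1 for t in preds if _chain_key(t) in ref_chains)
    return n_ref_matched, n_pred_correct


def sensitivity_precision(
    preds: Sequence[Transcript], refs: Sequence[Transcript]
) -> tuple[float, float]:
    mp, mr = _multi(preds), _multi(refs)
    n_correct, n_pred_correct = _match_counts(mp, mr)
    sens = n_correct / len(mr) if mr else 0.0
    prec = n_pred_correct / len(mp) if mp else 0.0
    return sens, prec


def pr_auc(preds: Sequence[Transcript], refs: Sequence[Transcript]) -> float:
    """Area under the precision-recall curve from an abundance sweep.

    Thresholds are the distinct prediction abundances in descending order;
    at each, predictions at or above the threshold are scored. Integration
    is trapezoidal over sensitivity, anchored by a rectangle from zero
    sensitivity at the most stringent threshold's precision — so a curve
    with a single point (s, p) has area p·s.
    """
    mp, mr = _multi(preds), _multi(refs)
    if not mp or not mr:
        return 0.0
    thresholds = sorted({t.abundance for t in mp}, reverse=True)
    points: list[tuple[float, float]] = []
    for thr in thresholds:
        kept = [t for t in mp if t.abundance >= thr]
        n_correct, n_pred_correct = _match_counts(kept, mr)
        points.append((n_correct / len(mr), n_pred_correct / len(kept)))
    points.sort(key=lambda p: p[0])
    points.insert(0, (0.0, points[0][1]))
    auc = 0.0
    for (s0, p0), (s1, p1) in zip(points, points[1:]):
        auc += (s1 - s0) * (p0 + p1) / 2.0
    return float(auc)


def _shared_exonic_bases(a: Transcript, b: Transcript) -> int:
    if a.chrom != b.chrom:
        return 0
    shared = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            shared += max(0, min(e1, e2) - max(s1, s2))
    return shared


def matched_fraction(pred: Transcript, refs: Sequence[Transcript]) -> float:
    """Best share of the prediction's exonic bases covered by one reference."""
    if not refs:
        return 0.0
    return max(_shared_exonic_bases(pred, r) for r in refs) / pred.exonic_length


def assembled_fraction(ref: Transcript, preds: Sequence[Transcript]) -> float:
    """Best share of the reference's exonic bases covered by one prediction."""
    if not preds:
        return 0.0
    return max(_shared_exonic_bases(ref, p) for p in preds) / ref.exonic_length


def bin_fraction(f: float) -> str:
    """Bin boundaries are left-closed, right-open; 95-100% includes 100%."""
    if f < 0.5:
        return "0-50"
    if f < 0.75:
        return "50-75"
    if f < 0.95:
        return "75-95"
    return "95-100"


def _novel_counts(
    preds: Sequence[Transcript], refs: Sequence[Transcript]
) -> tuple[int, int, int]:
    ref_chains = {_chain_key(t) for t in refs}
    junctions_by_key: dict[tuple, set] = {}
    donors_by_key: dict[tuple, set] = {}
    acceptors_by_key: dict[tuple, set] = {}
    for t in refs:
        key = (t.chrom, t.strand)
        junctions_by_key.setdefault(key, set()).update(t.junctions)
        donors_by_key.setdefault(key, set()).update(d for d, _ in t.junctions)
        acceptors_by_key.setdefault(key, set()).update(a for _, a in t.junctions)
    n_novel = n_nic = n_nnc = 0
    for t in preds:
        if _chain_key(t) in ref_chains:
            continue
        key = (t.chrom, t.strand)
        known = junctions_by_key.get(key, set())
        if not any(j in known for j in t.junctions):
            continue
        n_novel += 1
        novel_j = [j for j in t.junctions if j not in known]
        donors = donors_by_key.get(key, set())
        acceptors = acceptors_by_key.get(key, set())
        if all(d in donors and a in acceptors for d, a in novel_j):
            n_nic += 1
        else:
            n_nnc += 1
    return n_novel, n_nic, n_nnc


def evaluate(preds: Sequence[Transcript], refs: Sequence[Transcript]) -> EvalReport:
    """Full report: intron-chain metrics, PR-AUC, fraction bins, novel counts."""
    mp, mr = _multi(preds), _multi(refs)
    n_correct, n_pred_correct = _match_counts(mp, mr)
    matched_bins = {b: 0 for b in FRACTION_BINS}
    for t in preds:
        matched_bins[bin_fraction(matched_fraction(t, refs))] += 1
    assembled_bins = {b: 0 for b in FRACTION_BINS}
    for t in refs:
        assembled_bins[bin_fraction(assembled_fraction(t, preds))] += 1
    n_novel, n_nic, n_nnc = _novel_counts(mp, mr)
    return EvalReport(
        n_reference_known=len(mr),
        n_predicted=len(mp),
        n_correct=n_correct,
        n_predicted_correct=n_pred_correct,
        sensitivity=n_correct / len(mr) if mr else 0.0,
        precision=n_pred_correct / len(mp) if mp else 0.0,
        pr_auc=pr_auc(preds, refs),
        matched_fraction_bins=matched_bins,
        assembled_fraction_bins=assembled_bins,
        n_potential_novel=n_novel,
        n_nic=n_nic,
        n_nnc=n_nnc,
    )
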
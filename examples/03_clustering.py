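"""Collapse nearly redundant transcripts whose splice sites wobble slightly.

Builds five jittered copies of one three-exon transcript (each junction side
shifted by <=2 bp, so per-junction differences stay within the default 10 bp
allowance) and clusters them.
"""

import numpy as np

from isoforge import Transcript, cluster, similar

rng = np.random.default_rng(0)
base = [(1000, 1100), (1300, 1400), (1600, 1700)]
copies = []
for c in range(5):
    exons = [list(e) for e in base]
    for i in range(len(exons) - 1):
        exons[i][1] += int(rng.integers(-2, 3))
        exons[i + 1][0] += int(rng.integers(-2, 3))
    copies.append(
        Transcript(
            chrom="chr1",
            strand="+",
            exons=tuple(tuple(e) for e in exons),
            abundance=float(c + 1),
            transcript_id=f"t{c}",
            gene_id="g",
        )
    )

for t in copies:
    print(f"{t.transcript_id}: junctions {t.junctions} abundance {t.abundance:.0f}")
print("t0 ~ t1 within 10 bp allowance:", similar(copies[0], copies[1], 10))

merged = cluster(copies, allowance=10)
rep = merged[0]
print(f"\nclustered into {len(merged)} transcript(s)")
print(f"consensus {rep.transcript_id}: junctions {rep.junctions}")
print(f"summed abundance {rep.abundance:.0f}, span {rep.start}-{rep.end}")

# The consensus keeps the junction chain of the highest-abundance member,
# sums the cluster's read support, and its end exons span every member.
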
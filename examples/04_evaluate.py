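"""Score an assembly against its truth annotation.

Simulates a dataset with the default truncation and error model, assembles
it, and prints the intron-chain metrics and base-fraction histograms.
"""

import tempfile
from pathlib import Path

from isoforge import RunConfig, assemble, evaluate, read_gtf
from isoforge.synthetic import SimConfig, simulate, write_outputs

with tempfile.TemporaryDirectory() as tmp:
    paths = write_outputs(simulate(SimConfig(seed=4, n_genes=15)), Path(tmp) / "sim")
    out = Path(tmp) / "assembly.gtf"
    assemble(paths["alignments"], paths["classification"], out, RunConfig())
    report = evaluate(read_gtf(out), read_gtf(paths["annotation"]))

print(report.to_tsv())

# sensitivity = correctly recovered known intron chains / known multi-exon
# transcripts; precision = predictions with an exact reference chain match /
# all multi-exon predictions; pr_auc sweeps an abundance threshold over the
# predictions. The fraction bins count transcripts by the share of exonic
# bases matching (predictions) or covered by (references) a single partner.
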
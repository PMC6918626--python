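# Methods

## Problem setting

Single-molecule cDNA sequencing yields reads long enough to span most or all
of a transcript, but two artifacts complicate assembly: (i) incomplete cDNA
synthesis truncates molecules, so a read may miss the 5' and/or 3' end of
its transcript — increasingly likely for long transcripts — and (ii) errors
are dominated by insertions and deletions, which corrupt alignments and can
masquerade as splice junctions. The package assembles transcripts from
spliced alignments of such reads against a reference genome, using the read
completeness classification (5' primer / 3' primer / polyA detection) as an
additional signal.

## Read classes and coordinates

A read with 5' primer, 3' primer and polyA tail is *full-length*; with
exactly one primer it is a *non-full-length boundary read* anchoring that
end; with neither primer it is *internal* and is treated like a short read
(no boundary information). A read with both primers but no polyA is treated
as anchoring only its 5' end: a 3' extremity without polyA is not evidence
of a transcript end. All internal coordinates are 0-based half-open;
conversion to GTF's 1-based inclusive convention happens only at the file
boundary. On the reverse strand the 5' end of a read is its *rightmost*
aligned coordinate.

## Alignment smoothing

Insertions are dropped (they consume no reference); deletions of any length
are merged into the surrounding match, counting toward coverage. Deletions
are not a trusted junction signal — aligners emit introns as `N` — and
error-induced long deletions that aligners do mark as `N` are removed by the
minimum intron size: `N` ops shorter than `min_intron_size` (default 50 bp)
are merged like deletions, and only longer ones survive as junctions.
Records whose reference walk would begin or end with a kept intron, or that
would produce an empty segment, are rejected with a warning. Only primary
alignments with mapping quality ≥ 1 are used: one molecule, one phasing
path.

## Loci, boundaries and the splice graph

Records are chained into per-(chromosome, strand) bundles by single linkage
with `bundle_gap` (default 50 bp; the value is not critical as long as it is
small relative to intergenic gaps, and it is exposed as a flag). Spliced and
unspliced records without strand information are copied into both strands'
bundles rather than discarded.

Within a bundle, all splice positions and boundary-read end positions are
sorted together (splice before boundary at equal coordinates, so a
coinciding splice site always interrupts a boundary run). A maximal run of
same-type boundary positions — not separated by a splice position or a
different-type boundary, consecutive members within `boundary_allowance`
(default 10 bp, mirroring the clustering allowance; the two published
phrasings of the run condition are reconciled by requiring both) — of size
≥ `min_boundary_reads` (default 3) yields one boundary call: the leftmost
member for 5' runs and the rightmost for 3' runs on the forward strand,
mirrored on the reverse.

The covered genome is partitioned into partial exons at every splice
position, every called boundary position and every zero-coverage gap; a
boundary call landing inside an exonic region therefore splits the vertex
at the call position. Vertex weight is mean per-base coverage; junction
edges carry supporting-read counts; genomically abutting vertices crossed
contiguously by at least one read get adjacency edges weighted by the
crossing count. Boundary calls are wired to the virtual source/target with
their support as weight; vertices left without incoming or outgoing edges
get source/target links weighted by their coverage so the graph always
decomposes into s–t paths. The graph is stored in genomic order with a
strand flag; on the reverse strand the source side is the genomic right
(the transcript start), handled by the boundary wiring rather than by
reversing coordinates.

Each read is projected onto the ordered chain of vertices it overlaps;
consecutive chain members must be joined by the read's own junction or
crossed contiguously within one segment, and interior chain members must be
fully spanned (terminal vertices may be partially covered — truncated reads
still phase interior exons). Chains of ≥ 3 vertices become phasing paths;
identical chains merge with summed support, and shorter chains are kept as
separate constraints rather than absorbed into longer ones.

## Decomposition

Three objectives in priority order: preserve every phasing path, fit edge
weights, emit few paths. The realisation is seed / fit / peel:

* **Seed**: each maximal phasing path is extended to an s–t path by greedy
  steps that follow the heaviest incident edge not contradicting any
  phasing path through the frontier vertex (ties to the lower vertex
  index). When a bundle has no phasing path at all, a single
  maximum-bottleneck s–t path is seeded.
* **Fit**: `min Σ_e |w_e − Σ_{p ∋ e} x_p|` over `x ≥ 0` as a linear program
  (absolute values split into slack variables; HiGHS, deterministic). All
  edges participate, including source/sink links, which makes single-exon
  loci fittable.
* **Peel**: while some edge has positive residual ≥ `peel_floor` (default
  1.0 — one read of unexplained support), add the maximum-bottleneck s–t
  path through the largest-residual edge and re-fit; the iteration count is
  capped by the edge count and stops early when the chosen path already
  exists.

Candidates below `min_transcript_coverage` (default 1.0) are dropped unless
that would leave a phasing path uncovered, in which case the
highest-abundance covering candidate is retained; abundances are re-fit
once on the surviving set. When deviation and path count conflict, the
ordering is preserve > fit > fewer; minimal path count is not guaranteed
(the exact problem is NP-hard) — only the heuristic bound of one path per
maximal phasing path plus at most one per peel iteration.

## Clustering

Two multi-exon transcripts on the same chromosome and strand with equal
junction counts are similar when every junction's |Δdonor| + |Δacceptor| is
≤ `max_cluster_intron_distance` (default 10 bp; the boundary-inclusive
reading of the allowance is used, so a summed difference of exactly 10
clusters). Connected components of the similarity graph (single linkage)
are merged into their highest-abundance member — ties broken by longer
span, then leftmost, then lexicographic id — with summed abundance and end
exons extended to the cluster's extremes. Single-exon transcripts are
exempt: the predicate is defined on splice positions. The implementation
buckets by (chromosome, strand, junction count) with a first-donor window
prefilter; semantics equal all-pairs comparison.

## Evaluation

A prediction correctly recovers a known transcript when its intron chain
(ordered donor/acceptor coordinates) equals a reference transcript's
exactly, end-exon outer boundaries ignored. Sensitivity = matched
references / multi-exon references (each reference counted once however
many predictions match it); precision = chain-matching predictions /
multi-exon predictions. The PR curve sweeps the distinct prediction
abundances descending; the area is trapezoidal over sensitivity, anchored
by a rectangle at the most stringent threshold's precision (a single point
(s, p) gives area p·s). Base-fraction metrics use the best single-partner
exonic overlap on the same chromosome and are binned 0–50 / 50–75 / 75–95 /
95–100 % (left-closed, 100 % included in the last bin); single-exon
transcripts participate here but not in chain metrics. Predictions sharing
≥ 1 junction with the reference without a full match are potential novel
isoforms, split into NIC (all novel junctions reuse annotated donors and
acceptors, including new combinations of known junctions) and NNC
(otherwise).

## Synthetic data

The generator emulates the long-read data model without requiring any
external tool: non-overlapping multi-exon genes (4–8 exons of 80–300 bp,
introns 60–400 bp) whose isoforms are exon-skipping variants of a shared
scaffold — every isoform shares junctions with its gene's scaffold, forcing
branching splice graphs; reads are complete transcript copies truncated at
a uniform breakpoint from the 5' and/or 3' end with length-dependent
probabilities. The default truncation model is logistic in transcript
length with midpoint 2.5 kb (the length beyond which full-length reads
become unlikely), scale 300 bp, and ceilings 0.6 (5' loss, the dominant
mode under reverse transcription from the polyA end) and 0.3 (3' loss).
Labels follow directly: no truncation → full-length, 3' lost → 5'-only,
5' lost → 3'-only, both → internal. Indels are injected into CIGARs at 1 %
per exonic base (length ≤ 3), always inside exons so reference spans and
junction coordinates stay exact; an optional `splice_jitter` shifts
junction sides by up to 3 bp per read to emulate misalignment around splice
sites, which is the mechanism that produces the nearly redundant
transcripts clustering removes. It is off by default so exact junction
recovery can be asserted against the truth.

What the generator does **not** emulate: substitution errors and sequence
content of reads (alignments are emitted directly as SAM), soft-clipping,
mapping ambiguity/multi-mappers, strand-inference failure (optional via
`strand_tag_missing_rate`), expression variation between isoforms, or
splice-site wobble beyond ±3 bp. Passing tests on this generator
demonstrate the algorithmic contracts — boundary inference, phasing
preservation, abundance fitting, clustering semantics — not robustness to
every artifact of real aligner output. Everything is a deterministic
function of the seed; the genome sequence stream is separate from the read
stream so emitting FASTA never perturbs the reads.

## Numerical and design choices

* LP ties are resolved by the deterministic solver configuration; all
  combinatorial ties break toward the lower vertex index, then
  lexicographic path order — identical inputs give byte-identical GTF.
* The L1 objective (pure linear program) is used rather than least squares.
* Problem sizes in the test and acceptance runs (20 genes × 2–3 isoforms at
  depth 5; 200 planted graphs with ≤ 7 vertices) were chosen as the
  smallest sizes at which every contract is exercised with clear margins;
  the pipeline itself streams bundle by bundle and scales to full datasets.
* Degenerate inputs: empty alignment files produce an empty GTF with a
  warning; zero-coverage loci cannot arise (bundles are built from reads);
  an all-candidates-dropped locus yields no transcripts.

## Known limitations

* The decomposition realises the stated objectives by seed/LP/peel rather
  than by iterative vertex splitting; outputs satisfying the same contract
  may differ path-by-path from other implementations of the same
  objectives.
* Strand-unknown reads placed on both strands can yield mirrored duplicate
  transcripts on loci with no stranded evidence.
* Abundances are raw read-support estimates; no library-size or length
  normalisation is applied.
* End-exon extension during clustering can in principle overlap the
  consensus's neighbouring exon if members' spans differ by more than an
  intron; with the default 10 bp allowance this does not occur.
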
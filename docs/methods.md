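# Methods

## Problem and model

A stringently assembled heterozygous diploid genome yields two kinds of
contigs: *homotigs*, assembled from sequence identical between the two
haplotypes (their read pileups mix both haplotypes, so they sit at diploid
sequencing depth), and *heterotigs*, assembled from sequence unique to one
haplotype (haploid depth). Under three working assumptions — no large-scale
rearrangements or inversions between haplotypes, exactly one homologous
partner per heterotig (a *homolotig pair*), and every homolotig pair
embedded in a heterozygous *bubble* (flanked by a common homotig on each
side) — the scaffolding problem becomes: elucidate, from a noisy bidirected
scaffold graph, an alternating pattern of single homotigs and homolotig
pairs, then split each pair onto its two haplotypes.

The pipeline:

1. **Scaffold graph.** Each contig contributes two vertices' worth of
   attachment points (its 5' and 3' ends). A uniquely mapped innie read
   pair whose ends hit two different contigs nominates one end per contig
   (forward-strand hit → 3' end, reverse → 5' end) and suggests a gap of
   `insert − tail₁ − tail₂`, where a tail runs from the alignment's outer
   read edge to the nominated contig end. Edges are identified by their
   unordered pair of contig ends (so they fix the relative orientation of
   both contigs); weight = number of supporting pairs; gap estimate =
   arithmetic mean of the per-pair suggestions (negative gaps, i.e.
   overlaps, are retained). Every input pair receives exactly one
   PairStatus record, so edge weights plus non-link statuses account for
   every pair. Edges below a minimum support (default 2) are treated as
   nonexistent everywhere except DOT rendering of excluded edges.

2. **Repeat flagging.** Contigs with total degree above `degree_factor`
   (default 5) times the median degree, or depth above `depth_factor`
   times the modal depth, are excluded from bubbles, chains and output.
   `depth_factor` defaults to 3: the modal contig depth is typically the
   *haploid* depth (heterotigs outnumber homotigs roughly two to one in a
   bubble-rich assembly), so a factor of 2 would sit exactly on the
   ordinary diploid-depth homotig; 3 targets genuinely collapsed repeats.
   Both factors are configurable; statistics are computed over contigs of
   ≥ 100 bp.

3. **Perfect bubbles.** A perfect bubble is a 4-tuple (c₁) = a|b = (c₂)
   where each heterotig end carries exactly one edge (to the appropriate
   flank), both flank attachments use a single flank end carrying exactly
   those two edges, and the four contigs are distinct. Two perfect bubbles
   may share a flank (consecutive bubbles in a chain) but can never share
   a heterotig. The finder is checked against a literal brute-force
   4-tuple scan in the test suite.

4. **Homolog classification.** Pairs found in perfect bubbles are assumed
   to be true homolotig pairs and become positive training examples; the
   negatives are seeded random contig pairs sharing no graph edge (1:1 by
   default). The six features: length ratio (min/max), depth ratio
   (min/max), percent identical matches and percent length-alignment of
   the best local alignment, and each contig's depth relative to the modal
   depth. Without a depth table the three depth features are dropped
   (reduced-feature mode). The learner is pluggable — logistic regression
   by default (deterministic, well-calibrated at this separability), a
   multilayer perceptron and an SVM behind tags — always behind a feature
   scaler, with probability output thresholded at 0.5 (≥ counts positive).
   Local alignment is an in-package Smith–Waterman–Gotoh (match +2,
   mismatch −3, gap open −5, extend −2, a k-gap costing open+(k−1)·extend),
   numba-compiled, with fully specified tie-breaks (diagonal over vertical
   over horizontal; gap opening over extension on ties; first-maximum
   start cell in row-major order) so results are deterministic and can be
   checked exactly against an independent plain-Python reference.
   Alignments scoring below 20 report (0, 0).

5. **Imperfect bubbles and acceptance.** Candidate bubbles with missing or
   conflicting edges are seeded from every contig end carrying ≥ 2 edges
   (a shared flank), completed through the heterotigs' far ends, and
   ranked by a lexicographic perfectness score: fewer missing edges, then
   fewer conflicting edges, then higher total support, with a contig-id
   tie-break. One-flank (3-edge or 2-edge) candidates are admitted behind
   a flag (on by default). Candidates classified positive are accepted in
   rank order under the conflict rule: a bubble is disallowed if any of
   its edges is already included or touches an already-occupied contig
   end. Acceptance claims all four heterotig ends (even a missing-edge
   side), which keeps partial bubbles linear, and rejects any bubble that
   would connect two already-connected components (a union-find over
   slots, with an accepted pair as one slot, keeps the included subgraph
   an acyclic disjoint union of paths — a requirement for emitting linear
   scaffolds that the occupancy rule alone does not impose).

6. **Greedy linking by rank.** Remaining edges of the current rank's
   libraries are considered in descending weight (ties: lexicographically
   smaller edge key) and included iff both ends are free and no cycle
   forms. Rank 1 (the small-insert library) does bubbles + linking; every
   later rank only links existing chains and scaffolds into larger chains.
   Occupancy persists across ranks: once an end is used it stays used.

7. **Phasing.** Within each chain, read pairs (from all libraries) whose
   two uniquely mapped ends lie in heterotigs of two different accepted
   bubbles vote for placing those heterotigs on the same haplotype.
   Bubbles are visited in chain order and 2-colored greedily: each bubble
   joins the currently open complementary group pair on the side that
   maximizes link agreement (majority vote against all already-colored
   members; ties keep the candidate assignment; conflicting minority votes
   are counted and logged); a bubble with no evidence closes the open pair
   and starts a new one. Phasing runs once, after all ranks — it consumes
   the finished chains and feeds nothing back into linking, so a per-rank
   re-phasing would produce identical output at higher cost.

8. **Output.** Each chain is rendered twice: haplotype 1 carries homotigs
   plus color-1 heterotigs, haplotype 2 the complementary set, orientations
   applied (reverse-complement as needed), inter-contig gaps as N-runs of
   `max(round(gap), gap_floor)` (half-away-from-zero rounding; floor 10).
   A bubble with a single heterotig leaves an N-run of that heterotig's
   length on the other haplotype. Unphased pairs fall back to a
   deterministic convention (smaller id → haplotype 1). Singleton contigs
   are emitted identically in both files. All outputs (FASTA, TSVs, DOT)
   are byte-deterministic for fixed inputs and seed.

## Synthetic benchmark

The generator emulates the full study universe so every stage runs with no
external data. Haplotype A is seeded random DNA (or user-supplied FASTA);
haplotype B differs at variant sites, each a 1–5 bp indel with probability
`indel_fraction` (default 0.1, roughly the SNP:indel ratio seen in real
genomes) and otherwise a SNP. Error-free 75-bp innie pairs are drawn
per-haplotype to a target coverage (default 40× per haplotype per library)
with rounded-normal inserts truncated to [2·read_len, 2·mean]; defaults are
one 400 bp ± 50 library (rank 1) and one 1000 bp ± 100 library (rank 2).

**Variant placement.** Default is `clustered`: homozygous and heterozygous
tracts alternate with exponential lengths (means 400 bp each), variants
falling only in heterozygous tracts at a local rate chosen so the
genome-wide rate equals `het_rate`. Real heterozygosity is strongly
overdispersed, and this is not cosmetic here: with `placement="uniform"`
at rate 0.04 the mean variant spacing is 25 bp, padded variant blocks
(± 74 bp) almost never leave a homozygous run long enough to anchor a
homotig, and the entire genome merges into a single heterozygous block —
zero bubbles, nothing to scaffold. The clustered default reproduces the
bubble-rich regime (alternating homotigs and heterotig pairs) that a
stringent assembly of a real heterozygous genome produces, with ~930
contigs and ~310 homolotig pairs per 500 kb at the default settings.
Uniform placement remains available for studying the degenerate regime.

**Stringent assembly is simulated, not implemented.** The contig set is
derived from variant-block geometry: each variant padded by `pad` bases
(default 74 = read length − 1, the most shared context through which a
stringent assembler can extend a haplotype-specific contig); overlapping
padded blocks merge into one heterozygous block realized as a heterotig
pair; remaining homozygous runs become homotigs, with runs shorter than
`min_homozygous_run` (default 150 > 2·pad) absorbed into the flanking
blocks. The tilings partition each haplotype exactly, so every read end
lifts onto a unique contig; reads spanning a contig boundary are dropped
from membership and emitted as unmapped, mimicking assembler clipping.
The depth table and contig membership are computed from the rank-1
library's actual member reads (so heterotigs show ~1× haploid and homotigs
~2× haploid fold-coverage); the 1000-bp library contributes rank-2 linking
and phasing evidence only.

What passing tests on this universe do **not** show about real data:
there are no sequencing errors, no repeat families, no chimeric reads, no
mis-assemblies, and contig boundaries are geometrically exact — so the
benchmark validates the scaffolding and phasing logic, not robustness to
assembler or sequencing artifacts.

## Quality metrics

With per-read haplotype provenance, four metrics (contigs ≤ 100 bp are
always excluded):

* contig sequencing depth = aligned bases / contig length;
* contig homogeneity `hom(c) = |{x ∈ c : x ∈ A}| / |{x ∈ c}|` — heterotigs
  should peak at 0 and 1, homotigs at 0.5;
* phase-group homogeneity, the read-weighted version over all contigs in a
  group `g`: `hom(g) = Σ_c |{x ∈ c ∧ A}| / Σ_c |{x ∈ c}|`;
* heterogeneity between complementary groups `|hom(g_m) − hom(g_n)|`,
  reported as an absolute value so the metric does not depend on which
  group is labelled first; accurate phasing clusters at 1.

A precision/recall-style summary evaluates heterotig classification
against a depth cutoff of 1.5× the modal depth (haploid-depth contigs are
the true heterotigs): the fraction of classified heterotigs below the
cutoff, and the fraction of below-cutoff contigs that were classified.
Densities are exported as (value, count) TSV histograms; an optional flag
renders the four panels with matplotlib.

## Numerical and design choices

* Coordinates are 0-based half-open internally; SAM (1-based) and BLAST
  (1-based inclusive, subject-order-encoded strand) convert at parse time.
  Mates are matched by a trailing `/1 /2 _1 _2` token, or SAM flag bits
  when present.
* Pairs with a multi-mapped end are suppressed by default (opt-in flag to
  use all placement combinations).
* `depth_mode` bins depths into `bin_width`-wide bins centered on
  multiples of the width (default 1×); ties break toward the lower bin.
* Degenerate inputs: empty library list, single-class training sets,
  zero-length contigs and sub-minimum support all raise immediately with
  messages; fewer than `min_training` (10) perfect bubbles disables
  classification and falls back to bubbles-only scaffolds rather than
  training on noise.
* Problem sizes in the test suite: unit tests run on hand-built graphs and
  ≤ 200 bp sequences; the end-to-end benchmark is a 500-kb diploid at the
  default study conditions (het 0.04, two 40× libraries), run once per
  session through real FASTA/SAM files; the byte-determinism check repeats
  a 120-kb universe twice, since determinism does not depend on scale.

## Known limitations

* Rearrangements and inversions between haplotypes are out of scope by
  assumption; a bubble whose heterotigs are inverted copies will not be
  recognized as such.
* Bubbles with more than two parallel paths (polyploidy) are not modelled.
* Gap estimation is a plain mean over pair suggestions; no
  maximum-likelihood re-estimation, and intra-contig pair spans are
  recorded in PairStatus but not used to recalibrate insert sizes.
* The greedy linker is order-deterministic but makes no global
  optimization; a heavier edge always wins locally.
* The classifier is trained per-run on that run's perfect bubbles; no
  cross-validation or calibration is attempted, and with very few perfect
  bubbles the pipeline deliberately refuses to classify.
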
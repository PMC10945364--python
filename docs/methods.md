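# Methods

## Cleavage-site model

An endoribonuclease cut creates a new transcript 5′ end. In a 5′-end
sequencing library this appears as reads whose 5′ termini stack at one
genomic position on the transcribed strand. The pipeline models this
with a purely local statistic: at position *i*,

    score_i = (m_i + 0.5) / (sum_{k in W(i)} m_k + 10 * 0.5)

where m is the per-position median of replicate 5′-end counts and W(i)
is the 10-position window immediately upstream of *i* in transcript
orientation (i−1…i−10 on '+', i+1…i+10 on '−'). Every count carries a
+0.5 pseudocount so scores are strictly positive and the ratio

    ratio_i = score_i(toxin) / score_i(control)

is always defined. A position is called a cleavage site when ratio_i is
strictly greater than the threshold (default 60). On a uniform track of
any depth c the score is exactly (c+0.5)/(10c+5) = 0.1, so the statistic
is scale-free: library-depth differences between conditions cancel in
the ratio, and no library-size normalization is applied before scoring
(a CPM option exists but is off by default).

Assumptions: cuts are point events on the transcribed strand; the
upstream window is taken in transcript orientation because the cleavage
signature lives on transcripts (a genomic-coordinate window would
mishandle '−'-strand genes; `window_frame` in the scorer could expose
this, the stranded frame is the default and the only one used);
positions whose upstream window crosses a replicon end are skipped, not
padded — padding with pseudo-zeros would inflate scores at boundaries.
The threshold comparison is strict (>), and no multiple-testing
correction is applied: the rule is a fixed ratio cutoff, not a p-value.

### Replicate summary

"Median across replicates" is computed per position over the multiset of
replicate counts, absent positions counting as zero; with two replicates
this equals their mean. The median generalizes to any replicate number.
The alternative reading (a single summed value) would not be scale-free
in replicate number.

### Read filtering and counting

Reads with any mismatch at 5′-end offsets 0–29 (the first 30 aligned
nucleotides) are removed; offset 30, the 31st nucleotide, is kept. The
orientation filter requires agreement between the read strand and the
strand of a gene overlapping the read's 5′ end; reads overlapping no
gene are kept by default (configurable). Filtering happens after
alignment — mismatches are only knowable from alignment records (NM/MD
in SAM, an explicit offsets column in the tabular dialect). A read
reported at x equally best locations contributes 1/x at each location
("spread" counting), so each retained read carries total mass 1; this is
what makes both copies of an identical duplicated tRNA pair display the
cleavage signal at homologous positions. Whether to enumerate all
placements or only a primary one is a degree of freedom of the upstream
aligner; the ingest layer takes the records as given and derives x from
the NH tag, falling back to the read-name multiplicity in the file.

## Consensus motifs

Cut-site windows are generalized column-wise into the smallest IUPAC
code covering all bases observed in at least `min_fraction` of the
windows (default 1.0: full coverage, which reproduces a two-variant
consensus like CU(U/G)G^AA → CUKG^AA exactly; a frequency threshold is
exposed for larger site sets). Flanking fully-degenerate (N) columns are
trimmed and the cut offset shifted accordingly. Scanning uses regex
lookahead so overlapping occurrences are all reported; T and U are
interchangeable on input and output uses the RNA alphabet.

Anticodon-loop location takes a dot-bracket structure as *input* (no
folding is performed): hairpin loops are unpaired runs directly closed
by a base pair, and a cloverleaf must show exactly three of them (D,
anticodon, T), the second being the anticodon loop. Any other hairpin
count returns "unknown" rather than an error. Without a structure, a
sequence of plausible tRNA length (60–95 nt) falls back to the
standard-numbering heuristic interval 32–38, flagged as heuristic.

## Codon-based target prediction

A gene's sensitivity to loss of a serine-tRNA isoacceptor is scored by
absolute counts of the codons that isoacceptor decodes — absolute
rather than proportional, to limit length bias. Rare codons (UCU, UCA,
AGU) qualify a gene from 4 occurrences; frequent ones (UCC, UCG, AGC)
from 12. The expression list (ZIII+) uses ≥ 1500 normalized reads; the
comparison is inclusive (≥), with the operator configurable. Lists are
built over the supplied universe (the zone-specific genes); codon-list
membership is intersected with the expression list afterwards, via
exact Venn regions (region keys are the full set of lists containing a
gene, so regions partition the union and inclusion–exclusion holds by
construction).

Replicon bias is assessed per list with two-sided Fisher exact tests on
2×2 tables (member vs not × replicon A vs B), Bonferroni-corrected over
the replicon pairs. The choice of an exact conditional test is this
package's own: member counts per replicon can be small, where
chi-squared approximations are unreliable; the test is conservative,
which the null-calibration check reflects. Subset representativeness
(length and serine-codon-frequency distributions of a subset vs its
universe) is reported with two-sample Kolmogorov–Smirnov tests and
quantiles; it gates nothing.

## Synthetic data generator

The generator emulates the study design, not the chemistry:

- **Genome**: 1–3 replicons (chromosome, pSymA, pSymB) of random
  sequence at a configurable GC fraction (default 0.62, a GC-rich
  rhizobial genome), carrying non-overlapping tRNA (85 nt) and CDS
  (300–900 nt) genes on random strands. Duplicated tRNA pairs are
  bit-identical in transcript orientation and placed ≥ 1 kb apart on
  the same replicon, so 1/x counting is exercised without
  overlapping-feature ambiguity.
- **Planted sites**: a concrete realization of the consensus motif is
  written into chosen features in transcript orientation; the recorded
  position is the genomic coordinate of the first transcript nucleotide
  3′ of the cut. When the chosen feature has an identical twin the
  motif is written into both copies at the same transcript offset
  (identical genes cannot diverge and remain identical to an aligner);
  the expected signal set therefore includes the twin's homologous
  position. Planted intervals keep ≥ 12 nt separation: two cuts closer
  than the 10-nt scoring window place each other's peak in the upstream
  window and suppress the score, making closer ground truth unreachable
  by the statistic itself.
- **Reads**: single-end, default 150 nt, two replicates per condition.
  5′-end starts are Poisson per position per strand (default mean 2);
  in the toxin condition the intensity at each planted position is
  multiplied by its enrichment (default 300), thinned by a capture
  probability (default 1.0) that stands in for 5′-OH/5′-P end chemistry
  — the scoring pipeline never uses chemistry beyond which reads exist.
  With `reads_per_replicate` set, the same intensities are sampled
  conditioned on the total (multinomial), giving an exact read count
  while preserving the Poisson shape; unset, counts are i.i.d. Poisson.
  A `mismatch_rate` fraction of reads (default 0.05) carries one
  mismatch within its first 30 bases. Reads starting inside a
  duplicated gene are reported at both homologous placements with
  x = 2. Optional per-replicate scaling exercises the median step.
- **Zone expression**: a universe of 900 genes with 220 zone-specific
  (a ~10× scale-down of the real 2209-of-8933 setting), log-normal
  expression chosen so a realistic minority of zone genes clears the
  1500-read cut, gene lengths log-normal around 250 codons, serine
  codons at ~6% of codons with a GC-rich serine-codon mix (UCC/UCG/AGC
  frequent, UCU/UCA/AGU rare), replicon assignment ~55/22/23%, and an
  optional rare-codon bias factor on one replicon. Six boundary genes
  (UCU = 3/4, UCC = 11/12, reads = 1499/1500) are planted by default so
  threshold semantics are pinned on both sides. Ground-truth list
  labels are computed from the realized sequences by an independent
  triplet tally at generation time.

What the generator does **not** model: realistic Illumina error
profiles, adaptor sequence, fragment-length effects, paired-end reads,
transcription-unit structure (background is uniform rather than
gene-shaped), RNA secondary-structure effects on capture, and
correlated expression between neighbouring genes. Passing tests
therefore demonstrate that the statistics recover planted signal under
the stated noise model, not that the thresholds are optimal for any
real library.

## Problem sizes and numerical choices

Tests and the acceptance script use 20–30 kb single-replicon genomes
(≈ 60 k scored positions per run), 20 planted sites at 300× enrichment
over Poisson(2) background across five simulation seeds, 10⁵-read
mass-conservation checks, a 10 kb track for the vectorized-vs-literal
score comparison (agreement to 1e-9), 100 generator seeds of 300-gene
universes for null calibration of the replicon test and one 900-gene
biased universe for power — sizes chosen so the full suite completes in
a few minutes on one CPU while keeping every check at its intended
resolution. Vectorized scoring uses cumulative sums for the upstream
window; fractional 1/x increments are exact in binary floating point
for x ∈ {1, 2}, and the mass-conservation tolerance of 1e-9 covers
accumulated rounding for larger x. Ties in ratio do not merge sites:
every position is its own site. Degenerate inputs fail loudly
(zero-length replicons, frame violations, unbalanced dot-bracket
strings, unknown replicons in alignment records, negative thresholds).

## Known limitations

- Sensitivity of the >60 rule is not exactly 1 in every random
  universe: at a duplicated-gene cut, only half the enriched mass lands
  on each copy, and an unlucky control draw at exactly that position
  can push the ratio just below threshold (~2% of sites at 300×
  enrichment). This is a property of the fixed-cutoff rule, not of the
  implementation.
- The orientation filter needs gene annotation; in unannotated regions
  it passes reads through (configurable), so antisense artifacts
  outside genes are not removed.
- Consensus building assumes pre-aligned, equal-length windows with a
  common cut column; it does not align.
- The loop finder trusts the supplied structure; it does not fold, and
  non-cloverleaf structures yield "unknown" rather than a best guess.
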
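# Methods

## The site model

An Sm-site is modelled as a short uridine-rich sequence motif plus flanking
secondary structure.  Five motif classes are scanned: the exact U1-, U2- and
U5-type patterns (`AUUUGUG`, `AUUUUUG`, `AUUUUUUG`; together "canonical"),
the longer U7-type pattern (`AUUUGUCUAG`), and a degenerate noncanonical
pattern `AUNUKUN` that admits the base substitutions known not to abolish
Sm-ring assembly.  Matching is overlap-aware (every start position is
reported, so overlapping occurrences of one motif are all counted and the
output flags allow either counting convention to be recovered) and each motif
is scanned independently: a canonical occurrence is *also* an NC occurrence,
which is why per-gene true-noncanonical frequencies are computed by
subtraction (`nc_true = n_NC_raw − canonical_total`, provably ≥ 0).

Subject sequences are uppercased, `T` and `U` are identified (internal letter
`U`), soft-masking is ignored, and an `N` in the subject never matches any
pattern position — ambiguous bases are conservatively unscannable.

Window capture: ≤ 200 nt immediately 5' of the site and up to 50 nt
immediately 3'; a hit with fewer than 16 nt of downstream sequence available
is discarded outright.  That floor reproduces a known negative control: an
RNA with only 8 nt past its site (the U4atac situation) can never be called.

## Structure filter

The decision consumed downstream is binary per side: *is any base predicted
paired within 20 nt upstream / 10 nt downstream of the site?*  Both flanking
windows are folded independently, excluding the motif itself; a site is
retained only when both sides pass.

The default folder maximizes total pair weight (GC = 3, AU = 2, GU = 1;
wobble pairs allowed) over non-crossing pairings with hairpin loops of at
least `min_loop = 3` unpaired bases — a Nussinov-style O(n³) dynamic program,
numba-compiled.  Two refinements:

- **Deterministic traceback.**  Ties are broken by pairing the leftmost base
  with its smallest admissible partner, recursing left to right, so repeated
  runs give identical dot-brackets.
- **Helix pruning.**  Isolated helices shorter than `min_helix = 2` stacked
  pairs are unpaired in a post-pass and the score recomputed.  The pruning is
  a filter applied *after* maximization: the DP score is provably optimal
  (verified against exhaustive structure enumeration for every sequence of
  length ≤ 8 and random longer ones at `min_helix = 1`), and pruning can only
  lower it.

A maximum-weight folder is not a free-energy model.  It has no stacking
energies, no dangles, no entropic loop penalties; its purpose here is the
binary paired-within-window decision, which it supports exactly and
deterministically with no compiled third-party dependency.  For parity runs
against a thermodynamic folder, any tool emitting dot-brackets can be used
through the sidecar backend (`window_id → dot-bracket` TSV); the retention
decision depends only on the dot-bracket string, so identical structures give
identical decisions regardless of backend.

The window sizes (20 nt 5', 10 nt 3') and the capture bounds (200 nt / 16–50
nt) are the biological operating points of the survey and are exposed as
parameters but not varied by any test.

## Annotation handling

Internal coordinates are 0-based half-open everywhere; GFF3/GTF are read and
written 1-based inclusive, BED 0-based half-open, SAF 1-based inclusive.  CDS
rows are projected through the exon chain into transcript coordinates, and a
transcript position maps to 5'UTR / CDS / 3'UTR by half-open comparison
against those bounds (no-CDS transcripts are "noncoding").  A site that
straddles a region boundary takes the region of its first base.

One transcript represents each gene, chosen by MANE tag, then
Ensembl-canonical tag, then greatest spliced length, then smallest transcript
ID — the last two as explicit deterministic tie-breaks.  Region lengths
(5'UTR/CDS/3'UTR) are computed from the annotation itself.

When two annotations of the same transcript universe are scanned, hits are
reconciled by the key (transcript ID, motif class, captured downstream
sequence): hits shared under that key are emitted once, then
annotation-specific hits are appended.  Implementation note: two distinct
sites in *one* list can share the key (same motif in an identical downstream
context), so the merge keeps all first-list hits and appends second-list hits
whose key is new — idempotent, and commutative whenever shared hits agree.

## Intron counting

Introns are per gene: gene span minus the union of all exons of all of that
gene's transcripts.  (A literal genome-wide exon-complement would include
intergenic space; the per-gene reading is what "assign counts only to
intronic regions" requires.)  Reads enter as intervals; a read is assigned to
a gene when it overlaps any intron by ≥ 1 base (configurable), a multi-gene
read counts for each gene (or 1/k with `--fraction`), and strand is ignored
unless `--stranded`.  Genes with at least one intronic read are flagged as
carrying pre-mRNA signal.

## Enrichment statistics

The fidelity path imports externally computed per-gene log2 fold-changes and
BH-adjusted p-values (e.g. a DESeq2 Wald test).  Re-implementing shrinkage
estimation is explicitly out of scope; the internal route — median-of-ratios
size factors over genes positive in all samples, then
`log2((meanA + 0.5) / (meanB + 0.5))` of normalized condition means — exists
so simulation-only workflows run end to end, and carries no per-gene test.

Genes are classified enriched when log2 fΔ > 0.6 and padj < 0.05 (i.e.
> 1.5-fold), depleted when log2 fΔ < −0.6 and padj < 0.05, else neither.
Strata (Absent / Noncanonical / Canonical) are compared with one-sided
two-sample Wilcoxon rank-sum tests using the normal approximation with
midrank ties, tie-corrected variance and continuity correction (the R
`wilcox.test` convention), BH-corrected across the pairs of one call; ECDF
coordinates are emitted for cumulative-distribution plots.  Rank correlations
use Kendall τ-b with an asymptotic p-value.  Region densities are pooled
counts over pooled lengths × 10⁶ (sites per megabase), invariant to gene
order and to splitting genes with preserved totals.  The candidate funnel
intersects the enriched sets of several comparisons (ATP-induced, over-input,
Sm-associated), removes genomically ambiguous genes, and orders candidates by
descending minimum fold-change.

## Synthetic data

The generator emulates the statistical structure the analysis assumes — not
real genomes.  Defaults define the simulated study: 1000 genes; 15% carry one
structured canonical site (U1/U2/U5 drawn uniformly), 20% one structured
NC-only site (`AUAUGUA`, an NC instance matching no canonical pattern), 10%
one unstructured canonical site, the rest none; sites sit mid-3'UTR; region
lengths are lognormal (medians 150 / 900 / 900 nt for 5'UTR / CDS / 3'UTR,
floors at 100/300/300 nt) — transcripts of a few kilobases with substantial
3'UTRs, where such sites predominantly occur.  Counts are Gamma–Poisson
(negative binomial) at dispersion 0.1 over 3 + 3 samples with sample size
factors log-uniform in [0.7, 1.4], base means lognormal (median 200, σ = 1),
and a planted +1.0 log2 fold-change on canonical-site genes in the "ATP+"
condition.  Each gene has two exons separated by an 80–200 nt intron; reads
are placed wholly inside one intron or one exon so the truth tally is exact.

Two constructions make the ground truth *provable*, not just probable:

- **Motif-free background.**  Background sequence is rejection-sampled in
  80-nt blocks, rescanning each block plus its junction overlap with all five
  motifs.  A subtlety: a block can be motif-free yet end in an NC prefix
  (e.g. `…AUAUGU`) whose one unseen position is `N` — *any* continuation
  completes the motif and rejection would deadlock.  Candidate blocks are
  therefore scanned with an all-C guard appended (C completes an `N` position
  but no U-requiring position, and an all-C tail starts no motif).  After
  cassette insertion every transcript is re-scanned and rebuilt if any
  junction created a spurious match, so scanner specificity on simulated data
  is exactly measurable: zero unplanted calls.
- **Designed flanking windows.**  A structured site's captured windows are
  fully designed: a 6-bp GC stem with a CACA loop placed inside the decision
  windows, the remainder filled with C/A letters.  Under AU/GC/GU pairing a
  C/A stretch can pair with nothing in the window, so *every* possible pair
  involves a stem base inside the decision window — any maximum-weight
  structure pairs the stem and the filter must retain the site.  Unstructured
  sites get C/A-only windows throughout, where no pair exists at all, so the
  filter must reject them.  Sensitivity 1.0 and false-retention 0 are
  consequences of the construction, and the tests confirm them across seeds.

What the generator does **not** emulate: real sequence composition
(background is uniform-random minus motifs), multi-isoform genes (one
transcript per gene by default), strand diversity (plus strand), length-
dependent site frequency, overdispersion structure beyond a single NB
dispersion, or library-specific biases.  Passing tests therefore demonstrate
algorithmic correctness and statistical calibration, not performance on real
annotation idiosyncrasies.

## Numerical notes and limitations

- The rank-sum normal approximation tracks exact permutation enumeration to
  within 0.02 for continuous data at group sizes 3–8 (measured worst ≈
  0.019).  With mass ties at such sizes the approximation can deviate far
  more (tenths); that is intrinsic to the approximation, which the standard R
  implementation shares.  Fold-change inputs are continuous in practice.
- With a one-sided planted shift on 15% of genes, median-of-ratios
  normalization absorbs part of the shift: all fold-changes are offset
  downward by ~0.1–0.2 per run, so per-seed means of planted genes sit near
  0.85 while the planted *contrast* (canonical minus absent strata) is
  recovered at ~1.0.  Any normalization of this family behaves this way with
  asymmetric differential signal.
- Size-factor estimation requires at least one gene positive in every
  sample; all-zero samples raise an error suggesting a pseudocount path
  rather than silently producing infinities.
- Folding is limited to 1–1000 nt (the longest window actually folded is
  200 nt); Kendall τ is refused for constant vectors; empty strata and
  strata with n < 2 are refused by name.
- Determinism: all generators draw from `numpy` Generators seeded from the
  configuration seed via distinct stream keys (labels, sequences, counts,
  reads), so class labels are identical whether or not sequences are built,
  and every output file is byte-identical across reruns of the same seed.

## Problem sizes in the shipped checks

Oracle sweeps use: all 4^k sequences, k ≤ 8, plus 200 random 10–14-mers for
the folder; 1000 random sequences up to 2 kb for the scanner and mimic
searches; 500 random toy genes for intron arithmetic; 20 seeds × 200 genes
for structure-truth recovery; 20 + 100 seeds of 1000-gene count matrices for
fold-change recovery and null calibration.  These sizes were chosen to make
the checks decisive while keeping a full run of the suite under a minute of
compute for the oracle-heavy parts.
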
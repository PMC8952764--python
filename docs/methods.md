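# Methods

This note documents the models and procedures implemented in `genrelate`,
the parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Local alignment core

All genome and gene comparisons run on a self-contained seed–chain–extend
nucleotide aligner:

1. **Seeding.** Exact k-mer matches (default k = 11) between the query and
   an index over the forward strand of every subject contig; minus-strand
   matches are found by scanning the reverse complement of the query.
   Contigs are concatenated with 64 nt runs of `N` — longer than the
   maximum chaining gap — so no alignment can bridge two contigs.  `N`
   never matches anything, including another `N` (conservative identity
   counting).  k-mers occurring more than 200 times in the subject are
   ignored as repeats.
2. **Ungapped extension.** Seeds on one diagonal are processed together:
   the diagonal is split wherever a mismatch run alone would exceed the
   x-drop budget (run length > x_drop/|mismatch|, i.e. ≥ 7 with the
   defaults), and within each piece the single maximal-scoring subsegment
   is taken.  Taking the maximal subsegment (rather than stopping at the
   first x-drop) means gap-free optima are never truncated by transient
   dips, which is what makes exact agreement with Smith–Waterman possible
   on substitution-only pairs.
3. **Chaining and gapped refinement.** Nearby collinear segments (gaps and
   diagonal shift ≤ 50) are chained, and each chained region is realigned
   with a banded affine-gap Smith–Waterman (band = diagonal span ± 8,
   skipped if the DP window would exceed 2·10⁶ cells, in which case the
   ungapped members stand).  A gap of length L costs
   `gap_open + L·gap_extend`.
4. **Overlap resolution.** HSP candidates overlapping on both query and
   subject keep only the higher score; the survivors are sorted by bit
   score, ties broken by (query_start, subject_start).

Raw scores are converted to bits by `(λ·S − ln K)/ln 2`.  Defaults (match
+2 / mismatch −3 / gap −5,−2 / λ 0.625 / K 0.41 / k 11 / x-drop 20) mirror
common BLASTN settings; they are a documented stand-in, not a claim about
any particular external run.  The HSP identities, length and raw score are
recomputed from the final alignment (cigar), so re-scoring the aligned
substrings reproduces the raw score exactly.  An adapter can ingest
outfmt-6-like tabular alignments in place of the internal aligner
(1-based inclusive coordinates converted to 0-based half-open on read).

Verified properties: on ≤ 2 kb substitution-only pairs the top HSP raw
score equals the full Smith–Waterman score (Biopython oracle, identical
scheme); with indels it stays within 95%; identity counts are invariant
under query/subject role swap for gap-free alignments.

## ANIb

The query genome is fragmented into consecutive non-overlapping 1020 nt
windows per contig, trailing remainders discarded (padding would make
per-fragment identities incomparable).  Each fragment's best HSP against
the subject (highest bit score; ties broken by lowest subject start) is
accepted when identity ≥ 30% of alignment columns *and* the HSP spans
≥ 70% of the fragment; ANIb is the arithmetic mean of accepted fragments'
identity percentages.  The fragment length and both filters are exposed as
parameters; the defaults are the conventional ANIb acceptance settings.
When no fragment is accepted the result is *undefined* and reported as
missing, never 0 — a 0 would corrupt the downstream correlations.  ANIb is
directional (query fragmented, subject searched); on indel-free simulated
pairs the two directions agree within a couple of tenths of a point.

Self-ANIb is exactly 100.0, and on indel-free 100 kb pairs at substitution
rate δ ∈ {0.01, 0.03, 0.05, 0.10} the recovered ANIb stays within 0.5
points of 100·(1−δ).  There is a small (< 0.1 point) upward bias because
maximal-scoring segments begin and end on matches — the same end-trimming
any local aligner performs.

## dDDH

All HSPs with bit score ≥ 50 (suppresses spurious seeds between unrelated
genomes) enter a greedy selection by descending bit score in which any HSP
overlapping an already-kept one **on either genome** is discarded, so no
aligned column is counted twice.  The distance is
`d = 1 − Σ identities / Σ alignment columns` over the retained set (empty
set ⇒ d = 1), and

`dDDH% = 100 · logistic(a + b·d)`, a = 7.0, b = −136.73.

The coefficients are this package's own calibration, not any external
service's regression: the intercept puts the self-comparison at 99.9+%,
and the slope is solved from `logistic(a + b·0.045) = 0.70`, placing the
70% dDDH species boundary at the distance where ANIb is ≈ 95.5% — the
conventional co-occurrence of the two boundaries.  The mapping is strictly
decreasing in distance and clamped to [0, 100].  Published dDDH values
from external services are therefore *not* numerically reproduced (their
regression coefficients are not public); the packaged relatedness table
carries the published percentages as data instead.  A "probability dDDH ≥
70%" column is not modelled; the result exposes a boolean `ge70` flag.

## BSR

Each gene (nucleotide sequence) is aligned to its own source genome to get
the reference bit score — the best HSP must cover ≥ 90% of the gene,
otherwise an annotation/sequence mismatch is raised — and to each target
genome for the query bit score (0 when no HSP).  The ratio
query/reference is clipped to [0, 1] (a target match can in principle
outscore an imperfect self-score; clipping keeps the documented 0–1
scale), and `ratio > 0.4` (strict) calls a homolog.
Per-category percentages are rounded half-up to integers, matching the
convention of published relatedness tables.  Ratios are invariant under
duplication of target contigs, and the category summaries are invariant
under gene order.

## Relatedness statistics

The degree of taxonomic relatedness is the ordinal code of the most
specific shared rank: species 1, genus 2, family 3, order 4, subphylum 5;
no shared rank at any level is an error.  The reference strain itself
(degree 0) is excluded from all statistics — the packaged table holds the
27 comparison strains only.  Regression uses ordinary least squares with
95% confidence bands for the mean response and 95% prediction bands for
new observations (statsmodels); correlations are plain Pearson
product-moment coefficients with no p-values or multiplicity control.
Comparisons against published 2-decimal values use round-half-even.

On the packaged table, r(ANIb, degree) = −0.965 → −0.96,
r(ANIb, exoenzyme%) = 0.956 → 0.96 and r(ANIb, NRPS%) = 0.944 → 0.94
reproduce the published coefficients exactly at 2 decimals.  Two do not:
r(dDDH, degree) computes to −0.752 (published −0.76) and r(ANIb, PKS%) to
0.800 (published 0.74).  The packaged table necessarily carries the
integer-rounded percentages that were printed; the published coefficients
were evidently computed from the unrounded ANIb/dDDH values, which are not
recoverable.  Including the self-comparison as a 28th row, or recoding the
one strain whose shared rank is ambiguous, moves single coefficients but
breaks others, so the documented degree encoding is kept and the two
discrepant coefficients are reported as computed.  (A side effect of the
same rounding: the table's subphylum-level rows make r(ANIb, toxin%) =
0.94 and r(ANIb, PKS%) = 0.80; the PKS column is the only one whose
percentages *rise* again at degree 5, which is why its coefficient is the
most sensitive to rounding.)

## Bioassay statistics

Replicate-level mortality percentages (100·dead/n) are analysed with a
one-way ANOVA (between/within decomposition, p from the F distribution;
all-constant identical groups define F = 0, p = 1).  Mean separation uses
Fisher's *protected* LSD: pairwise tests run only after a significant
omnibus F, pair (i,j) differing when
`|m_i − m_j| > t(1−α/2, df_within)·√(MSE·(1/n_i + 1/n_j))`; unbalanced
groups are handled through these per-pair standard errors, and the single
reported LSD value uses the harmonic-mean group size.  Letters come from
the insert-and-absorb compact-letter-display algorithm and are
deterministic in group order; sharing a letter is equivalent to
non-significance of the pair.  A non-significant ANOVA yields one shared
letter for all groups (documented behaviour, not an error).  Mortality is
analysed untransformed by default; an arcsine-square-root option exists.
Independent experiments are pooled as replicates with the experiment label
retained but not modelled (the analysis is one-way by design).  Under a
null simulation (equal mortality, 6 groups × 12 replicates, 1000 runs)
the omnibus rejection rate sits inside the 99% binomial band of 0.05.

## Synthetic data generator

The generator defines the conditions under which the pipeline is tested:

* **Genomes.** IID bases at a target GC (default examples use 51.7%, a
  typical value for these fungal assemblies).  Evolution applies, in a
  fixed documented order, (1) per-site Bernoulli substitutions uniform
  over the three alternative bases (no transition bias — the simplest
  testable choice), (2) Poisson-count indels with geometric lengths capped
  at 50 nt, insertion/deletion equiprobable, positions applied in
  descending order, (3) segment rearrangements.  Rearrangements are
  translocations by default so that rearrangement-only evolution conserves
  the residue multiset exactly (a testable invariant); reverse-complement
  inversions are available behind `inversion_fraction` but default to off.
  The realised divergence returned is the substituted fraction of
  pre-indel sites.
* **Gene families.** Default desk-scale repertoire of 24 exoenzyme, 15
  toxin, 12 NRPS and 10 PKS genes of 1 kb (a scaled-down version of a
  real repertoire's proportions; real NRPS/PKS genes are many kilobases
  and real inventories larger).  Retention probabilities
  {1: 0.95, 2: 0.85, 3: 0.50, 4: 0.20, 5: 0.15} and homolog divergences
  {1: 0.04, 2: 0.12, 3: 0.20, 4: 0.30, 5: 0.40} follow the empirical decay
  of homolog percentages and ANIb across degrees 1–5; retention must be
  non-increasing in degree.  Genomes are assembled by joining retained
  (mutated) homologs with 200 nt random spacers; a truth table records
  ground-truth presence.  BSR calls recover the truth at ≥ 95% agreement
  for divergences ≤ 15%; at 30–40% divergence the 0.4 threshold begins to
  miss homologs (ratio ≈ 1 − 2.5·δ with the default scheme), which is a
  property of the threshold, not a defect.
* **Mortality.** Binomial dead counts per dose × replicate.  Defaults: six
  doses (0–7 µg/larva), ten larvae per replicate, twelve replicates
  labelled as three technical replicates in each of four experiments,
  scored at 21 days, with true mortalities
  {0: 0.01, 0.70: 0.43, 1.75: 0.38, 3.50: 0.50, 5.25: 0.64, 7.00: 0.64} —
  the characteristic non-dose-monotone pattern of a heterogeneous
  metabolite extract.

Randomness: every operation has its own generator seeded as
`SeedSequence(seed, spawn_key=(stream,))` with a fixed stream index per
operation, so stages are independently reproducible and identical
spec+seed yields byte-identical files.

**What passing tests do not show:** the simulator has no codon structure,
no repeat landscape, no GC heterogeneity, no biosynthetic-cluster
architecture, and gene conservation is IID per gene rather than
phylogenetically correlated.  Results on real assemblies will differ in
absolute values (e.g. real ANIb between related species reflects
alignable-fraction effects the IID model understates); the tests establish
correctness of the computations and calibration under the stated model,
not field performance.

## Problem sizes

The test and acceptance runs use 100 kb genomes for ANIb recovery, 20–60 kb
for dDDH and matrix checks, 2 kb fixtures for exact alignment oracles, a
61-gene repertoire for BSR, and 1000 null simulations for the type-I
calibration — sizes chosen so the full suite completes in well under a
minute while every statistical band (3 SD binomial, 99% binomial) retains
its intended power.
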
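# Methods

## Design and data model

The analysis assumes the reciprocal-hybrid design of the *C. briggsae* ×
*C. nigoni* study: six expression groups — the parents `Cbr` and `Cni`, and
per reciprocal hybrid (`BN`, `NB`) one column per haplotype (`BN_cbr`,
`BN_cni`, `NB_cbr`, `NB_cni`). With 3 `Cni` replicates and 2 replicates of
every other group, the pair-level count table has 13 columns. Counts are
organised by one-to-one ortholog pair; for a parental sample only the rows
of its own species' haplotype are informative, and counts sitting on the
other species' rows are dropped during assembly.

Orthologs come from reciprocal best protein-alignment hits (`e < 1e-4`;
queries with a tied top score are conservatively excluded, so the pairing
is deterministic and symmetric). Before alignment, overlapping gene models
on a chromosome are collapsed to the longest gene ("overlap" is any
coordinate intersection — the overlap fraction is deliberately not
thresholded) represented by its longest protein isoform; span ties break
to the lexicographically smaller gene id. One-to-n homolog grouping
(used for the mitochondria-related track) assigns each gene to the term of
its single best hit, ties broken by lower e-value then term id.

## Normalisation and filtering

CPM is `count × 1e6 / library size`, the library size being the column
total of the full pre-filter table. A pair is *expressed* iff its CPM is
strictly above 2 in at least 4 of the 13 columns; this single filter gates
every downstream test. The same implementation, with an inclusive `≥ 1` in
`≥ 2` columns rule, filters TE families. Two special normalisation
backgrounds exist: the mitochondria track divides by the summed counts of
the mitochondria-related gene list only, and the TE track by the combined
TE counts per column.

## Differential testing

The engine is a two-group conditional negative-binomial exact test:

1. **TMM factors.** Per column against a reference (the column whose
   upper-quartile count fraction is closest to the mean), the weighted mean
   of per-gene log2 ratios after trimming 30% of M-values and 5% of
   A-values from each tail; weights are inverse delta-method variances;
   factors are rescaled to geometric mean 1.
2. **Pseudo-sums.** Columns are scaled to the geometric mean of the
   effective (TMM-adjusted) library sizes, rounded, and summed within
   group. This reproduces the intent of the classic quantile-adjusted
   conditional approach without its full machinery; the package's
   correctness surface is simulation-calibrated, not bit-compatibility
   with any particular implementation.
3. **Dispersion.** The NB is parameterised as `var = μ + φμ²`. The common
   φ maximises the conditional log-likelihood (given group totals, on
   library-size-equalised counts) summed over features — a grid search on
   `φ ∈ [1e-8, 10]` refined by bounded scalar optimisation. Per-feature
   dispersions maximise the feature's own conditional likelihood plus the
   across-feature average weighted by `prior_df = 10` extra degrees of
   freedom, shrinking noisy feature-wise estimates toward the common value.
   Without any replicated group, φ falls back to 0.05 with a warning.
4. **Exact test.** Conditional on `s = sum_a + sum_b`, group totals are
   NB with means in proportion `n_a : n_b` (the null per-column mean is
   `s/(n_a+n_b)`) and dispersions `φ/n`; the two-sided p sums the
   probabilities of all splits no more probable than the observed one, with
   a `1 + 1e-7` relative tolerance on the comparison. At φ = 0 the
   conditional law is exactly binomial. `s = 0` returns p = 1 by
   convention.
5. **Multiplicity.** Benjamini–Hochberg step-up, implemented directly and
   checked bitwise against a brute-force oracle (and numerically against
   statsmodels).

Log2 fold changes are ratios of group-mean CPMs with a pseudo-count of 0.5
added to each mean (configurable), so they are always finite.

Null simulations (5,000 genes, φ = 0.05, 3v3) show raw p < 0.05 for ≈ 5%
of genes with a Kolmogorov–Smirnov distance to uniform below 0.05; a
planted 4-fold change at φ = 0.05 is recovered at FDR < 0.05 in ≥ 90% of
runs. Both checks run in the test suite.

## Classification rules

**Inheritance** (per hybrid, both hybrid-vs-parent contrasts at
FDR α = 0.05 and |log2FC| cutoff 1, applied sequentially): *no change* if
the hybrid matches both parents (FDR > α and |lfc| < 1 against each);
*dominant* toward the single parent for which the full match clause holds;
*underdominant* / *overdominant* if significant against both parents with
both fold changes negative / positive; otherwise *additive*. FDR (not raw
p) is used in every clause, and all cutoffs are strict inequalities. The
hybrid total expression is the per-replicate sum of the two haplotype
columns. Pairs with missing statistics are excluded with a warning rather
than defaulted into *additive*.

**Regulatory** (per hybrid): *conserved* if neither the parental contrast
nor the within-hybrid allele contrast is significant (FDR > α for both);
otherwise *cis* when `|ratio_P − ratio_H| < 1.8` in log2 units, else
*trans*. The 1.8 threshold is interpreted on the log2 scale, matching how
such ratios are conventionally plotted; both ratios are the DE engine's
fold changes, i.e. group-mean CPM ratios with the 0.5 prior. The allele
contrast uses BH FDR for consistency with the conserved clause.

**Imprinting**: the C. briggsae allele fraction
`f = CPM_cbr / (CPM_cbr + CPM_cni)` is computed per hybrid from
replicate-averaged CPMs, with a combined floor of 5 CPM below which the
pair is a no-call (fractions of near-zero counts are noise; the floor is
configurable). *Maternal* requires the maternal allele — Cni in BN, Cbr in
NB — at ≥ 75% in both hybrids (`1 − f_BN ≥ 0.75` and `f_NB ≥ 0.75`);
*paternal* symmetrically. The overall maternal/paternal *leaning* of a pair
is the mean maternal-allele fraction across the two hybrids compared with
0.5; this operationalises "tendency" as a mean-fraction rule.

**Enrichment**: Fisher's exact test (two-sided by the probability-mass
rule) on chromosome × category 2×2 tables over the expressed universe,
flagged at p < 0.01 and |log2 OR| > 0.4; the odds ratio receives the
Haldane–Anscombe 0.5 correction only when a zero cell would make the log
odds infinite. Gene-set over-representation is the hypergeometric upper
tail with BH FDR across sets and a normalised count `k/K`.

## The synthetic-data generator

The generator emulates the study's statistical structure, not its
sequences: no read-level simulation, no sequence divergence, no genome
model. Per ortholog it draws a baseline log2-CPM mean `μ ~ U(3, 10)`, and
classes impose constraints on the parental divergence `d = log2(Cbr/Cni)`
(parents sit at `μ ± d/2`), the hybrid total `T`, and the hybrid allelic
log2 ratio `r`:

| class | constraint |
|---|---|
| no_change | `d = 0`, `T = μ` |
| dominant (Cbr/Cni) | `|d| ≥ e`, `T` at the matched parent |
| additive | `|d| ≥ e`, `T = μ` (log2 midpoint) |
| over/underdominant | `T = max/min(parents) ± e` |
| conserved | `d = 0`, `r = 0` |
| cis | `r = d`, `|d| ≥ e` |
| trans | `r = 0`, `|d| ≥ e` |

with effect size `e = 2` by default and `|d| ~ U(e, 2e)` where divergence
is required — "at least the nominal effect, with spread", a realistic
range for orthologs called divergent at a 2-fold cutoff. Because
*conserved* forces `d = 0` it can only coexist with *no_change*, and
*cis*/*trans* require divergence; the two class mixes must therefore agree
on those shares, and incompatible requests are rejected with the
conflicting pair named rather than silently reassigned. Imprinted genes
are carved from the no_change/conserved pool and get a maternal (or
paternal) allele fraction of 0.9 — comfortably beyond the 0.75 call
threshold while leaving total expression unchanged; a parent-of-origin
skew flips sign between the hybrids, unlike cis divergence.

Counts are NB (`var = μ + φμ²`, default φ = 0.05 — typical for
low-replicate bulk RNA-seq in inbred lines) at library sizes drawn
log-normally with mean 5×10⁶ and CV 0.2. Each hybrid replicate draws its
per-gene *total* count and splits it binomially by the gene's allele
fraction, so allele counts are conserved by construction and both
haplotype columns share the replicate's library. All randomness flows from
one root seed through named substreams, making every output byte-
deterministic.

What passing recovery tests therefore shows: the classifiers invert the
generator's class definitions under NB noise at the study's replicate
budget. What they cannot show: robustness to mapping bias, reference
bias toward one genome, isoform-level effects, or dispersion that varies
systematically with expression — real-data features the generator does not
emulate.

## Problem sizes and numerical choices

The default recovery scenario uses 3,000 orthologs (500 per inheritance
class, seed-fixed); regulatory recovery uses 1,200 at `d ≥ 2.5`; the null
calibration uses 5,000 genes. These sizes give stable recall and
calibration estimates while keeping a full run on one CPU in minutes.
Ties and degenerate inputs are handled explicitly throughout: tied top
alignment scores disqualify (orthology), the exact test's probability
comparison uses a `1 + 1e-7` tolerance, all-zero columns get TMM factor 1
with a warning, `s = 0` tests return p = 1, constant vectors make the
Spearman correlation an explicit NaN-with-warning, and empty cross-tab
rows are emitted as zeros with a warning.

## Known limitations

- The exact test is calibrated by simulation against its own model family;
  it is not a bit-exact reproduction of any published implementation
  (quasi-likelihood F-tests and GLMs with covariates are out of scope).
- Compound regulatory categories (cis+trans, compensatory) are collapsed
  into the three-class scheme.
- Chromosome enrichment treats chromosomes as exchangeable units; no
  gene-length or expression-level covariate adjustment is attempted.
- Allelic fractions are computed from per-column-normalised CPMs; under a
  strongly asymmetric transcriptome the haplotype column totals could bias
  fractions slightly toward 0.5. At the default design this effect is far
  below the 0.75 call threshold.
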
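# Methods

## Statistical model

Window counts are modelled as negative binomial, parameterized by mean
μ and dispersion φ with variance μ + φμ² (the convention count-based
differential-expression tools use). The per-window two-group comparison
is the classic common-dispersion conditional exact test:

1. **TMM normalization.** The reference sample is the one whose
   75th-percentile count fraction is closest to the mean of those
   fractions. For every other sample, M-values (log2 ratio of count
   fractions) and A-values (average log abundance) are computed over
   windows with positive counts in both samples; 30% of M and 5% of A
   are trimmed from each tail, and the factor is 2^(weighted mean of
   the kept M), weights being inverse delta-method variances. Factors
   are rescaled to geometric mean 1; effective library size = raw
   library size × factor.
2. **Library equalization.** Counts are rescaled to the geometric mean
   of the effective library sizes and rounded half-to-even. This is a
   deliberate simplification of the quantile adjustment some tools use:
   it preserves the conditional-test logic with far less machinery, and
   correctness is certified by simulation properties rather than by
   numerical equality with any particular external implementation.
3. **Common dispersion.** φ maximizes the summed conditional-on-totals
   NB log-likelihood over windows and both groups (for a group of n
   samples with counts y_i and total z the φ-dependent part is
   Σ lnΓ(y_i + 1/φ) − n lnΓ(1/φ) + lnΓ(n/φ) − lnΓ(z + n/φ)), found by
   bounded scalar minimization on φ ∈ [1e-6, 10] (xatol 1e-6), which is
   deterministic. φ = 0 data drive the estimate to the lower bound.
4. **Exact test.** Conditioning on the pooled total N = A + B with
   μ̂ = N/(n_A + n_B), A ~ NB(n_A μ̂, φ/n_A) and B ~ NB(n_B μ̂, φ/n_B);
   the two-sided p sums the probabilities of all splits no more likely
   than the observed one, normalized by the total (minimum-likelihood
   convention, chosen over doubling because it reproduces p = 1 exactly
   for balanced splits). φ = 0 reduces to the conditional binomial.
   Split probabilities are compared with a 1e-8 relative tolerance so
   exact ties (symmetric splits) are always included regardless of
   floating-point noise. log2 fold change = log2((A/n_A + c)/(B/n_B + c))
   with prior count c = 0.5 (configurable) to avoid infinities at zero.
5. **FDR.** Benjamini–Hochberg step-up (delegated to statsmodels),
   with domain validation that p ∈ (0, 1].

## DMR calling

Seeds are windows with p strictly below p_sig (default 1e-4, strict
because the rule is "less than"). Each seed grows left and right,
absorbing any window with p < p_edge (default 0.1) whose nearest edge
lies **strictly** within edge_reach (default 1000 bp) of the current
span, to a fixed point; grown spans that touch or overlap merge. The
strict comparison is what makes one full non-qualifying 1-kb window
block extension past it (the window beyond sits at gap exactly
1000 bp); it is enforced identically by the test suite's brute-force
iterated-absorption reference. A `contiguous_only` mode restricts
absorption to zero-gap windows for users who prefer the conservative
reading. The DMR's fold change is taken from its minimum-p window
(one number per DMR without an aggregation rule being otherwise
defined); a mean-over-significant-windows alternative is available.
DMR names are cohort:chromosome:ordinal.

CpG density is counted on the forward strand only (CG is its own
reverse complement) over [start, end); density < 3 CpG/100 bp flags a
CpG desert, 8–10 CpG/100 bp is island-range.

## Gene association, overlap, clusters

A gene is associated with a DMR when the number of intervening bases is
at most max_distance (default 10 kb, covering gene body plus promoter
reach); overlapping intervals have distance 0, and for half-open
intervals the gap is b.start − a.end, so book-ended intervals also have
gap 0. Exact cross-cohort overlap is ≥1-bp genomic intersection of DMR
intervals (not window identity, since edge extension shifts
boundaries), with percentages normalized by the left-hand cohort's DMR
count. Extended overlap intersects one cohort's DMRs with the other's
windows at a relaxed p (default 0.05); since every called DMR contains
a window far below 0.05, extended sharing can only exceed exact
sharing. Chromosome clusters are single-linkage groups with inter-DMR
gap ≤ 2 Mb — a descriptive default for location figures, not an
inferential quantity.

## Classification

Features are log2(CPM + 1) over DMR-covered windows using effective
library sizes. PCA is centered SVD with a fixed sign convention
(largest-magnitude loading positive). The dendrogram is average-linkage
agglomerative clustering on Euclidean distances of centered features
(ties broken by lowest observation index, scipy's deterministic
behavior). LDA operates in the space of the top k = min(n − 2, 10)
principal components; the pooled within-class covariance is shrunk as
(1 − λ)S + λ·(tr S / k)·I with λ = 0.1 by default, which keeps the
model well-posed when samples are few and features many; prediction is
by the sign of the discriminant score against the class-mean midpoint.
Leave-one-out accuracy refits the discriminant (PCA basis included)
with each sample held out. Feature selection (DMR calling) is *not*
refit inside this LOO — when evaluating a full pipeline on real data,
DMRs should be called on training samples only to avoid selection
leakage; the permutation-null checks in the test suite are immune to
this because shuffled labels break any feature–label association.

## Synthetic data

The generator emulates the study design this package targets: cohorts
of ~20 case vs ~20 control samples, 1-kb windows, NB counts with
baseline mean 50 per window, dispersion 0.1, log-uniform library-size
factors in [0.5, 2.0] (a stand-in for the real spread of sequencing
depth, whose mapping to per-window means is not pinned down), and
planted DMRs of 1–3 windows at fold change 3, alternating direction so
roughly half gain and half lose methylation. Genomes are built from
100-bp tiles with exactly 1–3 CpGs (background) or 8–10 CpGs (2-kb
island blocks covering a configurable fraction, default 5%); accidental
CG dinucleotides created at tile joins are removed, so the CpG index
equals a sequence scan exactly. Planted regions are window-aligned,
disjoint, and separated by at least two windows. An optional read-level
emitter writes BED fragments whose 300-bp-extended midpoints are
uniform within their source window, reproducing the count matrix
through the counting module exactly away from chromosome ends.

What the simulation does **not** model: fragment-length distributions,
GC or CpG-coupling bias of the immunoprecipitation, batch effects, or
correlated windows. Passing tests therefore certify the statistical
machinery under the stated NB model, not robustness to those real-data
artifacts.

## Numerical and design choices

- Internal coordinates are 0-based half-open; DMR tables on disk are
  1-based inclusive (NCBI display convention) and round-trip exactly.
- Midpoint assignment of extended fragments (default) conserves totals
  and keeps windows independent under the NB model; an "overlap" mode
  credits every overlapped window for users wanting enrichment-style
  counting.
- Low-count filtering (default: drop windows with < 10 total counts)
  stabilizes dispersion estimation and shrinks the FDR denominator;
  library sizes are kept unchanged by filtering.
- No MAPQ filter by default (configurable); unmapped, secondary and
  supplementary alignments are always skipped; duplicate-read removal
  is off by default.
- The random-forest arm of biomarker evaluation is deliberately out of
  scope: LDA + PCA + dendrogram form the deterministic, fully
  specifiable core.
- Problem sizes in the test and acceptance runs (5000 windows, 12 v 12
  samples, 20 planted DMRs) are the package's simulated study scale:
  large enough for stable Monte-Carlo calibration checks, small enough
  to run on a laptop in seconds.

## Known limitations

Exact numerical equality with any specific release of external
differential-coverage tools is a non-goal; the enumeration definition
of the test is the correctness standard. Tag-wise/trended dispersion,
covariate designs, CpG-coupling normalization and pathway/network
enrichment are out of scope. Real cohort DMR counts depend on raw data
and historical tool versions and are not reproduced here.
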
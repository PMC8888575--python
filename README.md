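# medipdmr

Differential DNA methylation analysis for MeDIP-seq case/control
studies, built for epigenetic-biomarker work: find genomic regions
whose methylation-enriched read coverage differs between groups
(e.g. term vs preterm birth cohorts of mothers, fathers and children),
characterize them, and evaluate them as classifiers.

It is a library first — `import medipdmr` — with narrative scripts in
`examples/` and a thin `medipdmr` command-line wrapper for shell use.

## The method

The genome is tiled into fixed 1-kb windows and each aligned fragment,
extended to the sonication length (300 bp) from its 5′ end, is counted
in the window containing its midpoint. Window counts for sample *s* are
modelled as negative binomial with mean μ·f_s and variance μ + φμ²,
where f_s is the sample's effective library-size factor (TMM
normalization) and φ a common dispersion estimated by conditional
maximum likelihood. For each window a two-sided conditional exact test
compares groups: with counts rescaled to a common library size, the sum
of case counts A and control counts B are NB-distributed under the
null, and

p = Σ { P(s, t) : s + t = A + B, P(s, t) ≤ P(A, B) } / Σ P(s, t),

the minimum-likelihood two-sided convention (a perfectly balanced split
gives p = 1). Benjamini–Hochberg q-values control the FDR.

Windows with p < 1e-4 seed **DMRs** (differential methylation regions);
DMR edges extend while any window with p < 0.1 lies strictly within
1000 bp of the current span, and touching regions merge. Each DMR is
annotated with CpG count and density (regions under 3 CpG/100 bp are
CpG deserts, the bulk of the genome that MeDIP interrogates well),
associated with genes within 10 kb, compared across cohorts (exact
interval intersection, or extended against the other cohort's p < 0.05
windows), and summarized in chromosome-scale clusters. Biomarker
evaluation restricts samples to log2(CPM+1) over DMR windows and runs
PCA, average-linkage dendrograms, and linear discriminant analysis in a
PCA-reduced space with covariance shrinkage, reporting leave-one-out
accuracy.

A synthetic-data generator produces genomes with realistic CpG-density
structure (1–3 CpG/100 bp background, 8–10 CpG/100 bp islands) and
NB-distributed counts with planted DMRs of known location, width
(1–3 windows) and fold change, so every stage is testable without
external data.

## Worked example

`python examples/01_simulate_and_test.py` simulates a 12 v 12 cohort on
a 2-Mb genome with 8 planted DMRs (fold change 3) and prints:

```
windows tested: 2000
estimated NB dispersion phi: 0.1000  (simulated at 0.1)
TMM factors span 0.987 - 1.013 (geometric mean 1 by construction)

most significant windows (the planted regions should dominate):
chrom   start     end      p_value  log2_fold_change        fdr_q
 chr1 1004000 1005000 1.803816e-19          1.813547 3.607632e-16
 chr1 1006000 1007000 4.188651e-18          1.743316 4.188651e-15
 chr1  192000  193000 2.694156e-17         -1.854311 1.796104e-14
 ...
```

The dispersion estimate recovers the simulated φ, and the smallest
p-values land inside planted regions with log2 fold changes near
±log2(3) ≈ ±1.58 (attenuated slightly by the prior count). The other
examples cover DMR calling and CpG density (`02`), cross-cohort overlap
(`03`), classification (`04`), and the full pipeline with its manifest
(`05`).

The same stages are available from the shell:

```
medipdmr simulate --seed 1 --out-dir sim
medipdmr run --seed 1 --out-dir run1
```

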
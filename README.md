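# medipseq

Quantification and analysis of MeDIP-seq methylomes, built around the study
design of leukemia methylome profiling: a small cohort of AML samples from
several cytogenetic subtypes compared against normal bone marrow, with
differential methylation assessed across promoters, gene bodies, CpG
islands (CGIs), CGI shores and repeat classes (SINE/LINE/LTR/satellite).

The package is self-contained: a synthetic-cohort generator produces a toy
genome, ground-truth methylomes with implanted differentially methylated
regions (DMRs), immunoprecipitation fragments and coupled expression
values, so every stage of the analysis can be exercised and validated
against known truth without any external data.

## What it computes

**Methylation quantification.** MeDIP coverage reflects methylated-CpG
content within roughly one fragment length, so raw read density cannot be
read as absolute methylation in regions of different CpG density. The
quantifier models the count of fragments covering the center of each
100-bp window as

```
y_p ~ Normal( r · Σ_w C[p,w] · m_w + b ,  σ_p² )
```

where `C[p,w]` sums the triangular coupling kernel `max(0, (L−d)/L)` over
the CpGs of window `w` at distance `d` from the center of window `p`,
`m_w ∈ [0,1]` is the unknown absolute methylation of window `w`, `r` is the
sample's calibrated fragments-per-coupling-unit scale and `b` the
nonspecific background. The prior combines a uniform marginal on each
`m_w` with an edge-preserving Laplace smoothness term on adjacent windows;
the posterior is explored by Metropolis-within-Gibbs and each callable
window (total coupling ≥ `c_min`) is reported as the posterior median with
an 80 % credible interval.

**Statistics.** Feature-level methylation is quantile-normalized and
variability-filtered, then tested with empirical-Bayes moderated t/F
statistics (limma-style variance shrinkage). A DMR is a feature with
uncorrected p < 0.05 and |Δ| > 0.25, the effect floor being the 99th
percentile of |Δ| rounded up to 0.05; Benjamini–Hochberg adjusted p-values
and a uniform+Beta mixture-model FDR estimate accompany every call.
Downstream analyses include Ward/Pearson sample clustering with
prediction-strength stability, five-band whole-genome profiles compared by
Fisher's exact test, repeat CpG-density enrichment (exact Mann–Whitney),
and binned methylation–expression correlation with exact Spearman
statistics for small cohorts.

## Worked example

```python
import numpy as np
from medipseq import (BatmanModel, compute_coupling, generate_genome)
from medipseq.simulate import CohortDesign, generate_truth, simulate_fragments
from medipseq.fragments import filter_fragments

genome = generate_genome(seed=1)                      # 2 chromosomes x 500 kb
truth = generate_truth(genome, CohortDesign(), seed=2)  # 16 samples, 5 groups
coupling = compute_coupling(genome, fragment_length_mean=450.0)

raw = simulate_fragments(genome, truth, "t821_1", n_fragments=74_000, seed=10)
frags, report = filter_fragments(raw, mapq_min=10)
result = BatmanModel(frags, coupling).fit(seed=4)
print(result.summary())
```

```
Methylome fit for sample t821_1
  windows: 10000 total, 9437 callable (c_min = 0.5)
  calibration: r = 6.254 fragments/coupling, b = 2.436, sigma = 5.561 (2615 windows)
  sampler: 200 burn-in + 800 kept sweeps, acceptance 0.53
  mean callable score: 0.773
```

9437 of 10 000 windows carry enough CpG coupling to be callable; the
calibrated scale says one fully methylated coupling unit attracts ~6.3
fragments over a background of ~2.4, and the genome-wide mean score of 0.77
reflects the mostly methylated genome with unmethylated islands. Feeding
feature-level methylation into the differential model:

```python
from medipseq.annotate import aggregate_features
from medipseq.dmr import DifferentialMethylation

matrix = aggregate_features(tracks, genome)           # one track per sample
model = DifferentialMethylation(matrix, truth.group_labels)
res = model.fit(contrast=("rest", "NBM"))             # all AML-like vs control
print(res.summary())
```

```
Differential methylation: rest vs NBM
  features: 422 input, 310 tested (0 skipped with missing cells, 112 below variability threshold 0.0663)
  empirical Bayes: d0 = 4.86, s0^2 = 0.000175, residual df = 11
  DMR rule: p < 0.05 and |delta| > 0.25
  calls: 22 DMRs (13 hyper, 9 hypo); min adjusted p = 2.41e-16
  p-value mixture: lambda = 0.081, Beta(0.111, 17.824), logL = 2492.5; FDR at p<0.05 = 0.005
```

The 22 calls are dominated by hypermethylated CGIs — the implanted
AML-specific island hypermethylation — with the mixture model estimating a
sub-percent false discovery rate among them.

The same workflow runs end to end from the shell:

```bash
medipseq all --outdir run1          # simulate → quantify → … → expression
medipseq --set fragments.n_fragments=50000 quantify --outdir run1
```

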
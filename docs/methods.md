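# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the limitations of `medipseq`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and windowing conventions

All internal coordinates are 0-based half-open `[start, end)`; 1-based
inclusive coordinates appear only in GFF3 files. The genome is tiled with
non-overlapping 100-bp windows; a trailing partial window is dropped so the
grid is identical across samples. CpG methylation is treated as symmetric
across strands; fragments carry strand only as metadata.

## The quantification model

MeDIP enrichment at a genomic position reflects the methylated CpGs within
roughly one fragment length, weighted by the geometry of random fragment
placement. For a fragment known to cover a given CpG, with its anchor
point uniform along the fragment, the probability that it also covers a
position at distance `d` is `max(0, (L − d)/L)` with `L` the mean fragment
length — this triangular kernel is the coupling factor. Summing it over
the CpGs homed in window `w`, evaluated at the center of window `p`, gives
the banded coupling matrix `C[p, w]`; the row sum `C_tot` measures how much
methylated-CpG signal a window's center can receive at all.

The observation used in the likelihood is the number of filtered fragments
covering each window **center** (not ≥1-bp overlap): for center counts the
triangular kernel is exactly the fragment-placement probability, so the
mean function

    E[y_p] = r · Σ_w C[p,w] · m_w + b

is consistent by construction. (Per-window coverage reported in output
tracks remains the conventional ≥1-bp-overlap count.) The noise is
Gaussian with a Poisson-matched, per-window scale
`σ_p = sqrt(max(smoothed coverage, 2))`.

### Calibration

`r` (fragments per coupling unit) and `b` (background) are sample-specific.
`b` is the mean center-coverage of windows with almost no coupling
(`C_tot < c_min/2`), where only nonspecific pull-down can place fragments.
`r` is anchored on the *near-fully-methylated* population: starting from an
upper-quartile ratio `(y − b)/C_tot` over the upper half of the coupling
distribution, windows whose implied methylation lies in [0.8, 1.2] are
selected and `r` re-estimated as their median ratio, iterated a few times.
Scores are therefore absolute relative to the near-fully-methylated
reference state, the usual convention when MeDIP enrichment is normalized
against fully methylated regions. A naive regression of coverage on
coupling is badly biased here because the highest-coupling windows are CpG
islands, which are mostly unmethylated; the ratio-median iteration
deliberately climbs to the methylated envelope instead.

Two guards: a fitted non-positive scale raises a calibration error, and
`r` is floored at 8 background-noise standard deviations per median
coupling unit — the working signal-to-noise of genuine MeDIP enrichment.
The floor matters only for data with no detectable enrichment anywhere
(e.g. a fully unmethylated genome), which then correctly reads as
unmethylated rather than unidentified.

### Prior, sampler and output

Each window's methylation has a uniform marginal prior on [0, 1] plus an
edge-preserving Laplace (L1) smoothness term, `exp(−λ·|m_w − m_{w+1}|)`
with λ = 25, between adjacent windows that carry any coupling. Methylomes
are regionally coherent — islands, gene bodies and repeats are
plateau-like at the 100-bp scale — and at realistic depth (~1 CpG per
window) the deconvolution is under-determined without this structure; the
L1 form flattens plateaus without blurring island boundaries the way a
Gaussian penalty does. The posterior is explored by
Metropolis-within-Gibbs (reflective uniform proposals of half-width 0.1;
defaults 200 burn-in + 800 kept sweeps, chosen for stable medians at
desk-scale runtime; the sweep kernel is JIT-compiled). The reported score
is the posterior median, with an 80 % credible half-width. Windows with
`C_tot < c_min = 0.5` are reported missing regardless of coverage — below
that the likelihood barely constrains methylation. On a CpG-sparse genome
where windows are uncoupled, the marginal posterior has a truncated-Normal
closed form; the test suite checks the sampler against a grid-integrated
oracle to within 0.02.

### Saturation and reference validation

Saturation analysis splits the fragments into two disjoint halves,
subsamples both to a grid of depths (≤ 0.5 of the total), quantifies each
and correlates the two methylomes over co-callable windows; grid points
with fewer than 10 such windows are flagged unstable rather than dropped
silently. Reference validation maps per-site reference methylation (array
or bisulfite style values) to the window containing each site, partitions
the reference into 100 bins of width 1 %, and correlates per-bin mean
reference with per-bin mean score.

## The synthetic cohort

The generator is the package's study design, not a fixture.

**Genome.** Default 2 chromosomes × 500 kb; 50 genes, each with a 1-kb
promoter upstream of its TSS and a 3–8-kb body; one CGI per gene (60 %
promoter, 25 % intragenic, 15 % intergenic) plus intergenic extras; CGI
shores as 2-kb flanks (a TSS-upstream variant is available as
`shore_mode="tss_upstream"`); 40 repeats per class (SINE, LINE, LTR,
satellite) with family names, SINEs preferentially nested in gene bodies.
Background CpGs are placed as a clustered point process at ~1 per 100 bp;
CGIs are ~8× denser (validated ≥ 4× background). Everything is a pure
function of the seed.

**Truth methylomes.** Each window gets a truth class by center containment
with precedence CGI > promoter > shore > repeat > gene body > background.
Feature-level baselines are Beta draws: CGIs mostly unmethylated
(85 % from Beta(1.5, 12)), promoters bimodal (60 % unmethylated CGI-type,
40 % methylated CpG-poor type — without this spread the binned
methylation–expression analysis is degenerate), gene bodies/repeats/
background centered near 0.85–0.94, matching somatic bisulfite levels at
methylated CpGs and anchoring the calibration's fully-methylated reference.
With the default configuration ~84 % of gene-body truth scores exceed 0.6
and the SINE score distribution has its top band (>0.8) highest in the
control group.

**Design.** Five groups — four AML-like subtypes of 3 samples and 4
controls (NBM). The default DMR plan implants: shared AML CGI
hypermethylation (12 islands, Δ = +0.4), AML-wide hypomethylation of 22 %
of SINEs (Δ = −0.3; the top score band ends up ~20 points depleted in the
AML-like groups), and per-subtype DMRs in every feature class (promoters
+0.4, CGIs +0.45, gene bodies −0.3, shores ±0.3, repeats −0.3…−0.35).
Implants shift every window overlapping the target feature for the
affected groups; per-sample scores add Gaussian noise (sd 0.05) around the
group mean, truncated to [0, 1]. Implanted |Δ| is validated ≥ 0.25.

**Fragments.** With probability `background_rate` (default 0.05) a
fragment is placed uniformly; otherwise it is anchored on a CpG drawn with
probability proportional to its true methylation and positioned uniformly
among the starts covering that CpG — i.e. placement probability
proportional to covered methylated-CpG content. Lengths are
Normal(450, 100) truncated to [100, 1000] bp. 5 % of records are converted
to coordinate-identical flagged duplicates and 5 % get mapping quality
below 10, so the read filter (duplicate removal, mapq < 10 exclusion) is
exercised deterministically.

**Expression.** `log2 expression = baseline + coupling × promoter
methylation + noise`, with per-gene baselines Normal(8, 1.5), default
coupling −4 and noise sd 0.5 — the inverse promoter-methylation regime.

What the generator does **not** emulate: nucleotide sequence and alignment
artifacts, copy-number structure, fragment-length biases that depend on
GC, inter-sample batch effects beyond what quantile normalization removes,
and biological correlation between methylation and expression beyond the
linear promoter coupling. Passing tests therefore demonstrate the
correctness and calibration of the analysis machinery under the stated
generative assumptions, not performance on real libraries.

## Statistical workflow

Quantile normalization equalizes the per-sample distributions of
feature-level methylation (rows with missing cells are passed through
unnormalized and flagged); ties receive the mean of their tied reference
values. The variability filter removes, per feature class, features whose
across-sample range falls below the class mean of per-feature standard
deviations (strict inequality, so an all-constant class removes nothing).

Variance shrinkage follows the standard moderated-t derivation: pooled
within-group residual variances `s_g²` with `d_g` df; `d0` and `s0²`
estimated by the method of moments on `log s_g²` (trigamma inversion by
Newton iteration); `s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g)`; moderated t
with `d0 + d_g` df, and moderated F for the omnibus comparison. Contrasts
are each subtype against all other samples, plus all AML-like samples
against NBM. Deltas are computed on the normalized scale by default
(switchable via `normalize=False`).

A DMR requires uncorrected p < 0.05 **and** |Δ| > 0.25, both strict. The
0.25 floor reproduces the derivation from the |Δ| distribution: the 99th
percentile (linear interpolation) rounded *up* to the nearest 0.05 (0.23 →
0.25). BH adjustment is reported alongside. The p-value mixture
`f(p) = λ + (1−λ)·Beta(p; a, b)` is fitted by Nelder–Mead maximum
likelihood from three starts; because a near-uniform Beta is
unidentifiable against the uniform null, the null-heavy solution λ = 1 is
reported (flagged) unless the mixture beats the pure-null model by 3 log
units with a decreasing (a < 1) signal component. The FDR at the call
threshold is `λ·p_thresh / ecdf(p_thresh)`.

## Clustering and profiles

Sample distance is `1 − Pearson r` between feature profiles; Ward linkage
is applied to that matrix via the Lance–Williams recurrence (the classical
Ward criterion assumes Euclidean input; combining it with correlation
distance follows methylome-study practice). Cluster features are DMRs
with p < 0.001. Prediction strength over 5 folds clusters the train and
test halves separately, assigns test samples to the nearest train centroid
in correlation distance, and takes the worst per-test-cluster proportion
of co-assigned pairs; ps(1) = 1 by definition, singleton test clusters
count as 1 and are tallied. Values above ~0.8 indicate well-separated
clusters.

Whole-genome profiles categorize scores into five bands (<0.2, 0.2–0.4,
0.4–0.6, 0.6–0.8, 0.8–1.0; left-closed, last band closed, so 0.2 falls in
the second band); group panels average samples per window before binning.
Group profiles are compared with Fisher's exact test — full enumeration
over fixed-margin tables when at most 10⁶ candidates, otherwise a seeded
Monte-Carlo exact test — applied by default to the rounded band
*percentages* (row totals ≈ 100): on raw genome-scale window counts any
difference is hyper-significant, and only the shape comparison can produce
the near-unity p-values a well-matched global profile should give.
Binning is over windows, not features.

## Expression integration

Per sample, genes are banded by methylation (<0.4, 0.4–0.6, 0.6–0.8,
≥0.8) and band means of methylation and expression are correlated
(Pearson); the analysis is per-sample, with a pooled summary. The first
band is read as "<0.4" — the natural complement of the other three bands.
Over/under-expressed gene sets are compared by two-sided Mann–Whitney on
promoter methylation (sets must be disjoint, ≥ 3 genes each). Locus-level
correlation is Spearman's ρ with an exact permutation p for n ≤ 9 (full
enumeration of rank pairings) and the t-approximation above that. The
exact Mann–Whitney path (pooled n ≤ 20) enumerates group assignments with
average-rank tie handling.

## Problem sizes and determinism

Default study: 2 × 500 kb genome, 16 samples; quantifier checks run at 30×
usable depth (74 000 raw fragments per sample before the ~10 %
duplicate/low-quality contamination) on three representative samples; the
statistical stages run on a feature-rich 2 × 1.5 Mb, 150-gene cohort built
from ground-truth scores so that their operating characteristics are
measured independently of quantifier noise. Every generator and sampler
is a pure function of its explicit seed; the pipeline derives per-sample
seeds from the named config seeds, and re-running a stage with the same
configuration reproduces its outputs byte-for-byte.

## Known limitations

* One methylation parameter per 100-bp window: windows straddling sharp
  island boundaries mix two methylation states and absorb the averaging
  error.
* The calibration convention ties the score scale to the sample's own
  near-fully-methylated population; a genome without such a population
  (globally intermediate methylation) would be rescaled toward it.
* The Gaussian observation model underweights the heavy upper tail of
  coverage at strongly enriched islands; heteroscedastic σ mitigates but
  does not remove this.
* Prediction strength with 16 samples and 5 folds has coarse granularity
  (test halves of 8); ps values for k > 4 are not meaningful at this n.
* The mixture FDR assumes p-values are independent draws from the mixture;
  correlated features (overlapping shores and islands) make it slightly
  optimistic.
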
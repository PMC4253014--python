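# Methods

## The simulation model

A two-condition counting experiment is described by the entity count EC,
the abundance profile (relative abundances summing to 1), the perturbation
(which entities change, and by what fold), the per-condition replicate
count NR, the depth ND (average data-points per entity; a sample's total
count is drawn uniformly from 0.9–1.1 × ND·EC), and the replicate
variability SV.

**Perturbation.** Fold-changes f > 1 are drawn from a Uniform, Log-normal
or Normal distribution (rejection-sampled to stay above 1), or supplied as
an empirical list. A perturbed entity's abundance x becomes x/√f in
condition 1 and x·√f in condition 2 (directions swapped for
down-regulation), so the geometric mean of the two condition means stays
at x and their ratio is exactly f; each condition vector is then
renormalized to sum to 1 independently. The recorded labels and
fold-changes are the ground truth that evaluation scores against. Note
that renormalization means an "unchanged" entity's expected count ratio
between conditions is not 1 whenever the perturbation is asymmetric —
which is precisely why normalization matters and why the non-DA oracle is
defined on counts, not on nominal fold-changes.

**Count models.**

* *Multinomial*: each replicate is one multinomial draw from the condition
  mean vector. Pure counting noise; appropriate when replicate
  variability is negligible.
* *NB*: each entity × replicate count is an independent draw with mean
  μ = abundance·ND·EC and variance μ + φμ². No within-sample coupling.
* *Full* (default): each replicate first receives latent biological means
  drawn from the Gamma mixing component of the NB — Gamma(1/φ, φμ), which
  has mean μ and variance φμ² and degenerates to the constant μ at φ = 0 —
  and the latent vector is renormalized and sampled once from a
  multinomial at the replicate's depth. Marginally each count is ≈
  NB(μ, φ); jointly, entities compete for a fixed total as they do on a
  sequencer, and at SV = 0 the model reduces exactly to the Multinomial
  model. We deliberately do **not** draw the latent means from a discrete
  NB: that would add shot noise twice (once in the latent draw, once in
  the multinomial) and break the multinomial limit.

**Dispersion.** SV is the NB overdispersion φ (dimensionless; variance =
μ + φμ²). Bulk RNA-seq typically lives in φ ∈ (0.1, 0.9); metagenomic
gene profiles can exceed 5. A scalar SV may be applied to all entities
(`dispersion_mode="common"`) or, by default, used as the mean of a
per-entity Gamma draw (shape 1 by default, i.e. Exponential(SV)),
reflecting dispersion heterogeneity across genes. A per-entity vector is
accepted directly — this is how estimated dispersion models re-enter
simulation.

**Outliers.** Optionally, up to a chosen fraction of entities (15% when
enabled) have one randomly chosen sample's count multiplied or divided by
a factor (default 100), rounded half-up with a floor at zero — the
single-sample aberrations commonly seen in real count data.

**Model-free simulation.** When no parametric model fits the replicate
variability (single-cell RNA-seq being the canonical case), replicate
counts for a target entity are subsampled from the pilot entity with the
closest average count, scaled by the ratio of means and stochastically
rounded (floor + Bernoulli on the fraction, keeping expectations
unbiased). When the pilot has fewer than NR × n_sims replicates, values
are drawn instead from the matched entity's mean-group (20 equal-occupancy
bins on log average count). The grouping is justified empirically by
`validate_grouping`: mean-scaled counts of an entity are KS-compared to
the pooled scaled counts of its 10 nearest mean-neighbours ("similar" = no
rejection at the chosen α, default 0.05), and the similar fraction under
nearest-neighbour grouping should far exceed the fraction under random
grouping. This holds when dispersion follows a mean trend; with
mean-independent dispersion heterogeneity the grouping carries no
information and the check correctly reports no advantage.

## Estimating parameters from pilot data

* *Profile*: pooled frequencies across pilot samples (0.5 pseudocount for
  all-zero entities); entities below 10 counts in every sample are
  filtered first.
* *Dispersion*: per-entity method-of-moments φ̂ = max(0, (s² − m)/m²) on
  within-condition depth-normalized counts, pooled across conditions with
  degrees-of-freedom weights. The mean-dispersion trend is a running mean
  (window 51) over mean-ranked entities — a mean, not a median, because
  per-entity moment estimates under a Gamma dispersion prior are
  right-skewed and a median would systematically understate the
  dispersion level fed back into simulation. The scalar summary is a 10%
  trimmed mean over entities with normalized mean ≥ 1. For testing,
  per-entity values are shrunk halfway toward the trend.
* *Perturbation*: the built-in NB exact test (after mode normalization,
  5% FDR) supplies the empirical fold-change list of significant entities;
  the list is then topped up with randomly chosen non-significant entities
  of fold-change > 1.5 (either direction) until it reaches the expected
  number of truly DA entities, estimated as max over ranks k of
  k·(1 − q₍ₖ₎) from the BH q-value profile. Empirical fold-changes keep
  their observed direction when re-applied.

## Mode normalization

UFCs are per-entity log2 ratios of average counts (condition 2 over 1),
with a 0.5 pseudocount added to both means when either is zero. The
density of UFCs is estimated with a Gaussian kernel on a 512-point grid
spanning the data range ± 3 bandwidths. Numerical details that matter:

* *Mode counting*: a local maximum counts as a mode only with topographic
  prominence ≥ 10% of the density maximum. This screens out both isolated
  extreme UFCs (single-entity spikes in the tails) and low-prominence
  ripples on a wide cluster's shoulder, either of which would masquerade
  as the expected down/null/up triple.
* *Bandwidth annealing*: bandwidths run from 0.5 down to 0.02 in steps of
  0.02 (log2 units). Mode counts are grouped into contiguous runs; a
  count is trusted only if it persists for at least max(3, ⌈longest
  run/3⌉) consecutive steps, because real clusters fragment at small
  bandwidths and a count of exactly 3 that appears for a single step is
  an artifact. Among trusted runs, the count closest to 3 wins (ties to
  larger bandwidths); the run's smallest bandwidth supplies the working
  density.
* *Mode choice*: odd counts take the middle mode (the presumed null
  cluster); even counts take the mode with the narrowest peak and raise
  `bimodal_warning`. Peak widths (full width at half maximum) are
  measured at the run's *largest* bandwidth: at cluster scale the null
  peak — replicate noise only — is never wider than a DA peak (noise plus
  fold-change spread), whereas at sharp bandwidths a tight-fold-change DA
  cluster can look spuriously narrow.
* *Location refinement*: with two or more modes, the chosen mode's
  location is the median UFC of the valley-bounded segment containing the
  peak. The raw apex is biased toward the heavier neighbouring DA cluster
  by its overlapping tail (measured at +3–8% on the factor ratio under
  50%-up/25%-down perturbations at NR=3); the segment median removes
  essentially all of that bias. A unimodal density keeps its apex, since
  without valleys a global median would absorb one-sided DA mass.
* *Factors*: the between-condition scale is the geometric mean of the raw
  condition-mean ratios of the 10 entities nearest the mode; within a
  condition, samples scale by library size relative to the condition's
  geometric-mean depth; the factor vector is reported with geometric
  mean 1.

Mode normalization assumes a discernible null cluster. With ≳ 80% of
entities perturbed in one direction, or with fewer than ~20 entities, the
mode is unidentifiable and the method fails or warns accordingly.

## The test panel

All tests consume factor-normalized counts (counts divided by per-sample
factors) and emit p-values, BH q-values and a log2 fold-change
(condition-2 over condition-1 means, 0.5 pseudocount).

* *NB exact*: condition sums of normalized counts are rounded and
  compared by the exact conditional test. For iid NB counts with common
  dispersion φ, one condition's sum given the total s is
  BetaBinomial(s, n₁/φ, n₂/φ); the p-value doubles the smaller tail
  (capped at 1). Tails are enumerated exactly for s ≤ 10,000; for larger
  totals the s→∞ limit — the condition-1 proportion is Beta(n₁/φ, n₂/φ) —
  is used, with a half-count continuity correction. At φ ≤ 1e-10 the law
  is Binomial(s, n₁/(n₁+n₂)) and the exact binomial test is used at any
  s. Dispersion defaults to the pilot-estimated model (per-entity, shrunk
  0.5 toward the trend); with single replicates a dispersion must be
  supplied.
* *Wilcoxon*: two-sided rank-sum per entity; exact distribution when both
  groups have ≤ 10 samples and no ties, tie-corrected normal
  approximation otherwise; requires ≥ 3 samples per group.
* *Welch t*: on log2(normalized count + 1), Welch–Satterthwaite degrees
  of freedom. Zero variance in both groups yields p = 1 at equal means
  and p = 0 (warned) otherwise.
* *Fisher pooled*: per entity, the 2×2 table of (entity vs all-other)
  pooled normalized counts per condition, two-sided Fisher exact;
  chi-square fallback (warned) for margins beyond 1e8. Pooling ignores
  replicate variability: the test is calibrated only when replicates
  carry no extra-multinomial variation, and is anticonservative under
  overdispersion — which is why the package's null-calibration check runs
  the Full model at SV = 0 (the regime where every panel member's
  sampling assumptions hold).

External tools can be registered under the same contract
(`register_dat`); duplicate names are rejected.

## Evaluation and design

Scores are −p, so the AUC is the Mann–Whitney probability that a random
truly-DA entity outranks a random null one (ties get half credit);
ROC/precision–recall curves come from the same ranking. Sensitivity at
FDR q is the fraction of truly DA entities with q-value ≤ q; actual FDR
is the truly-null fraction among entities called at q (0 with a flag when
nothing is called). Entities removed by the count filter are excluded
from scoring. The separability F-score is F_between/F_within with sample
variances; zero within-variance with distinct means returns +inf.

The design grid derives one 31-bit seed per (cell, simulation) by CRC-32
of the tuple, so cells are independent and individually reproducible, and
the whole report is a pure function of (grid, seed). Target attainment
uses the mean AUC over a cell's simulations (10 by default). The
saturation point of a series is the smallest design value within 5% of
the maximum observed metric. Recommendations minimize NR·ND among cells
meeting the target, preferring smaller NR, then smaller ND, then the
lexicographically first test name. At NR=1 the NB exact test receives the
grid's own simulation dispersion, since nothing can be estimated from
single replicates.

## Benchmark protocol sizes

The bundled protocols (`countdesign.benchmarks`) use 10 simulations for
the replicate-sweep and pilot-fidelity studies, 20 for normalization
accuracy, and 10 for null calibration — matching the repetition counts of
the studies they reproduce; each completes in seconds to a couple of
minutes on one core.

## What the synthetic data does and does not show

The generators emulate power-law abundance, NB replicate variability with
gene-level dispersion heterogeneity, depth variation, asymmetric
perturbation, and gross single-sample outliers. They do not model GC or
length bias, mapping ambiguity, batch structure, zero inflation beyond
what the NB induces, or correlated expression between entities (beyond
the multinomial sum constraint). Passing tests therefore demonstrate
correctness of the machinery and behaviour under the stated generative
assumptions — not performance guarantees on any particular real dataset;
the model-free path and pilot-learning exist precisely to anchor the
simulation in a user's own data.

## Known limitations

* At high dispersion the discrimination ceiling is intrinsic: under the
  NB model with φ = 0.85 and five replicates, fold-changes of 3–5 yield
  AUC ≈ 0.90–0.91 for the exact conditional test *even when the true
  per-entity dispersions and the ideal normalization are supplied*
  (reaching AUC 0.95 under this protocol empirically requires effective
  common dispersion ≤ ~0.5). Headline AUC figures quoted for comparable
  settings elsewhere are only attainable if "sample variability" maps to
  a lower effective dispersion than the φ used here.
* The realized FDR of the NB exact test overshoots the nominal q at small
  NR because moment dispersion estimates are noisy; shrinkage halves but
  does not remove this.
* Mode normalization's factor ratio retains per-dataset noise of ~10%
  (relative) under 75%-DA perturbations at NR=3 — the null cluster then
  holds only a quarter of the entities and overlaps both DA clusters.
  Averaged over repeated designs it is unbiased; single-dataset factors
  should be read together with the `bimodal_warning` and `n_modes` flags.
* `learn_perturbation_from_data` under-counts weakly perturbed entities
  when the pilot is underpowered (detection bias); re-simulated datasets
  are then slightly easier than the truth. Measured on the pilot-fidelity
  protocol this contributes a ~4–5% relative AUC error.
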
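# Methods

This note records the statistical procedures the package implements, the
assumptions behind the synthetic-data generator, and the design choices made
where the underlying methodology admits more than one reading.

## Somatic filtering

Calls are eliminated by three rules applied in sequence: (R1) synonymous
functional class, or intergenic/intronic region; (R2) population allele
frequency ≥ 0.002; (R3) strand bias, support reads < 5, or VAF below the
sample-type floor (0.05 tumor, 0.01 plasma). Choices worth stating:

- Each removed call is attributed to the **first** rule it violates, so
  per-rule counts partition the removals and are well defined.
- The ExAC and gnomAD frequencies are collapsed into one field as the maximum
  of available values; the same 0.002 cutoff applies to both sources.
- A missing population AF is treated as 0: absence from the population
  databases is evidence of rarity, the standard annotation convention.
- The VAF floors are exclusive on removal (a call **at** exactly 0.05/0.01
  survives); the population-AF cutoff is inclusive on removal (≥ 0.002 goes).
- Strand bias is consumed as a precomputed boolean; its computation belongs
  to the upstream caller.

## CNI (copy-number instability)

Per sample: raw bin counts are divided by the relative bin length, then by a
rolling-median GC trend (bins ordered by GC fraction; window a configurable
fraction of the panel, default 0.3; trend rescaled to mean 1). Corrected
counts are median-centered — so CNI measures *regional* imbalance, not global
depth — and turned into log2 ratios against the per-bin median of the
centered baseline cohort. Each bin's ratio is standardized by the baseline
cohort's per-bin mean and SD (ddof = 1). The instability threshold is the
95th percentile of the pooled baseline Z values plus twice their SD, computed
once from the baseline pool; bins whose Z exceeds it are unstable and their
Z-scores are summed. CNI ≥ 0 by construction (empty set ⇒ 0).

Ambiguities resolved as package choices, each behind a flag:

- "Z-score versus a baseline group" is read as per-bin standardization by the
  baseline mean/SD — the only reading that yields a per-sample, per-region
  Z-score. The pooled-baseline threshold is the default; a per-sample
  threshold variant can be obtained by passing that sample's own Z vector.
- The threshold is one-sided (gains) by default; `two_sided=True` thresholds
  |Z| instead.
- GC correction uses a rolling-median trend rather than a spline: it is
  deterministic, monotone-robust and dependency-light; downstream contracts
  only need the bias removed, not a particular smoother.
- Bins with zero baseline SD are masked with a warning rather than producing
  infinite Z-scores.

## MATH

MAD(VAF)/median(VAF) over VAFs inside the inclusive [0.02, 1.0] window. The
default is this literal ratio; `convention="mroz"` applies the 1.4826
Gaussian-consistency constant and the ×100 percentage scale used in the
original MATH literature. A sample with no VAF in the window returns a
missing value, never 0 — zero would assert homogeneity that was not observed.

## TMB

mutation_count × 10⁶ / panel exonic bases, with the numerator taken from the
**post-filter** retained call set; the coupling to the filtering stage is
explicit in `compute_metrics_table`.

## Response discrimination

Alteration matrices encode SNV presence (1 iff ≥ 1 retained call in the
gene) or signed CNV levels; genes sort by descending alteration frequency and
all-constant genes are dropped (no PCA signal). PCA is column-centered SVD
with a deterministic sign convention — each component's largest-|loading|
entry is positive — so outputs are reproducible without seeds. "Principal
component genes" are those with |loading| above a configurable quantile
(default top 25%) on components 1–2. The ROC AUC uses the Mann–Whitney
pairwise-probability form with the better group as the positive class; ties
count ½. Clustering is 2-means with farthest-pair initialization, again
deterministic. The response grades CR/PR collapse to "better" and SD/PD to
"poor" throughout.

## nCTPS signature and survival

nCTPS(s) = PC1(s) + PC2(s) from a centered PCA over the signature-gene
submatrix — the reading of a "sum of the two component scores" that yields
one number per patient. Genes are centered but not variance-scaled by
default (`scale_unit_variance` flag available). Kaplan–Meier estimation and
the k-group log-rank test are delegated to lifelines; the log-rank follows
the O−E / hypergeometric-variance form with df = k − 1.

The cutoff is a **maximally selected rank statistic**: per-subject log-rank
scores a_i = δ_i − Λ̂(t_i) (Nelson–Aalen cumulative hazard), and for each
candidate cutoff (midpoints of consecutive unique scores whose splits stay
inside the 10–90% quantile window) the standardized statistic
|S − m·ā| / √(m(N−m)/(N(N−1)) · Σ(a_i − ā)²) with S the score sum above the
cutoff. The maximizer is returned, ties broken toward the more balanced
split. This is the linear-rank formulation of maximally selected statistics,
which is not identical to maximizing the hypergeometric chi-square log-rank
over splits; on separable data the rank form selects the cutoff in the
separating gap, which is the behavior the survival-cutoff literature (and
the R maxstat package) defines. The p-value later computed at a selected
cutoff is optimistic by construction and is labeled uncorrected;
`maxstat_permutation_p` provides a permutation-adjusted value, and a
`selected_under_null` flag marks maxima below the 1.96 normal bound.
Censoring ties at event times follow the standard convention (events
precede censorings).

The stratified analysis crosses the nCTPS dichotomy with a TMB dichotomy
(its own maxstat cutoff, or a user threshold) and runs the k-group log-rank
over the populated cross-classes, dropping empty ones with a warning.

## Multi-omics screen

- Chi-square CNV screen: condition × {altered, neutral} 2×2 by default
  (`collapse="full"` keeps all five states), Pearson chi-square without
  continuity correction; genes with a zero marginal are untestable, never
  significant.
- Dosage association: states map to deletion / normal / gain / amplification
  with deep deletion merged into deletion (a four-class dosage scheme);
  exactly two usable groups → two-sided rank-sum, more → Kruskal–Wallis with
  tie correction; groups under 2 samples are excluded.
- BH (Benjamini–Hochberg) adjustment across testable genes in every screen;
  significance at p < 0.05.
- Drug-sensitivity correlation: Pearson by default (Spearman flag), two-sided
  p from the t transform, ≥ 3 shared cell lines required per pair. Positive r
  means higher expression with a higher response score; whether that encodes
  sensitivity depends on the response source's sign convention, which the
  caller must supply.

## Synthetic-cohort generator

What it emulates, and with which laws:

- **Panel**: equal-length, non-overlapping target bins with uniform GC in a
  configurable range. Defaults (120 bins × 2 kb in the demo) keep runtimes in
  seconds; a realistic 1086-gene panel is emulated in the acceptance script
  with a 1.5 Mb layout.
- **Bin counts**: expected count = depth × relative length × GC factor ×
  copy-ratio multiplier; the GC factor is a smooth unimodal curve peaking at
  GC = 0.5 (exp(−strength·((gc−0.5)/0.5)²)). Counts are negative-binomial
  (dispersion 50 by default — mild overdispersion typical of capture panels;
  `nb_dispersion=None` gives the Poisson special case). Baseline samples
  never carry events; events covering no panel bin are ignored with a
  warning and recorded.
- **Variants**: per-sample true count = round(rate × panel bases / 10⁶);
  VAFs follow Beta(2, 8) — a right-skewed law with most VAFs in the 5–40%
  range, chosen for testability since no distributional facts about real
  plasma VAF spectra are assumed — conditioned above the filtering floor so
  every clean record passes all rules. Contaminants each violate exactly one
  named rule, so per-rule filter behavior is attributable in tests.
- **Expression/survival**: expression = per-gene baseline + slope × CNV
  state + Gaussian noise; survival exponential with hazard ratio between the
  response groups; censoring by an independent exponential whose rate is set
  so the expected censored fraction equals `censor_rate` exactly
  (μ = λ·c/(1−c)).

What it does **not** emulate: read-level artifacts (mappability, duplicates),
subclonal structure beyond the VAF law, segment-level CNV calling,
non-exponential hazards, and batch effects. Passing tests therefore
demonstrate that the statistics recover what they are defined to measure
under their stated assumptions, not that those assumptions hold in any given
clinical cohort.

## Problem sizes and determinism

The replicate-based properties use 8 + 8 samples on a 60-bin panel over 100
seeded replicates (CNI separation; PC1-AUC recovery with a 2-SD planted
effect), 200 seeds of n = 40 for the null calibration of the stratified
4-class log-rank, and 1000 genes of n = 30 for the dosage-null uniformity
check — sizes at which the asymptotic approximations involved are already
serviceable and the full suite runs in well under a minute. All generator
randomness flows through `numpy.random.default_rng(seed)`; PCA signs,
k-means initialization and maxstat tie-breaks are deterministic by
construction, so identical seeds give bit-identical outputs end to end.

## Known limitations

- The CNI threshold rule inherits the ambiguity of its verbal definition;
  both the percentile/SD statistics and sidedness are exposed rather than
  hidden.
- The uncorrected log-rank p at a maxstat-selected cutoff overstates
  significance; use the permutation adjustment when the cutoff is not
  prespecified.
- The chi-square screen treats samples as independent; paired tumor/normal
  designs would need a matched test.
- `dosage_association` is a marginal per-gene test; no attempt is made to
  model gene–gene correlation in the FDR control beyond BH's robustness.
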
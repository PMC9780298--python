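"""nCTPS signature scoring and survival stratification.

Simulates a 100-patient expression cohort in which twelve signature genes
are dosage-coupled to group-differential copy-number states and survival
follows an exponential law with a hazard ratio of 3 between the groups.
Scores every patient (nCTPS = PC1 + PC2 over the signature genes), selects a
maximally selected rank-statistic cutoff, and runs the log-rank test plus
the 4-class stratified analysis against a second marker.
"""

import warnings

import numpy as np

from ctdna_chemoscore import cohort
from ctdna_chemoscore.survival import (
    assign_high_low,
    compute_nctps,
    logrank_test,
    maxstat_cutoff,
    stratified_prognosis,
)

warnings.simplefilter("ignore")
samples = [f"P{i:03d}" for i in range(100)]
groups = {s: ("better" if i < 50 else "poor") for i, s in enumerate(samples)}
genes = [f"SIG{i:02d}" for i in range(12)] + [f"BG{i:02d}" for i in range(28)]
states = cohort.generate_cnv_states(genes, samples, groups, signal_genes=genes[:12],
                                    effect=1.5, seed=1)
expression, clinical, truth = cohort.generate_expression_survival(
    samples, states, groups, dosage_slope=1.0, noise_sd=0.5,
    baseline_hazard=0.1, hazard_ratio=3.0, censor_rate=0.2, seed=2,
)

sig = compute_nctps(expression, genes[:12])
clin = clinical.set_index("sample")
scores = sig.nctps.reindex(clin.index)
cutoff, stat, under_null = maxstat_cutoff(scores, clin["time"], clin["event"])
sig.apply_cutoff(cutoff)
res = logrank_test(sig.high_low.reindex(clin.index), clin["time"].to_numpy(),
                   clin["event"].to_numpy())
print(f"maxstat cutoff = {cutoff:.3f} (standardized statistic {stat:.2f}, "
      f"under-null flag {under_null})")
print(f"log-rank: chi2 = {res.statistic:.2f}, df = {res.df}, "
      f"p = {res.p:.2e} (uncorrected for cutoff selection)")

second = expression.loc[genes[:12]].mean(axis=0).reindex(clin.index)
cut2, _, _ = maxstat_cutoff(second, clin["time"], clin["event"])
strat = stratified_prognosis(sig.high_low.reindex(clin.index), assign_high_low(second, cut2),
                             clin["time"].to_numpy(), clin["event"].to_numpy())
print(f"stratified 4-class log-rank: chi2 = {strat.statistic:.2f}, p = {strat.p:.2e}")
print("per-class sizes:", strat.n_per_group)

# The simulated hazard ratio of 3 shows up as a highly significant split at
# the selected cutoff; the stratified test refines it across both markers.
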
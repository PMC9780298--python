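import numpy as np
import pandas as pd
import pytest

from ctdna_chemoscore import cohort


@pytest.fixture
def small_panel():
    return cohort.generate_panel(n_bins=40, bin_length=500, gc_range=(0.3, 0.7), seed=11)


@pytest.fixture
def toy_groups():
    samples = [f"T{i:02d}" for i in range(16)]
    return {s: ("better" if i < 8 else "poor") for i, s in enumerate(samples)}


def make_separation_cohort(seed: int, multiplier: float = 2.5, n_event_bins: int = 5):
    """Panel cohort where the 8 'better' samples carry multi-bin copy gains
    and the 8 'poor' samples carry none."""
    rng = np.random.default_rng(seed)
    panel = cohort.generate_panel(n_bins=60, bin_length=500, gc_range=(0.35, 0.65), seed=seed)
    test = [f"T{i:02d}" for i in range(16)]
    better, poor = test[:8], test[8:]
    events = []
    bins = panel.bins
    for s in better:
        for _ in range(2):
            start = int(rng.integers(0, panel.n_bins - n_event_bins))
            rows = bins.iloc[start : start + n_event_bins]
            events.append(
                cohort.CnvEvent(
                    s, rows.iloc[0]["chrom"], int(rows.iloc[0]["start"]),
                    int(rows.iloc[-1]["end"]), multiplier,
                )
            )
    bc, truth = cohort.generate_bin_counts(
        panel, n_baseline=8, n_test=16, cnv_events=events,
        gc_bias_strength=0.8, depth_mean=150.0, seed=seed + 1,
    )
    groups = {s: ("better" if s in better else "poor") for s in test}
    return bc, groups, truth


def make_cnv_feature_cohort(seed: int, delta: float, n_genes: int = 30, n_signal: int = 6):
    """Continuous gene-level CNV features for 8+8 samples; the signal genes
    are shifted by +delta (in units of the per-gene noise SD) in the better
    group."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i:02d}" for i in range(16)]
    groups = {s: ("better" if i < 8 else "poor") for i, s in enumerate(samples)}
    genes = [f"G{i:02d}" for i in range(n_genes)]
    values = rng.normal(0, 1, size=(n_genes, 16))
    for gi in range(n_signal):
        for si, s in enumerate(samples):
            if groups[s] == "better":
                values[gi, si] += delta
    return pd.DataFrame(values, index=genes, columns=samples), groups
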
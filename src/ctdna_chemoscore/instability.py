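"""Per-sample genomic-instability metrics from panel data.

CNI (copy-number instability): raw bin counts are GC-corrected and
length-normalized, median-centered, turned into log2 ratios against a
baseline-cohort reference, standardized per bin against the baseline cohort
(Z-scores), and the Z-scores of "unstable" bins — those above the 95th
percentile of the pooled baseline Z distribution plus twice its standard
deviation — are summed.

MATH (mutant-allele tumor heterogeneity): median absolute deviation of the
somatic VAFs divided by their median, over VAFs in [2%, 100%].

TMB (tumor mutational burden): retained somatic mutation count x 1e6 /
panel exonic base number, i.e. mutations per megabase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BinCountSet, PanelDesign

__all__ = [
    "InstabilityMetrics",
    "gc_correct_and_normalize",
    "compute_log2_ratios",
    "compute_cni",
    "cni_for_cohort",
    "compute_math",
    "compute_tmb",
    "compare_groups_mannwhitney",
    "compute_metrics_table",
]


@dataclass
class InstabilityMetrics:
    sample: str
    cni: float
    unstable_bins: set[int] = field(default_factory=set)
    math: float | None = None
    tmb: float | None = None
    mutation_count: int | None = None


def gc_correct_and_normalize(
    panel: PanelDesign,
    counts: np.ndarray,
    window_fraction: float = 0.3,
) -> np.ndarray:
    """Remove GC-dependent coverage bias and target-length effects.

    Counts are first divided by the relative bin length, then by a
    rolling-median GC trend (bins ordered by GC fraction, window a fraction of
    the panel, trend rescaled to mean 1). Deterministic and dependency-light;
    the output should carry no monotone association with GC beyond noise.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    if not counts.any():
        raise ValueError("all-zero counts: nothing to correct")
    n = panel.n_bins
    if counts.shape[0] != n:
        raise ValueError("counts length must match panel bin count")
    if n < 8:
        raise ValueError("need >= 8 bins to fit the GC trend")
    window = max(3, int(round(window_fraction * n)))
    if window > n:
        raise ValueError("smoother window exceeds bin count; reduce window_fraction")
    if window % 2 == 0:
        window += 1

    lengths = panel.lengths.astype(float)
    length_factor = lengths / np.median(lengths)
    per_len = counts / length_factor

    gc = panel.bins["gc_fraction"].to_numpy()
    order = np.argsort(gc, kind="stable")
    trend_sorted = (
        pd.Series(per_len[order]).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    trend = np.empty(n)
    trend[order] = trend_sorted
    trend = np.where(trend <= 0, np.nan, trend)
    trend = trend / np.nanmean(trend)
    trend = np.where(np.isnan(trend), 1.0, trend)
    return per_len / trend


def compute_log2_ratios(
    corrected: np.ndarray,
    baseline: np.ndarray,
    median_center: bool = True,
) -> np.ndarray:
    """log2 of sample over reference per bin, after median-centering both so
    the ratio reflects regional change rather than global depth. Bins with a
    non-positive reference level are masked (NaN) with a warning."""
    corrected = np.asarray(corrected, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if corrected.shape != baseline.shape:
        raise ValueError("sample and baseline vectors must be congruent")
    if median_center:
        corrected = corrected / np.median(corrected)
        baseline = baseline / np.median(baseline)
    bad = baseline <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} bins with non-positive baseline level masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad | (corrected <= 0), np.nan, np.log2(corrected / baseline))
    return out


def compute_cni(
    sample_ratios: np.ndarray,
    baseline_ratios: np.ndarray,
    percentile: float = 95.0,
    sd_multiplier: float = 2.0,
    two_sided: bool = False,
) -> tuple[float, set[int], np.ndarray]:
    """Z-standardize a sample's log2 ratios against the baseline cohort and
    sum the Z-scores of unstable bins.

    baseline_ratios is an (n_baseline x n_bins) matrix. Per bin, Z uses the
    baseline mean and SD (ddof=1); the instability threshold is the given
    percentile of the pooled baseline Z values plus ``sd_multiplier`` times
    their SD. One-sided by default (gains); ``two_sided`` thresholds |Z|.
    Bins with zero baseline SD are masked with a warning.
    """
    sample_ratios = np.asarray(sample_ratios, dtype=float)
    baseline_ratios = np.asarray(baseline_ratios, dtype=float)
    if baseline_ratios.ndim != 2 or baseline_ratios.shape[0] < 2:
        raise ValueError("baseline cohort must contain >= 2 samples")
    if baseline_ratios.shape[1] != sample_ratios.shape[0]:
        raise ValueError("sample and baseline bin vectors must be congruent")

    mu = np.nanmean(baseline_ratios, axis=0)
    sd = np.nanstd(baseline_ratios, axis=0, ddof=1)
    degenerate = ~(sd > 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} bins with degenerate baseline SD masked")
    sd_safe = np.where(degenerate, np.nan, sd)

    z = (sample_ratios - mu) / sd_safe
    baseline_z = (baseline_ratios - mu) / sd_safe
    pooled = baseline_z[np.isfinite(baseline_z)]
    threshold = float(np.percentile(pooled, percentile) + sd_multiplier * np.std(pooled, ddof=1))

    magnitude = np.abs(z) if two_sided else z
    with np.errstate(invalid="ignore"):
        unstable = np.flatnonzero(np.nan_to_num(magnitude, nan=-np.inf) > threshold)
    cni = float(magnitude[unstable].sum()) if unstable.size else 0.0
    return cni, set(int(i) for i in unstable), z


def cni_for_cohort(
    bin_counts: BinCountSet,
    window_fraction: float = 0.3,
    percentile: float = 95.0,
    sd_multiplier: float = 2.0,
    two_sided: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full CNI pipeline over a cohort: GC/length correction, log2 ratios
    against the per-bin median of the corrected baseline cohort, then CNI per
    test sample. Returns a per-sample table and a detail dict (threshold,
    per-sample Z traces)."""
    panel = bin_counts.panel
    corrected = {
        s: gc_correct_and_normalize(panel, bin_counts.counts[s].to_numpy(), window_fraction)
        for s in bin_counts.counts.columns
    }
    centered = {s: v / np.median(v) for s, v in corrected.items()}
    reference = np.median(
        np.vstack([centered[s] for s in bin_counts.baseline_samples]), axis=0
    )
    ratios = {
        s: compute_log2_ratios(corrected[s], reference, median_center=True)
        for s in bin_counts.counts.columns
    }
    baseline_matrix = np.vstack([ratios[s] for s in bin_counts.baseline_samples])

    rows, traces = [], {}
    for s in bin_counts.test_samples:
        cni, unstable, z = compute_cni(
            ratios[s], baseline_matrix, percentile, sd_multiplier, two_sided
        )
        rows.append({"sample": s, "cni": cni, "n_unstable_bins": len(unstable)})
        traces[s] = z
    table = pd.DataFrame(rows)
    details = {"z_traces": traces, "baseline_ratio_matrix": baseline_matrix}
    return table, details


MATH_VAF_RANGE = (0.02, 1.0)


def compute_math(vafs, convention: str = "literal") -> float | None:
    """MAD over median of the VAFs inside the 2%-100% inclusion window.

    ``convention='literal'`` is the plain MAD/median ratio; ``'mroz'`` applies
    the 1.4826 Gaussian-consistency constant and the x100 percentage scale of
    the original MATH literature. Returns None (flagged missing, not 0) when
    no VAF survives inclusion.
    """
    vafs = np.asarray(list(vafs), dtype=float)
    lo, hi = MATH_VAF_RANGE
    included = vafs[(vafs >= lo) & (vafs <= hi)]
    if included.size == 0:
        return None
    med = float(np.median(included))
    mad = float(np.median(np.abs(included - med)))
    value = mad / med
    if convention == "literal":
        return value
    if convention == "mroz":
        return 100.0 * 1.4826 * value
    raise ValueError(f"unknown MATH convention {convention!r}")


def compute_tmb(mutation_count: int, exonic_base_total: int) -> float:
    """Mutations per megabase: count x 1e6 / panel exonic base number."""
    if exonic_base_total <= 0:
        raise ValueError("exonic_base_total must be positive")
    if mutation_count < 0:
        raise ValueError("mutation_count must be non-negative")
    return mutation_count * 1e6 / exonic_base_total


def compare_groups_mannwhitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two groups of metric values.

    Exact enumeration p when the combined sample is small (n <= 12) and
    tie-free; normal approximation with tie correction otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact_ok = pooled.size <= 12 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact_ok else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def compute_metrics_table(
    bin_counts: BinCountSet,
    retained_variants: pd.DataFrame,
    math_convention: str = "literal",
    **cni_kwargs,
) -> pd.DataFrame:
    """Assemble the per-sample metrics table (sample, cni, n_unstable_bins,
    math, tmb, mutation_count) from bin counts plus the post-filter variant
    table. TMB uses the retained mutation count, as in the filtering-coupled
    definition."""
    cni_table, _ = cni_for_cohort(bin_counts, **cni_kwargs)
    ebt = bin_counts.panel.exonic_base_total
    rows = []
    for _, row in cni_table.iterrows():
        s = row["sample"]
        sub = retained_variants[retained_variants["sample"] == s]
        n_mut = int(len(sub))
        rows.append(
            {
                "sample": s,
                "cni": row["cni"],
                "n_unstable_bins": int(row["n_unstable_bins"]),
                "math": compute_math(sub["vaf"], convention=math_convention) if n_mut else None,
                "tmb": compute_tmb(n_mut, ebt),
                "mutation_count": n_mut,
            }
        )
    return pd.DataFrame(rows)
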
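"""CNI / MATH / TMB: hand-checked formula values, an independent brute-force
CNI oracle, and behavior on synthetic cohorts."""

import math

import numpy as np
import pytest
from scipy import stats

from ctdna_chemoscore import cohort
from ctdna_chemoscore.instability import (
    cni_for_cohort,
    compare_groups_mannwhitney,
    compute_cni,
    compute_log2_ratios,
    compute_math,
    compute_tmb,
    gc_correct_and_normalize,
)


def brute_force_cni(sample_ratios, baseline_ratios, percentile=95.0, sd_mult=2.0):
    """Direct enumeration of the CNI definition with plain-Python statistics;
    shares no code with the implementation."""
    n_base = len(baseline_ratios)
    n_bins = len(sample_ratios)
    z_sample = []
    z_base_pooled = []
    for b in range(n_bins):
        col = [baseline_ratios[i][b] for i in range(n_base)]
        mu = sum(col) / n_base
        var = sum((x - mu) ** 2 for x in col) / (n_base - 1)
        sd = math.sqrt(var)
        z_sample.append((sample_ratios[b] - mu) / sd)
        z_base_pooled.extend((x - mu) / sd for x in col)
    mean_z = sum(z_base_pooled) / len(z_base_pooled)
    sd_z = math.sqrt(
        sum((x - mean_z) ** 2 for x in z_base_pooled) / (len(z_base_pooled) - 1)
    )
    threshold = float(np.percentile(z_base_pooled, percentile)) + sd_mult * sd_z
    unstable = [b for b in range(n_bins) if z_sample[b] > threshold]
    return sum(z_sample[b] for b in unstable), set(unstable)


class TestGcCorrection:
    def test_bias_free_counts_unchanged_up_to_noise(self, small_panel):
        bc, _ = cohort.generate_bin_counts(
            small_panel, 2, 0, gc_bias_strength=0.0, depth_mean=500.0,
            nb_dispersion=None, seed=1,
        )
        raw = bc.counts.iloc[:, 0].to_numpy().astype(float)
        corrected = gc_correct_and_normalize(small_panel, raw)
        assert np.nanmedian(np.abs(corrected - raw) / raw) < 0.1

    def test_length_normalization_exact(self):
        import pandas as pd

        bins = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(10) * 1000,
                "end": np.arange(10) * 1000 + np.tile([100, 200], 5),
                "gene": [f"g{i}" for i in range(10)],
                "gc_fraction": 0.5,
            }
        )
        panel = cohort.PanelDesign(bins)
        counts = np.tile([100.0, 200.0], 5)  # identical per-base coverage
        corrected = gc_correct_and_normalize(panel, counts)
        assert np.allclose(corrected, corrected[0])

    def test_reduces_gc_association(self, small_panel):
        bc, _ = cohort.generate_bin_counts(
            small_panel, 2, 0, gc_bias_strength=2.0, depth_mean=800.0, seed=2
        )
        raw = bc.counts.iloc[:, 0].to_numpy().astype(float)
        corrected = gc_correct_and_normalize(small_panel, raw)
        gc = small_panel.bins["gc_fraction"]
        rho_raw = abs(stats.spearmanr(raw, gc).statistic)
        rho_corr = abs(stats.spearmanr(corrected, gc).statistic)
        assert rho_corr < rho_raw

    def test_too_few_bins_rejected(self):
        panel = cohort.generate_panel(5, 100, seed=0)
        with pytest.raises(ValueError, match="8 bins"):
            gc_correct_and_normalize(panel, np.ones(5))

    def test_all_zero_counts_rejected(self, small_panel):
        with pytest.raises(ValueError, match="all-zero"):
            gc_correct_and_normalize(small_panel, np.zeros(small_panel.n_bins))


class TestLog2Ratios:
    def test_identity_gives_zero(self):
        base = np.full(20, 100.0)
        assert np.allclose(compute_log2_ratios(base.copy(), base), 0.0)

    def test_doubled_bin_gives_one(self):
        base = np.full(21, 100.0)
        sample = base.copy()
        sample[3] = 200.0
        ratios = compute_log2_ratios(sample, base)
        assert ratios[3] == pytest.approx(1.0)
        assert np.allclose(np.delete(ratios, 3), 0.0)

    def test_quartered_bin_gives_minus_two(self):
        base = np.full(21, 100.0)
        sample = base.copy()
        sample[7] = 25.0
        assert compute_log2_ratios(sample, base)[7] == pytest.approx(-2.0)

    def test_zero_baseline_bins_masked(self):
        base = np.full(11, 100.0)
        base[2] = 0.0
        with pytest.warns(UserWarning, match="masked"):
            ratios = compute_log2_ratios(np.full(11, 100.0), base)
        assert np.isnan(ratios[2])


class TestComputeCni:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for rep in range(10):
            baseline = rng.normal(0, 0.3, size=(10, 20))
            sample = rng.normal(0, 0.3, size=20)
            sample[rng.integers(0, 20, size=3)] += rng.uniform(1, 4, size=3)
            cni, unstable, _ = compute_cni(sample, baseline)
            o_cni, o_unstable = brute_force_cni(sample.tolist(), baseline.tolist())
            assert unstable == o_unstable
            assert cni == pytest.approx(o_cni, abs=1e-9)

    def test_null_samples_score_near_zero(self):
        rng = np.random.default_rng(7)
        baseline = rng.normal(0, 0.3, size=(20, 30))
        cnis = [compute_cni(rng.normal(0, 0.3, size=30), baseline)[0] for _ in range(50)]
        assert np.median(cnis) == pytest.approx(0.0)

    def test_planted_z_sums_into_cni(self):
        rng = np.random.default_rng(3)
        baseline = rng.normal(0, 1.0, size=(5, 10))
        mu = baseline.mean(axis=0)
        sd = baseline.std(axis=0, ddof=1)
        sample = mu.copy()
        sample[4] = mu[4] + 10 * sd[4]  # plant z = 10 in one bin
        cni, unstable, z = compute_cni(sample, baseline)
        assert unstable == {4}
        assert cni == pytest.approx(10.0, abs=1e-9)

    def test_monotone_in_added_unstable_bins(self):
        rng = np.random.default_rng(5)
        baseline = rng.normal(0, 1.0, size=(8, 15))
        mu = baseline.mean(axis=0)
        sd = baseline.std(axis=0, ddof=1)
        sample = mu.copy()
        sample[0] = mu[0] + 8 * sd[0]
        one, _, _ = compute_cni(sample, baseline)
        sample[1] = mu[1] + 8 * sd[1]
        two, _, _ = compute_cni(sample, baseline)
        assert two >= one

    def test_degenerate_baseline_bin_masked(self):
        baseline = np.random.default_rng(1).normal(size=(4, 12))
        baseline[:, 5] = 1.0  # zero variance
        with pytest.warns(UserWarning, match="degenerate"):
            cni, _, z = compute_cni(baseline[0] * 0, baseline)
        assert np.isnan(z[5])

    def test_requires_two_baseline_samples(self):
        with pytest.raises(ValueError, match=">= 2"):
            compute_cni(np.zeros(5), np.zeros((1, 5)))


class TestCniSeparation:
    def test_better_group_with_events_scores_higher(self):
        from conftest import make_separation_cohort

        bc, groups, _ = make_separation_cohort(seed=123)
        table, _ = cni_for_cohort(bc)
        vals = table.set_index("sample")["cni"]
        better = [vals[s] for s in vals.index if groups[s] == "better"]
        poor = [vals[s] for s in vals.index if groups[s] == "poor"]
        _, p = compare_groups_mannwhitney(better, poor)
        assert np.median(better) > np.median(poor)
        assert p < 0.05


class TestMath:
    def test_constant_vafs_give_zero(self):
        assert compute_math([0.2, 0.2, 0.2]) == 0.0

    def test_hand_computed_value(self):
        # median 0.20, deviations {0.10, 0, 0.20} -> MAD 0.10, MATH 0.5
        assert compute_math([0.10, 0.20, 0.40]) == pytest.approx(0.5)

    def test_two_percent_floor_excludes(self):
        assert compute_math([0.015, 0.10, 0.20, 0.40]) == pytest.approx(0.5)

    def test_bounds_inclusive(self):
        assert compute_math([0.02, 0.02, 1.0]) is not None
        assert compute_math([0.019]) is None

    def test_empty_after_inclusion_flagged_missing(self):
        assert compute_math([0.001, 0.005]) is None

    def test_mroz_convention_scale(self):
        literal = compute_math([0.10, 0.20, 0.40])
        mroz = compute_math([0.10, 0.20, 0.40], convention="mroz")
        assert mroz == pytest.approx(100 * 1.4826 * literal)

    @pytest.mark.parametrize("c", [0.5, 0.9, 2.0])
    def test_scale_invariance(self, c):
        vafs = [0.05, 0.11, 0.23, 0.31]
        scaled = [v * c for v in vafs]
        if max(scaled) <= 1.0 and min(scaled) >= 0.02:
            assert compute_math(scaled) == pytest.approx(compute_math(vafs))


class TestTmb:
    @pytest.mark.parametrize(
        "count, bases, expected",
        [(30, 1_500_000, 20.0), (0, 123, 0.0), (7, 1_000_000, 7.0)],
    )
    def test_formula(self, count, bases, expected):
        assert compute_tmb(count, bases) == expected

    def test_linear_in_count(self):
        assert compute_tmb(60, 1_500_000) == 2 * compute_tmb(30, 1_500_000)

    def test_invalid_panel_size(self):
        with pytest.raises(ValueError):
            compute_tmb(1, 0)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = compare_groups_mannwhitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = compare_groups_mannwhitney([1, 2], [1, 2])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_mannwhitney([], [1.0])

    def test_shift_monotonicity(self):
        u1, _ = compare_groups_mannwhitney([1, 2, 3], [2, 3, 4])
        u2, _ = compare_groups_mannwhitney([2, 3, 4], [2, 3, 4])
        assert u2 >= u1
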
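"""nCTPS gene-signature scoring and survival stratification.

The nCT predictive score (nCTPS) of a sample is the sum of its first two
principal-component scores from a PCA over the therapeutic-relevant gene
panel of an expression matrix. The continuous score is dichotomized at a
maximally selected log-rank cutoff, and prognosis is compared by
Kaplan-Meier curves and log-rank tests, optionally stratified by a TMB
dichotomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .discrimination import fit_pca

__all__ = [
    "SignatureModel",
    "SurvivalResult",
    "compute_nctps",
    "assign_high_low",
    "maxstat_cutoff",
    "km_estimate",
    "logrank_test",
    "logrank_scores",
    "stratified_prognosis",
    "two_group_logrank_statistic",
]


@dataclass
class SignatureModel:
    gene_list: list[str]
    used_genes: list[str]
    loadings: pd.DataFrame  # genes x {PC1, PC2}
    nctps: pd.Series  # sample -> score
    cutoff: float | None = None
    high_low: pd.Series | None = None

    def apply_cutoff(self, cutoff: float) -> "SignatureModel":
        self.cutoff = float(cutoff)
        self.high_low = assign_high_low(self.nctps, cutoff)
        return self


@dataclass
class SurvivalResult:
    statistic: float
    df: int
    p: float
    n_per_group: dict[str, int]
    km_curves: dict[str, pd.DataFrame]


def compute_nctps(
    expression: pd.DataFrame,
    gene_list: Sequence[str],
    scale_unit_variance: bool = False,
) -> SignatureModel:
    """PCA over the gene-list submatrix (samples as observations, centered
    per gene, optionally unit-variance scaled); nctps(s) = PC1(s) + PC2(s).

    Genes absent from the matrix are logged and skipped; at least two usable
    genes and three samples are required.
    """
    gene_list = list(gene_list)
    used = [g for g in gene_list if g in expression.index]
    missing = sorted(set(gene_list) - set(used))
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from matrix: {missing[:5]}...")
    if len(used) < 2:
        raise ValueError("need >= 2 signature genes present in the expression matrix")
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 samples")

    sub = expression.loc[used].T.astype(float)  # samples x genes
    if scale_unit_variance:
        sd = sub.std(axis=0, ddof=1).replace(0, 1.0)
        sub = sub / sd
    n_comp = min(2, min(sub.shape[0] - 1, sub.shape[1]))
    model = fit_pca(sub, n_components=n_comp)
    scores = model.scores
    nctps = scores.sum(axis=1) if n_comp == 2 else scores.iloc[:, 0]
    return SignatureModel(
        gene_list=gene_list,
        used_genes=used,
        loadings=model.loadings,
        nctps=nctps.rename("nctps"),
    )


def assign_high_low(scores: pd.Series, cutoff: float) -> pd.Series:
    return pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index, name="group")


def two_group_logrank_statistic(mask_a: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Chi-square log-rank statistic for the split ``mask_a`` vs rest, via the
    O-E / hypergeometric-variance form. Vector implementation used by the
    maxstat search; cross-checked against lifelines in the tests."""
    order = np.argsort(times, kind="stable")
    t, e, a = times[order], events[order].astype(bool), mask_a[order].astype(bool)
    event_times = np.unique(t[e])
    n = len(t)
    O = E = V = 0.0
    for et in event_times:
        at_risk = t >= et
        n_risk = at_risk.sum()
        n_risk_a = (at_risk & a).sum()
        d = (e & (t == et)).sum()
        d_a = (e & (t == et) & a).sum()
        O += d_a
        E += d * n_risk_a / n_risk
        if n_risk > 1:
            V += d * (n_risk_a / n_risk) * (1 - n_risk_a / n_risk) * (n_risk - d) / (n_risk - 1)
    if V == 0:
        return 0.0
    return float((O - E) ** 2 / V)


def logrank_scores(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Per-subject log-rank scores: event indicator minus the Nelson-Aalen
    cumulative hazard at the subject's time. These are the rank scores that
    maximally selected rank statistics standardize."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order].astype(bool)
    uniq = np.unique(t[e]) if e.any() else np.array([])
    cumhaz_at = {}
    h = 0.0
    for et in uniq:
        n_risk = (t >= et).sum()
        d = (e & (t == et)).sum()
        h += d / n_risk
        cumhaz_at[et] = h
    # cumulative hazard evaluated at each subject's own time
    haz = np.zeros(len(times))
    for i, (ti, _) in enumerate(zip(times, events)):
        past = uniq[uniq <= ti]
        haz[i] = cumhaz_at[past[-1]] if past.size else 0.0
    return events.astype(float) - haz


def maxstat_cutoff(
    scores: pd.Series | Mapping[str, float],
    times: Sequence[float],
    events: Sequence[int],
    quantile_window: tuple[float, float] = (0.1, 0.9),
) -> tuple[float, float, bool]:
    """Maximally selected rank statistic (log-rank scores) cutoff.

    Candidate cutoffs are midpoints between consecutive sorted unique scores
    inside the quantile window. For each, the standardized linear rank
    statistic |S - m*abar| / sqrt(m(N-m)/(N(N-1)) * sum (a_i - abar)^2) is
    computed over the log-rank scores a_i of the subjects above the cutoff;
    the maximizing cutoff is returned with the standardized statistic (ties
    broken toward the more balanced split). The third element flags selection
    under the null: the maximal statistic stayed below the 1.96 normal bound,
    so the "best" cutoff carries no real signal. The log-rank p-value later
    computed at a selected cutoff is optimistic (selection effect); see
    ``maxstat_permutation_p`` for an adjusted value.
    """
    s = pd.Series(dict(scores) if not isinstance(scores, pd.Series) else scores).astype(float)
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    vals = s.to_numpy()
    uniq = np.unique(vals)
    if uniq.size < 2:
        raise ValueError("all scores equal: no cutoff exists")
    lo_q, hi_q = np.quantile(vals, quantile_window)
    mids = (uniq[:-1] + uniq[1:]) / 2
    cand = mids[(mids >= lo_q) & (mids <= hi_q)]
    if cand.size < 2:
        cand = mids  # window too narrow for this score set; fall back to all splits

    a = logrank_scores(times, events)
    n = len(vals)
    abar = a.mean()
    ss = ((a - abar) ** 2).sum()
    best = None
    for c in cand:
        mask = vals > c
        m = mask.sum()
        if m == 0 or m == n or ss == 0:
            continue
        S = a[mask].sum()
        var = m * (n - m) / (n * (n - 1)) * ss
        stat = abs(S - m * abar) / np.sqrt(var)
        key = (stat, -abs(n / 2 - m))
        if best is None or key > best[0]:
            best = (key, float(c), float(stat))
    if best is None:
        raise ValueError("no admissible cutoff")
    _, cutoff, stat = best
    under_null = stat < stats.norm.ppf(0.975)
    return cutoff, stat, bool(under_null)


def maxstat_permutation_p(
    scores: pd.Series,
    times: Sequence[float],
    events: Sequence[int],
    n_permutations: int = 200,
    seed: int = 0,
    quantile_window: tuple[float, float] = (0.1, 0.9),
) -> float:
    """Selection-adjusted p for the maxstat statistic by permuting the score
    labels against the survival records."""
    rng = np.random.default_rng(seed)
    s = pd.Series(scores).astype(float)
    _, observed, _ = maxstat_cutoff(s, times, events, quantile_window)
    hits = 0
    vals = s.to_numpy()
    for _ in range(n_permutations):
        perm = pd.Series(rng.permutation(vals), index=s.index)
        _, stat, _ = maxstat_cutoff(perm, times, events, quantile_window)
        if stat >= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def km_estimate(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival curve with right censoring.

    Returns a DataFrame with columns time and survival, starting at S(0)=1
    and non-increasing.
    """
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(
    groups: Sequence[str],
    times: Sequence[float],
    events: Sequence[int],
) -> SurvivalResult:
    """k-group log-rank test (O-E with hypergeometric variance, df = k-1),
    with the per-group KM curves attached."""
    groups = pd.Series(list(groups)).astype(str)
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    uniq = groups.unique()
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(times, groups.to_numpy(), events)
    curves = {
        g: km_estimate(times[(groups == g).to_numpy()], events[(groups == g).to_numpy()])
        for g in uniq
    }
    return SurvivalResult(
        statistic=float(res.test_statistic),
        df=len(uniq) - 1,
        p=float(res.p_value),
        n_per_group={g: int((groups == g).sum()) for g in uniq},
        km_curves=curves,
    )


def stratified_prognosis(
    nctps_group: Sequence[str],
    tmb_group: Sequence[str],
    times: Sequence[float],
    events: Sequence[int],
) -> SurvivalResult:
    """k-group log-rank over the {nCTPS high/low} x {TMB high/low} cross-
    classes; empty classes are dropped with a log entry."""
    a = pd.Series(list(nctps_group)).astype(str)
    b = pd.Series(list(tmb_group)).astype(str)
    cross = "nCTPS-" + a + "/TMB-" + b
    counts = cross.value_counts()
    present = counts[counts > 0]
    if len(present) < 2:
        raise ValueError("need >= 2 non-empty cross-classes")
    if len(present) < 4:
        warnings.warn(f"only {len(present)} of 4 cross-classes populated")
    return logrank_test(cross.to_numpy(), times, events)
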
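"""The gene-screening funnel: CNV tumor-vs-normal chi-square screen,
CNV-dosage expression association, gene-set intersection, and
expression-drug-sensitivity correlation.

Copy-number states are the usual five-level coding {-2, -1, 0, 1, 2}
(deep deletion, deletion, neutral, gain, amplification). The chi-square
screen collapses states to altered/neutral by default; the dosage test
merges deep deletions into the deletion group, mirroring the four dosage
classes (single deletion, normal, single gain, amplification).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "cnv_chisquare_screen",
    "dosage_association",
    "dosage_screen",
    "intersect_screens",
    "drug_sensitivity_correlation",
]

VALID_STATES = {-2, -1, 0, 1, 2}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (the correction applied
    across genes in every screen here)."""
    return multipletests(np.asarray(list(pvalues), dtype=float), method="fdr_bh")[1]


def _check_states(states: pd.DataFrame) -> None:
    bad = set(np.unique(states.to_numpy())) - VALID_STATES
    if bad:
        raise ValueError(f"invalid CNV states: {sorted(bad)}")


def cnv_chisquare_screen(
    states: pd.DataFrame,
    condition: Mapping[str, str],
    collapse: str = "binary",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene chi-square test of CNV state against tumor/normal condition.

    ``collapse='binary'`` tests the 2x2 table condition x {altered, neutral};
    ``collapse='full'`` keeps all observed state levels. Pearson chi-square
    without continuity correction; BH adjustment across testable genes.
    Genes whose table has a zero marginal are reported untestable, never
    significant.
    """
    _check_states(states)
    cond = pd.Series({s: condition[s] for s in states.columns})
    levels = set(cond.unique())
    if len(levels) < 2:
        raise ValueError("both tumor and normal conditions are required")

    rows = []
    for g in states.index:
        vals = states.loc[g]
        if collapse == "binary":
            feat = (vals != 0).astype(int)
        elif collapse == "full":
            feat = vals
        else:
            raise ValueError(f"unknown collapse mode {collapse!r}")
        tab = pd.crosstab(cond, feat)
        testable = tab.shape[0] >= 2 and tab.shape[1] >= 2 and (tab.sum(0) > 0).all() and (tab.sum(1) > 0).all()
        if testable:
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            rows.append({"gene": g, "chi2": float(chi2), "p": float(p), "testable": True})
        else:
            rows.append({"gene": g, "chi2": np.nan, "p": np.nan, "testable": False})
    out = pd.DataFrame(rows).set_index("gene")
    mask = out["testable"].to_numpy()
    out["p_adjusted"] = np.nan
    if mask.any():
        out.loc[mask, "p_adjusted"] = bh_adjust(out.loc[mask, "p"])
    out["significant"] = (out["p_adjusted"] < alpha).fillna(False)
    return out


_DOSAGE_GROUPS = {-2: "deletion", -1: "deletion", 0: "normal", 1: "gain", 2: "amplification"}


def dosage_association(
    expression_row: Sequence[float],
    states_row: Sequence[int],
    min_group_size: int = 2,
) -> tuple[str, float, float]:
    """Test whether a gene's expression differs across its CNV dosage groups.

    States map to the four dosage classes (deep deletion merged into
    deletion). Exactly two usable groups -> two-sided rank-sum
    (Wilcoxon/Mann-Whitney); more -> Kruskal-Wallis with tie correction.
    Groups with fewer than ``min_group_size`` samples are excluded; fewer
    than two usable groups makes the gene untestable.
    """
    expr = np.asarray(list(expression_row), dtype=float)
    st = np.asarray(list(states_row), dtype=int)
    if expr.shape != st.shape:
        raise ValueError("expression and state rows must be congruent")
    labels = np.array([_DOSAGE_GROUPS[s] for s in st])
    groups = [expr[labels == g] for g in pd.unique(labels)]
    groups = [g for g in groups if g.size >= min_group_size]
    if len(groups) < 2:
        return ("untestable", np.nan, np.nan)
    if np.ptp(np.concatenate(groups)) == 0:
        return ("degenerate", 0.0, 1.0)
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return ("wilcoxon_ranksum", float(res.statistic), float(res.pvalue))
    res = stats.kruskal(*groups)
    return ("kruskal_wallis", float(res.statistic), float(res.pvalue))


def dosage_screen(
    expression: pd.DataFrame,
    states: pd.DataFrame,
    alpha: float = 0.05,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Run ``dosage_association`` per gene over shared samples, with BH
    adjustment across testable genes."""
    shared = [s for s in expression.columns if s in states.columns]
    if len(shared) < 2 * min_group_size:
        raise ValueError("too few shared samples between expression and CNV tables")
    genes = [g for g in expression.index if g in states.index]
    rows = []
    for g in genes:
        test, stat, p = dosage_association(
            expression.loc[g, shared], states.loc[g, shared], min_group_size
        )
        rows.append({"gene": g, "test": test, "statistic": stat, "p": p})
    out = pd.DataFrame(rows).set_index("gene")
    mask = out["p"].notna().to_numpy()
    out["p_adjusted"] = np.nan
    if mask.any():
        out.loc[mask, "p_adjusted"] = bh_adjust(out.loc[mask, "p"])
    out["significant"] = (out["p"] < alpha).fillna(False)
    return out


@dataclass
class VennReport:
    regions: dict[str, list[str]]

    @property
    def triple(self) -> list[str]:
        return self.regions["A&B&C"]

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}


def intersect_screens(set_a, set_b, set_c) -> VennReport:
    """All seven Venn regions of the three screened gene sets, with
    case-normalized labels and deterministic sorted membership lists."""
    A = {str(g).upper() for g in set_a}
    B = {str(g).upper() for g in set_b}
    C = {str(g).upper() for g in set_c}
    regions = {
        "A_only": A - B - C,
        "B_only": B - A - C,
        "C_only": C - A - B,
        "A&B_only": (A & B) - C,
        "A&C_only": (A & C) - B,
        "B&C_only": (B & C) - A,
        "A&B&C": A & B & C,
    }
    return VennReport({k: sorted(v) for k, v in regions.items()})


def drug_sensitivity_correlation(
    expression: pd.DataFrame,
    response: pd.DataFrame,
    method: str = "pearson",
    min_shared: int = 3,
) -> pd.DataFrame:
    """Correlate each gene's expression with each drug's sensitivity score
    across shared cell lines.

    Positive r means higher expression goes with a higher sensitivity score;
    whether that encodes sensitivity or resistance depends on the response
    source's sign convention, which the caller must know. Two-sided p from
    the t transform; BH across all tested pairs; pairs with fewer than
    ``min_shared`` shared lines are flagged untestable.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError("method must be pearson or spearman")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for g in expression.index:
        ex = expression.loc[g].dropna()
        for d in response.index:
            rs = response.loc[d].dropna()
            shared = ex.index.intersection(rs.index)
            if len(shared) < min_shared:
                rows.append({"gene": g, "drug": d, "n": len(shared), "r": np.nan, "p": np.nan})
                continue
            x, y = ex[shared].to_numpy(), rs[shared].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"gene": g, "drug": d, "n": len(shared), "r": np.nan, "p": np.nan})
                continue
            res = corr_fn(x, y)
            rows.append(
                {"gene": g, "drug": d, "n": len(shared), "r": float(res.statistic), "p": float(res.pvalue)}
            )
    out = pd.DataFrame(rows)
    mask = out["p"].notna().to_numpy()
    out["p_adjusted"] = np.nan
    if mask.any():
        out.loc[mask, "p_adjusted"] = bh_adjust(out.loc[mask, "p"])
    return out
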
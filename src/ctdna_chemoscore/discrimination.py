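"""PCA-based discrimination of chemotherapy response groups.

Per-gene alteration features (SNV presence or gene-level CNV states) are
assembled into a sample x gene matrix, reduced by PCA, and the principal-
component scores are scored against the better/poor response labels by the
Mann-Whitney (pairwise-probability) form of the ROC AUC. A deterministic
2-means clustering quantifies how well the unsupervised structure matches
the response groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlterationMatrix",
    "PcaModel",
    "build_alteration_matrix",
    "fit_pca",
    "discrimination_auc",
    "cluster_samples",
]

GROUPS = ("better", "poor")

# CR/PR respond, SD/PD do not: the two-group collapse used throughout.
RESPONSE_TO_GROUP = {"CR": "better", "PR": "better", "SD": "poor", "PD": "poor"}


@dataclass
class AlterationMatrix:
    """Sample x gene feature matrix; genes ordered by descending alteration
    frequency; all-constant genes dropped (they carry no PCA signal)."""

    kind: str  # snv_binary | cnv_level
    values: pd.DataFrame  # samples x genes
    group: dict[str, str]
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PcaModel:
    loadings: pd.DataFrame  # genes x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # samples x components
    pc_genes: dict[int, list[str]]
    mean_: np.ndarray


def normalize_group_labels(labels: Mapping[str, str]) -> dict[str, str]:
    """Map raw response grades (CR/PR/SD/PD) or already-collapsed labels to
    the better/poor dichotomy."""
    out = {}
    for s, g in labels.items():
        g = str(g)
        if g in GROUPS:
            out[s] = g
        elif g.upper() in RESPONSE_TO_GROUP:
            out[s] = RESPONSE_TO_GROUP[g.upper()]
        else:
            raise ValueError(f"unrecognized response label {g!r} for sample {s!r}")
    return out


def build_alteration_matrix(
    data: pd.DataFrame,
    kind: str,
    group: Mapping[str, str],
    samples: Sequence[str] | None = None,
) -> AlterationMatrix:
    """Build the sample x gene matrix behind the alteration landscape.

    ``kind='snv_binary'``: ``data`` is a retained-variant table (needs sample
    and gene columns); a cell is 1 iff the sample has >= 1 retained call in
    the gene. ``kind='cnv_level'``: ``data`` is a gene x sample signed-value
    table used as-is. Genes are sorted by descending alteration frequency;
    constant genes are dropped with a log entry.
    """
    if kind not in {"snv_binary", "cnv_level"}:
        raise ValueError(f"unknown matrix kind {kind!r}")
    if data.empty:
        raise ValueError("empty input: cannot build an alteration matrix")

    if kind == "snv_binary":
        sample_list = list(samples) if samples is not None else sorted(data["sample"].unique())
        presence = pd.crosstab(data["sample"], data["gene"]).clip(upper=1)
        mat = presence.reindex(index=sample_list, columns=sorted(presence.columns), fill_value=0)
        altered = (mat != 0).sum(axis=0)
    else:
        mat = data.T.copy()  # gene x sample input -> samples x genes
        if samples is not None:
            mat = mat.reindex(index=list(samples))
        altered = (mat != 0).sum(axis=0)

    group = normalize_group_labels(group)
    missing = [s for s in mat.index if s not in group]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")

    order = altered.sort_values(ascending=False, kind="stable").index
    mat = mat[order]
    constant = [g for g in mat.columns if mat[g].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping {len(constant)} all-constant genes")
        mat = mat.drop(columns=constant)
    if mat.shape[1] == 0:
        raise ValueError("no informative genes remain after dropping constants")
    return AlterationMatrix(
        kind=kind,
        values=mat.astype(float),
        group={s: group[s] for s in mat.index},
        dropped_genes=constant,
    )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|loading| entry of each
    component is positive."""
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


def fit_pca(
    matrix: AlterationMatrix | pd.DataFrame,
    n_components: int = 2,
    loading_quantile: float = 0.75,
) -> PcaModel:
    """Column-centered PCA by SVD with a deterministic sign convention.

    ``pc_genes`` lists, for components 1-2, the genes whose |loading| exceeds
    the ``loading_quantile`` quantile (default: top 25%).
    """
    values = matrix.values if isinstance(matrix, AlterationMatrix) else matrix
    X = values.to_numpy(dtype=float)
    n_samples, n_genes = X.shape
    max_rank = min(n_samples - 1, n_genes)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")

    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = _fix_signs(Vt[:n_components].T)
    scores = Xc @ loadings
    explained = (S[:n_components] ** 2) / (n_samples - 1)
    total_var = (S**2).sum() / (n_samples - 1)

    load_df = pd.DataFrame(
        loadings, index=values.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    pc_genes = {}
    for i in range(min(2, n_components)):
        mag = load_df.iloc[:, i].abs()
        cut = mag.quantile(loading_quantile)
        pc_genes[i + 1] = sorted(mag.index[mag >= cut])
    return PcaModel(
        loadings=load_df,
        explained_variance=explained,
        explained_variance_ratio=explained / total_var if total_var > 0 else explained * 0,
        scores=pd.DataFrame(scores, index=values.index, columns=load_df.columns),
        pc_genes=pc_genes,
        mean_=mean,
    )


def discrimination_auc(scores: Mapping[str, float] | pd.Series, labels: Mapping[str, str]) -> float:
    """ROC AUC in its Mann-Whitney pairwise-probability form, with the
    "better" group as the positive class: the mean over all (better, poor)
    pairs of 1[score_better > score_poor] + 0.5 * 1[equal]."""
    scores = pd.Series(dict(scores) if not isinstance(scores, pd.Series) else scores)
    labels = normalize_group_labels(labels)
    pos = np.array([scores[s] for s in scores.index if labels[s] == "better"])
    neg = np.array([scores[s] for s in scores.index if labels[s] == "poor"])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both response groups must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def cluster_samples(scores: pd.DataFrame, group: Mapping[str, str] | None = None) -> dict:
    """Deterministic 2-means over the first two PC scores.

    Initialization is the farthest pair of samples; Lloyd iterations run to
    convergence. Returns cluster labels, the cluster x group cross-tab with
    a chi-square (or Fisher exact, when any expected cell is small) test, and
    the best-matching agreement rate. Identical points yield a single
    effective cluster with agreement flagged undefined.
    """
    if len(scores) < 4:
        raise ValueError("need >= 4 samples to cluster")
    X = scores.to_numpy(dtype=float)[:, :2]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    if d2.max() == 0:
        return {"labels": pd.Series(0, index=scores.index), "degenerate": True, "agreement": None}
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centers = X[[min(i, j), max(i, j)]].astype(float)
    labels = np.zeros(len(X), dtype=int)
    for _ in range(100):
        dist = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new = dist.argmin(axis=1)
        if (new == labels).all() and _ > 0:
            break
        labels = new
        for k in (0, 1):
            if (labels == k).any():
                centers[k] = X[labels == k].mean(axis=0)
    out = {"labels": pd.Series(labels, index=scores.index), "degenerate": False}
    if group is not None:
        group = normalize_group_labels(group)
        gvec = pd.Series([group[s] for s in scores.index], index=scores.index)
        tab = pd.crosstab(out["labels"], gvec)
        out["crosstab"] = tab
        if tab.shape == (2, 2):
            expected = stats.contingency.expected_freq(tab.to_numpy())
            if (expected < 5).any():
                _, p = stats.fisher_exact(tab.to_numpy())
                out["test"] = ("fisher_exact", float(p))
            else:
                chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
                out["test"] = ("chi_square", float(p))
        match = (gvec == gvec.unique()[0]).to_numpy()
        agree = max(
            (labels == 0)[match].sum() + (labels == 1)[~match].sum(),
            (labels == 1)[match].sum() + (labels == 0)[~match].sum(),
        ) / len(labels)
        out["agreement"] = float(agree)
    return out
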
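"""PCA discrimination of response groups from gene-level CNV features.

Creates a 16-sample cohort in which six genes carry a +2 SD copy-number
shift in the responsive group, fits a PCA on the gene x sample matrix, and
reports the PC1 ROC AUC and the 2-means cluster agreement. A matched null
cohort (no shifted genes) shows what chance looks like.
"""

import warnings

import numpy as np
import pandas as pd

from ctdna_chemoscore.discrimination import (
    build_alteration_matrix,
    cluster_samples,
    discrimination_auc,
    fit_pca,
)

warnings.simplefilter("ignore")
rng = np.random.default_rng(5)
samples = [f"S{i:02d}" for i in range(16)]
groups = {s: ("better" if i < 8 else "poor") for i, s in enumerate(samples)}
genes = [f"G{i:02d}" for i in range(30)]

for label, delta in [("planted 2-SD signal", 2.0), ("null", 0.0)]:
    values = rng.normal(0, 1, size=(30, 16))
    for gi in range(6):
        for si, s in enumerate(samples):
            if groups[s] == "better":
                values[gi, si] += delta
    df = pd.DataFrame(values, index=genes, columns=samples)
    mat = build_alteration_matrix(df, "cnv_level", groups)
    model = fit_pca(mat, n_components=2)
    auc = discrimination_auc(model.scores.iloc[:, 0], groups)
    clus = cluster_samples(model.scores, groups)
    print(f"{label:22s} PC1 AUC = {auc:.3f}   cluster agreement = {clus['agreement']:.3f}"
          f"   PC1 genes: {model.pc_genes[1][:6]}")

# AUC near 1 with the planted signal and near 0.5 under the null: per-gene
# copy-number dosage can separate responders where mutation presence cannot.
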
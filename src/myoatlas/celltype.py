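"""Cell-type composition from marker-gene eigenvectors.

The expression of the genes marking each cell type is summarised by the
first principal component across samples ("eigenvector"); the per-sample
scores act as a relative-abundance proxy.  Muscle differences in these
scores are tested with linear mixed models (muscle fixed, individual
random) with BH-FDR across the cell-type family, and the muscles are
clustered on their mean scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .lmm import LMMResult, fit_muscle_lmm

__all__ = [
    "EigenTable",
    "celltype_eigenvectors",
    "fit_muscle_lmm",
    "celltype_association",
    "cluster_muscles",
]


@dataclass
class EigenTable:
    """Sample x cell-type PC1 scores with per-set variance explained."""

    scores: pd.DataFrame
    variance_explained: pd.Series
    n_markers_used: pd.Series

    def __getitem__(self, key):
        return self.scores[key]

    @property
    def columns(self):
        return self.scores.columns


def _pc1_scores(stdmat: np.ndarray) -> tuple[np.ndarray, float]:
    """First right-singular vector of a standardized genes x samples matrix,
    returned as unit-norm per-sample scores plus variance explained."""
    u, s, vt = np.linalg.svd(stdmat, full_matrices=False)
    scores = vt[0]
    varexp = float(s[0] ** 2 / np.sum(s ** 2)) if s.sum() > 0 else 0.0
    return scores, varexp


def _standardize_rows(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def celltype_eigenvectors(
    expr: pd.DataFrame, markers: dict[str, list[str]]
) -> EigenTable:
    """PC1 summary of each marker set across samples.

    Marker genes absent from ``expr`` are dropped with a warning; an empty
    resolvable set raises.  The sign of each score column is oriented so it
    correlates positively with the mean standardized expression of its
    marker set; a singleton set returns the standardized gene itself.
    """
    scores, varexp, nused = {}, {}, {}
    for name, genes in markers.items():
        present = [g for g in genes if g in expr.index]
        dropped = len(genes) - len(present)
        if dropped:
            warnings.warn(f"{name}: {dropped} marker genes not in expression matrix")
        if not present:
            raise ValueError(f"marker set {name!r} has no resolvable genes")
        mat = _standardize_rows(expr.loc[present].to_numpy(float))
        if len(present) == 1:
            v = mat[0] / np.linalg.norm(mat[0]) if np.linalg.norm(mat[0]) else mat[0]
            ve = 1.0
        else:
            v, ve = _pc1_scores(mat)
        mean_profile = mat.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        scores[name] = v - v.mean()
        varexp[name] = ve
        nused[name] = len(present)
    return EigenTable(
        scores=pd.DataFrame(scores, index=expr.columns),
        variance_explained=pd.Series(varexp),
        n_markers_used=pd.Series(nused),
    )


def celltype_association(
    eigen: EigenTable, metadata: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, LMMResult]]:
    """Mixed-model muscle test per cell type with BH-FDR across cell types.

    Returns a summary table (F, p, q, variance components, flags) and the
    full per-cell-type results, whose pairwise contrasts are reported for
    cell types significant at ``q < alpha``.
    """
    results: dict[str, LMMResult] = {}
    for ct in eigen.columns:
        results[ct] = fit_muscle_lmm(eigen.scores[ct], metadata)
    pvals = np.array([results[ct].pvalue for ct in eigen.columns])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for ct, q in zip(eigen.columns, qvals):
        results[ct].qvalue = float(q)
    summary = pd.DataFrame({
        "celltype": list(eigen.columns),
        "F": [results[ct].fvalue for ct in eigen.columns],
        "p": pvals,
        "q": qvals,
        "var_individual": [results[ct].var_individual for ct in eigen.columns],
        "var_residual": [results[ct].var_residual for ct in eigen.columns],
        "singular": [results[ct].singular for ct in eigen.columns],
        "significant": qvals < alpha,
    }).set_index("celltype")
    return summary, results


def cluster_muscles(
    eigen: EigenTable, metadata: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Mean eigen-score per muscle and a correlation-distance dendrogram.

    Returns ``(linkage, mean_table)``; the linkage is average-linkage on
    1 - Pearson correlation between the muscles' mean score profiles.
    """
    means = eigen.scores.groupby(metadata["muscle"], sort=False).mean()
    prof = means.to_numpy(float)
    n = prof.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = prof[i], prof[j]
            if np.allclose(a, b):
                d = 0.0
            elif a.std() == 0 or b.std() == 0:
                d = 1.0
            else:
                d = 1.0 - float(np.corrcoef(a, b)[0, 1])
            dist[i, j] = dist[j, i] = max(d, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Z, means
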
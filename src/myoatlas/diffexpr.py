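"""Precision-weighted mixed-model differential expression.

Counts are transformed to log2-CPM and each observation receives a
precision weight from the fitted mean-variance trend (the voom approach);
each gene is then fitted with the atlas mixed model (muscle fixed,
individual random) using those weights.  Genes whose expression tracks a
cell-type eigenvector (Pearson r > 0.5 at FDR < 0.05) are flagged as driven
by cell-type composition; the remaining significant genes form the
muscle-intrinsic set.  The same machinery runs at transcript level, with
transcripts of flagged genes excluded from the intrinsic set.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .lmm import fit_muscle_lmm
from .preprocess import tmm_norm_factors


def voom_weights(
    counts: pd.DataFrame,
    factors: pd.Series | None,
    design_labels: pd.Series,
    span: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-CPM and per-observation precision weights from the mean-variance
    trend.

    A fixed-effects model on ``design_labels`` (the muscle indicator) gives
    per-gene residual standard deviations; sqrt-SD is smoothed against mean
    log2-count by lowess, the trend is evaluated at each observation's
    fitted log2-count (clamped to the trend endpoints), and the weight is
    the predicted sqrt-SD to the power -4.
    """
    if counts.shape[0] < 10:
        raise ValueError("too few genes to estimate a mean-variance trend")
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    lib_np = lib.to_numpy()
    y = np.log2((counts.to_numpy(float) + 0.5) / (lib_np + 1.0)[None, :] * 1e6)

    labels = design_labels.reindex(counts.columns)
    levels = list(pd.unique(labels))
    X = np.ones((counts.shape[1], len(levels)))
    for j, lev in enumerate(levels[1:], 1):
        X[:, j] = (labels == lev).to_numpy(float)
    q, _ = np.linalg.qr(X)
    fitted = (q @ (q.T @ y.T)).T
    resid = y - fitted
    dof = counts.shape[1] - np.linalg.matrix_rank(X)
    sigma = np.sqrt((resid ** 2).sum(axis=1) / max(dof, 1))

    sx = y.mean(axis=1) + np.mean(np.log2(lib_np + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = lowess(sy, sx, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], lo[:, 1]

    fitted_cpm = 2.0 ** fitted
    fitted_count = 1e-6 * fitted_cpm * (lib_np + 1.0)[None, :]
    fitted_logcount = np.log2(fitted_count)
    pred = np.interp(fitted_logcount, lx, ly)  # clamps outside the range
    pred = np.maximum(pred, 1e-6)
    w = pred ** -4
    expr = pd.DataFrame(y, index=counts.index, columns=counts.columns)
    weights = pd.DataFrame(w, index=counts.index, columns=counts.columns)
    return expr, weights


def _pair_cols(levels):
    return list(itertools.combinations(levels, 2))


def per_gene_mixed_de(
    expr: pd.DataFrame,
    weights: pd.DataFrame | None,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Weighted mixed-model fit per gene with BH-FDR across genes.

    Returns a table with the muscle-term F and p, BH q across tested genes,
    singular/degenerate flags, and per-pair contrast estimates and
    Tukey-adjusted p-values in columns ``est:A|B`` / ``p:A|B``.
    """
    if weights is not None and (weights.shape != expr.shape):
        raise ValueError("weights must align with the expression matrix")
    meta = metadata.reindex(expr.columns)
    levels = list(pd.unique(meta["muscle"]))
    pairs = _pair_cols(levels)

    records = []
    for gene in expr.index:
        yv = expr.loc[gene]
        if np.ptp(yv.to_numpy()) == 0:
            rec = {"gene": gene, "F": np.nan, "p": np.nan,
                   "singular": False, "degenerate": True}
            for a, b in pairs:
                rec[f"est:{a}|{b}"] = np.nan
                rec[f"p:{a}|{b}"] = np.nan
            records.append(rec)
            continue
        w = weights.loc[gene].to_numpy() if weights is not None else None
        res = fit_muscle_lmm(yv, meta, weights=w)
        rec = {"gene": gene, "F": res.fvalue, "p": res.pvalue,
               "singular": res.singular, "degenerate": False}
        cons = res.contrasts.set_index(["muscle_a", "muscle_b"])
        for a, b in pairs:
            row = cons.loc[(a, b)]
            rec[f"est:{a}|{b}"] = row["estimate"]
            rec[f"p:{a}|{b}"] = row["p_adj"]
        records.append(rec)
    deg = pd.DataFrame.from_records(records).set_index("gene")

    tested = ~deg["degenerate"]
    q = np.full(len(deg), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(
            deg.loc[tested, "p"], method="fdr_bh")[1]
    deg["q"] = q
    deg["significant"] = deg["q"] < alpha
    deg.attrs["muscle_levels"] = levels
    deg.attrs["pairs"] = pairs
    deg.attrs["alpha"] = alpha
    return deg


def flag_celltype_driven(
    deg: pd.DataFrame,
    expr: pd.DataFrame,
    eigen,
    r_threshold: float = 0.5,
    q_threshold: float = 0.05,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Flag differentially expressed genes whose expression tracks a
    cell-type eigenvector (Pearson r > ``r_threshold`` and correlation FDR
    < ``q_threshold``).

    Correlation p-values are BH-adjusted over the whole tested
    (gene x cell type) grid.  Returns the table with ``celltype_driven``,
    ``driver_celltype`` and ``driver_r`` columns added.
    """
    scores = eigen.scores if hasattr(eigen, "scores") else eigen
    genes = deg.index[deg["significant"].fillna(False)] if significant_only \
        else deg.index[~deg["degenerate"]]
    out = deg.copy()
    out["celltype_driven"] = False
    out["driver_celltype"] = ""
    out["driver_r"] = np.nan
    if len(genes) == 0:
        return out

    E = expr.loc[genes].to_numpy(float)
    E = E - E.mean(axis=1, keepdims=True)
    En = np.linalg.norm(E, axis=1)
    En[En == 0] = 1.0
    S = scores.reindex(expr.columns).to_numpy(float).T
    S = S - S.mean(axis=1, keepdims=True)
    Sn = np.linalg.norm(S, axis=1)
    Sn[Sn == 0] = 1.0
    R = (E / En[:, None]) @ (S / Sn[:, None]).T  # genes x celltypes
    n = expr.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R ** 2, 1e-300))
    P = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    Q = multipletests(P.ravel(), method="fdr_bh")[1].reshape(P.shape)

    hit = (R > r_threshold) & (Q < q_threshold)
    celltypes = list(scores.columns)
    for i, gene in enumerate(genes):
        if hit[i].any():
            j = int(np.argmax(np.where(hit[i], R[i], -np.inf)))
            out.loc[gene, "celltype_driven"] = True
            out.loc[gene, "driver_celltype"] = celltypes[j]
            out.loc[gene, "driver_r"] = R[i, j]
    return out


def pairwise_deg_fraction(
    deg: pd.DataFrame, exclude_flagged: bool = False, alpha: float = 0.05
) -> pd.DataFrame:
    """Percentage of genes differentially expressed per muscle pair.

    Cell (i, j) = 100 x (# genes whose pair contrast survives per-pair BH
    across genes at ``alpha``) / (# genes tested); diagonal 0.  With
    ``exclude_flagged``, cell-type-driven genes are removed first.
    """
    tab = deg[~deg["degenerate"]]
    if exclude_flagged and "celltype_driven" in tab.columns:
        tab = tab[~tab["celltype_driven"].fillna(False)]
    levels = deg.attrs.get("muscle_levels")
    pairs = deg.attrs.get("pairs")
    if levels is None:
        pcols = [c for c in deg.columns if c.startswith("p:")]
        pairs = [tuple(c[2:].split("|")) for c in pcols]
        levels = sorted({m for p in pairs for m in p})
    mat = pd.DataFrame(0.0, index=levels, columns=levels)
    n_tested = len(tab)
    if n_tested == 0:
        return mat
    for a, b in pairs:
        p = tab[f"p:{a}|{b}"].to_numpy(float)
        ok = np.isfinite(p)
        if not ok.any():
            continue
        qq = multipletests(p[ok], method="fdr_bh")[1]
        pct = 100.0 * float((qq < alpha).sum()) / n_tested
        mat.loc[a, b] = mat.loc[b, a] = pct
    return mat


def transcript_level_de(
    transcript_counts: pd.DataFrame,
    transcript_to_gene: pd.DataFrame,
    metadata: pd.DataFrame,
    flagged_genes: set[str] | list[str] = (),
    genes_kept: set[str] | list[str] | None = None,
    factors: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Transcript-level DE with the identical voom + mixed-model machinery.

    Transcripts are restricted to those of genes in ``genes_kept`` (the
    filtered gene dataset) when provided; transcripts whose parent gene is
    cell-type flagged are marked ``celltype_related`` and excluded from the
    intrinsic set.
    """
    t2g = transcript_to_gene.set_index("transcript")["gene"]
    tx = transcript_counts
    if genes_kept is not None:
        keep = t2g.reindex(tx.index).isin(set(genes_kept))
        tx = tx.loc[keep.to_numpy()]
    if factors is None:
        factors = tmm_norm_factors(tx)
    expr, weights = voom_weights(tx, factors, metadata["muscle"])
    det = per_gene_mixed_de(expr, weights, metadata, alpha=alpha)
    det["gene"] = t2g.reindex(det.index).to_numpy()
    det["celltype_related"] = det["gene"].isin(set(flagged_genes))
    det["intrinsic"] = det["significant"] & ~det["celltype_related"]
    return det
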
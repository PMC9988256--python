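"""Count-level preprocessing: sample QC, expression filtering, TMM
normalisation, log-CPM, and per-gene variance decomposition.

The filtering and normalisation rules follow the standard edgeR-style bulk
RNA-seq workflow: samples need more than 5 million assigned reads, genes
need 10 or more reads in at least 16 samples (the smallest muscle group),
between-sample scaling uses the trimmed mean of M-values (TMM), and
expression values are log2 counts per million with a small prior count.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def sample_qc(counts: pd.DataFrame, min_assigned_reads: int = 5_000_000) -> list[str]:
    """Samples whose total assigned reads exceed the threshold (strict >)."""
    if counts.size == 0:
        raise ValueError("empty count matrix")
    totals = counts.sum(axis=0)
    return [s for s in counts.columns if totals[s] > min_assigned_reads]


def filter_low_expressed(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 16
) -> pd.DataFrame:
    """Keep genes with ``min_count`` or more reads in at least ``min_samples``
    samples."""
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def tmm_norm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors.

    The reference sample is the column whose upper-quartile count fraction is
    closest to the mean upper quartile.  For each sample, the factor is
    2^(inverse-variance-weighted mean of gene-wise log2 ratios vs the
    reference), after trimming ``logratio_trim`` from each tail of the M
    values and ``abs_trim`` from each tail of the A values; factors are then
    scaled to have geometric mean 1.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib == 0).any():
        raise ValueError("sample with zero total count")
    mat = counts.to_numpy(dtype=float)
    f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75)
                    for j in range(mat.shape[1])])
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(mat.shape[1])
    ref, ref_lib = mat[:, ref_j], lib[ref_j]
    for j in range(mat.shape[1]):
        if j == ref_j:
            continue
        obs = mat[:, j]
        ok = (obs > 0) & (ref > 0)
        if not ok.any():
            continue
        o, r = obs[ok], ref[ok]
        m = np.log2((o / lib[j]) / (r / ref_lib))
        a = 0.5 * np.log2((o / lib[j]) * (r / ref_lib))
        # asymptotic variance of M (delta method), used as inverse weight
        v = (lib[j] - o) / (lib[j] * o) + (ref_lib - r) / (ref_lib * r)
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
               (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any() and np.isfinite(m[keep]).all():
            factors[j] = 2.0 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def cpm_log(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts per million on effective library sizes.

    value = log2((count + prior) / (library x factor / 1e6)).
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    return np.log2((counts + prior_count).div(lib / 1e6, axis=1))


def variance_decomposition(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    factor_names: list[str],
) -> pd.DataFrame:
    """Per-gene percentage of variance attributed to each design factor.

    Every factor is entered as a fixed effect; for each gene the partial
    (Type II) sum of squares of each factor is computed against the model
    containing all other factors.  Constant or aliased factors are dropped
    with a warning.  Percentages are normalised over (sum of partial SS +
    residual SS) so each row lies in [0, 100] and sums to 100 with the
    residual column.
    """
    meta = metadata.reindex(expr.columns)
    blocks: dict[str, np.ndarray] = {}
    for f in factor_names:
        if f not in meta.columns:
            raise ValueError(f"factor {f!r} not in metadata")
        col = meta[f]
        if col.nunique(dropna=False) < 2:
            warnings.warn(f"factor {f!r} is constant; dropped")
            continue
        if np.issubdtype(col.dtype, np.number):
            blocks[f] = col.to_numpy(float)[:, None]
        else:
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(float)
            blocks[f] = dummies

    n = expr.shape[1]
    ones = np.ones((n, 1))

    def design(keys):
        cols = [ones] + [blocks[k] for k in keys]
        return np.concatenate(cols, axis=1)

    # drop factors that are aliased by the rest (rank-deficient full design)
    keys = list(blocks)
    changed = True
    while changed:
        changed = False
        X = design(keys)
        full_rank = np.linalg.matrix_rank(X)
        if full_rank < X.shape[1]:
            for k in list(keys):
                rest = [q for q in keys if q != k]
                if np.linalg.matrix_rank(design(rest + [k])) == \
                        np.linalg.matrix_rank(design(rest)):
                    warnings.warn(f"factor {k!r} aliased; dropped")
                    keys.remove(k)
                    changed = True
                    break

    Y = expr.to_numpy(float).T  # samples x genes

    def rss(keys_):
        X = design(keys_)
        q, _ = np.linalg.qr(X)
        resid = Y - q @ (q.T @ Y)
        return (resid ** 2).sum(axis=0)

    rss_full = rss(keys)
    parts = {k: np.maximum(rss(
        [q for q in keys if q != k]) - rss_full, 0.0) for k in keys}
    denom = sum(parts.values()) + rss_full
    denom = np.where(denom <= 0, 1.0, denom)
    out = {k: 100.0 * parts[k] / denom for k in keys}
    out["residual"] = 100.0 * rss_full / denom
    table = pd.DataFrame(out, index=expr.index)
    # rows sum to 100 by construction; fix degenerate all-zero genes
    zero = table.sum(axis=1) < 1e-9
    table.loc[zero, :] = 0.0
    table.loc[zero, "residual"] = 100.0
    return table
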
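"""Consensus weighted gene co-expression network across individuals.

Per individual, gene-gene similarity is the biweight midcorrelation of that
individual's samples, turned into a signed-hybrid adjacency (positive
correlations raised to a soft power, negative set to zero) and then into a
topological overlap matrix (TOM).  Because per-individual TOMs can sit on
different overall scales, each is calibrated by matching a high quantile
(default 0.95) to the median of those quantiles across individuals; the
consensus TOM is the elementwise low quantile (default 0.40) of the
calibrated TOMs, so only gene pairs supported across individuals keep high
overlap.  Modules come from average-linkage clustering of 1 - TOM with a
dynamic hybrid tree cut, are summarised by module eigengenes, merged at an
eigengene-correlation threshold, and scored against pathway knowledge with
an enrichment factor that drives the parameter sweep.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .celltype import _pc1_scores, _standardize_rows
from .lmm import LMMResult, fit_muscle_lmm, random_effect_lrt

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class NetworkParams:
    power: int = 8
    min_module_size: int = 20
    deep_split: int = 0
    merge_cut_height: float = 0.2
    calibration_quantile: float = 0.95
    consensus_quantile: float = 0.40

    def __post_init__(self):
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")


# ---------------------------------------------------------------------------
# correlation / adjacency / TOM

def bicor(data) -> np.ndarray:
    """Biweight midcorrelation between columns of ``data`` (samples x genes).

    Median/MAD-based with biweights zeroed beyond 9 MADs.  Columns with zero
    MAD fall back to Pearson normalisation for the pairs they touch
    (logged via warning).  Requires at least 4 observations.
    """
    X = np.asarray(data, float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("bicor needs a 2-D array with >= 4 observations")
    med = np.median(X, axis=0, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=0, keepdims=True)
    zero_mad = mad[0] == 0
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = dev / (9.0 * safe_mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    a = dev * w
    if zero_mad.any():
        warnings.warn(f"{int(zero_mad.sum())} zero-MAD columns fell back to Pearson")
        mean_dev = X - X.mean(axis=0, keepdims=True)
        a[:, zero_mad] = mean_dev[:, zero_mad]
    norm = np.sqrt((a ** 2).sum(axis=0))
    norm[norm == 0] = 1.0
    ahat = a / norm[None, :]
    C = ahat.T @ ahat
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


def adjacency_signed_hybrid(cor: np.ndarray, power: int) -> np.ndarray:
    """Signed-hybrid soft-threshold adjacency: cor^power for positive
    correlations, 0 otherwise; diagonal 0 (connectivity convention)."""
    A = np.where(cor > 0, cor, 0.0) ** power
    np.fill_diagonal(A, 0.0)
    return A


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij) with k the connectivity; diagonal 1."""
    A = np.asarray(adjacency, float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    T = num / den
    np.fill_diagonal(T, 1.0)
    return T


def consensus_tom(
    toms: list[np.ndarray],
    calibration_quantile: float = 0.95,
    consensus_quantile: float = 0.40,
) -> np.ndarray:
    """Quantile-calibrated elementwise-quantile consensus of TOMs.

    Each TOM is rescaled so its ``calibration_quantile`` of off-diagonal
    entries matches the median of those quantiles across TOMs; the consensus
    entry is the elementwise ``consensus_quantile`` of the calibrated TOMs,
    clipped to [0, 1], with unit diagonal.
    """
    if len(toms) < 2:
        raise ValueError("need at least two TOMs")
    shape = toms[0].shape
    if any(t.shape != shape for t in toms):
        raise ValueError("TOMs must share the same gene set")
    iu = np.triu_indices(shape[0], k=1)
    qs = np.array([np.quantile(t[iu], calibration_quantile) for t in toms])
    if (qs == 0).any():
        raise ValueError("zero calibration quantile in an input TOM")
    ref = np.median(qs)
    scaled = np.stack([t * (ref / q) for t, q in zip(toms, qs)])
    cons = np.quantile(scaled, consensus_quantile, axis=0)
    np.clip(cons, 0.0, 1.0, out=cons)
    np.fill_diagonal(cons, 1.0)
    return cons


def per_individual_toms(
    expr: pd.DataFrame, metadata: pd.DataFrame, power: int,
    min_samples: int = 4,
) -> dict[str, np.ndarray]:
    """Signed-hybrid TOM per individual from that individual's samples."""
    toms = {}
    for ind, sub in metadata.groupby("individual", sort=False):
        cols = [s for s in sub.index if s in expr.columns]
        if len(cols) < min_samples:
            continue
        C = bicor(expr[cols].to_numpy(float).T)
        toms[ind] = tom_similarity(adjacency_signed_hybrid(C, power))
    return toms


# ---------------------------------------------------------------------------
# dynamic tree cut

# deepSplit -> minimum relative gap of a module branch (its attachment
# height minus its core scatter, relative to the attachment height); lower
# values split more aggressively
def _split_presets(deep_split: int) -> float:
    ds = float(np.clip(deep_split, 0, 4))
    return 0.025 - ds / 4.0 * (0.025 - 0.005)


def cut_modules(
    diss: np.ndarray,
    params: NetworkParams,
    gene_ids=None,
    cut_height_fraction: float = 0.99,
) -> pd.Series:
    """Dynamic hybrid tree cut of a dissimilarity matrix (1 - TOM).

    Average-linkage clustering; a branch qualifies as a module when it is
    large enough, forms below the static cut (``cut_height_fraction`` of
    the top merge height), and is separated from its surroundings: its
    relative gap — attachment height minus core scatter (the mean merge
    height inside the branch), divided by the attachment height — exceeds
    the deep-split preset.  Among nested qualifying branches the one with
    the largest relative gap wins (so stragglers attached just below a
    module's join point are left out), and a branch whose two children both
    qualify is split.  Genes outside any module get the label "unassigned".
    """
    D = np.asarray(diss, float)
    n = D.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    labels = pd.Series(UNASSIGNED, index=list(gene_ids), name="module")
    if n < params.min_module_size:
        return labels

    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    hmax = float(heights.max())
    cut_h = cut_height_fraction * hmax
    min_gap_rel = _split_presets(params.deep_split)

    # bottom-up leaf lists, internal merge-height sums, attachment heights
    leaves: list[np.ndarray] = [np.array([i]) for i in range(n)]
    height_sum = np.zeros(2 * n - 1)
    parent_h = np.full(2 * n - 1, hmax)
    sizes = np.ones(2 * n - 1, int)
    for m in range(n - 1):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        node = n + m
        height_sum[node] = height_sum[a] + height_sum[b] + heights[m]
        leaves.append(np.concatenate([leaves[a], leaves[b]]))
        sizes[node] = sizes[a] + sizes[b]
        parent_h[a] = parent_h[b] = heights[m]

    def gap_rel(node: int) -> float:
        s = sizes[node]
        sc = height_sum[node] / (s - 1) if s > 1 else 0.0
        attach = parent_h[node]
        return (attach - sc) / attach if attach > 0 else 0.0

    def qualifies(node: int) -> bool:
        if sizes[node] < params.min_module_size:
            return False
        sc = height_sum[node] / (sizes[node] - 1)
        return sc <= cut_h and gap_rel(node) >= min_gap_rel

    # bottom-up selection: children are processed before parents
    selected: list[list[int]] = [[] for _ in range(2 * n - 1)]
    for m in range(n - 1):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        node = n + m
        sel = selected[a] + selected[b]
        if qualifies(node):
            if len(sel) >= 2:
                pass                      # two sub-modules: keep the split
            elif len(sel) == 1 and gap_rel(sel[0]) > gap_rel(node):
                pass                      # a better-separated core wins
            else:
                sel = [node]
        selected[node] = sel

    accepted = sorted(selected[2 * n - 2], key=lambda nd: -sizes[nd])
    ids = np.asarray(list(gene_ids))
    for rank, node in enumerate(accepted, start=1):
        labels.iloc[leaves[node]] = f"M{rank}"
    labels.index = ids
    return labels


# ---------------------------------------------------------------------------
# eigengenes, merging, connectivity

def module_eigengenes(
    expr: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Module eigengene (PC1 of the standardized member genes across all
    samples, sign-oriented to the module mean profile) per assigned module.

    Returns ``(me_table, variance_explained)``.
    """
    modules = [m for m in assignment.unique() if m != UNASSIGNED]
    me, ve = {}, {}
    for mod in sorted(modules, key=_module_sort_key):
        genes = assignment.index[assignment == mod]
        genes = [g for g in genes if g in expr.index]
        mat = _standardize_rows(expr.loc[genes].to_numpy(float))
        if len(genes) == 1:
            v = mat[0]
            nrm = np.linalg.norm(v)
            v = v / nrm if nrm else v
            varexp = 1.0
        else:
            v, varexp = _pc1_scores(mat)
        if np.dot(v, mat.mean(axis=0)) < 0:
            v = -v
        me[mod] = v - v.mean()
        ve[mod] = varexp
    return pd.DataFrame(me, index=expr.columns), pd.Series(ve)


def _module_sort_key(m: str):
    try:
        return (0, int(str(m).lstrip("M")))
    except ValueError:
        return (1, str(m))


def merge_modules(
    expr: pd.DataFrame,
    assignment: pd.Series,
    merge_cut_height: float = 0.2,
    max_iter: int = 20,
) -> tuple[pd.Series, pd.DataFrame]:
    """Merge modules whose eigengenes are similar.

    Average-linkage clustering of eigengenes on 1 - correlation; branches
    below ``merge_cut_height`` are merged (into the largest member's label),
    eigengenes recomputed, iterated to stability.  Returns the final
    assignment and eigengene table.
    """
    assignment = assignment.copy()
    for _ in range(max_iter):
        me, _ = module_eigengenes(expr, assignment)
        mods = list(me.columns)
        if len(mods) < 2:
            break
        C = np.corrcoef(me.to_numpy(float).T)
        dist = np.clip(1.0 - C, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
        grp = hierarchy.fcluster(Z, t=merge_cut_height, criterion="distance")
        if len(set(grp)) == len(mods):
            break
        sizes = assignment.value_counts()
        for g in set(grp):
            members = [m for m, gg in zip(mods, grp) if gg == g]
            if len(members) < 2:
                continue
            target = max(members, key=lambda m: sizes.get(m, 0))
            assignment[assignment.isin(members)] = target
    me, _ = module_eigengenes(expr, assignment)
    return assignment, me


def intramodular_connectivity(
    adjacency: np.ndarray,
    assignment: pd.Series,
    hub_fraction: float = 0.10,
) -> pd.DataFrame:
    """Within-module connectivity and hub flags.

    kWithin_i is the summed adjacency of gene i to its module co-members;
    hubs are the top ``hub_fraction`` by kWithin within each module (at
    least one per module).  Unassigned genes are absent from the output.
    """
    A = np.asarray(adjacency, float).copy()
    np.fill_diagonal(A, 0.0)
    gene_pos = {g: i for i, g in enumerate(assignment.index)}
    rows = []
    for mod in assignment.unique():
        if mod == UNASSIGNED:
            continue
        genes = list(assignment.index[assignment == mod])
        idx = [gene_pos[g] for g in genes]
        sub = A[np.ix_(idx, idx)]
        kwithin = sub.sum(axis=1)
        n_hub = max(1, int(np.floor(hub_fraction * len(genes))))
        order = np.argsort(-kwithin)
        hub = np.zeros(len(genes), bool)
        hub[order[:n_hub]] = True
        for g, kw, hb in zip(genes, kwithin, hub):
            rows.append((g, mod, float(kw), bool(hb)))
    return pd.DataFrame(rows, columns=["gene", "module", "kWithin", "hub"]
                        ).set_index("gene")


# ---------------------------------------------------------------------------
# enrichment factor and the parameter sweep

@dataclass
class EnrichmentFactorResult:
    n1: int  # same module & same pathway
    n2: int  # same module only
    n3: int  # same pathway only
    n4: int  # neither
    ef: float
    infinite: bool = False
    params: NetworkParams | None = None
    n_genes: int = 0
    n_modules: int = 0


def enrichment_factor(
    assignment: pd.Series, pathways: dict[str, list[str]],
    params: NetworkParams | None = None,
    annotated_only: bool = True,
) -> EnrichmentFactorResult:
    """Concordance of module assignment with pathway knowledge.

    Every unordered pair of module-assigned genes is classified: (1) same
    module & share a pathway, (2) same module only, (3) share a pathway
    only, (4) neither.  EF = (n1 * n4) / (n2 * n3); a zero denominator is
    reported as an infinite-EF flag.  With ``annotated_only`` (the default)
    genes without any pathway annotation are excluded from the pair
    classification; with ``annotated_only=False`` they enter it and count
    as sharing no pathway, so modules absorbing unannotated genes are
    penalised through group 2.
    """
    annotated = set().union(*pathways.values()) if pathways else set()
    genes = [g for g in assignment.index
             if assignment[g] != UNASSIGNED
             and (not annotated_only or g in annotated)]
    n = len(genes)
    if n < 2:
        return EnrichmentFactorResult(0, 0, 0, 0, np.nan, infinite=False,
                                      params=params, n_genes=n)
    lab = assignment.loc[genes].to_numpy()
    same_mod = lab[:, None] == lab[None, :]
    P = np.zeros((n, len(pathways)), bool)
    gpos = {g: i for i, g in enumerate(genes)}
    for j, members in enumerate(pathways.values()):
        for g in members:
            if g in gpos:
                P[gpos[g], j] = True
    same_pw = (P.astype(np.int64) @ P.T.astype(np.int64)) > 0
    iu = np.triu_indices(n, k=1)
    sm, sp = same_mod[iu], same_pw[iu]
    n1 = int((sm & sp).sum())
    n2 = int((sm & ~sp).sum())
    n3 = int((~sm & sp).sum())
    n4 = int((~sm & ~sp).sum())
    if n2 * n3 == 0:
        return EnrichmentFactorResult(n1, n2, n3, n4, np.inf, infinite=True,
                                      params=params, n_genes=n,
                                      n_modules=len(np.unique(lab)))
    ef = (n1 * n4) / (n2 * n3)
    return EnrichmentFactorResult(n1, n2, n3, n4, float(ef), params=params,
                                  n_genes=n, n_modules=len(np.unique(lab)))


def consensus_modules(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    params: NetworkParams,
    toms: dict[str, np.ndarray] | None = None,
) -> tuple[pd.Series, np.ndarray, pd.DataFrame]:
    """Full consensus pipeline: per-individual TOMs -> calibrated consensus
    -> tree cut -> eigengene merge.  Returns (assignment, consensus TOM,
    eigengene table)."""
    if toms is None:
        toms = per_individual_toms(expr, metadata, params.power)
    cons = consensus_tom(list(toms.values()), params.calibration_quantile,
                         params.consensus_quantile)
    assignment = cut_modules(1.0 - cons, params, gene_ids=expr.index)
    assignment, me = merge_modules(expr, assignment, params.merge_cut_height)
    return assignment, cons, me


DEFAULT_GRID = {
    "powers": (6, 8, 10, 12, 14, 18, 22),
    "min_module_sizes": (15, 20, 30),
    "deep_splits": (0, 2, 4),
    "merge_cut_heights": (0.1, 0.15, 0.2, 0.25, 0.3),
}


def parameter_sweep(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    grid: dict | None = None,
    pathways: dict[str, list[str]] | None = None,
    base_params: NetworkParams = NetworkParams(),
    annotated_only: bool = False,
) -> tuple[list[EnrichmentFactorResult], NetworkParams]:
    """Grid search over network parameters scored by enrichment factor.

    For every grid point the full consensus pipeline is run (per-individual
    TOMs are recomputed per power, the tree cut per (min size, deep split),
    the eigengene merge per cut height) and the merged consensus modules are
    scored against ``pathways``.  Unannotated genes enter the pair
    classification by default so parameter sets that sweep unannotated
    genes into modules are penalised.  Returns the EF results sorted
    best-first and the argmax parameters (ties broken by smaller power,
    then smaller minimum module size).
    """
    if pathways is None:
        raise ValueError("pathway knowledge is required to score the sweep")
    grid = {**DEFAULT_GRID, **(grid or {})}
    results: list[EnrichmentFactorResult] = []
    for power in grid["powers"]:
        p_power = replace(base_params, power=int(power))
        toms = per_individual_toms(expr, metadata, int(power))
        cons = consensus_tom(list(toms.values()), p_power.calibration_quantile,
                             p_power.consensus_quantile)
        diss = 1.0 - cons
        for min_size in grid["min_module_sizes"]:
            for ds in grid["deep_splits"]:
                p_cut = replace(p_power, min_module_size=int(min_size),
                                deep_split=int(ds))
                raw = cut_modules(diss, p_cut, gene_ids=expr.index)
                for ch in grid["merge_cut_heights"]:
                    p_full = replace(p_cut, merge_cut_height=float(ch))
                    merged, _ = merge_modules(expr, raw, float(ch))
                    results.append(enrichment_factor(
                        merged, pathways, p_full,
                        annotated_only=annotated_only))
    # rank by the continuity-corrected EF (Haldane-Anscombe: 0.5 added to
    # every pair count), which stays finite when no pathway is split across
    # modules (n3 = 0) and still penalises discordant same-module pairs;
    # ties break by smaller power, then smaller module size
    def rank_key(r: EnrichmentFactorResult):
        ef_cc = ((r.n1 + 0.5) * (r.n4 + 0.5)) / ((r.n2 + 0.5) * (r.n3 + 0.5))
        return (-ef_cc, r.params.power, r.params.min_module_size)

    results.sort(key=rank_key)
    return results, results[0].params


# ---------------------------------------------------------------------------
# module-muscle association and module selection

def module_muscle_association(
    me: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, LMMResult]]:
    """Mixed-model muscle test per module eigengene, BH across modules, plus
    a likelihood-ratio test of the individual random effect."""
    meta = metadata.reindex(me.index)
    results: dict[str, LMMResult] = {}
    lrt = {}
    for mod in me.columns:
        results[mod] = fit_muscle_lmm(me[mod], meta)
        if results[mod].degenerate:
            lrt[mod] = (0.0, 1.0)
        else:
            lrt[mod] = random_effect_lrt(me[mod], meta)
    pvals = np.array([results[m].pvalue for m in me.columns])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for m, q in zip(me.columns, qvals):
        results[m].qvalue = float(q)
    summary = pd.DataFrame({
        "module": list(me.columns),
        "F": [results[m].fvalue for m in me.columns],
        "p": pvals,
        "q": qvals,
        "muscle_related": qvals < alpha,
        "ranef_lr": [lrt[m][0] for m in me.columns],
        "ranef_p": [lrt[m][1] for m in me.columns],
    }).set_index("module")
    return summary, results


def flag_celltype_modules(
    assignment: pd.Series,
    markers: dict[str, list[str]],
    min_markers: int = 5,
) -> pd.Series:
    """Flag modules containing at least ``min_markers`` genes of any single
    cell-type marker set (modules driven by cell-type composition)."""
    modules = [m for m in assignment.unique() if m != UNASSIGNED]
    flags = {}
    for mod in modules:
        genes = set(assignment.index[assignment == mod])
        flags[mod] = any(len(genes & set(ms)) >= min_markers
                         for ms in markers.values())
    return pd.Series(flags, dtype=bool)


def select_top_modules(
    module_de_f: dict[str, np.ndarray | list[float]],
    annotation_q: dict[str, float] | None = None,
    f_quantile_threshold: float = 5.5,
    q_threshold: float = 0.01,
) -> list[str]:
    """Modules whose member genes' DE F-values have a third quartile
    strictly above the threshold, intersected with an optional per-module
    annotation FDR criterion (skipped with a warning when absent)."""
    if annotation_q is None:
        warnings.warn("no annotation enrichment supplied; q criterion skipped")
    selected = []
    for mod, fvals in module_de_f.items():
        fvals = np.asarray(fvals, float)
        fvals = fvals[np.isfinite(fvals)]
        if fvals.size == 0:
            continue
        if np.quantile(fvals, 0.75) <= f_quantile_threshold:
            continue
        if annotation_q is not None and \
                not (annotation_q.get(mod, np.inf) < q_threshold):
            continue
        selected.append(mod)
    return selected
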
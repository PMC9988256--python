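"""Quantitative scoring of segmented histology object tables.

Myofiber typing: percentile-based quality filtering of segmented fibers,
selection of the best cryosection per sample, per-sample RMS scaling of the
three myosin-heavy-chain mean fluorescence intensities, natural-log
transform, and mean-shift clustering (bandwidth h = 0.02) with removal of
clusters holding less than 1% of all fibers.  Capillary scoring: objects
double-positive for CD31 and ENG with area in (3, 51) um^2 and circularity
above 0.5, expressed per unit tissue area.  RNA-foci scoring: speckles
smaller than 3.5 um^2 with circularity above 0.98, averaged per myofiber.
All rule inequalities are strict, following their verbal definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import MeanShift

from .lmm import LMMResult, fit_muscle_lmm

MFI_PREFIX = "mfi_"


@dataclass(frozen=True)
class FiberTypingParams:
    bandwidth: float = 0.02
    min_cluster_fraction: float = 0.01
    min_fibers_per_sample: int = 100
    boundary_percentile: float = 5.0
    interior_percentile: float = 95.0
    csa_percentiles: tuple[float, float] = (10.0, 99.0)
    circularity_percentile: float = 1.0
    # the verbatim protocol text excludes circularity *greater* than the 1st
    # percentile, which would discard 99% of fibers; the default corrects
    # this to exclusion below the 1st percentile
    strict_circularity_text: bool = False

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not 0 < self.min_cluster_fraction < 1:
            raise ValueError("min_cluster_fraction must be in (0, 1)")


@dataclass
class FiberTypeResult:
    labels: pd.Series                 # object_id -> cluster id (-1 = excluded)
    proportions: pd.DataFrame         # sample x surviving cluster
    centroids: pd.DataFrame           # cluster x log-scaled MFI channels
    excluded_fraction: float
    n_modes: int


def _percentile_mask(values: np.ndarray, pct: float, side: str) -> np.ndarray:
    """Strict exclusion mask against a linear-interpolation percentile;
    degenerate (constant) features exclude nothing."""
    if np.ptp(values) == 0:
        return np.zeros(len(values), bool)
    thr = np.percentile(values, pct)
    return values < thr if side == "below" else values > thr


def filter_myofibers(
    objects: pd.DataFrame, params: FiberTypingParams = FiberTypingParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentile quality filter for segmented myofibers.

    Excludes objects with boundary certainty below the 5th percentile,
    interior certainty above the 95th, CSA outside the (10th, 99th)
    percentiles computed per muscle (all other criteria on the pooled
    samples), or circularity below the 1st percentile.  Returns the
    retained table and an exclusion ledger recording which rules fired.
    """
    if objects.empty:
        raise ValueError("empty object table")
    required = {"area_um2", "circularity", "boundary_certainty",
                "interior_certainty"}
    if required - set(objects.columns):
        raise ValueError(f"missing columns: {sorted(required - set(objects.columns))}")

    ledger = pd.DataFrame(index=objects.index)
    ledger["boundary_low"] = _percentile_mask(
        objects["boundary_certainty"].to_numpy(float),
        params.boundary_percentile, "below")
    ledger["interior_high"] = _percentile_mask(
        objects["interior_certainty"].to_numpy(float),
        params.interior_percentile, "above")

    csa = objects["area_um2"].to_numpy(float)
    lo = np.zeros(len(objects), bool)
    hi = np.zeros(len(objects), bool)
    group = objects["muscle"] if "muscle" in objects.columns \
        else pd.Series("all", index=objects.index)
    for _, idx in objects.groupby(group, sort=False).indices.items():
        lo[idx] = _percentile_mask(csa[idx], params.csa_percentiles[0], "below")
        hi[idx] = _percentile_mask(csa[idx], params.csa_percentiles[1], "above")
    ledger["csa_low"] = lo
    ledger["csa_high"] = hi

    side = "above" if params.strict_circularity_text else "below"
    ledger["circularity"] = _percentile_mask(
        objects["circularity"].to_numpy(float),
        params.circularity_percentile, side)

    excluded = ledger.any(axis=1)
    ledger["excluded"] = excluded
    return objects.loc[~excluded].copy(), ledger


def select_section(
    objects: pd.DataFrame, params: FiberTypingParams = FiberTypingParams()
) -> pd.DataFrame:
    """Per sample: the cryosection with the most retained fibers (ties by
    section_id order) and an inclusion flag (>= min_fibers_per_sample)."""
    rows = []
    for sample, sub in objects.groupby("sample_id", sort=False):
        counts = sub.groupby("section_id").size().sort_index()
        best = counts.index[np.argmax(counts.to_numpy())]
        n = int(counts[best])
        rows.append((sample, best, n, n >= params.min_fibers_per_sample))
    return pd.DataFrame(rows, columns=["sample_id", "section_id", "n_fibers",
                                       "included"]).set_index("sample_id")


def fiber_type_clustering(
    objects: pd.DataFrame, params: FiberTypingParams = FiberTypingParams()
) -> FiberTypeResult:
    """Mean-shift myofiber typing on RMS-scaled, log-transformed MFIs.

    Per sample and channel, MFIs are divided by the root-mean-square
    (scaling without centering) and natural-log transformed; all samples
    are pooled and clustered by mean shift with the configured bandwidth;
    clusters holding less than ``min_cluster_fraction`` of all fibers are
    discarded (label -1) and per-sample proportions are reported over the
    surviving clusters as fractions of each sample's total fibers.
    """
    channels = [c for c in objects.columns if c.startswith(MFI_PREFIX)]
    if len(channels) != 3:
        raise ValueError("expected exactly 3 MFI channels")
    mfi = objects[channels].to_numpy(float).copy()
    if (mfi <= 0).any():
        warnings.warn("non-positive MFI values shifted by machine epsilon")
        mfi[mfi <= 0] = np.finfo(float).eps
    scaled = np.empty_like(mfi)
    for sample, idx in objects.groupby("sample_id", sort=False).indices.items():
        rms = np.sqrt(np.mean(mfi[idx] ** 2, axis=0))
        scaled[idx] = mfi[idx] / rms[None, :]
    logmfi = np.log(scaled)

    ms = MeanShift(bandwidth=params.bandwidth, bin_seeding=True,
                   min_bin_freq=max(1, int(0.001 * len(logmfi))),
                   cluster_all=True)
    raw_labels = ms.fit_predict(logmfi)

    counts = pd.Series(raw_labels).value_counts()
    total = len(raw_labels)
    surviving = sorted(counts.index[counts / total >= params.min_cluster_fraction])
    remap = {old: new for new, old in enumerate(
        sorted(surviving, key=lambda c: -counts[c]))}
    labels = np.array([remap.get(l, -1) for l in raw_labels])

    obj_index = objects["object_id"] if "object_id" in objects.columns \
        else objects.index
    label_s = pd.Series(labels, index=obj_index, name="cluster")

    prop_rows = {}
    for sample, idx in objects.groupby("sample_id", sort=False).indices.items():
        lab = labels[idx]
        denom = len(lab)
        prop_rows[sample] = {
            c: float((lab == remap[c]).sum()) / denom for c in surviving
        }
    proportions = pd.DataFrame(prop_rows).T.reindex(
        columns=[remap[c] for c in surviving]).fillna(0.0)
    proportions.columns = [f"cluster{c}" for c in proportions.columns]

    centroids = pd.DataFrame(
        [logmfi[labels == remap[c]].mean(axis=0) for c in surviving],
        index=[f"cluster{remap[c]}" for c in surviving], columns=channels)
    return FiberTypeResult(
        labels=label_s, proportions=proportions, centroids=centroids,
        excluded_fraction=float((labels == -1).mean()), n_modes=len(surviving))


def capillary_metrics(
    vessels: pd.DataFrame,
    tissue_area_um2,
    area_range: tuple[float, float] = (3.0, 51.0),
    min_circularity: float = 0.5,
) -> pd.DataFrame:
    """Per-sample CD31-positive area fraction and capillary density.

    A capillary is an object positive for both CD31 and ENG with area
    strictly inside ``area_range`` (um^2) and circularity strictly above
    ``min_circularity``; density = capillaries per um^2 of tissue.
    ``tissue_area_um2`` is a scalar or a mapping section_id -> area.
    """
    for col in ("cd31_pos", "eng_pos"):
        if col not in vessels.columns:
            raise ValueError(f"missing positivity flag column {col!r}")

    def section_area(section):
        if np.isscalar(tissue_area_um2):
            return float(tissue_area_um2)
        return float(tissue_area_um2[section])

    is_cap = (
        vessels["cd31_pos"].astype(bool)
        & vessels["eng_pos"].astype(bool)
        & (vessels["area_um2"] > area_range[0])
        & (vessels["area_um2"] < area_range[1])
        & (vessels["circularity"] > min_circularity)
    )
    rows = []
    for sample, sub in vessels.groupby("sample_id", sort=False):
        sections = sub["section_id"].unique()
        total_area = sum(section_area(s) for s in sections)
        cd31_area = sub.loc[sub["cd31_pos"].astype(bool), "area_um2"].sum()
        n_cap = int(is_cap.loc[sub.index].sum())
        rows.append((sample, 100.0 * cd31_area / total_area,
                     n_cap, n_cap / total_area))
    return pd.DataFrame(rows, columns=[
        "sample_id", "cd31_area_pct", "n_capillaries", "capillary_density",
    ]).set_index("sample_id")


def foci_metrics(
    foci: pd.DataFrame,
    fibers_per_sample,
    negative_control: pd.DataFrame | None = None,
    max_area: float = 3.5,
    min_circularity: float = 0.98,
    control_percentile: float = 100.0,
) -> pd.DataFrame:
    """Average RNA foci per myofiber per sample.

    A focus is a speckle with area strictly below ``max_area`` um^2 and
    circularity strictly above ``min_circularity``; with a negative-control
    table, foci must additionally exceed the control intensity threshold
    (the ``control_percentile`` of control speckle intensities, default the
    maximum, so approximately all control foci classify as negative).
    """
    fibers = pd.Series(fibers_per_sample, dtype=float)
    if (fibers <= 0).any():
        raise ValueError("fiber counts must be positive")
    is_focus = (foci["area_um2"] < max_area) & \
               (foci["circularity"] > min_circularity)
    if negative_control is not None:
        ctl = negative_control
        ctl_pass = ctl[(ctl["area_um2"] < max_area)
                       & (ctl["circularity"] > min_circularity)]
        pool = ctl_pass if len(ctl_pass) else ctl
        thr = float(np.percentile(pool["intensity"], control_percentile)) \
            if len(pool) else -np.inf
        is_focus &= foci["intensity"] > thr
    counts = foci.loc[is_focus].groupby("sample_id").size()
    rows = []
    for sample, n_fib in fibers.items():
        n = int(counts.get(sample, 0))
        rows.append((sample, n, n / n_fib))
    return pd.DataFrame(rows, columns=[
        "sample_id", "n_foci", "foci_per_fiber"]).set_index("sample_id")


def compare_group_metric(
    metric: pd.Series, metadata: pd.DataFrame
) -> LMMResult:
    """Mixed-model muscle comparison of a per-sample histology metric."""
    meta = metadata.reindex(metric.index)
    return fit_muscle_lmm(metric, meta)
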
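"""Seeded synthetic data emulating the leg-muscle atlas study design.

The real atlas profiles 7 leg-muscle tissues (6 muscles, one sampled at two
locations) from 20 individuals, with the tissues falling into three latent
groups: G1 = hamstrings (GR, STM, STD), G2 = quadriceps (RF, VL, VM),
G3 = lower leg (GL).  The generator reproduces the statistical structure the
downstream models assume:

* negative-binomial gene counts whose log-mean combines a gene baseline,
  muscle and individual random effects, an optional batch effect, a
  cell-type mixture term driven by per-sample cell-type fractions acting on
  marker-gene signatures, planted co-expression modules driven by
  sample-level latent factors, and optional planted group-differential genes;
* disjoint marker-gene sets, one per cell type;
* object tables for myofiber typing (3-cluster MFI structure with
  per-sample multiplicative intensity scales), capillary scoring and
  RNA-foci counting, each with ground-truth records.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_MUSCLES = ("GR", "STM", "STD", "RF", "VL", "VM", "GL")
DEFAULT_GROUP_MAP = {
    "GR": "G1", "STM": "G1", "STD": "G1",
    "RF": "G2", "VL": "G2", "VM": "G2",
    "GL": "G3",
}
DEFAULT_CELLTYPES = ("fast_twitch", "slow_twitch", "endothelial", "FAP", "immune")

# Dirichlet concentrations per latent group.  Endothelial concentration is
# 50% higher in G2/G3 than G1, mirroring the higher capillary content of the
# quadriceps and lower-leg muscles; G3 additionally carries more non-muscle
# cells (FAP/immune), which is what sets the lower-leg muscle apart.
DEFAULT_FRACTION_PRIOR = {
    "G1": (12.0, 8.0, 4.0, 3.0, 3.0),
    "G2": (8.0, 12.0, 6.0, 3.0, 3.0),
    "G3": (6.0, 12.0, 6.0, 5.0, 5.0),
}


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout: individuals x muscle tissues with random missingness."""

    n_individuals: int = 20
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    group_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))
    n_batches: int = 2
    # the real atlas retains 128 of the 140 possible individual x muscle cells
    missingness_rate: float = 12.0 / 140.0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if len(set(self.muscles)) != len(self.muscles):
            raise ValueError("duplicate muscle labels")
        if set(self.muscles) - set(self.group_map):
            raise ValueError("every muscle must map to a group")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must be in [0, 1)")


@dataclass(frozen=True)
class GenerativeParams:
    """Knobs of the count generator (log-scale effects, NB noise, layout)."""

    n_genes: int = 2000
    n_celltypes: int = len(DEFAULT_CELLTYPES)
    celltype_names: tuple[str, ...] = DEFAULT_CELLTYPES
    markers_per_celltype: int = 30
    celltype_fraction_prior: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_FRACTION_PRIOR.items()}
    )
    # muscle/group effect scales are kept below the co-expression detection
    # floor of the signed-hybrid power transform, so the planted latent-factor
    # blocks are the only co-expression structure in the default world
    muscle_effect_sd: float = 0.08
    group_effect_sd: float = 0.12
    individual_effect_sd: float = 0.40
    batch_effect_sd: float = 0.10
    nb_dispersion: float = 0.10
    library_size_range: tuple[float, float] = (8e6, 15e6)
    # (size, within-module correlation) of planted co-expression blocks
    planted_modules: tuple[tuple[int, float], ...] = (
        (80, 0.8), (70, 0.8), (60, 0.8), (50, 0.8), (40, 0.8),
    )
    # planted group-differential genes: count and log2 fold change (G1 vs rest)
    n_group_de_genes: int = 0
    group_de_log2fc: float = 1.0
    # the first k planted modules get a group-level shift on their latent
    # factor, making them muscle-related (as the atlas's modules are)
    n_muscle_related_modules: int = 1
    module_group_shift: float = 1.0
    marker_signature_high: float = 8.0
    marker_signature_low: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_celltypes < 1:
            raise ValueError("non-positive dimensions")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for conc in self.celltype_fraction_prior.values():
            if any(c <= 0 for c in conc):
                raise ValueError("Dirichlet concentrations must be positive")
        if sum(s for s, _ in self.planted_modules) > self.n_genes:
            raise ValueError("planted module sizes exceed gene pool")
        if len(self.celltype_names) != self.n_celltypes:
            raise ValueError("celltype_names length mismatch")


@dataclass
class TruthRecord:
    """Ground truth attached to a simulated dataset."""

    fractions: pd.DataFrame | None = None          # samples x cell types
    muscle_effects: pd.DataFrame | None = None     # genes x muscles, log scale
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    module_labels: pd.Series | None = None         # gene -> module or "unassigned"
    module_factors: pd.DataFrame | None = None     # samples x modules latent factors
    de_genes: pd.DataFrame | None = None           # gene, log2fc, up_group
    fiber_labels: pd.Series | None = None          # object -> true cluster (-1 contaminant)
    extra: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            if isinstance(val, pd.DataFrame):
                val = {"index": list(val.index), "columns": list(val.columns),
                       "values": val.to_numpy().tolist()}
            elif isinstance(val, pd.Series):
                val = {"index": list(val.index), "values": val.to_list()}
            out[key] = val
        return out


# ---------------------------------------------------------------------------
# deterministic gene layout: [module blocks][marker genes][DE genes][background]

def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _gene_layout(params: GenerativeParams):
    """Assign planted roles to gene indices, deterministically from params."""
    n_mod = sum(s for s, _ in params.planted_modules)
    n_marker = params.n_celltypes * params.markers_per_celltype
    n_de = params.n_group_de_genes
    if n_mod + n_marker + n_de > params.n_genes:
        raise ValueError("planted structure exceeds gene pool")
    idx = 0
    module_slices = []
    for size, rho in params.planted_modules:
        module_slices.append((slice(idx, idx + size), rho))
        idx += size
    marker_slices = []
    for _ in range(params.n_celltypes):
        marker_slices.append(slice(idx, idx + params.markers_per_celltype))
        idx += params.markers_per_celltype
    de_slice = slice(idx, idx + n_de)
    return module_slices, marker_slices, de_slice


def simulate_marker_sets(params: GenerativeParams) -> dict[str, list[str]]:
    """Disjoint marker-gene sets, one per cell type, matching the layout
    used by :func:`simulate_bulk_counts` for the same parameters."""
    if params.n_celltypes * params.markers_per_celltype > params.n_genes:
        raise ValueError("marker demand exceeds gene pool")
    _, marker_slices, _ = _gene_layout(params)
    ids = _gene_ids(params.n_genes)
    return {
        name: ids[sl] for name, sl in zip(params.celltype_names, marker_slices)
    }


def simulate_bulk_counts(
    design: StudyDesign, params: GenerativeParams
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate a genes x samples negative-binomial count matrix.

    Returns ``(counts, metadata, truth)`` where metadata has columns
    ``sample, individual, muscle, batch`` and truth carries the per-sample
    cell-type fractions, per-gene effects, marker membership, planted module
    labels and latent module factors.
    """
    rng = np.random.default_rng(params.seed)
    genes = _gene_ids(params.n_genes)
    module_slices, marker_slices, de_slice = _gene_layout(params)

    # -- sample sheet -------------------------------------------------------
    individuals = [f"I{i + 1:02d}" for i in range(design.n_individuals)]
    cells = [(ind, mus) for ind in individuals for mus in design.muscles]
    n_total = len(cells)
    n_drop = int(round(design.missingness_rate * n_total))
    keep = np.ones(n_total, bool)
    if n_drop:
        keep[rng.choice(n_total, size=n_drop, replace=False)] = False
    cells = [c for c, k in zip(cells, keep) if k]
    meta = pd.DataFrame(cells, columns=["individual", "muscle"])
    meta["sample"] = meta["individual"] + "_" + meta["muscle"]
    # library-prep batches cut across individuals (each sample is a library)
    meta["batch"] = [f"B{(i % design.n_batches) + 1}" for i in range(len(meta))]
    meta = meta[["sample", "individual", "muscle", "batch"]].set_index(
        "sample", drop=False)
    n_samples = len(meta)

    # -- per-gene and per-sample effects ------------------------------------
    baseline = rng.normal(2.0, 1.8, size=params.n_genes)
    # hierarchical muscle effects: a component shared by the muscles of a
    # latent group plus a muscle-specific component, so muscles of the same
    # group have correlated expression shifts (as the atlas observes)
    group_names = sorted({design.group_map[m] for m in design.muscles})
    group_eff = rng.normal(0.0, params.group_effect_sd,
                           size=(params.n_genes, len(group_names)))
    muscle_eff = rng.normal(0.0, params.muscle_effect_sd,
                            size=(params.n_genes, len(design.muscles)))
    for j, mus in enumerate(design.muscles):
        muscle_eff[:, j] += group_eff[:, group_names.index(design.group_map[mus])]
    indiv_eff = rng.normal(0.0, params.individual_effect_sd,
                           size=(params.n_genes, design.n_individuals))
    batch_eff = rng.normal(0.0, params.batch_effect_sd,
                           size=(params.n_genes, design.n_batches))

    mus_idx = meta["muscle"].map({m: i for i, m in enumerate(design.muscles)}).to_numpy()
    ind_idx = meta["individual"].map({v: i for i, v in enumerate(individuals)}).to_numpy()
    bat_idx = meta["batch"].map({f"B{i + 1}": i for i in range(design.n_batches)}).to_numpy()

    eta = (baseline[:, None]
           + muscle_eff[:, mus_idx]
           + indiv_eff[:, ind_idx]
           + batch_eff[:, bat_idx])

    # -- cell-type mixture term ---------------------------------------------
    fractions = np.empty((n_samples, params.n_celltypes))
    for s in range(n_samples):
        group = design.group_map[meta["muscle"].iloc[s]]
        conc = np.asarray(params.celltype_fraction_prior[group], float)
        fractions[s] = rng.dirichlet(conc)
    signature = np.ones((params.n_genes, params.n_celltypes))
    for c, sl in enumerate(marker_slices):
        signature[sl, :] = params.marker_signature_low
        signature[sl, c] = params.marker_signature_high
    eta += np.log(signature @ fractions.T)

    # -- planted co-expression modules --------------------------------------
    # shared sample-level latent factor, loading sqrt(rho/(1-rho))*s0 where s0
    # approximates the residual log-scale noise of the NB counts
    s0 = 0.35
    module_names = [f"PM{k + 1}" for k in range(len(module_slices))]
    factors = rng.normal(0.0, 1.0, size=(n_samples, len(module_slices)))
    sample_groups = np.array([design.group_map[m] for m in meta["muscle"]])
    group_levels = sorted(set(sample_groups))
    group_shift = {g: params.module_group_shift * (i - (len(group_levels) - 1) / 2)
                   for i, g in enumerate(group_levels)}
    muscle_related = module_names[:params.n_muscle_related_modules]
    for k, _ in enumerate(muscle_related):
        factors[:, k] += np.array([group_shift[g] for g in sample_groups])
    module_labels = pd.Series("unassigned", index=genes, name="module")
    for k, (sl, rho) in enumerate(module_slices):
        lam = np.sqrt(rho / (1.0 - rho)) * s0
        eta[sl, :] += lam * factors[:, k][None, :]
        module_labels.iloc[sl] = module_names[k]

    # -- planted group-differential genes ------------------------------------
    de_records = []
    de_genes_idx = range(de_slice.start, de_slice.stop)
    groups = np.array([design.group_map[m] for m in meta["muscle"]])
    for j, g in enumerate(de_genes_idx):
        up_group = ("G1", "G2", "G3")[j % 3]
        shift = params.group_de_log2fc * np.log(2.0)
        eta[g, groups == up_group] += shift
        de_records.append({"gene": genes[g], "log2fc": params.group_de_log2fc,
                           "up_group": up_group})

    # -- negative-binomial sampling -----------------------------------------
    lib = rng.uniform(*params.library_size_range, size=n_samples)
    prob = np.exp(eta - eta.max(axis=0, keepdims=True))
    prob /= prob.sum(axis=0, keepdims=True)
    mu = prob * lib[None, :]
    r = 1.0 / params.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu * params.nb_dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    truth = TruthRecord(
        fractions=pd.DataFrame(fractions, index=meta.index,
                               columns=list(params.celltype_names)),
        muscle_effects=pd.DataFrame(muscle_eff, index=genes,
                                    columns=list(design.muscles)),
        marker_sets=simulate_marker_sets(params),
        module_labels=module_labels,
        module_factors=pd.DataFrame(factors, index=meta.index,
                                    columns=module_names),
        de_genes=pd.DataFrame(de_records, columns=["gene", "log2fc", "up_group"]),
        extra={"muscle_related_modules": muscle_related},
    )
    return counts_df, meta, truth


def split_transcripts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    transcripts_per_gene: int = 2,
    usage_shift_genes: int = 0,
    usage_shift: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split gene counts into transcript counts by multinomial usage.

    The first ``usage_shift_genes`` genes get a muscle-group-dependent usage
    shift (isoform switching with flat gene totals): in G1 samples transcript
    1 gains ``usage_shift`` of the mass at the expense of transcript 2.
    Returns ``(transcript_counts, tx2gene)``.
    """
    rng = np.random.default_rng(seed)
    groups = metadata["muscle"].map(DEFAULT_GROUP_MAP).reindex(counts.columns)
    base_usage = rng.dirichlet(np.full(transcripts_per_gene, 5.0),
                               size=counts.shape[0])
    tx_rows, tx_ids, tx_gene = [], [], []
    cnt = counts.to_numpy()
    is_g1 = (groups == "G1").to_numpy()
    for gi, gene in enumerate(counts.index):
        usage = np.tile(base_usage[gi], (counts.shape[1], 1))
        if gi < usage_shift_genes and transcripts_per_gene >= 2:
            shift = np.minimum(usage[is_g1, 1], usage_shift)
            usage[is_g1, 0] += shift
            usage[is_g1, 1] -= shift
        split = np.stack([
            rng.multinomial(cnt[gi, s], usage[s]) for s in range(counts.shape[1])
        ]).T
        for t in range(transcripts_per_gene):
            tx_rows.append(split[t])
            tx_ids.append(f"{gene}.t{t + 1}")
            tx_gene.append(gene)
    tx_counts = pd.DataFrame(np.asarray(tx_rows), index=tx_ids,
                             columns=counts.columns)
    tx2gene = pd.DataFrame({"transcript": tx_ids, "gene": tx_gene})
    return tx_counts, tx2gene


# ---------------------------------------------------------------------------
# histology object tables

DEFAULT_MFI_CENTERS = (
    (900.0, 90.0, 70.0),    # MyHC1-dominated (slow, type 1)
    (80.0, 950.0, 110.0),   # MyHC2A-dominated
    (70.0, 160.0, 1000.0),  # MyHC2X-dominated
)
DEFAULT_MIXTURE_WEIGHTS = (0.45, 0.35, 0.20)
MFI_CHANNELS = ("mfi_myhc1", "mfi_myhc2a", "mfi_myhc2x")


def simulate_myofiber_objects(
    n_samples: int,
    n_fibers_per_sample: int,
    cluster_centers: Sequence[Sequence[float]] = DEFAULT_MFI_CENTERS,
    noise_sd: float = 0.01,
    contamination_rate: float = 0.0,
    seed: int = 0,
    mixture_weights: Sequence[float] | None = None,
    sample_scale_sd: float = 0.2,
    muscles: Sequence[str] | None = None,
    exact_mixture: bool = True,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Segmented-myofiber feature table with 3-channel MFI cluster structure.

    Each fiber's raw MFI triplet is log-normal around its cluster centre,
    multiplied by a per-sample per-channel scale (staining batch effect).
    Clean fibers carry saturated segmentation-certainty scores and mid-range
    CSA/circularity; contaminants get low certainty and extreme CSA so the
    percentile filters have something to remove.
    """
    centers = np.asarray(cluster_centers, float)
    if centers.size == 0:
        raise ValueError("at least one cluster centre required")
    if not (0 <= contamination_rate <= 1):
        raise ValueError("contamination_rate must be in [0, 1]")
    if mixture_weights is None:
        w = np.asarray(DEFAULT_MIXTURE_WEIGHTS[: len(centers)], float)
    else:
        w = np.asarray(mixture_weights, float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)

    rows, labels = [], []
    for s in range(n_samples):
        sample = f"S{s + 1:03d}"
        muscle = muscles[s] if muscles is not None else DEFAULT_MUSCLES[s % 7]
        scale = np.exp(rng.normal(0.0, sample_scale_sd, size=3))
        if exact_mixture:
            # plant the mixture weights exactly (largest-remainder rounding)
            # so per-sample proportions are the weights by construction
            base = np.floor(w * n_fibers_per_sample).astype(int)
            rem = w * n_fibers_per_sample - base
            short = n_fibers_per_sample - base.sum()
            base[np.argsort(-rem)[:short]] += 1
            lab = rng.permutation(np.repeat(np.arange(len(centers)), base))
        else:
            lab = rng.choice(len(centers), size=n_fibers_per_sample, p=w)
        mfi = np.exp(np.log(centers[lab]) + rng.normal(0, noise_sd,
                                                       (n_fibers_per_sample, 3)))
        mfi *= scale[None, :]
        n_cont = int(round(contamination_rate * n_fibers_per_sample))
        is_cont = np.zeros(n_fibers_per_sample, bool)
        if n_cont:
            is_cont[rng.choice(n_fibers_per_sample, n_cont, replace=False)] = True
        csa = rng.lognormal(np.log(3000.0), 0.35, n_fibers_per_sample)
        csa[is_cont] = np.where(rng.random(n_cont) < 0.5,
                                rng.uniform(10, 80, n_cont),
                                rng.uniform(30000, 60000, n_cont))
        circ = np.clip(rng.normal(0.82, 0.06, n_fibers_per_sample), 0.2, 1.0)
        boundary = np.full(n_fibers_per_sample, 0.9)
        interior = np.full(n_fibers_per_sample, 0.1)
        boundary[is_cont] = rng.uniform(0.0, 0.3, n_cont)
        interior[is_cont] = rng.uniform(0.7, 1.0, n_cont)
        lab = np.where(is_cont, -1, lab)
        for i in range(n_fibers_per_sample):
            rows.append((f"{sample}_f{i:05d}", sample, muscle, f"{sample}_sec1",
                         csa[i], circ[i], mfi[i, 0], mfi[i, 1], mfi[i, 2],
                         boundary[i], interior[i]))
            labels.append(lab[i])
    objects = pd.DataFrame(rows, columns=[
        "object_id", "sample_id", "muscle", "section_id", "area_um2",
        "circularity", *MFI_CHANNELS, "boundary_certainty", "interior_certainty",
    ])
    truth = TruthRecord(
        fiber_labels=pd.Series(labels, index=objects["object_id"], name="cluster"),
        extra={"mixture_weights": w.tolist(),
               "centers": centers.tolist()},
    )
    return objects, truth


def simulate_vessel_objects(
    n_sections: int,
    objects_per_section: int,
    tissue_area_um2: float,
    capillary_fraction: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Vessel-staining object table with a planted number of true capillaries.

    True capillaries satisfy all three scoring rules (CD31+ and ENG+, area in
    (3, 51) um^2, circularity > 0.5); the remaining objects each violate at
    least one rule.  Returns the table and a truth dict with the planted
    per-section capillary counts.
    """
    if tissue_area_um2 <= 0:
        raise ValueError("tissue area must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    planted: dict[str, int] = {}
    for s in range(n_sections):
        section = f"sec{s + 1:03d}"
        sample = f"S{s + 1:03d}"
        n_cap = int(round(capillary_fraction * objects_per_section))
        planted[section] = n_cap
        for i in range(objects_per_section):
            if i < n_cap:
                area = rng.uniform(5.0, 45.0)
                circ = rng.uniform(0.6, 0.95)
                cd31, eng = True, True
            else:
                # violate one randomly chosen rule, keep the rest valid
                area = rng.uniform(5.0, 45.0)
                circ = rng.uniform(0.6, 0.95)
                cd31, eng = True, True
                rule = rng.integers(0, 3)
                if rule == 0:
                    if rng.random() < 0.5:
                        cd31 = False
                    else:
                        eng = False
                elif rule == 1:
                    area = rng.uniform(55.0, 400.0) if rng.random() < 0.5 \
                        else rng.uniform(0.5, 2.5)
                else:
                    circ = rng.uniform(0.05, 0.45)
            rows.append((f"{section}_o{i:05d}", sample, section, area, circ,
                         cd31, eng))
    objects = pd.DataFrame(rows, columns=[
        "object_id", "sample_id", "section_id", "area_um2", "circularity",
        "cd31_pos", "eng_pos",
    ])
    return objects, {"planted_capillaries": planted,
                     "tissue_area_um2": tissue_area_um2}


def simulate_foci_objects(
    n_fibers: int,
    foci_per_fiber_mean: float,
    false_positive_rate: float,
    seed: int = 0,
    n_samples: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """RNAscope speckle table: true foci pass the area/circularity rules,
    false positives violate at least one; fiber assignment is recorded."""
    if n_fibers <= 0:
        raise ValueError("need at least one myofiber")
    rng = np.random.default_rng(seed)
    rows = []
    true_counts: dict[str, int] = {}
    per_sample = n_fibers // n_samples
    fid = 0
    for s in range(n_samples):
        sample = f"S{s + 1:03d}"
        n_true = 0
        for _ in range(per_sample):
            fiber = f"fiber{fid:06d}"
            fid += 1
            for _ in range(rng.poisson(foci_per_fiber_mean)):
                area = rng.uniform(0.2, 3.0)
                circ = rng.uniform(0.985, 1.0)
                intensity = rng.uniform(120.0, 255.0)
                rows.append((f"focus{len(rows):07d}", sample, fiber, area,
                             circ, intensity))
                n_true += 1
            n_fp = rng.poisson(false_positive_rate * foci_per_fiber_mean)
            for _ in range(n_fp):
                if rng.random() < 0.5:
                    area, circ = rng.uniform(4.0, 12.0), rng.uniform(0.985, 1.0)
                else:
                    area, circ = rng.uniform(0.2, 3.0), rng.uniform(0.5, 0.97)
                rows.append((f"focus{len(rows):07d}", sample, fiber, area,
                             circ, rng.uniform(120.0, 255.0)))
        true_counts[sample] = n_true
    objects = pd.DataFrame(rows, columns=[
        "object_id", "sample_id", "fiber_id", "area_um2", "circularity",
        "intensity",
    ])
    return objects, {"true_foci": true_counts,
                     "fibers_per_sample": {f"S{s + 1:03d}": per_sample
                                           for s in range(n_samples)}}


def simulate_knowledge_network(
    truth: TruthRecord, pathway_noise: float, seed: int = 0
) -> dict[str, list[str]]:
    """Pathway membership derived from planted modules, with a fraction of
    genes reassigned to random pathways (``pathway_noise`` in [0, 1])."""
    if truth.module_labels is None:
        raise ValueError("truth record carries no module labels")
    if not 0 <= pathway_noise <= 1:
        raise ValueError("pathway_noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = truth.module_labels[truth.module_labels != "unassigned"]
    modules = sorted(labels.unique())
    assigned = labels.copy()
    n_flip = int(round(pathway_noise * len(assigned)))
    if n_flip:
        flip = rng.choice(len(assigned), size=n_flip, replace=False)
        assigned.iloc[flip] = rng.choice(modules, size=n_flip)
    return {
        f"pathway_{m}": sorted(assigned.index[assigned == m]) for m in modules
    }
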
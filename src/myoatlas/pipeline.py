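"""End-to-end pipeline: synthetic data (or supplied tables) through
preprocessing, cell-type composition, differential expression, consensus
network and histology, with seeding, logging and an output manifest.

A single global seed fans out to per-stage seeds via CRC32 of the stage
name XOR the global seed (masked to 31 bits), so toggling stages never
changes another stage's stream.  Re-running with the same config and seed
is bit-identical; the manifest embeds the config and the SHA256 of every
output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, celltype as ct, diffexpr as de, histology as hist
from . import io as mio
from . import network as net
from . import preprocess as pp
from . import synthetic as syn

logger = logging.getLogger("myoatlas.pipeline")

STAGES = ("simulate", "preprocess", "celltype", "diffexpr", "network",
          "histology")


def stage_seed(global_seed: int, stage: str) -> int:
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) & 0x7FFFFFFF


def _from_dict(cls, d: dict, where: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class HistologyConfig:
    n_samples: int = 14
    fibers_per_sample: int = 1500
    noise_sd: float = 0.01
    contamination_rate: float = 0.05
    vessel_sections: int = 14
    vessel_objects_per_section: int = 200
    tissue_area_um2: float = 1e6
    capillary_fraction: float = 0.4
    foci_fibers: int = 200
    foci_per_fiber_mean: float = 2.0
    foci_false_positive_rate: float = 0.2


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    stages: tuple[str, ...] = STAGES
    design: syn.StudyDesign = field(default_factory=syn.StudyDesign)
    generative: syn.GenerativeParams = field(default_factory=syn.GenerativeParams)
    network: net.NetworkParams = field(default_factory=net.NetworkParams)
    histology: HistologyConfig = field(default_factory=HistologyConfig)
    # optional real-data inputs; when set, the simulate stage is skipped
    counts_path: str | None = None
    metadata_path: str | None = None
    markers_path: str | None = None

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {}
        tuple_fields = {
            "design": {"muscles": 1},
            "generative": {"planted_modules": 2, "celltype_names": 1,
                           "library_size_range": 1},
        }
        for key, cls in (("design", syn.StudyDesign),
                         ("generative", syn.GenerativeParams),
                         ("network", net.NetworkParams),
                         ("histology", HistologyConfig)):
            if key in d:
                block = dict(d.pop(key))
                for f, depth in tuple_fields.get(key, {}).items():
                    if f in block:
                        block[f] = tuple(tuple(x) for x in block[f]) \
                            if depth == 2 else tuple(block[f])
                if key == "generative" and "celltype_fraction_prior" in block:
                    block["celltype_fraction_prior"] = {
                        g: tuple(v) for g, v
                        in block["celltype_fraction_prior"].items()}
                sub[key] = _from_dict(cls, block, key)
        if "stages" in d:
            stages = tuple(d.pop("stages"))
            bad = set(stages) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
            sub["stages"] = stages
        cfg = _from_dict(PipelineConfig, {**d, **sub}, "pipeline")
        return cfg

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        def unpack(x):
            if isinstance(x, tuple):
                return [unpack(v) for v in x]
            if isinstance(x, dict):
                return {k: unpack(v) for k, v in x.items()}
            return x

        return unpack(asdict(self))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label="id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the output manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    outputs: dict[str, str] = {}
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            logger.info("stage %s (seed %d)", stage, stage_seed(config.seed, stage))
            try:
                _STAGE_FNS[stage](config, state, out, outputs)
            except Exception:
                logger.exception("stage %s failed", stage)
                raise RuntimeError(f"pipeline stage {stage!r} failed") from None
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {k: {"path": v, "sha256": _sha256(out / v)}
                    for k, v in outputs.items()},
    }
    manifest["parameter_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def _stage_simulate(config, state, out, outputs):
    seed = stage_seed(config.seed, "simulate")
    if config.counts_path is not None:
        state["counts"] = mio.read_counts(config.counts_path)
        state["metadata"] = mio.read_metadata(config.metadata_path)
        state["markers"] = mio.read_gmt(config.markers_path) \
            if config.markers_path else {}
        state["truth"] = None
        return
    params = syn.GenerativeParams(**{**asdict(config.generative), "seed": seed})
    counts, meta, truth = syn.simulate_bulk_counts(config.design, params)
    state.update(counts=counts, metadata=meta, truth=truth,
                 markers=truth.marker_sets)
    mio.write_counts(counts, out / "counts.tsv")
    mio.write_metadata(meta, out / "metadata.tsv")
    mio.write_gmt(truth.marker_sets, out / "markers.gmt")
    mio.write_json(truth.to_json_dict(), out / "truth.json")
    outputs.update({"counts": "counts.tsv", "metadata": "metadata.tsv",
                    "markers": "markers.gmt", "truth": "truth.json"})


def _stage_preprocess(config, state, out, outputs):
    counts, meta = state["counts"], state["metadata"]
    kept = pp.sample_qc(counts)
    counts = counts[kept]
    meta = meta.loc[kept]
    min_samples = min(16, max(2, counts.shape[1] - 1))
    filtered = pp.filter_low_expressed(counts, 10, min_samples)
    factors = pp.tmm_norm_factors(filtered)
    expr = pp.cpm_log(filtered, factors)
    vartab = pp.variance_decomposition(
        expr, meta, ["muscle", "individual", "batch"])
    state.update(filtered=filtered, factors=factors, expr=expr,
                 metadata=meta, variance=vartab)
    _write_tsv(expr, out / "log_cpm.tsv", "gene_id")
    _write_tsv(vartab, out / "variance_decomposition.tsv", "gene_id")
    factors.to_frame().to_csv(out / "norm_factors.tsv", sep="\t",
                              index_label="sample")
    outputs.update({"log_cpm": "log_cpm.tsv",
                    "variance_decomposition": "variance_decomposition.tsv",
                    "norm_factors": "norm_factors.tsv"})


def _stage_celltype(config, state, out, outputs):
    eigen = ct.celltype_eigenvectors(state["expr"], state["markers"])
    summary, _ = ct.celltype_association(eigen, state["metadata"])
    _, means = ct.cluster_muscles(eigen, state["metadata"])
    state["eigen"] = eigen
    _write_tsv(eigen.scores, out / "celltype_eigenvectors.tsv", "sample")
    _write_tsv(summary, out / "celltype_association.tsv", "celltype")
    _write_tsv(means, out / "celltype_muscle_means.tsv", "muscle")
    outputs.update({"celltype_eigenvectors": "celltype_eigenvectors.tsv",
                    "celltype_association": "celltype_association.tsv",
                    "celltype_muscle_means": "celltype_muscle_means.tsv"})


def _stage_diffexpr(config, state, out, outputs):
    meta = state["metadata"]
    expr, weights = de.voom_weights(state["filtered"], state["factors"],
                                    meta["muscle"])
    deg = de.per_gene_mixed_de(expr, weights, meta)
    if "eigen" in state:
        deg = de.flag_celltype_driven(deg, expr, state["eigen"])
    frac = de.pairwise_deg_fraction(deg, exclude_flagged="eigen" in state)
    state.update(deg=deg, voom_expr=expr)
    _write_tsv(deg, out / "deg_table.tsv", "gene_id")
    _write_tsv(frac, out / "pairwise_deg_percent.tsv", "muscle")
    outputs.update({"deg_table": "deg_table.tsv",
                    "pairwise_deg_percent": "pairwise_deg_percent.tsv"})


def _stage_network(config, state, out, outputs):
    expr, meta = state["expr"], state["metadata"]
    assignment, cons, me = net.consensus_modules(expr, meta, config.network)
    summary, _ = net.module_muscle_association(me, meta)
    conn = net.intramodular_connectivity(
        net.adjacency_signed_hybrid(
            net.bicor(expr.to_numpy(float).T), config.network.power),
        assignment)
    flags = net.flag_celltype_modules(assignment, state.get("markers", {}))
    state.update(modules=assignment, me=me, module_summary=summary)
    _write_tsv(assignment.to_frame(), out / "module_assignment.tsv", "gene_id")
    _write_tsv(me, out / "module_eigengenes.tsv", "sample")
    _write_tsv(summary, out / "module_muscle_association.tsv", "module")
    _write_tsv(conn, out / "intramodular_connectivity.tsv", "gene_id")
    flags.rename("celltype_driven").to_frame().to_csv(
        out / "module_celltype_flags.tsv", sep="\t", index_label="module")
    outputs.update({
        "module_assignment": "module_assignment.tsv",
        "module_eigengenes": "module_eigengenes.tsv",
        "module_muscle_association": "module_muscle_association.tsv",
        "intramodular_connectivity": "intramodular_connectivity.tsv",
        "module_celltype_flags": "module_celltype_flags.tsv",
    })


def _stage_histology(config, state, out, outputs):
    h = config.histology
    seed = stage_seed(config.seed, "histology")
    fibers, _ = syn.simulate_myofiber_objects(
        h.n_samples, h.fibers_per_sample, noise_sd=h.noise_sd,
        contamination_rate=h.contamination_rate, seed=seed)
    params = hist.FiberTypingParams()
    retained, ledger = hist.filter_myofibers(fibers, params)
    sections = hist.select_section(retained, params)
    included = sections.index[sections["included"]]
    pool = retained[retained["sample_id"].isin(included)]
    typing = hist.fiber_type_clustering(pool, params)

    vessels, vtruth = syn.simulate_vessel_objects(
        h.vessel_sections, h.vessel_objects_per_section, h.tissue_area_um2,
        h.capillary_fraction, seed=seed + 1)
    cap = hist.capillary_metrics(vessels, h.tissue_area_um2)

    foci, ftruth = syn.simulate_foci_objects(
        h.foci_fibers, h.foci_per_fiber_mean, h.foci_false_positive_rate,
        seed=seed + 2, n_samples=4)
    foc = hist.foci_metrics(foci, ftruth["fibers_per_sample"])

    state.update(fiber_typing=typing, capillary=cap, foci=foc)
    _write_tsv(typing.proportions, out / "fiber_type_proportions.tsv", "sample")
    _write_tsv(cap, out / "capillary_metrics.tsv", "sample")
    _write_tsv(foc, out / "foci_metrics.tsv", "sample")
    outputs.update({"fiber_type_proportions": "fiber_type_proportions.tsv",
                    "capillary_metrics": "capillary_metrics.tsv",
                    "foci_metrics": "foci_metrics.tsv"})


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "celltype": _stage_celltype,
    "diffexpr": _stage_diffexpr,
    "network": _stage_network,
    "histology": _stage_histology,
}


def report(manifest: dict, outdir: str | Path | None = None) -> list[str]:
    """Render summary figures (heatmaps and boxplots) from a run manifest.

    Reads only the TSVs named in the manifest and writes PNG figures next
    to them; returns the figure paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not manifest or not manifest.get("outputs"):
        raise ValueError("empty manifest")
    base = Path(outdir) if outdir is not None else \
        Path(manifest["config"]["outdir"])
    figures = []

    def heatmap(name, df, title):
        fig, ax = plt.subplots(figsize=(1 + 0.5 * df.shape[1],
                                        1 + 0.5 * df.shape[0]))
        im = ax.imshow(df.to_numpy(float), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(df.shape[1]), df.columns, rotation=90)
        ax.set_yticks(range(df.shape[0]), df.index)
        ax.set_title(title)
        fig.colorbar(im)
        path = base / f"fig_{name}.png"
        fig.savefig(path, bbox_inches="tight", dpi=100)
        plt.close(fig)
        figures.append(str(path))

    outs = manifest["outputs"]
    if "celltype_muscle_means" in outs:
        df = pd.read_csv(base / outs["celltype_muscle_means"]["path"],
                         sep="\t", index_col=0)
        heatmap("celltype_means", df, "Mean cell-type eigen-scores per muscle")
    if "pairwise_deg_percent" in outs:
        df = pd.read_csv(base / outs["pairwise_deg_percent"]["path"],
                         sep="\t", index_col=0)
        heatmap("pairwise_deg", df, "% DEGs per muscle pair")
    if "fiber_type_proportions" in outs:
        df = pd.read_csv(base / outs["fiber_type_proportions"]["path"],
                         sep="\t", index_col=0)
        fig, ax = plt.subplots()
        df.plot.box(ax=ax)
        ax.set_ylabel("proportion of fibers")
        path = base / "fig_fiber_type_proportions.png"
        fig.savefig(path, bbox_inches="tight", dpi=100)
        plt.close(fig)
        figures.append(str(path))
    if "capillary_metrics" in outs:
        df = pd.read_csv(base / outs["capillary_metrics"]["path"],
                         sep="\t", index_col=0)
        fig, ax = plt.subplots()
        ax.boxplot(df["capillary_density"].dropna())
        ax.set_ylabel("capillaries per um^2")
        path = base / "fig_capillary_density.png"
        fig.savefig(path, bbox_inches="tight", dpi=100)
        plt.close(fig)
        figures.append(str(path))
    if not figures:
        raise ValueError("manifest lists no reportable outputs")
    return figures
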
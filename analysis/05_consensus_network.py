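"""Consensus co-expression network across individuals.

Builds per-individual biweight-midcorrelation networks (signed hybrid,
power 8), calibrates the per-individual TOMs at the 0.95 quantile, takes
the elementwise 40th-percentile consensus, cuts modules (min size 20,
deep split 0), merges similar eigengenes at 0.2, and then: scores module
concordance with the pathway knowledge (enrichment factor), tests
module-muscle association, flags modules driven by cell-type composition
(>= 5 markers of one cell type), computes intramodular hub genes, and
selects top modules by the DE F-value rule (Q3 > 5.5).
"""

import argparse
from pathlib import Path

import pandas as pd

from myoatlas import io as mio
from myoatlas import network as net


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", type=Path, default=Path("scratch/analysis"))
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    expr = mio.read_counts(args.scratch / "log_cpm.tsv")
    meta = mio.read_metadata(args.scratch / "metadata_qc.tsv")
    pathways = mio.read_gmt(args.scratch / "pathways.gmt")
    markers = mio.read_gmt(args.scratch / "markers.gmt")

    params = net.NetworkParams()  # power 8, min size 20, deepSplit 0, merge 0.2
    assignment, cons, me = net.consensus_modules(expr, meta, params)
    assignment.to_frame().to_csv(args.scratch / "module_assignment.tsv",
                                 sep="\t", index_label="gene_id")

    ef = net.enrichment_factor(assignment, pathways, params)
    assoc, _ = net.module_muscle_association(me, meta)
    flags = net.flag_celltype_modules(assignment, markers)

    adj = net.adjacency_signed_hybrid(
        net.bicor(expr.to_numpy(float).T), params.power)
    conn = net.intramodular_connectivity(adj, assignment)
    hubs = conn[conn["hub"]].sort_values("kWithin", ascending=False)

    deg_path = args.scratch / "deg_table.tsv"
    selected = []
    if deg_path.exists():
        deg = pd.read_csv(deg_path, sep="\t", index_col=0)
        f_by_module = {m: deg["F"].reindex(
            assignment.index[assignment == m]).dropna().to_numpy()
            for m in me.columns}
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = net.select_top_modules(f_by_module)

    summary = pd.DataFrame({
        "size": assignment.value_counts().reindex(me.columns),
        "muscle_related": assoc["muscle_related"].reindex(me.columns),
        "q": assoc["q"].reindex(me.columns),
        "celltype_driven": flags.reindex(me.columns),
        "top_by_de_f": [m in selected for m in me.columns],
        "hub_gene": [hubs[hubs["module"] == m].index[0]
                     if (hubs["module"] == m).any() else "" for m in me.columns],
    })
    summary.to_csv(args.results / "05_module_summary.tsv", sep="\t",
                   index_label="module")

    n_unassigned = int((assignment == "unassigned").sum())
    print(f"{len(me.columns)} modules "
          f"({n_unassigned} genes unassigned); enrichment factor vs pathway "
          f"knowledge: {ef.ef if not ef.infinite else 'inf'} "
          f"(n1={ef.n1}, n2={ef.n2}, n3={ef.n3}, n4={ef.n4})")
    print(f"muscle-related modules: "
          f"{int(summary['muscle_related'].sum())}/{len(summary)}; "
          f"cell-type driven: {int(summary['celltype_driven'].sum())}; "
          f"top by DE F-rule: {int(summary['top_by_de_f'].sum())}")
    print(summary.to_string())


if __name__ == "__main__":
    main()
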
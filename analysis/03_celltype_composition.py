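"""Cell-type composition across muscles from marker-gene eigenvectors.

Summarises each cell-type marker set by its first principal component,
tests muscle differences per cell type with the atlas mixed model
(BH-FDR across cell types), and clusters the muscles on their mean
scores — the analysis that groups the muscles into hamstrings (G1),
quadriceps (G2) and the lower leg (G3).
"""

import argparse
from pathlib import Path

from scipy.cluster import hierarchy

from myoatlas import celltype as ct
from myoatlas import io as mio


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", type=Path, default=Path("scratch/analysis"))
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    expr = mio.read_counts(args.scratch / "log_cpm.tsv")
    meta = mio.read_metadata(args.scratch / "metadata_qc.tsv")
    markers = mio.read_gmt(args.scratch / "markers.gmt")

    eigen = ct.celltype_eigenvectors(expr, markers)
    summary, results = ct.celltype_association(eigen, meta)
    summary.to_csv(args.results / "03_celltype_association.tsv", sep="\t")
    eigen.scores.to_csv(args.scratch / "celltype_eigenvectors.tsv", sep="\t",
                        index_label="sample")

    Z, means = ct.cluster_muscles(eigen, meta)
    means.round(4).to_csv(args.results / "03_muscle_mean_scores.tsv",
                          sep="\t", index_label="muscle")
    k3 = hierarchy.fcluster(Z, 3, criterion="maxclust")

    print("muscle-association of cell-type scores (q = BH-FDR):")
    print(summary[["F", "q", "significant"]].round(4).to_string())
    print("\nmuscle clusters at k=3:")
    for grp in sorted(set(k3)):
        print(f"  cluster {grp}: "
              + ", ".join(m for m, g in zip(means.index, k3) if g == grp))
    top = summary["F"].idxmax()
    contrasts = results[top].contrasts
    sig = contrasts[contrasts["p_adj"] < 0.05]
    print(f"\nmost muscle-dependent cell type: {top}; "
          f"{len(sig)}/{len(contrasts)} pairwise contrasts significant")


if __name__ == "__main__":
    main()
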
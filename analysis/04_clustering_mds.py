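"""Non-parametric structure: dissimilarity, redundancy, Ward tree, MDS, k-means.

Computes the allele-sharing dissimilarity matrix from the filtered panel,
scans it for redundant / near-duplicate accessions (the planted duplicate
pairs should surface here), builds the Ward dendrogram (Newick), embeds the
panel with classical MDS on LD-pruned markers, and runs k-means + BIC on the
top-10 principal coordinates.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from radpop.distance_clustering import (
    classical_mds,
    dissimilarity,
    kmeans_bic,
    redundancy_scan,
    tree_to_newick,
    ward_tree,
)
from radpop.genotype_io import read_vcf
from radpop.ld_analysis import ld_prune

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = read_vcf(ROOT / "panel_filtered.vcf")
    dm = dissimilarity(gm)
    dm.to_frame().to_csv(ROOT / "dissimilarity.tsv", sep="\t")

    scan = redundancy_scan(dm, threshold=0.005)
    scan.to_csv(ROOT / "redundancy.tsv", sep="\t", index=False)
    print(f"near-duplicate pairs (d < 0.005): {len(scan)}")
    if len(scan):
        print(scan.head().to_string(index=False))

    Z = ward_tree(dm)
    (ROOT / "ward_dendrogram.nwk").write_text(tree_to_newick(Z, dm.labels))

    pruned = ld_prune(gm)
    print(f"LD pruning for ordination: {gm.n_loci} -> {pruned.n_loci} markers")
    dm_p = dissimilarity(pruned)
    coords, eigval = classical_mds(dm_p, dims=10)
    pd.DataFrame(
        coords, index=dm_p.labels,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    ).to_csv(ROOT / "mds_coords.tsv", sep="\t")
    var_frac = eigval[:2].sum() / eigval[eigval > 0].sum()
    print(f"first two principal coordinates explain {100 * var_frac:.1f}% "
          "of the positive-eigenvalue variance")

    sols, best = kmeans_bic(coords, range(1, 16), restarts=20, seed=7)
    pd.DataFrame(
        {"k": [s.k for s in sols], "wss": [s.objective for s in sols],
         "bic": [s.bic for s in sols]}
    ).to_csv(ROOT / "kmeans_bic.tsv", sep="\t", index=False)
    print(f"k-means + BIC on top-10 coordinates: best k = {best.k}")


if __name__ == "__main__":
    main()
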
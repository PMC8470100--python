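#!/usr/bin/env python
"""Between-breed structure: pairwise F_ST, IBS distances, NJ tree, PCA.

Reads the QC'd genotype matrix from step 02 and writes the pairwise
Weir-Cockerham F_ST matrix, the individual IBS distance matrix, a
neighbour-joining tree in Newick format (on breed-mean distances for
readability) and PCA scores with explained variance.
"""

import argparse
from pathlib import Path

from rohpop.io import read_genotype_tsv
from rohpop.pipeline import FLOAT_FMT
from rohpop.structure import (fst_matrix, ibs_distance, nj_tree, pca_scores,
                              population_mean_distance)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    out = Path(args.outdir)

    panel = read_genotype_tsv(out / "genotypes.tsv", out / "markers.tsv")

    fst = fst_matrix(panel)
    fst.to_csv(out / "fst_matrix.tsv", sep="\t", float_format=FLOAT_FMT)
    print("pairwise F_ST (Weir-Cockerham):")
    print(fst.round(3).to_string())

    dist = ibs_distance(panel)
    dist.to_csv(out / "ibs_distance.tsv", sep="\t", float_format=FLOAT_FMT)
    breed_dist = population_mean_distance(dist, panel.populations)
    tree = nj_tree(breed_dist)
    (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
    print(f"\nbreed NJ tree: {tree.to_newick()}")

    pca = pca_scores(panel, n_components=5)
    scores = pca.scores.copy()
    scores.insert(0, "population",
                  [panel.populations[s] for s in scores.index])
    scores.rename_axis("sample").reset_index().to_csv(
        out / "pca_scores.tsv", sep="\t", index=False,
        float_format=FLOAT_FMT)
    pv = pca.percent_variance
    print(f"\nPCA: PC1 {pv[0]:.1f}%, PC2 {pv[1]:.1f}% of variance "
          f"({len(pv)} components written)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
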
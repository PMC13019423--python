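#!/usr/bin/env python
"""Unsupervised structure of the preprocessed spectra.

PCA with biplot-style ranking of the wavenumbers driving PC1-PC2,
leave-one-out nearest-centroid discrimination in the PC1-PC2 plane, and
a Ward dendrogram cut at k=3 scored against the isolation methods.
"""

import argparse
from pathlib import Path

import pandas as pd

from evspec.qc import choose_n_components, fit_pca
from evspec.spectra_io import read_spectra
from evspec.unsupervised import (
    biplot_summary,
    cut_tree,
    hca,
    pairwise_score_discrimination,
    tree_to_newick,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    pre = read_spectra(args.outdir / "spectra_preprocessed.csv")
    A = max(choose_n_components(pre.intensities, 0.90, 10), 2)
    model = fit_pca(pre.intensities, A)
    evr = model.explained_variance_ratio
    print(f"PCA: {A} components hold {evr.sum():.0%} of variance "
          f"(PC1 {evr[0]:.0%}, PC2 {evr[1]:.0%})")

    bip = biplot_summary(model, (0, 1), pre.labels, pre.axis.values)
    pd.DataFrame(bip.top_bands, columns=["wavenumber", "loading_magnitude"]).to_csv(
        args.outdir / "top_bands.csv", index=False
    )
    top5 = ", ".join(f"{w:.0f}" for w, _ in bip.top_bands[:5])
    print(f"strongest PC1-PC2 contributions at {top5} cm-1")

    disc = pairwise_score_discrimination(model, pre.labels, (0, 1))
    print(f"PC1-PC2 LOO nearest-centroid discrimination: {disc:.1%}")

    tree = hca(pre.intensities)
    (args.outdir / "dendrogram.nwk").write_text(
        tree_to_newick(tree, pre.sample_ids), encoding="utf-8"
    )
    cut = cut_tree(tree, 3, pre.labels)
    pd.DataFrame(
        {"sample_id": pre.sample_ids, "cluster": cut.assignments, "group": pre.labels}
    ).to_csv(args.outdir / "cluster_assignments.csv", index=False)
    majorities = {int(k): str(v) for k, v in cut.majority_labels.items()}
    print(f"Ward cut at k=3: majorities {majorities}, purity {cut.purity:.1%}")
    print(f"wrote top_bands.csv, dendrogram.nwk, cluster_assignments.csv "
          f"under {args.outdir}/")


if __name__ == "__main__":
    main()
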
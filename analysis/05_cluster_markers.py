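#!/usr/bin/env python
"""Clustering of 1-day-old neurons and late-marker analyses.

Clusters the panel's N1d cells (vst variable genes, 15 PCA dimensions,
Jaccard-SNN graph, Leiden resolution 1), tabulates birthdate composition
per cluster, builds the early-variable-gene set from the E12/E13 rankings,
and computes late-marker-positive fractions per birthdate against
thresholds anchored in the most late-born clusters.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from isochron import scqc
from isochron.hetero import select_variable_genes
from isochron.progclust import (
    cluster_markers,
    cluster_neurons,
    composition,
    early_variable_gene_set,
    late_marker_thresholds,
    marker_positive_fraction,
    normalized_group_profile,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 7


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    adata = scqc.read_counts(ROOT / "scratch" / "data" / "counts")
    adata = scqc.rpm_log2(scqc.filter_genes(adata, 100, 2))
    n1d = adata[adata.obs["stage"] == "N1d"].copy()

    # ~14% of the panel's genes as variable genes, proportional to the
    # conventional 2000-of-~15k recipe on genome-wide matrices
    assign = cluster_neurons(n1d, n_var_genes=100, dims=15, resolution=1.0, seed=SEED)
    print(f"N1d clustering: K={assign.k} clusters over {n1d.n_obs} cells "
          f"(modularity {assign.modularity:.1f})")
    pd.DataFrame({"cell_id": n1d.obs_names, "cluster": assign.labels}).to_csv(
        RESULTS / "n1d_clusters.csv", index=False
    )

    comp = composition(assign.labels, n1d.obs["birthdate"].to_numpy())
    comp["fractions"].round(3).to_csv(RESULTS / "n1d_composition.csv")
    print("birthdate composition per cluster:")
    print(comp["fractions"].round(2).to_string())
    fr = comp["fractions"]
    early_frac = fr[["E12", "E13"]].sum(axis=1)
    for c in fr.index[early_frac > 0.5]:
        bal = fr.loc[c, "E12"] / (fr.loc[c, "E12"] + fr.loc[c, "E13"])
        print(f"  early cluster {c}: E12 share among early-born = {bal:.2f}")

    markers = cluster_markers(n1d, assign.labels, n_top=10)
    markers.to_csv(RESULTS / "n1d_markers.csv", index=False, float_format="%.4g")

    # early-variable-gene set from per-birthdate N1d rankings
    def _ranking(bd):
        sub = n1d[n1d.obs["birthdate"] == bd]
        return select_variable_genes(np.asarray(sub.X), np.asarray(sub.var_names), 50)

    genes, overlap = early_variable_gene_set(_ranking("E12"), _ranking("E13"), top_k=50)
    print(f"early variable gene set: {len(genes)} genes "
          f"(top-50 + top-50, overlap {overlap})")
    pd.DataFrame({"gene": genes}).to_csv(RESULTS / "early_variable_genes.csv", index=False)

    profile = normalized_group_profile(n1d, genes, n1d.obs["birthdate"].to_numpy())
    profile.round(3).to_csv(RESULTS / "early_gene_profile.csv")

    # late reference clusters: those with the largest E14+E15 fraction
    late_frac = comp["fractions"].reindex(columns=["E14", "E15"]).fillna(0).sum(axis=1)
    late_clusters = late_frac.sort_values(ascending=False).index[:2].tolist()
    print(f"late reference clusters (highest E14+E15 fraction): {late_clusters}")

    # marker analogues: top differential genes of the late clusters
    late_markers = (
        markers[markers["cluster"].isin(late_clusters)]
        .sort_values("log2fc", ascending=False)["gene"].head(4).tolist()
    )
    thr, missing = late_marker_thresholds(n1d, assign.labels, late_clusters, late_markers)
    rows = []
    for bd in ("E12", "E13", "E14", "E15"):
        mask = (n1d.obs["birthdate"] == bd).to_numpy()
        out = marker_positive_fraction(n1d, thr, mask).assign(birthdate=bd)
        rows.append(out)
    fr = pd.concat(rows, ignore_index=True)
    fr.to_csv(RESULTS / "late_marker_fractions.csv", index=False, float_format="%.4g")
    wide = fr.pivot(index="marker", columns="birthdate", values="fraction")
    print("late-marker-positive fraction among expressing cells:")
    print(wide.round(2).to_string())


if __name__ == "__main__":
    main()
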
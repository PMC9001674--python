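"""Clustering of newborn neurons and downstream marker analyses.

Community detection follows the conventional single-cell recipe: top
variable genes by the vst ranking, PCA on scaled log2(RPM+1) values, a
k-nearest-neighbour graph with Jaccard-weighted shared-nearest-neighbour
edges, and modularity (Leiden) communities at the stated resolution.
Downstream operations quantify birthdate composition per cluster, build the
early-variable-gene set from two per-birthdate rankings, profile group
expression on a 0-1 scale per gene, and compute late-marker-positive cell
fractions above thresholds anchored in designated late-born reference
clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .hetero import select_variable_genes
from .scqc import _dense, rpm_log2

__all__ = [
    "ClusterAssignment",
    "cluster_neurons",
    "composition",
    "cluster_markers",
    "early_variable_gene_set",
    "normalized_group_profile",
    "late_marker_thresholds",
    "marker_positive_fraction",
]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # 1..K per cell
    params: dict
    modularity: float

    @property
    def k(self) -> int:
        return int(len(np.unique(self.labels)))


def _snn_graph(emb: np.ndarray, k_neighbors: int, prune: float) -> igraph.Graph:
    """Jaccard-weighted shared-nearest-neighbour graph on an embedding."""
    n = emb.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(emb)
    _, idx = nn.kneighbors(emb)  # includes self
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sparse.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (A @ A.T).tocoo()  # shared-neighbour counts
    mask = inter.row < inter.col
    r, c, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jac = shared / (2 * k_neighbors - shared)
    keep = jac > prune
    g = igraph.Graph(
        n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())), directed=False
    )
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_neurons(
    adata: ad.AnnData,
    n_var_genes: int = 2000,
    dims: int = 15,
    resolution: float = 1.0,
    k_neighbors: int = 20,
    prune: float = 1.0 / 15.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Graph-community clustering of cells.

    Top ``n_var_genes`` vst-variable genes (capped at the genes with
    nonzero variance), PCA to ``dims`` components on per-gene scaled
    log2(RPM+1), kNN/SNN graph, Leiden modularity communities at
    ``resolution``.  Deterministic given ``seed``.
    """
    if adata.n_obs < k_neighbors + 1:
        raise ValueError("fewer cells than k_neighbors + 1")
    if "log2" not in adata.layers:
        adata = rpm_log2(adata.copy())
    counts = _dense(adata.X)
    mu = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    n_usable = int(((mu > 0) & (var > 0)).sum())
    k = min(n_var_genes, n_usable)
    ranking = select_variable_genes(counts, np.asarray(adata.var_names, str), k)
    gidx = np.flatnonzero(ranking["highly_variable"].to_numpy())

    M = np.asarray(adata.layers["log2"])[:, gidx]
    sd = M.std(axis=0, ddof=1)
    M = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_comp = min(dims, M.shape[0] - 1, M.shape[1])
    emb = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(M)

    g = _snn_graph(emb, k_neighbors=k_neighbors, prune=prune)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership) + 1
    return ClusterAssignment(
        labels=labels,
        params={
            "n_var_genes": k, "dims": n_comp, "resolution": resolution,
            "k_neighbors": k_neighbors, "prune": prune, "seed": seed,
        },
        modularity=float(part.quality()),
    )


def composition(labels: np.ndarray, birthdates: np.ndarray) -> dict[str, pd.DataFrame]:
    """Birthdate counts and row-normalized fractions per cluster."""
    counts = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(birthdates, name="birthdate"))
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return {"counts": counts, "fractions": fractions}


def cluster_markers(
    adata: ad.AnnData,
    labels: np.ndarray,
    n_top: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest marker table per cluster.

    Genes are screened by a two-sided rank-sum (Mann-Whitney) test with
    Benjamini-Hochberg correction across genes, then ranked within each
    cluster by one-vs-rest log2 fold change of mean log2(RPM+1); the top
    ``n_top`` genes passing the screen are reported.  Size-1 clusters are
    skipped with a warning.
    """
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 clusters")
    if "log2" not in adata.layers:
        adata = rpm_log2(adata.copy())
    L = np.asarray(adata.layers["log2"])
    genes = np.asarray(adata.var_names, str)
    rows = []
    for c in np.unique(labels):
        in_c = labels == c
        if in_c.sum() < 2:
            warnings.warn(f"cluster {c}: size < 2, skipped")
            continue
        a, b = L[in_c], L[~in_c]
        lfc = a.mean(axis=0) - b.mean(axis=0)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", axis=0)
        p = np.asarray(res.pvalue, float)
        padj = multipletests(p, method="fdr_bh")[1]
        passing = np.flatnonzero(padj <= alpha)
        top = passing[np.argsort(-lfc[passing], kind="stable")][:n_top]
        for rank, j in enumerate(top, start=1):
            rows.append(
                {"cluster": int(c), "rank": rank, "gene": genes[j],
                 "log2fc": float(lfc[j]), "p": float(p[j]), "padj": float(padj[j])}
            )
    return pd.DataFrame(rows, columns=["cluster", "rank", "gene", "log2fc", "p", "padj"])


def early_variable_gene_set(
    rank_a: pd.DataFrame, rank_b: pd.DataFrame, top_k: int = 50
) -> tuple[list[str], int]:
    """Deduplicated union of the top-``top_k`` variable genes of two rankings.

    Genes appearing in both lists are kept once; returns the gene list and
    the overlap count, so the set size is always 2*top_k - overlap.
    """
    def _top(df: pd.DataFrame) -> list[str]:
        if (df["rank"] <= top_k).sum() < top_k:
            raise ValueError(f"ranking covers fewer than top_k={top_k} genes")
        return df.sort_values("rank")["gene_id"].head(top_k).tolist()

    a, b = _top(rank_a), _top(rank_b)
    overlap = len(set(a) & set(b))
    merged = a + [g for g in b if g not in set(a)]
    return merged, overlap


def normalized_group_profile(
    adata: ad.AnnData, gene_set: list[str], groups: np.ndarray
) -> pd.DataFrame:
    """Per-gene group means of log2 expression, min-max scaled to [0, 1].

    Rows are genes, columns groups; a gene constant across groups maps to an
    all-zero row (flagged in the ``constant`` column).
    """
    if "log2" not in adata.layers:
        adata = rpm_log2(adata.copy())
    L = np.asarray(adata.layers["log2"])
    groups = np.asarray(groups)
    glabels = np.unique(groups)
    jdx = [adata.var_names.get_loc(g) for g in gene_set]
    means = np.column_stack(
        [L[groups == g][:, jdx].mean(axis=0) for g in glabels]
    )  # genes x groups
    lo = means.min(axis=1, keepdims=True)
    span = means.max(axis=1, keepdims=True) - lo
    constant = span[:, 0] == 0
    norm = np.where(span > 0, (means - lo) / np.where(span > 0, span, 1.0), 0.0)
    out = pd.DataFrame(norm, index=gene_set, columns=list(glabels))
    out["constant"] = constant
    return out


def late_marker_thresholds(
    adata: ad.AnnData,
    labels: np.ndarray,
    late_clusters: list[int],
    markers: list[str],
) -> tuple[pd.Series, list[str]]:
    """Per-marker threshold = mean RPM over cells of the reference clusters.

    Returns (thresholds, missing_markers).
    """
    if not late_clusters:
        raise ValueError("late_clusters must be non-empty")
    if "rpm" not in adata.layers:
        adata = rpm_log2(adata.copy())
    in_late = np.isin(labels, late_clusters)
    if not in_late.any():
        raise ValueError("no cells in the designated late clusters")
    R = np.asarray(adata.layers["rpm"])
    present = [m for m in markers if m in adata.var_names]
    missing = [m for m in markers if m not in adata.var_names]
    thr = pd.Series(
        {m: float(R[in_late, adata.var_names.get_loc(m)].mean()) for m in present},
        name="threshold",
    )
    return thr, missing


def marker_positive_fraction(
    adata: ad.AnnData, thresholds: pd.Series, group_mask: np.ndarray
) -> pd.DataFrame:
    """Fraction of expressing group cells above each marker's threshold.

    Only cells with marker RPM > 0 enter the denominator (a dropout guard);
    the numerator counts those with RPM strictly above the threshold.  A
    zero denominator yields a NaN fraction.
    """
    if "rpm" not in adata.layers:
        adata = rpm_log2(adata.copy())
    R = np.asarray(adata.layers["rpm"])[np.asarray(group_mask, bool)]
    rows = []
    for m, thr in thresholds.items():
        v = R[:, adata.var_names.get_loc(m)]
        expressing = v > 0
        denom = int(expressing.sum())
        num = int((v[expressing] > thr).sum())
        rows.append(
            {"marker": m, "threshold": float(thr), "n_positive": num,
             "n_expressing": denom,
             "fraction": num / denom if denom else float("nan")}
        )
    return pd.DataFrame(rows)
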
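"""Permutation-based single-cell molecular heterogeneity statistic.

Within-condition heterogeneity is measured as the ratio between the
variance explained by the first principal component on the actual data and
the same quantity after each gene has been independently shuffled across
cells.  For each of ``n_reps`` cross-validations, ``n_cells`` cells (80 by
default) are subsampled without replacement, the ``k_genes`` most variable
genes (80) are selected on that subsample by a vst-style standardized
variance, PCA is run on scaled log2(RPM+1) values, and the actual PC1
variance fraction is divided by the fraction after gene-wise permutation.
A ratio near 1 means no covariance structure beyond chance; structured
populations (latent subtypes) push the ratio above 1.

Variable-gene ranking follows the vst recipe: a local quadratic regression
of log10(variance) on log10(mean) across genes yields an expected variance
per gene; per-cell values are standardized with the expected SD, clipped at
sqrt(n_cells), and the variance of the clipped values is the ranking
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .scqc import _dense, rpm_log2

__all__ = [
    "HeterogeneityRun",
    "select_variable_genes",
    "pc1_fraction",
    "permute_genes",
    "heterogeneity_ratio",
    "compare_heterogeneity",
    "loess_fit",
]


# ---------------------------------------------------------------------------
# vst-style variable gene ranking
# ---------------------------------------------------------------------------


def loess_fit(
    x: np.ndarray, y: np.ndarray, span: float = 0.3, degree: int = 2
) -> np.ndarray:
    """Local polynomial regression fitted value at each x.

    Tricube-weighted degree-``degree`` fits over the ``span`` fraction of
    nearest points (contiguous window in sorted x), vectorized over all
    evaluation points.  Returns fitted y in the input order.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    idx = np.arange(n)
    start = np.clip(idx - k // 2, 0, n - k)
    win = start[:, None] + np.arange(k)[None, :]  # (n, k)
    xw = xs[win] - xs[:, None]
    yw = ys[win]
    d = np.abs(xw)
    dmax = d.max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    w = (1.0 - (d / (dmax * 1.0001)) ** 3) ** 3

    # weighted polynomial fit centered at each xs[i]; fitted value = beta0
    P = np.stack([xw**p for p in range(degree + 1)], axis=-1)  # (n, k, d+1)
    A = np.einsum("nkp,nk,nkq->npq", P, w, P)
    b = np.einsum("nkp,nk,nk->np", P, w, yw)
    # ridge jitter guards rank-deficient windows (many tied x)
    A += 1e-12 * np.eye(degree + 1)[None]
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    fitted_sorted = beta[:, 0]

    out = np.empty(n)
    out[order] = fitted_sorted
    return out


def select_variable_genes(
    counts: np.ndarray,
    gene_ids: np.ndarray,
    k: int,
    span: float = 0.3,
) -> pd.DataFrame:
    """Rank genes by vst-style standardized variance of raw counts.

    Returns a DataFrame indexed like ``gene_ids`` with columns mean,
    variance, expected_variance, standardized_variance, rank (1 = most
    variable) and highly_variable (top-``k`` flag).  Ties break by gene id.
    """
    counts = _dense(counts).astype(float)
    n, G = counts.shape
    if n < 2:
        raise ValueError("need >= 2 cells")
    mu = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    fit_mask = (mu > 0) & (var > 0)
    if int(fit_mask.sum()) < k:
        raise ValueError(
            f"k={k} exceeds the {int(fit_mask.sum())} genes with nonzero mean and variance"
        )

    expected = np.zeros(G)
    fitted = loess_fit(np.log10(mu[fit_mask]), np.log10(var[fit_mask]), span=span)
    expected[fit_mask] = 10.0**fitted

    std_var = np.zeros(G)
    sd_exp = np.sqrt(expected[fit_mask])
    z = (counts[:, fit_mask] - mu[fit_mask]) / sd_exp
    z = np.minimum(z, np.sqrt(n))
    # variance of clipped standardized values about the clipped mean
    std_var[fit_mask] = z.var(axis=0, ddof=1)

    df = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids, str),
            "mean": mu,
            "variance": var,
            "expected_variance": expected,
            "standardized_variance": std_var,
        }
    )
    order = np.lexsort((df["gene_id"].to_numpy(), -df["standardized_variance"].to_numpy()))
    rank = np.empty(G, int)
    rank[order] = np.arange(1, G + 1)
    df["rank"] = rank
    df["highly_variable"] = df["rank"] <= k
    return df


# ---------------------------------------------------------------------------
# PC1 fraction and permutation
# ---------------------------------------------------------------------------


def pc1_fraction(X: np.ndarray, scale: bool = True) -> float:
    """Fraction of variance carried by PC1 of a cells x genes submatrix.

    Columns are centered (and unit-scaled when ``scale``); the fraction is
    the leading eigenvalue share of the gene-gene covariance spectrum.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 cells and >= 2 genes")
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("constant submatrix")
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=min(Xc.shape) - 0, svd_solver="full")
    pca.fit(Xc)
    return float(pca.explained_variance_ratio_[0])


def permute_genes(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each gene (column) across cells."""
    X = np.asarray(X)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        out[:, j] = X[rng.permutation(n), j]
    return out


# ---------------------------------------------------------------------------
# the heterogeneity procedure
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneityRun:
    """Per-condition cross-validated actual/permuted PC1 ratios."""

    condition: str
    n_cells_subsample: int
    n_top_genes: int
    n_reps: int
    seed: int
    table: pd.DataFrame  # columns: rep, actual_pc1, permuted_pc1, ratio

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio"].to_numpy()


def _rep_rng(master_seed: int, rep: int) -> np.random.Generator:
    # counter-based fan-out: rep i is reproducible in isolation
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(rep,)))


def heterogeneity_ratio(
    adata: ad.AnnData,
    condition: str,
    condition_col: str = "condition",
    n_cells: int = 80,
    k_genes: int = 80,
    n_reps: int = 100,
    seed: int = 0,
    scale: bool = True,
    genes_per_rep: bool = True,
) -> HeterogeneityRun:
    """Cross-validated actual-vs-permuted PC1 variance ratio for one condition.

    Each rep subsamples ``n_cells`` cells without replacement, selects the
    top ``k_genes`` variable genes (on the subsample when ``genes_per_rep``,
    the default; on the whole condition otherwise), computes the PC1
    variance fraction of the scaled log2(RPM+1) submatrix, permutes each
    gene once across the subsampled cells, recomputes, and records the
    ratio.  Per-rep seeds are fanned out from ``seed`` so rep *i* is
    reproducible in isolation.
    """
    mask = np.asarray(adata.obs[condition_col] == condition)
    sub = adata[mask]
    n_avail = sub.n_obs
    if n_avail < n_cells:
        raise ValueError(
            f"condition {condition!r} has {n_avail} cells; {n_cells} required "
            f"(deficit {n_cells - n_avail})"
        )
    if "log2" not in sub.layers:
        sub = rpm_log2(sub.copy())
    counts = _dense(sub.X)
    log2 = np.asarray(sub.layers["log2"])
    gene_ids = np.asarray(sub.var_names, str)

    global_rank = None
    if not genes_per_rep:
        global_rank = select_variable_genes(counts, gene_ids, k_genes)
        global_idx = np.flatnonzero(global_rank["highly_variable"].to_numpy())

    rows = []
    for rep in range(n_reps):
        rng = _rep_rng(seed, rep)
        cells = rng.choice(n_avail, size=n_cells, replace=False)
        if genes_per_rep:
            ranking = select_variable_genes(counts[cells], gene_ids, k_genes)
            gidx = np.flatnonzero(ranking["highly_variable"].to_numpy())
        else:
            gidx = global_idx
        M = log2[np.ix_(cells, gidx)]
        actual = pc1_fraction(M, scale=scale)
        permuted = pc1_fraction(permute_genes(M, rng), scale=scale)
        rows.append(
            {"rep": rep, "actual_pc1": actual, "permuted_pc1": permuted,
             "ratio": actual / permuted}
        )
    return HeterogeneityRun(
        condition=condition, n_cells_subsample=n_cells, n_top_genes=k_genes,
        n_reps=n_reps, seed=seed, table=pd.DataFrame(rows),
    )


def compare_heterogeneity(
    runs: list[HeterogeneityRun],
    early: tuple[str, ...] = ("E12", "E13"),
    late: tuple[str, ...] = ("E14", "E15"),
) -> dict:
    """Summaries and group contrasts over heterogeneity runs.

    Returns a dict with a per-run ``summary`` table (mean/median/IQR of the
    ratios), an ``epoch`` table contrasting early vs late birthdates within
    each stage (repeated-measures contrast: paired t on per-rep epoch means,
    reported as F(1, n-1) = t^2; Welch fallback when rep counts are
    unbalanced), and a ``dl_sl`` two-sided Mann-Whitney comparison of the
    adult deep-layer vs superficial-layer runs when both are present.

    Run conditions are expected as "<birthdate>_<stage>" labels (adult runs
    as "adult_DL"/"adult_SL").
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 runs")
    summary = pd.DataFrame(
        {
            "condition": [r.condition for r in runs],
            "n_reps": [r.n_reps for r in runs],
            "mean_ratio": [float(r.ratios.mean()) for r in runs],
            "median_ratio": [float(np.median(r.ratios)) for r in runs],
            "iqr_ratio": [
                float(np.subtract(*np.percentile(r.ratios, [75, 25]))) for r in runs
            ],
        }
    )

    by_cond = {r.condition: r for r in runs}

    def _split(label: str) -> tuple[str, str]:
        bd, _, stage = label.partition("_")
        return bd, stage

    stages = sorted({_split(r.condition)[1] for r in runs if _split(r.condition)[0] != "adult"})
    epoch_rows = []
    for stage in stages:
        e_runs = [by_cond[f"{bd}_{stage}"] for bd in early if f"{bd}_{stage}" in by_cond]
        l_runs = [by_cond[f"{bd}_{stage}"] for bd in late if f"{bd}_{stage}" in by_cond]
        if not e_runs or not l_runs:
            continue
        reps = {r.n_reps for r in e_runs + l_runs}
        if len(reps) == 1:
            e_mat = np.mean([r.ratios for r in e_runs], axis=0)
            l_mat = np.mean([r.ratios for r in l_runs], axis=0)
            t = stats.ttest_rel(e_mat, l_mat)
            epoch_rows.append(
                {"stage": stage, "test": "rm_paired", "F": float(t.statistic**2),
                 "df1": 1, "df2": len(e_mat) - 1, "p": float(t.pvalue)}
            )
        else:
            warnings.warn(f"stage {stage}: unbalanced rep counts; Welch fallback")
            e_all = np.concatenate([r.ratios for r in e_runs])
            l_all = np.concatenate([r.ratios for r in l_runs])
            w = stats.ttest_ind(e_all, l_all, equal_var=False)
            epoch_rows.append(
                {"stage": stage, "test": "welch", "F": float(w.statistic**2),
                 "df1": 1, "df2": float(w.df), "p": float(w.pvalue)}
            )

    dl_sl = None
    if "adult_DL" in by_cond and "adult_SL" in by_cond:
        u = stats.mannwhitneyu(
            by_cond["adult_DL"].ratios, by_cond["adult_SL"].ratios,
            alternative="two-sided",
        )
        dl_sl = {"U": float(u.statistic), "p": float(u.pvalue)}

    return {"summary": summary, "epoch": pd.DataFrame(epoch_rows), "dl_sl": dl_sl}
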
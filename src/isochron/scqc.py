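"""Single-cell count-matrix QC, normalization and radial expression tables.

The in-memory container is :class:`anndata.AnnData` (cells x genes, raw
integer counts in ``X``); on disk the matrix travels as Matrix Market
(genes x cells) plus ``genes.tsv`` / ``cells.tsv``, with a dense-CSV
fallback.  QC follows the Patch-seq convention: cells are dropped when
they detect fewer than ``min_genes`` genes or exceed ``max_mito``
mitochondrial read fraction (both comparisons strict, so a cell at exactly
2000 genes and exactly 12% mitochondrial reads is kept).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_counts",
    "write_counts",
    "qc_filter",
    "filter_genes",
    "rpm_log2",
    "radial_expression_table",
]

_META_COLS = ["cell_id", "condition", "birthdate", "stage", "subtype_truth", "radial_position"]


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def write_counts(adata: ad.AnnData, out_dir: str | Path) -> None:
    """Write counts as Matrix Market (genes x cells) + genes.tsv + cells.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(_dense(adata.X).T)  # genes x cells on disk
    spio.mmwrite(str(out / "counts.mtx"), mat, field="integer")
    adata.var.to_csv(out / "genes.tsv", sep="\t", index=False)
    cols = [c for c in _META_COLS if c in adata.obs.columns]
    adata.obs[cols].to_csv(out / "cells.tsv", sep="\t", index=False)


def read_counts(in_dir: str | Path) -> ad.AnnData:
    """Read a Matrix Market + TSV directory written by :func:`write_counts`.

    Mitochondrial genes are taken from an explicit ``mito`` column when
    present, otherwise flagged by the conventional ``mt-`` name prefix.
    """
    p = Path(in_dir)
    mat = spio.mmread(str(p / "counts.mtx"))
    X = np.asarray(sparse.csr_matrix(mat).T.todense())
    var = pd.read_csv(p / "genes.tsv", sep="\t")
    obs = pd.read_csv(p / "cells.tsv", sep="\t")
    if "mito" not in var.columns:
        var["mito"] = var["gene_id"].str.lower().str.startswith("mt-")
    var.index = var["gene_id"].astype(str)
    obs.index = obs["cell_id"].astype(str)
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)


def qc_filter(
    adata: ad.AnnData, min_genes: int = 2000, max_mito: float = 0.12
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Drop low-quality cells; return the kept matrix and a per-cell report.

    A cell is dropped when genes_detected < ``min_genes`` OR mito_fraction >
    ``max_mito``; cells with zero total counts are dropped and flagged
    separately (their mito fraction is undefined).
    """
    if "mito" not in adata.var.columns:
        raise ValueError("qc_filter requires a 'mito' flag column in var")
    X = _dense(adata.X)
    total = X.sum(axis=1)
    genes_detected = (X > 0).sum(axis=1)
    mito = np.asarray(adata.var["mito"], bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, mito].sum(axis=1) / np.where(total > 0, total, 1), np.nan)
    zero_total = total == 0
    kept = (~zero_total) & (genes_detected >= min_genes) & (mito_frac <= max_mito)
    report = pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "genes_detected": genes_detected,
            "mito_fraction": mito_frac,
            "zero_total": zero_total,
            "kept": kept,
            "min_genes": min_genes,
            "max_mito": max_mito,
        }
    )
    return adata[kept].copy(), report


def filter_genes(
    adata: ad.AnnData, min_count: int = 100, min_cells: int = 2
) -> ad.AnnData:
    """Keep genes with >= ``min_count`` counts in >= ``min_cells`` cells."""
    X = _dense(adata.X)
    keep = (X >= min_count).sum(axis=0) >= min_cells
    return adata[:, keep].copy()


def rpm_log2(adata: ad.AnnData, pseudocount: float = 1.0) -> ad.AnnData:
    """Add reads-per-million and log2(RPM + pseudocount) layers in place."""
    X = _dense(adata.X).astype(float)
    total = X.sum(axis=1)
    if np.any(total == 0):
        raise ValueError("cells with zero total counts present; run qc_filter first")
    rpm = X / total[:, None] * 1e6
    adata.layers["rpm"] = rpm
    adata.layers["log2"] = np.log2(rpm + pseudocount)
    return adata


def radial_expression_table(adata: ad.AnnData, genes: list[str]) -> pd.DataFrame:
    """Long-format table of min-max-normalized log2 expression by depth.

    Per gene, log2(RPM+1) values are rescaled to [0, 1] across cells
    (a constant gene maps to all-zero and is flagged); rows are sorted by
    recorded radial position.  Columns: cell_id, radial_position, gene,
    normalized_value, constant.
    """
    if "log2" not in adata.layers:
        raise ValueError("run rpm_log2 first")
    if "radial_position" not in adata.obs.columns or adata.obs["radial_position"].isna().any():
        raise ValueError("all cells need a recorded radial_position")
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    rows = []
    log2 = np.asarray(adata.layers["log2"])
    for g in genes:
        j = adata.var_names.get_loc(g)
        v = log2[:, j]
        rng = v.max() - v.min()
        norm = (v - v.min()) / rng if rng > 0 else np.zeros_like(v)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": adata.obs_names,
                    "radial_position": np.asarray(adata.obs["radial_position"], float),
                    "gene": g,
                    "normalized_value": norm,
                    "constant": rng == 0,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["gene", "radial_position"], kind="stable").reset_index(drop=True)
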
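"""End-to-end orchestration: config validation, staged runs, manifest, report.

A run is fully described by (inputs, config, master seed).  ``run_pipeline``
executes the stages in dependency order on the synthetic fixtures —
simulate, laminar quantification, QC/normalization, heterogeneity,
clustering/markers — hashing every output file into a JSON manifest so
reruns can be compared by hash equality.  ``report`` consolidates a run
directory into tidy per-analysis tables plus a short text summary that
includes a null-calibration check on the homogeneous condition.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import ftquant, hetero, progclust, scqc, synthgen

__all__ = ["PipelineConfig", "run_pipeline", "report"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's stated values."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "ftquant", "qc", "hetero", "cluster")
    # gating
    brdu_percentile: float = 20.0
    top_ft_fraction: float = 0.10
    # QC / gene filter
    min_genes: int = 2000
    max_mito: float = 0.12
    gene_min_count: int = 100
    gene_min_cells: int = 2
    # heterogeneity
    het_n_cells: int = 80
    het_k_genes: int = 80
    het_n_reps: int = 100
    # clustering
    n_var_genes: int = 2000
    dims: int = 15
    resolution: float = 1.0
    k_neighbors: int = 20
    # fixture scale
    fixture_cells_per_condition: int = 120

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []

    def _save(df: pd.DataFrame, name: str) -> None:
        df = df.copy()
        df.insert(0, "schema_version", SCHEMA_VERSION)
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        produced.append(path)

    data_dir = out / "data"
    if "simulate" in config.stages:
        spec = synthgen.default_expression_spec(
            seed=config.seed, n_cells=config.fixture_cells_per_condition
        )
        paths = synthgen.make_fixtures(config.seed, data_dir)
        produced += [p for p in paths.values() if p.is_file()]
        produced += sorted(paths["counts_dir"].glob("*"))

    if "ftquant" in config.stages:
        cells = pd.read_csv(data_dir / "cells.csv")
        landmarks = pd.read_csv(data_dir / "landmarks.csv")
        cohort_map = pd.read_csv(data_dir / "cohorts.csv")
        kept, gate_report = ftquant.gate_direct_born(cells, config.brdu_percentile)
        _save(gate_report, "gating.csv")
        pos_parts, cohorts = [], []
        for _, row in cohort_map.iterrows():
            sid = row["section_id"]
            lm = landmarks[landmarks["section_id"] == sid]
            geom = ftquant.SectionGeometry(
                section_id=sid,
                pia=lm[lm["structure"] == "pia"][["x", "y"]].to_numpy(),
                subplate=lm[lm["structure"] == "subplate"][["x", "y"]].to_numpy(),
            )
            sec = ftquant.radial_positions(kept[kept["section_id"] == sid], geom)
            sec = sec[~sec["outside_band"]]
            pos_parts.append(sec.assign(pup_id=row["pup_id"], injection_age=row["injection_age"]))
            cohorts.append(
                ftquant.LaminarCohort(
                    row["injection_age"], row["collection_age"], row["pup_id"],
                    np.clip(sec["radial_position"].to_numpy(), 0, 1),
                )
            )
        _save(pd.concat(pos_parts, ignore_index=True), "positions.csv")
        disp_rows = [
            {"cohort": c.label, "injection_age": c.injection_age, "pup_id": c.pup_id,
             **asdict(ftquant.dispersion(c.positions))}
            for c in cohorts
        ]
        _save(pd.DataFrame(disp_rows), "dispersion.csv")
        clust = ftquant.cluster_cohorts(cohorts)
        (out / "clustering.json").write_text(
            json.dumps({"flat2": clust["flat2"], "dendrogram": clust["dendrogram"]}, indent=1)
        )
        produced.append(out / "clustering.json")

    adata = None
    if {"qc", "hetero", "cluster"} & set(config.stages):
        adata = scqc.read_counts(data_dir / "counts")

    if "qc" in config.stages:
        adata, qc_report = scqc.qc_filter(
            adata, min_genes=config.min_genes, max_mito=config.max_mito
        )
        if adata.n_obs == 0:
            raise RuntimeError(
                "stage qc: no cells pass QC; min_genes is likely out of scale "
                "for this matrix"
            )
        _save(qc_report, "qc.csv")
        adata = scqc.filter_genes(adata, config.gene_min_count, config.gene_min_cells)
        adata = scqc.rpm_log2(adata)

    if "hetero" in config.stages:
        runs = []
        for cond in adata.obs["condition"].unique():
            runs.append(
                hetero.heterogeneity_ratio(
                    adata, cond, n_cells=config.het_n_cells,
                    k_genes=config.het_k_genes, n_reps=config.het_n_reps,
                    seed=config.seed,
                )
            )
        long = pd.concat(
            [r.table.assign(condition=r.condition, seed=r.seed) for r in runs],
            ignore_index=True,
        )
        _save(long, "hetero_runs.csv")
        cmp = hetero.compare_heterogeneity(runs)
        _save(cmp["summary"], "hetero_summary.csv")
        _save(cmp["epoch"], "hetero_epoch_tests.csv")

    if "cluster" in config.stages:
        n1d = adata[adata.obs["stage"] == "N1d"].copy()
        assign = progclust.cluster_neurons(
            n1d, n_var_genes=min(config.n_var_genes, n1d.n_vars), dims=config.dims,
            resolution=config.resolution, k_neighbors=config.k_neighbors,
            seed=config.seed,
        )
        _save(
            pd.DataFrame({"cell_id": n1d.obs_names, "cluster": assign.labels}),
            "clusters.csv",
        )
        comp = progclust.composition(assign.labels, n1d.obs["birthdate"].to_numpy())
        _save(comp["fractions"].reset_index(), "composition.csv")

    manifest = {
        "config": {**asdict(config), "stages": list(config.stages)},
        "seed": config.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(produced))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report(run_dir: str | Path) -> dict:
    """Consolidate a completed run directory into summary tables + text."""
    run = Path(run_dir)
    sections: dict[str, pd.DataFrame] = {}
    notes: list[str] = []
    for name, title in [
        ("dispersion.csv", "dispersion_by_age"),
        ("hetero_runs.csv", "heterogeneity_by_condition"),
        ("composition.csv", "composition"),
    ]:
        path = run / name
        if path.exists():
            sections[title] = pd.read_csv(path)
        else:
            notes.append(f"missing stage output: {name}; section skipped")

    if "heterogeneity_by_condition" in sections:
        runs = sections["heterogeneity_by_condition"]
        homogeneous = runs[runs["condition"] == "adult_SL"]
        if len(homogeneous):
            m = homogeneous["ratio"].mean()
            ok = 0.9 <= m <= 1.1
            notes.append(
                f"null calibration (adult_SL mean ratio {m:.3f}): "
                + ("PASS" if ok else "FAIL")
            )
    summary_path = run / "report.txt"
    summary_path.write_text(
        "\n".join([f"sections: {sorted(sections)}"] + notes) + "\n"
    )
    return {"sections": sections, "notes": notes}
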
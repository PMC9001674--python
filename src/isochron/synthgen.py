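"""Synthetic data with known ground truth.

Two generators back every downstream stage of the pipeline:

* :func:`simulate_cohort` emulates a birthdating imaging experiment — one
  cortical section with a pial-surface and a subplate-lower-border landmark
  polyline, and a cohort of detected cells whose true normalized radial
  depths are drawn from a (clamped) normal distribution.  Cells are either
  "direct-born" (bright pulse label, no proliferation-label incorporation)
  or diluted, so the intensity gate downstream has a recoverable truth.
* :func:`simulate_counts` emulates single-cell RNA-seq count matrices with
  per-condition latent subtype programs: negative-binomial counts around
  gamma-distributed baseline gene means shared across conditions, subtype
  program genes shifted by a log2 fold change, independent Bernoulli
  dropout, and a flagged mitochondrial gene block.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "CohortSimSpec",
    "ConditionSpec",
    "ExprSimSpec",
    "simulate_cohort",
    "simulate_counts",
    "make_fixtures",
]


# ---------------------------------------------------------------------------
# imaging cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters of one simulated isochronic cohort on one section.

    Intensities are log-normal: ``ft_hi``/``ft_lo`` and ``brdu_hi``/``brdu_lo``
    are (location, scale) pairs on the natural-log scale.  Direct-born cells
    draw pulse-label (FT) intensity from ``ft_hi`` and proliferation-label
    (BrdU) intensity from ``brdu_lo``; diluted cells the other way round.
    """

    n_cells: int
    center: float = 0.5
    spread_sd: float = 0.1
    frac_direct_born: float = 0.15
    ft_hi: tuple[float, float] = (3.0, 0.3)
    ft_lo: tuple[float, float] = (1.0, 0.3)
    brdu_hi: tuple[float, float] = (3.0, 0.3)
    brdu_lo: tuple[float, float] = (0.0, 0.3)
    section_width: float = 1000.0
    section_height: float = 1500.0
    landmark_jitter: float = 15.0
    n_landmark_points: int = 9
    section_id: str = "s0"
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "center",
            "spread_sd",
            "frac_direct_born",
            "section_width",
            "section_height",
            "landmark_jitter",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite parameter: {name}={v!r}")
        for name in ("ft_hi", "ft_lo", "brdu_hi", "brdu_lo"):
            pair = getattr(self, name)
            if len(pair) != 2 or not all(math.isfinite(v) for v in pair):
                raise ValueError(f"non-finite parameter: {name}={pair!r}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.ft_hi[0] <= self.ft_lo[0]:
            raise ValueError("ft_hi location must exceed ft_lo location")
        if self.brdu_hi[0] <= self.brdu_lo[0]:
            raise ValueError("brdu_hi location must exceed brdu_lo location")
        if not (0.0 <= self.frac_direct_born <= 1.0):
            raise ValueError("frac_direct_born must lie in [0, 1]")


def _landmark_polyline(
    rng: np.random.Generator, y0: float, width: float, jitter: float, n_pts: int
) -> np.ndarray:
    xs = np.linspace(0.0, width, n_pts)
    ys = y0 + rng.normal(0.0, jitter, n_pts)
    return np.column_stack([xs, ys])


def simulate_cohort(spec: CohortSimSpec):
    """Simulate one detected-cell table plus section landmarks.

    Returns ``(cells, geometry, truth)`` where *cells* is a DataFrame with
    the detected-cell schema (section_id, x, y, ft_intensity, brdu_intensity,
    size), *geometry* a :class:`isochron.ftquant.SectionGeometry`, and
    *truth* a DataFrame holding the generator's per-cell ground truth
    (true normalized depth, direct-born flag).
    """
    from .ftquant import SectionGeometry  # local import avoids a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)

    pia = _landmark_polyline(
        rng, spec.section_height, spec.section_width, spec.landmark_jitter, spec.n_landmark_points
    )
    subplate = _landmark_polyline(
        rng, 0.0, spec.section_width, spec.landmark_jitter, spec.n_landmark_points
    )
    geom = SectionGeometry(section_id=spec.section_id, pia=pia, subplate=subplate)

    n = spec.n_cells
    depth = np.clip(rng.normal(spec.center, spec.spread_sd, n), 0.0, 1.0)
    direct = rng.random(n) < spec.frac_direct_born

    x = rng.uniform(0.0, spec.section_width, n)
    # interpolate the two landmark lines at each cell's x and place the cell
    # at its true depth fraction between them
    y_sub = np.interp(x, subplate[:, 0], subplate[:, 1])
    y_pia = np.interp(x, pia[:, 0], pia[:, 1])
    y = y_sub + depth * (y_pia - y_sub)

    def _lognorm(pair: tuple[float, float], size: int) -> np.ndarray:
        return rng.lognormal(pair[0], pair[1], size)

    ft = np.where(direct, _lognorm(spec.ft_hi, n), _lognorm(spec.ft_lo, n))
    brdu = np.where(direct, _lognorm(spec.brdu_lo, n), _lognorm(spec.brdu_hi, n))
    size = rng.lognormal(4.0, 0.2, n)

    cells = pd.DataFrame(
        {
            "section_id": spec.section_id,
            "x": x,
            "y": y,
            "ft_intensity": ft,
            "brdu_intensity": brdu,
            "size": size,
        }
    )
    truth = pd.DataFrame(
        {"section_id": spec.section_id, "true_depth": depth, "direct_born": direct}
    )
    return cells, geom, truth


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionSpec:
    """One simulated condition (birthdate x stage) of the count matrix."""

    label: str
    n_cells: int
    birthdate: str = "E13"
    stage: str = "N1d"
    k_subtypes: int = 1
    subtype_props: tuple[float, ...] | None = None
    program_size: int = 40
    effect_logfc: float = 0.0
    dropout_rate: float = 0.1
    #: conditions sharing a program_group use the same subtype program genes,
    #: so their cells can co-cluster into shared molecular types
    program_group: str | None = None

    def props(self) -> np.ndarray:
        if self.subtype_props is None:
            return np.full(self.k_subtypes, 1.0 / self.k_subtypes)
        return np.asarray(self.subtype_props, float)

    def validate(self) -> None:
        if self.k_subtypes < 1:
            raise ValueError(f"{self.label}: k_subtypes must be >= 1")
        p = self.props()
        if len(p) != self.k_subtypes:
            raise ValueError(f"{self.label}: subtype_props length != k_subtypes")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.label}: subtype_props must sum to 1")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError(f"{self.label}: dropout_rate must lie in [0, 1]")


@dataclass(frozen=True)
class ExprSimSpec:
    """Parameters of a multi-condition synthetic count matrix.

    Baseline per-gene means are gamma-distributed (``mean_gamma_shape`` /
    ``mean_gamma_scale``) and drawn once, shared across conditions, so
    between-condition differences come only from the planted programs.
    ``nb_dispersion`` is the negative-binomial size parameter theta
    (variance = mu + mu^2 / theta).  ``n_gradient_genes`` genes (if any)
    scale their mean with each cell's recorded radial position, emulating
    laminar expression gradients.
    """

    n_genes: int = 1000
    mito_gene_frac: float = 0.02
    conditions: tuple[ConditionSpec, ...] = ()
    mean_gamma_shape: float = 0.6
    mean_gamma_scale: float = 150.0
    nb_dispersion: float = 2.0
    n_gradient_genes: int = 0
    gradient_logfc: float = 2.0
    #: NB size for gradient genes; laminar markers are tightly position-
    #: determined, so they carry less biological overdispersion
    gradient_dispersion: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0.0 <= self.mito_gene_frac <= 1.0):
            raise ValueError("mito_gene_frac must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for cond in self.conditions:
            cond.validate()


def _exact_subtype_labels(rng: np.random.Generator, n: int, props: np.ndarray) -> np.ndarray:
    """Assign subtype indices with counts as close to n*props as possible."""
    counts = np.floor(n * props).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        frac = n * props - np.floor(n * props)
        counts[np.argsort(-frac)[:rem]] += 1
    labels = np.repeat(np.arange(len(props)), counts)
    return rng.permutation(labels)


def simulate_counts(spec: ExprSimSpec) -> ad.AnnData:
    """Simulate a genes-by-cells count matrix as an AnnData (cells x genes).

    ``adata.X`` holds raw integer counts; ``adata.var`` carries ``mito`` and
    program-membership flags; ``adata.obs`` carries cell_id, condition,
    birthdate, stage, subtype_truth and radial_position.

    Random streams are structured so that two specs differing only in a
    condition's ``effect_logfc`` produce bit-identical counts for all
    non-program genes: the gamma stage uses scale-free standard-gamma draws
    and the Poisson stage uses one child stream per gene.  This makes
    effect-size ladders paired by construction.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))

    G = spec.n_genes
    base_mean = rng.gamma(spec.mean_gamma_shape, spec.mean_gamma_scale, G) + 0.1
    n_mito = int(np.ceil(spec.mito_gene_frac * G))
    mito = np.zeros(G, dtype=bool)
    mito[:n_mito] = True

    grad_genes = np.array([], dtype=int)
    if spec.n_gradient_genes > 0:
        # laminar-marker analogues: robustly expressed genes (top quartile of
        # baseline mean), so the planted gradient is readable above noise
        candidates = np.flatnonzero(~mito & (base_mean >= np.quantile(base_mean, 0.75)))
        grad_genes = rng.choice(candidates, spec.n_gradient_genes, replace=False)

    gene_ids = np.array(
        [f"mt-g{i:04d}" if mito[i] else f"g{i:04d}" for i in range(G)]
    )

    blocks, obs_rows, program_of_gene = [], [], np.full(G, "", dtype=object)
    group_programs: dict[str, list[np.ndarray]] = {}
    for ci, cond in enumerate(spec.conditions):
        n = cond.n_cells
        crng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1, ci)))
        sub = _exact_subtype_labels(crng, n, cond.props())
        # disjoint program gene blocks, drawn among non-mito, non-gradient
        # genes; conditions in the same program_group reuse one draw
        free = np.flatnonzero(~mito)
        free = np.setdiff1d(free, grad_genes, assume_unique=False)
        need = cond.k_subtypes * cond.program_size if cond.k_subtypes > 1 else 0
        programs: list[np.ndarray] = []
        truth_base = cond.program_group or cond.label
        if need > 0:
            if cond.program_group is not None and cond.program_group in group_programs:
                programs = group_programs[cond.program_group]
                if len(programs) != cond.k_subtypes:
                    raise ValueError(
                        f"{cond.label}: program_group {cond.program_group!r} was "
                        f"defined with {len(programs)} subtypes"
                    )
            else:
                chosen = crng.choice(free, need, replace=False)
                programs = [
                    chosen[s * cond.program_size : (s + 1) * cond.program_size]
                    for s in range(cond.k_subtypes)
                ]
                if cond.program_group is not None:
                    group_programs[cond.program_group] = programs
            for s, genes in enumerate(programs):
                tag = f"{truth_base}:s{s}"
                for g in genes:
                    if tag not in str(program_of_gene[g]):
                        program_of_gene[g] = (
                            program_of_gene[g] + ";" if program_of_gene[g] else ""
                        ) + tag

        mean = np.tile(base_mean, (n, 1))
        for s, genes in enumerate(programs):
            mean[np.ix_(sub == s, genes)] *= 2.0 ** cond.effect_logfc

        pos = crng.uniform(0.0, 1.0, n)
        if grad_genes.size:
            mean[:, grad_genes] *= 2.0 ** (spec.gradient_logfc * (pos[:, None] - 0.5))

        theta = spec.nb_dispersion
        grng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2, ci)))
        lam = grng.standard_gamma(theta, (n, G)) * (mean / theta)
        if grad_genes.size:
            tg = spec.gradient_dispersion
            g2 = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(5, ci)))
            lam[:, grad_genes] = g2.standard_gamma(tg, (n, grad_genes.size)) * (
                mean[:, grad_genes] / tg
            )
        counts = np.empty((n, G), dtype=np.int64)
        for g in range(G):
            prng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(3, ci, g))
            )
            counts[:, g] = prng.poisson(lam[:, g])
        if cond.dropout_rate > 0:
            drng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(4, ci)))
            counts[drng.random(counts.shape) < cond.dropout_rate] = 0
        blocks.append(counts)
        obs_rows.append(
            pd.DataFrame(
                {
                    "condition": cond.label,
                    "birthdate": cond.birthdate,
                    "stage": cond.stage,
                    "subtype_truth": [f"{truth_base}:s{s}" for s in sub],
                    "radial_position": pos,
                }
            )
        )

    if blocks:
        X = np.vstack(blocks).astype(np.int64)
        obs = pd.concat(obs_rows, ignore_index=True)
    else:
        X = np.zeros((0, G), dtype=np.int64)
        obs = pd.DataFrame(
            columns=["condition", "birthdate", "stage", "subtype_truth", "radial_position"]
        )
    obs.insert(0, "cell_id", [f"c{i:05d}" for i in range(len(obs))])
    obs.index = obs["cell_id"].astype(str)

    var = pd.DataFrame(
        {"gene_id": gene_ids, "mito": mito, "program": program_of_gene.astype(str)},
        index=gene_ids,
    )
    out = ad.AnnData(X=X, obs=obs, var=var)
    out.uns["base_mean"] = base_mean
    out.uns["nb_dispersion"] = spec.nb_dispersion
    return out


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

#: cohort layout of the imaging fixture: (injection_age, center, spread_sd)
_IMAGING_COHORTS = (
    ("E13.5", 0.35, 0.16),
    ("E15.5", 0.75, 0.05),
)


def default_expression_spec(seed: int = 0, n_cells: int = 120) -> ExprSimSpec:
    """Condition panel mimicking the study design.

    Birthdates E12-E15 at stages AP / N1d / N4d, plus adult deep-layer
    (three latent subtypes) and adult superficial-layer (one subtype)
    conditions.  Early N1d conditions carry stronger latent structure than
    their AP and N4d counterparts — a transient surge of heterogeneity one
    day after birth — and late conditions are near-homogeneous.
    """
    conds = []
    for bd in ("E12", "E13", "E14", "E15"):
        early = bd in ("E12", "E13")
        for stage in ("AP", "N1d", "N4d"):
            if stage == "N1d" and early:
                # shared early newborn-neuron programs: E12- and E13-born
                # cells draw from the same three molecular types
                k, lfc, group = 3, 2.0, "early_N1d"
            elif early:
                k, lfc, group = 2, 0.8, f"early_{stage}"
            else:
                k, lfc, group = 1, 0.0, None
            conds.append(
                ConditionSpec(
                    label=f"{bd}_{stage}", n_cells=n_cells, birthdate=bd, stage=stage,
                    k_subtypes=k, effect_logfc=lfc, program_size=40,
                    program_group=group,
                )
            )
    conds.append(
        ConditionSpec(
            label="adult_DL", n_cells=n_cells, birthdate="adult", stage="adult_DL",
            k_subtypes=3, effect_logfc=2.0, program_size=40,
        )
    )
    conds.append(
        ConditionSpec(
            label="adult_SL", n_cells=n_cells, birthdate="adult", stage="adult_SL",
            k_subtypes=1, effect_logfc=0.0,
        )
    )
    return ExprSimSpec(n_genes=1000, conditions=tuple(conds), seed=seed)


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the standard small imaging + expression fixtures.

    Imaging: 3 pups x 2 cohorts (a broad early-born and a compact late-born
    one) as cells.csv / landmarks.csv / cohorts.csv.  Expression: the
    :func:`default_expression_spec` panel as Matrix Market + TSV metadata.
    Returns the written paths.
    """
    from .scqc import write_counts

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cells_l, lm_rows, cohort_rows, truth_l = [], [], [], []
    k = 0
    for pup in ("p1", "p2", "p3"):
        for age, center, sd in _IMAGING_COHORTS:
            sid = f"{pup}_{age}"
            spec = CohortSimSpec(
                n_cells=150, center=center, spread_sd=sd, section_id=sid,
                seed=seed * 1000 + k,
            )
            k += 1
            cells, geom, truth = simulate_cohort(spec)
            cells_l.append(cells)
            truth_l.append(truth)
            for structure, poly in (("pia", geom.pia), ("subplate", geom.subplate)):
                for i, (x, y) in enumerate(poly):
                    lm_rows.append(
                        {"section_id": sid, "structure": structure,
                         "point_index": i, "x": x, "y": y}
                    )
            cohort_rows.append(
                {"section_id": sid, "injection_age": age,
                 "collection_age": "P7", "pup_id": pup}
            )

    paths = {
        "cells": out / "cells.csv",
        "landmarks": out / "landmarks.csv",
        "cohorts": out / "cohorts.csv",
        "truth": out / "imaging_truth.csv",
        "counts_dir": out / "counts",
    }
    pd.concat(cells_l, ignore_index=True).to_csv(paths["cells"], index=False)
    pd.DataFrame(lm_rows).to_csv(paths["landmarks"], index=False)
    pd.DataFrame(cohort_rows).to_csv(paths["cohorts"], index=False)
    pd.concat(truth_l, ignore_index=True).to_csv(paths["truth"], index=False)

    adata = simulate_counts(default_expression_spec(seed=seed))
    write_counts(adata, paths["counts_dir"])
    return paths
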
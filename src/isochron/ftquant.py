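"""Birthdating-cohort image quantification.

Operations on detected-cell tables from pulse-label (FT) / chronic-BrdU
birthdating experiments: per-section intensity gating of directly
progenitor-born neurons, normalized radial position between the subplate
lower border (0) and the pial surface (1), laminar dispersion summaries,
hierarchical clustering of cohort position distributions, and the standard
two-sample comparisons (Welch t on dispersions, Kolmogorov-Smirnov on raw
positions) plus an OLS time trend of dispersion with a 95% band.

Quantiles use linear interpolation between order statistics throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from shapely.geometry import LineString

__all__ = [
    "SectionGeometry",
    "LaminarCohort",
    "DispersionSummary",
    "TrendFit",
    "gate_direct_born",
    "gate_top_ft",
    "radial_positions",
    "normalize_positions",
    "mean_normalized_density",
    "dispersion",
    "cluster_cohorts",
    "compare_dispersion",
    "compare_distributions",
    "dispersion_trend",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionGeometry:
    """Manually traced landmark polylines of one section (pixel units)."""

    section_id: str
    pia: np.ndarray
    subplate: np.ndarray
    cp_upper: np.ndarray | None = None
    cp_lower: np.ndarray | None = None

    def __post_init__(self):
        for name in ("pia", "subplate"):
            poly = getattr(self, name)
            if np.asarray(poly).shape[0] < 2:
                raise ValueError(f"{name} polyline needs >= 2 points")
        if LineString(self.pia).intersects(LineString(self.subplate)):
            raise ValueError("pia and subplate polylines must not intersect")


@dataclass
class LaminarCohort:
    """Normalized radial positions of one isochronic cohort."""

    injection_age: str
    collection_age: str
    pup_id: str
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        if self.positions.size and (
            self.positions.min() < -1e-9 or self.positions.max() > 1 + 1e-9
        ):
            raise ValueError("positions must lie in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.injection_age}_{self.pup_id}"


@dataclass(frozen=True)
class DispersionSummary:
    n: int
    sd: float
    iqr: float
    mean_pos: float
    iqr_mean_normalized: float


@dataclass(frozen=True)
class TrendFit:
    label: str
    slope: float
    intercept: float
    ci95_slope: tuple[float, float]
    fitted: pd.DataFrame  # columns: day, fitted, band_lo, band_hi


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


def gate_direct_born(
    cells: pd.DataFrame, brdu_percentile: float = 20.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gate directly progenitor-born (FT-bright, BrdU-negative) cells.

    Per section, keeps cells with FT intensity strictly above the section
    median and BrdU intensity strictly below the section's
    ``brdu_percentile``-th percentile (linear-interpolation percentile).
    Returns ``(kept, report)``; *report* has one row per section with the
    thresholds applied and the kept count.
    """
    kept_parts, report_rows = [], []
    for sid, grp in cells.groupby("section_id", sort=True):
        ft_med = float(np.median(grp["ft_intensity"]))
        brdu_thr = float(np.percentile(grp["brdu_intensity"], brdu_percentile))
        if grp["ft_intensity"].nunique() == 1:
            warnings.warn(
                f"section {sid}: all FT intensities equal; median gate keeps no cells"
            )
        mask = (grp["ft_intensity"] > ft_med) & (grp["brdu_intensity"] < brdu_thr)
        kept_parts.append(grp[mask])
        report_rows.append(
            {
                "section_id": sid,
                "n_cells": len(grp),
                "ft_median": ft_med,
                "brdu_threshold": brdu_thr,
                "n_kept": int(mask.sum()),
            }
        )
    kept = (
        pd.concat(kept_parts) if kept_parts else cells.iloc[0:0]
    )
    return kept, pd.DataFrame(report_rows)


def gate_top_ft(cells: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Keep, per section, the cells in the top ``fraction`` of FT intensity.

    The cut is the (1 - fraction) linear-interpolation quantile; boundary
    ties are all kept (>=).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    parts = []
    for _, grp in cells.groupby("section_id", sort=True):
        q = np.quantile(grp["ft_intensity"], 1.0 - fraction)
        parts.append(grp[grp["ft_intensity"] >= q])
    return pd.concat(parts) if parts else cells.iloc[0:0]


# ---------------------------------------------------------------------------
# radial position
# ---------------------------------------------------------------------------


def radial_positions(
    cells: pd.DataFrame, geom: SectionGeometry, tol: float = 0.1
) -> pd.DataFrame:
    """Normalized radial depth of each cell between the landmark polylines.

    r = d_sub / (d_sub + d_pia) with nearest-point Euclidean distances to
    the subplate-lower-border and pia polylines; r = 0 on the subplate
    border, 1 on the pia.  Cells whose distance sum exceeds the local band
    thickness by more than ``tol`` (relative) are flagged ``outside`` and
    should be excluded from cohorts.
    """
    pia_ls = LineString(geom.pia)
    sub_ls = LineString(geom.subplate)
    pts = shapely.points(np.column_stack([cells["x"], cells["y"]]))
    d_pia = shapely.distance(pts, pia_ls)
    d_sub = shapely.distance(pts, sub_ls)
    denom = d_sub + d_pia
    r = np.where(denom > 0, d_sub / np.where(denom > 0, denom, 1.0), 0.0)

    # local thickness: distance from each cell's nearest subplate point to pia
    nearest_on_sub = shapely.shortest_line(pts, sub_ls)
    sub_pts = shapely.get_point(nearest_on_sub, 1)
    thickness = shapely.distance(sub_pts, pia_ls)
    outside = denom > thickness * (1.0 + tol)

    out = cells.copy()
    out["radial_position"] = r
    out["outside_band"] = outside
    return out


def normalize_positions(
    cohort: LaminarCohort,
    mode: Literal["cortex", "cortical_plate"],
    geom: SectionGeometry | None = None,
) -> tuple[LaminarCohort, int]:
    """Rescale cohort positions to the chosen reference band.

    ``cortex`` mode is the identity (positions are already normalized to
    the full cortical band).  ``cortical_plate`` mode rescales so that the
    cortical-plate lower/upper landmark polylines map to 0/1; the band ends
    are the mean cortex-depth of each CP polyline's vertices.  Positions
    falling outside [0, 1] after rescaling are excluded; their count is
    returned alongside the new cohort.
    """
    if mode == "cortex":
        return cohort, 0
    if mode != "cortical_plate":
        raise ValueError(f"unknown mode: {mode!r}")
    if geom is None or geom.cp_upper is None or geom.cp_lower is None:
        raise ValueError("cortical_plate mode requires cp_upper/cp_lower landmarks")

    def _band_depth(poly: np.ndarray) -> float:
        df = pd.DataFrame({"x": poly[:, 0], "y": poly[:, 1]})
        return float(radial_positions(df, geom)["radial_position"].mean())

    r_lo, r_hi = _band_depth(geom.cp_lower), _band_depth(geom.cp_upper)
    if r_hi <= r_lo:
        raise ValueError("cp_upper must lie above cp_lower")
    rescaled = (cohort.positions - r_lo) / (r_hi - r_lo)
    inside = (rescaled >= 0.0) & (rescaled <= 1.0)
    new = LaminarCohort(
        cohort.injection_age, cohort.collection_age, cohort.pup_id, rescaled[inside]
    )
    return new, int((~inside).sum())


# ---------------------------------------------------------------------------
# dispersion statistics
# ---------------------------------------------------------------------------


def mean_normalized_density(
    positions: np.ndarray, n_bins: int = 20, hist_range: tuple[float, float] = (0.0, 2.0)
) -> np.ndarray:
    """Density of positions normalized to their mean, summing to 1."""
    positions = np.asarray(positions, float)
    if positions.size == 0:
        raise ValueError("empty cohort")
    m = positions.mean()
    if m == 0:
        raise ValueError("zero mean position; cannot mean-normalize")
    counts, _ = np.histogram(positions / m, bins=n_bins, range=hist_range)
    total = counts.sum()
    if total == 0:
        raise ValueError("all positions fall outside the histogram range")
    return counts / total


def dispersion(positions: np.ndarray) -> DispersionSummary:
    """Sample SD (n-1), IQR and mean-normalized IQR of cohort positions."""
    positions = np.asarray(positions, float)
    n = positions.size
    if n < 2:
        raise ValueError("dispersion needs n >= 2 positions")
    sd = float(np.std(positions, ddof=1))
    q1, q3 = np.percentile(positions, [25.0, 75.0])
    mean = float(positions.mean())
    return DispersionSummary(
        n=n, sd=sd, iqr=float(q3 - q1), mean_pos=mean,
        iqr_mean_normalized=float((q3 - q1) / mean) if mean != 0 else float("nan"),
    )


def _centered_features(
    cohorts: Sequence[LaminarCohort], n_bins: int
) -> np.ndarray:
    feats = []
    for c in cohorts:
        centered = c.positions - c.positions.mean()
        counts, _ = np.histogram(centered, bins=n_bins, range=(-0.5, 0.5))
        total = counts.sum()
        feats.append(counts / total if total else counts.astype(float))
    return np.asarray(feats)


def _tree_to_nested(node, labels):
    if node.is_leaf():
        return labels[node.id]
    return [_tree_to_nested(node.left, labels), _tree_to_nested(node.right, labels)]


def cluster_cohorts(
    cohorts: Sequence[LaminarCohort], n_bins: int = 20, method: str = "average"
) -> dict:
    """Agglomerative clustering of mean-centered position distributions.

    Each cohort becomes a density histogram of mean-centered positions over
    [-0.5, 0.5]; cohorts are clustered on Euclidean distances between these
    profiles.  Returns the dendrogram (nested lists), the flat 2-cluster
    labels, and the feature matrix.
    """
    if len(cohorts) < 2:
        raise ValueError("need >= 2 cohorts")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    feats = _centered_features(cohorts, n_bins)
    Z = linkage(feats, method=method, metric="euclidean")
    flat = fcluster(Z, t=2, criterion="maxclust")
    labels = [c.label for c in cohorts]
    return {
        "labels": labels,
        "flat2": dict(zip(labels, (int(v) for v in flat))),
        "dendrogram": _tree_to_nested(to_tree(Z), labels),
        "features": feats,
        "linkage": Z,
    }


def compare_dispersion(
    sds_a: Sequence[float], sds_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch unequal-variance t-test on per-cohort dispersion values.

    Returns (statistic, Welch-Satterthwaite df, two-sided p).  When both
    groups are constant with equal means the test is degenerate; by
    convention the statistic is 0 and p = 1 (a warning is emitted).
    """
    a, b = np.asarray(sds_a, float), np.asarray(sds_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("both groups constant and equal; degenerate Welch test")
            return 0.0, float(a.size + b.size - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_distributions(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on raw positions."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def dispersion_trend(points: pd.DataFrame) -> dict[str, TrendFit]:
    """Per-label OLS of dispersion (sd) on collection day, with 95% bands.

    ``points`` needs columns ``day``, ``sd``, ``label``; each label needs
    >= 3 points with at least two distinct days.
    """
    fits: dict[str, TrendFit] = {}
    for label, grp in points.groupby("label", sort=True):
        if len(grp) < 3:
            raise ValueError(f"label {label}: need >= 3 points")
        if grp["day"].nunique() < 2:
            raise ValueError(f"label {label}: all days identical; no slope")
        X = sm.add_constant(np.asarray(grp["day"], float))
        model = sm.OLS(np.asarray(grp["sd"], float), X).fit()
        ci = model.conf_int(alpha=0.05)
        pred = model.get_prediction(X).summary_frame(alpha=0.05)
        fits[label] = TrendFit(
            label=label,
            slope=float(model.params[1]),
            intercept=float(model.params[0]),
            ci95_slope=(float(ci[1][0]), float(ci[1][1])),
            fitted=pd.DataFrame(
                {
                    "day": np.asarray(grp["day"], float),
                    "fitted": pred["mean"].to_numpy(),
                    "band_lo": pred["mean_ci_lower"].to_numpy(),
                    "band_hi": pred["mean_ci_upper"].to_numpy(),
                }
            ),
        )
    return fits
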
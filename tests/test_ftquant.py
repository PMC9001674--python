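"""Gating, radial geometry and dispersion statistics of imaging cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_cell_table
from isochron import ftquant
from isochron.ftquant import (
    LaminarCohort,
    SectionGeometry,
    cluster_cohorts,
    compare_dispersion,
    compare_distributions,
    dispersion,
    dispersion_trend,
    gate_direct_born,
    gate_top_ft,
    mean_normalized_density,
    normalize_positions,
    radial_positions,
)
from isochron.synthgen import CohortSimSpec, simulate_cohort


def _table(ft, brdu, section="s0"):
    n = len(ft)
    return pd.DataFrame(
        {
            "section_id": section,
            "x": np.zeros(n),
            "y": np.zeros(n),
            "ft_intensity": ft,
            "brdu_intensity": brdu,
            "size": np.full(n, 30.0),
        }
    )


def brute_force_gate(cells: pd.DataFrame) -> set:
    kept = set()
    for sid in cells["section_id"].unique():
        grp = cells[cells["section_id"] == sid]
        med = np.median(grp["ft_intensity"])
        p20 = np.percentile(grp["brdu_intensity"], 20)
        for i, row in grp.iterrows():
            if row["ft_intensity"] > med and row["brdu_intensity"] < p20:
                kept.add(i)
    return kept


class TestGating:
    def test_hand_example_all_rejected_by_brdu_gate(self):
        # median FT 2.5 passes {3,4}; 20th pct of BrdU is 0, "< 0" keeps none
        kept, report = gate_direct_born(_table([1, 2, 3, 4], [0, 0, 9, 9]))
        assert len(kept) == 0
        assert report.loc[0, "ft_median"] == 2.5
        assert report.loc[0, "brdu_threshold"] == 0.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            cells = random_cell_table(rng)
            kept, _ = gate_direct_born(cells)
            assert set(kept.index) == brute_force_gate(cells)

    def test_empty_input(self):
        kept, report = gate_direct_born(_table([], []))
        assert len(kept) == 0 and len(report) == 0

    def test_degenerate_all_equal_ft_warns(self):
        with pytest.warns(UserWarning, match="all FT intensities equal"):
            kept, _ = gate_direct_born(_table([2, 2, 2], [0, 1, 2]))
        assert len(kept) == 0

    def test_recovers_ground_truth_on_separated_modes(self):
        cells, _, truth = simulate_cohort(CohortSimSpec(n_cells=400, seed=2))
        kept, _ = gate_direct_born(cells)
        called = np.zeros(len(cells), bool)
        called[kept.index] = True
        direct = truth["direct_born"].to_numpy()
        sensitivity = called[direct].mean()
        specificity = (~called[~direct]).mean()
        assert sensitivity >= 0.9 and specificity >= 0.9

    def test_top_ft_single_max_cell(self):
        cells = _table(np.arange(10, dtype=float), np.zeros(10))
        kept = gate_top_ft(cells, 0.10)
        assert list(kept["ft_intensity"]) == [9.0]

    def test_top_ft_fraction_one_keeps_all(self):
        cells = _table([1, 5, 2], [0, 0, 0])
        assert len(gate_top_ft(cells, 1.0)) == 3

    def test_top_ft_quantile_convention(self):
        # quantile(0.8) of [1,1,1,1,2] = 1.8; only the 2 passes
        kept = gate_top_ft(_table([1, 1, 1, 1, 2], np.zeros(5)), 0.2)
        assert list(kept["ft_intensity"]) == [2.0]

    def test_top_ft_bad_fraction(self):
        with pytest.raises(ValueError):
            gate_top_ft(_table([1], [0]), 0.0)


def _brute_polyline_distance(p, poly, per_seg=4000):
    pts = []
    for a, b in zip(poly[:-1], poly[1:]):
        t = np.linspace(0, 1, per_seg)[:, None]
        pts.append(a + t * (b - a))
    pts = np.vstack(pts)
    return np.min(np.hypot(*(pts - p).T))


class TestRadialPosition:
    def _geom(self):
        pia = np.array([[0.0, 100.0], [50.0, 100.0], [100.0, 100.0]])
        sub = np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0]])
        return SectionGeometry("s0", pia=pia, subplate=sub)

    def test_parallel_landmarks_linear_depth(self):
        geom = self._geom()
        cells = pd.DataFrame({"x": [50.0], "y": [25.0]})
        r = radial_positions(cells, geom)["radial_position"].iloc[0]
        assert r == pytest.approx(0.25)

    def test_cell_on_pia_is_one(self):
        geom = self._geom()
        cells = pd.DataFrame({"x": [30.0], "y": [100.0]})
        assert radial_positions(cells, geom)["radial_position"].iloc[0] == 1.0

    def test_matches_brute_force_polyline_oracle(self, imaging_cohort):
        cells, geom, _ = imaging_cohort
        sub = cells.iloc[:40]
        got = radial_positions(sub, geom)["radial_position"].to_numpy()
        for i, (_, row) in enumerate(sub.iterrows()):
            p = np.array([row["x"], row["y"]])
            d_sub = _brute_polyline_distance(p, geom.subplate)
            d_pia = _brute_polyline_distance(p, geom.pia)
            assert abs(got[i] - d_sub / (d_sub + d_pia)) < 0.02

    def test_rigid_motion_invariance(self, imaging_cohort):
        cells, geom, _ = imaging_cohort
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([123.0, -55.0])

        def xform(a):
            return a @ R.T + shift

        geom2 = SectionGeometry("s0", pia=xform(geom.pia), subplate=xform(geom.subplate))
        xy2 = xform(cells[["x", "y"]].to_numpy())
        cells2 = cells.assign(x=xy2[:, 0], y=xy2[:, 1])
        r1 = radial_positions(cells, geom)["radial_position"].to_numpy()
        r2 = radial_positions(cells2, geom2)["radial_position"].to_numpy()
        np.testing.assert_allclose(r1, r2, atol=1e-9)

    def test_outside_band_flagged(self):
        geom = self._geom()
        cells = pd.DataFrame({"x": [50.0], "y": [250.0]})
        assert radial_positions(cells, geom)["outside_band"].iloc[0]


class TestNormalizePositions:
    def test_cortex_mode_identity(self):
        c = LaminarCohort("E13.5", "P7", "p1", np.array([0.1, 0.5, 0.9]))
        out, n_excl = normalize_positions(c, "cortex")
        np.testing.assert_array_equal(out.positions, c.positions)
        assert n_excl == 0

    def _cp_geom(self):
        pia = np.array([[0.0, 100.0], [100.0, 100.0]])
        sub = np.array([[0.0, 0.0], [100.0, 0.0]])
        cp_lo = np.array([[0.0, 20.0], [100.0, 20.0]])
        cp_up = np.array([[0.0, 80.0], [100.0, 80.0]])
        return SectionGeometry("s0", pia=pia, subplate=sub, cp_upper=cp_up, cp_lower=cp_lo)

    def test_cp_midpoint_maps_to_half(self):
        geom = self._cp_geom()
        c = LaminarCohort("E13.5", "P7", "p1", np.array([0.5]))
        out, _ = normalize_positions(c, "cortical_plate", geom)
        assert out.positions[0] == pytest.approx(0.5)

    def test_cp_excludes_out_of_band(self):
        geom = self._cp_geom()
        c = LaminarCohort("E13.5", "P7", "p1", np.array([0.1, 0.5, 0.95]))
        out, n_excl = normalize_positions(c, "cortical_plate", geom)
        assert n_excl == 2 and len(out.positions) == 1

    def test_cp_mode_requires_landmarks(self):
        c = LaminarCohort("E13.5", "P7", "p1", np.array([0.5]))
        with pytest.raises(ValueError, match="cp_upper/cp_lower"):
            normalize_positions(c, "cortical_plate", None)

    def test_cp_mode_recovers_generator_center(self):
        # depths drawn around 0.5 of the cortex; CP band [0.2, 0.8] maps the
        # cohort mean to ~0.5 in CP units
        rng = np.random.default_rng(0)
        pos = np.clip(rng.normal(0.5, 0.08, 400), 0, 1)
        geom = self._cp_geom()
        c = LaminarCohort("E13.5", "P7", "p1", pos)
        out, _ = normalize_positions(c, "cortical_plate", geom)
        assert abs(out.positions.mean() - 0.5) < 0.03


class TestDispersion:
    def test_hand_computed_summary(self):
        d = dispersion(np.array([0.2, 0.4]))
        assert d.sd == pytest.approx(np.sqrt(0.02), rel=1e-12)
        assert d.iqr == pytest.approx(0.1)
        assert d.mean_pos == pytest.approx(0.3)
        assert d.iqr_mean_normalized == pytest.approx(1 / 3)

    def test_constant_vector(self):
        d = dispersion(np.full(5, 0.4))
        assert d.sd == 0 and d.iqr == 0

    def test_rejects_single_point(self):
        with pytest.raises(ValueError):
            dispersion(np.array([0.5]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30),
        st.floats(-5, 5, allow_nan=False),
    )
    def test_translation_invariance(self, xs, shift):
        a = np.asarray(xs)
        d0, d1 = dispersion(a), dispersion(a + shift)
        assert d1.sd == pytest.approx(d0.sd, abs=1e-9)
        assert d1.iqr == pytest.approx(d0.iqr, abs=1e-9)

    def test_density_normalization_and_scale_invariance(self):
        pos = np.array([0.2, 0.3, 0.4, 0.8])
        d1 = mean_normalized_density(pos, 20)
        assert d1.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(d1, mean_normalized_density(2 * pos, 20))

    def test_density_all_equal_single_bin(self):
        d = mean_normalized_density(np.full(10, 0.3), 20)
        assert d.max() == 1.0
        edges = np.linspace(0, 2, 21)
        occupied = np.flatnonzero(d)[0]
        assert edges[occupied] <= 1.0 <= edges[occupied + 1]

    def test_density_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            mean_normalized_density(np.zeros(5), 10)


class TestClusterCohorts:
    @staticmethod
    def _cohort(age, pup, center, sd, n, seed):
        rng = np.random.default_rng(seed)
        pos = np.clip(rng.normal(center, sd, n), 0, 1)
        return LaminarCohort(age, "P7", pup, pos)

    def test_centering_removes_location(self):
        a = self._cohort("E12.5", "p1", 0.2, 0.03, 200, 0)
        b = self._cohort("E15.5", "p2", 0.8, 0.03, 200, 1)
        broad = [self._cohort("E13.5", f"q{i}", 0.5, 0.2, 200, 10 + i) for i in range(2)]
        res = cluster_cohorts([a, b] + broad)
        assert res["flat2"][a.label] == res["flat2"][b.label]

    def test_broad_vs_narrow_bipartition(self):
        narrow = [self._cohort("E15.5", f"p{i}", 0.7, 0.04, 300, i) for i in range(3)]
        broad = [self._cohort("E12.5", f"p{i}", 0.4, 0.15, 300, 10 + i) for i in range(3)]
        res = cluster_cohorts(narrow + broad)
        ids_n = {res["flat2"][c.label] for c in narrow}
        ids_b = {res["flat2"][c.label] for c in broad}
        assert len(ids_n) == 1 and len(ids_b) == 1 and ids_n != ids_b

    def test_duplicate_cohort_zero_distance(self):
        a = self._cohort("E13.5", "p1", 0.5, 0.1, 100, 0)
        b = LaminarCohort("E13.5", "p2", a.collection_age, a.positions)
        b = LaminarCohort(a.injection_age, a.collection_age, "p2", a.positions)
        res = cluster_cohorts([a, b, self._cohort("E15.5", "p3", 0.7, 0.05, 100, 1)])
        f = res["features"]
        assert np.linalg.norm(f[0] - f[1]) == 0

    def test_too_few_cohorts_rejected(self):
        with pytest.raises(ValueError):
            cluster_cohorts([self._cohort("E13.5", "p1", 0.5, 0.1, 50, 0)])


class TestComparisons:
    def test_identical_groups_degenerate_welch(self):
        with pytest.warns(UserWarning):
            t, df, p = compare_dispersion([1.0, 1.0], [1.0, 1.0])
        assert t == 0 and p == 1

    def test_welch_matches_hand_formula(self):
        a, b = np.array([1.0, 2, 3]), np.array([1.0, 2, 3, 100])
        t, df, p = compare_dispersion(a, b)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 3)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == pytest.approx(df_hand, rel=1e-12)

    def test_welch_antisymmetry(self):
        t1, _, p1 = compare_dispersion([1.0, 2, 3], [4.0, 5, 7])
        t2, _, p2 = compare_dispersion([4.0, 5, 7], [1.0, 2, 3])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_ks_identical_and_disjoint(self):
        a = np.array([0.1, 0.2, 0.3])
        assert compare_distributions(a, a)[0] == 0
        assert compare_distributions(np.zeros(3), np.ones(3))[0] == 1

    def test_ks_matches_ecdf_sweep(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = rng.random(20), rng.random(20)
            stat, _ = compare_distributions(a, b)
            grid = np.concatenate([a, b])
            ecdf_diff = max(
                abs((a <= x).mean() - (b <= x).mean()) for x in grid
            )
            assert stat == pytest.approx(ecdf_diff, abs=1e-12)


class TestDispersionTrend:
    def test_perfect_line_recovered(self):
        days = np.array([2.0, 3, 4, 5])
        df = pd.DataFrame({"day": days, "sd": 0.3 - 0.02 * days, "label": "E15.5"})
        fit = dispersion_trend(df)["E15.5"]
        assert fit.slope == pytest.approx(-0.02, abs=1e-12)
        assert fit.intercept == pytest.approx(0.3, abs=1e-12)
        np.testing.assert_allclose(fit.fitted["fitted"], 0.3 - 0.02 * days, atol=1e-12)

    def test_point_order_irrelevant(self):
        df = pd.DataFrame(
            {"day": [2.0, 3, 4, 5], "sd": [0.3, 0.25, 0.27, 0.2], "label": "x"}
        )
        f1 = dispersion_trend(df)["x"]
        f2 = dispersion_trend(df.iloc[::-1].reset_index(drop=True))["x"]
        assert f1.slope == pytest.approx(f2.slope)

    def test_compacting_vs_flat_series(self):
        rng = np.random.default_rng(1)
        days = np.repeat(np.arange(2.0, 8.0), 3)
        compacting = 0.25 - 0.025 * days + rng.normal(0, 0.01, days.size)
        flat = 0.18 + rng.normal(0, 0.01, days.size)
        df = pd.DataFrame(
            {
                "day": np.concatenate([days, days]),
                "sd": np.concatenate([compacting, flat]),
                "label": ["E15.5-like"] * days.size + ["E13.5-like"] * days.size,
            }
        )
        fits = dispersion_trend(df)
        lo, hi = fits["E15.5-like"].ci95_slope
        assert fits["E15.5-like"].slope < 0 and hi < 0
        lo, hi = fits["E13.5-like"].ci95_slope
        assert lo < 0 < hi

    def test_identical_days_rejected(self):
        df = pd.DataFrame({"day": [3.0, 3, 3], "sd": [0.1, 0.2, 0.3], "label": "x"})
        with pytest.raises(ValueError, match="no slope"):
            dispersion_trend(df)
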
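"""Gradient ordering, moving-window profiles and spline fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from genotag.gradient_analysis import (
    blast_subset,
    fit_spline,
    gradient_correlations,
    moving_profiles,
    order_by_gradient,
)


@pytest.fixture(scope="module")
def blast(gradient_run):
    truth = gradient_run["truth"]
    u = gradient_run["u"]
    mask = truth.cells.population.isin(["KRAS_blast", "FLT3_blast"])
    labels = pd.Series(
        np.where(mask, 0, 1), index=truth.cells.index, name="cluster"
    )
    ub = blast_subset(u, labels, [0])
    return {"truth": truth, "u": u, "ub": ub, "labels": labels}


class TestBlastSubset:
    def test_subset_size_matches_planted_blast_count(self, blast):
        truth = blast["truth"]
        n_blast = int(truth.cells.population.isin(["KRAS_blast", "FLT3_blast"]).sum())
        assert blast["ub"].shape[0] == n_blast

    def test_all_clusters_marked_gives_identity(self, blast):
        ub = blast_subset(blast["u"], blast["labels"], [0, 1])
        assert ub.shape == blast["u"].shape

    def test_no_blast_clusters_error(self, blast):
        with pytest.raises(ValueError):
            blast_subset(blast["u"], blast["labels"], [])
        with pytest.raises(ValueError):
            blast_subset(blast["u"], blast["labels"], [99])


class TestOrderByGradient:
    def test_planted_order_recovered(self, blast):
        ordering = order_by_gradient(blast["ub"])
        pos = blast["truth"].cells.loc[ordering, "position"].to_numpy()
        tau, _ = kendalltau(np.arange(len(ordering)), pos)
        assert abs(tau) >= 0.9  # sign-invariant: SVD sign is arbitrary

    def test_sign_flip_reverses_ordering(self, blast):
        ub = blast["ub"]
        ordering = order_by_gradient(ub)
        flipped = order_by_gradient(-ub)
        # same ordering up to global reversal (ties permitting)
        pos = {c: i for i, c in enumerate(ordering)}
        ranks_fwd = np.array([pos[c] for c in flipped])
        tau, _ = kendalltau(np.arange(len(flipped)), ranks_fwd)
        assert abs(tau) > 0.99

    def test_rank_deficient_matrix_errors(self):
        u = pd.DataFrame(np.outer(np.arange(10, dtype=float), [1.0, 2.0, 3.0]))
        u.index = [f"c{i}" for i in range(10)]
        with pytest.raises(ValueError, match="rank"):
            order_by_gradient(u)

    def test_too_few_cells_errors(self):
        u = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError):
            order_by_gradient(u)


class TestMovingProfiles:
    def _tiny(self):
        idx = pd.Index([f"c{i}" for i in range(10)], name="cell")
        u = pd.DataFrame(
            {"flat": np.ones(10), "ramp": np.arange(10, dtype=float)}, index=idx
        )
        clones = pd.Series(["a"] * 5 + ["b"] * 5, index=idx)
        return idx, u, clones

    def test_constant_column_gives_constant_profile(self):
        idx, u, clones = self._tiny()
        prof = moving_profiles(idx, u, clones, None, window=3)
        assert np.allclose(prof.antibody_profiles["flat"], 1.0)

    def test_window_equal_n_gives_global_means(self):
        idx, u, clones = self._tiny()
        prof = moving_profiles(idx, u, clones, None, window=10)
        assert prof.antibody_profiles.shape[0] == 1
        assert prof.antibody_profiles["ramp"].iloc[0] == pytest.approx(4.5)
        assert prof.clone_fractions["a"].iloc[0] == pytest.approx(0.5)

    def test_profile_length_is_n_minus_window_plus_one(self):
        idx, u, clones = self._tiny()
        prof = moving_profiles(idx, u, clones, None, window=4)
        assert len(prof.antibody_profiles) == 7

    def test_clone_fractions_bounded_and_subunit_sum(self, blast):
        ub = blast["ub"]
        ordering = order_by_gradient(ub)
        clones = blast["truth"].cells.loc[ordering, "population"]
        prof = moving_profiles(ordering, ub, clones, None, window=100)
        frac = prof.clone_fractions.to_numpy()
        assert (frac >= 0).all() and (frac <= 1).all()
        assert (frac.sum(axis=1) <= 1 + 1e-9).all()

    def test_window_validation(self):
        idx, u, clones = self._tiny()
        with pytest.raises(ValueError):
            moving_profiles(idx, u, clones, None, window=1)
        with pytest.raises(ValueError):
            moving_profiles(idx, u, clones, None, window=11)


class TestGradientCorrelations:
    def test_planted_slopes_recovered_with_signs(self, blast):
        """Rising/falling planted markers correlate strongly and with the
        correct sign along the inferred gradient; the two mutually exclusive
        clones trend in opposite directions."""
        ub = blast["ub"]
        truth = blast["truth"]
        ordering = order_by_gradient(ub)
        pos = truth.cells.loc[ordering, "position"].to_numpy()
        orient, _ = kendalltau(np.arange(len(ordering)), pos)
        clones = truth.cells.loc[ordering, "population"]
        prof = moving_profiles(ordering, ub, clones, None, window=200)
        corr = gradient_correlations(prof)
        sgn = np.sign(orient)
        slopes = {"CD15": 2.1, "CD11b": -2.1, "CD34": 1.6, "CD56": -1.6}
        for marker, slope in slopes.items():
            r = corr.loc[marker, "value"] * sgn
            assert np.sign(r) == np.sign(slope)
            assert abs(r) >= 0.9
        tk = corr.loc["KRAS_blast", "value"]
        tf = corr.loc["FLT3_blast", "value"]
        assert np.sign(tk) == -np.sign(tf)
        assert corr.loc["KRAS_blast", "p_value"] < 1e-10

    def test_perfectly_linear_profile(self):
        idx = pd.Index([f"c{i}" for i in range(30)])
        u = pd.DataFrame({"lin": np.arange(30, dtype=float)}, index=idx)
        clones = pd.Series(["a"] * 15 + ["b"] * 15, index=idx)
        prof = moving_profiles(idx, u, clones, None, window=5)
        corr = gradient_correlations(prof)
        assert corr.loc["lin", "value"] == pytest.approx(1.0)
        assert corr.loc["b", "value"] > 0  # clone b rises along the ordering

    def test_zero_variance_series_not_applicable(self):
        idx = pd.Index([f"c{i}" for i in range(10)])
        u = pd.DataFrame({"flat": np.ones(10)}, index=idx)
        clones = pd.Series(["a"] * 10, index=idx)
        prof = moving_profiles(idx, u, clones, None, window=3)
        corr = gradient_correlations(prof)
        assert np.isnan(corr.loc["flat", "value"])
        assert np.isnan(corr.loc["a", "value"])


class TestFitSpline:
    def test_interpolates_knots(self):
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(
            {"x": np.cumsum(rng.uniform(0.1, 1, 12)), "y": rng.normal(0, 1, 12)}
        )
        spline = fit_spline(pts)
        t = np.linspace(0, 1, 12)
        assert np.allclose(spline(t), pts.to_numpy(), atol=1e-10)

    def test_collinear_points_give_line(self):
        t = np.linspace(0, 1, 20)
        pts = pd.DataFrame({"x": 2 * t + 1, "y": -3 * t})
        spline = fit_spline(pts)
        fine = np.linspace(0, 1, 333)
        vals = spline(fine)
        expected = np.column_stack([2 * fine + 1, -3 * fine])
        assert np.abs(vals - expected).max() < 1e-8

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            fit_spline(pd.DataFrame({"x": [0, 1, 2], "y": [0, 1, 2]}))


def test_sign_invariance_of_whole_analysis(blast):
    """Negating u mirrors the ordering and flips correlation signs while
    preserving magnitudes."""
    ub = blast["ub"]
    truth = blast["truth"]
    for mat in (ub, -ub):
        ordering = order_by_gradient(mat)
        clones = truth.cells.loc[ordering, "population"]
        prof = moving_profiles(ordering, ub.loc[ordering], clones, None, window=150)
        corr = gradient_correlations(prof)
        if mat is ub:
            base = corr["value"].abs()
        else:
            assert np.allclose(
                corr["value"].abs().to_numpy(), base.to_numpy(), atol=0.05, equal_nan=True
            )
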
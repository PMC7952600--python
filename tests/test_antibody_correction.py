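"""SVD-regression correction of antibody counts."""

import numpy as np
import pandas as pd
import pytest

from genotag.antibody_correction import (
    build_design,
    build_quality_matrix,
    correct_counts,
    correction_diagnostics,
    transform_counts,
)


def _df(arr, cols=None):
    arr = np.asarray(arr, float)
    cols = cols or [f"ab{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


class TestTransformCounts:
    def test_log1p_values(self):
        c = _df([[0.0, np.e - 1], [0.0, 0.0]])
        out = transform_counts(c)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(1.0)

    def test_all_zero_matrix_unchanged(self):
        c = _df(np.zeros((5, 3)))
        assert (transform_counts(c).to_numpy() == 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_counts(_df([[-1.0]]))


class TestBuildDesign:
    def _q(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        depth = np.exp(rng.normal(0, 0.4, n))
        q = np.column_stack(
            [
                rng.poisson(depth * 500),
                rng.poisson(depth * 400),
                rng.poisson(depth * 20),
                rng.poisson(depth * 3000),
            ]
        )
        return pd.DataFrame(
            q, columns=["reads", "umis", "iso", "amplicon"]
        )

    @pytest.mark.parametrize("n_vectors", [1, 2, 3])
    def test_design_shape(self, n_vectors):
        d = build_design(self._q(), n_vectors)
        assert d.X.shape == (50, n_vectors + 1)
        assert np.allclose(d.X[:, 0], 1.0)

    def test_identical_rows_degenerate_to_intercept(self):
        q = pd.DataFrame(np.tile([5.0, 4.0, 1.0, 100.0], (20, 1)))
        d = build_design(q, 2)
        assert d.n_vectors == 0
        assert d.X.shape == (20, 1)

    def test_constant_column_dropped_with_warning(self):
        q = self._q()
        q["iso"] = 7
        with pytest.warns(UserWarning, match="constant"):
            d = build_design(q, 2)
        assert d.n_vectors == 2

    def test_invalid_n_vectors(self):
        with pytest.raises(ValueError):
            build_design(self._q(), 4)

    def test_rank_one_structure_fully_removed(self):
        """A rank-1 technical factor is completely captured by one singular
        vector: regression on it reconstructs the factor's effect exactly."""
        rng = np.random.default_rng(1)
        depth = rng.normal(0, 1, 200)
        q = pd.DataFrame(
            np.exp(np.outer(depth, [1.0, 1.0, 1.0, 1.0]) + [6, 5, 2, 8]) - 1
        )
        d = build_design(q, 1)
        # log-c column proportional to the same factor
        c = pd.DataFrame({"ab": np.exp(depth + 3) - 1})
        u = correct_counts(transform_counts(c), d)
        assert float(np.abs(u.to_numpy()).max()) < 1e-8


class TestCorrectCounts:
    def test_residuals_orthogonal_to_design(self, small_run):
        u = small_run["u"].to_numpy()
        X = small_run["design"].X
        rel = np.abs(X.T @ u).max() / np.linalg.norm(u)
        assert rel < 1e-8

    def test_column_means_zero(self, small_run):
        assert np.abs(small_run["u"].to_numpy().mean(axis=0)).max() < 1e-10

    def test_shape_and_order_preserved(self, small_run):
        u = small_run["u"]
        truth = small_run["truth"]
        assert u.shape == truth.counts.shape
        assert list(u.index) == list(truth.counts.index)

    def test_intercept_only_design_centers_columns(self):
        rng = np.random.default_rng(2)
        c = _df(rng.poisson(50, (30, 4)))
        log_c = transform_counts(c)
        q = pd.DataFrame(np.tile([1.0, 1.0, 1.0, 1.0], (30, 1)))
        d = build_design(q, 1)  # degenerate -> intercept only
        u = correct_counts(log_c, d)
        expected = log_c - log_c.mean()
        assert np.allclose(u.to_numpy(), expected.to_numpy())

    def test_measured_depth_covariate_removed(self, small_run):
        """The measured technical covariate (z-scored log amplicon reads, a
        column of q in the design span) is uncorrelated with every residual."""
        u = small_run["u"]
        conf = np.log1p(small_run["q"]["total_amplicon_reads"].to_numpy())
        for j in range(u.shape[1]):
            col = u.iloc[:, j].to_numpy()
            if col.std() < 1e-12:
                continue  # fully explained by the design
            assert abs(np.corrcoef(col, conf)[0, 1]) < 1e-6

    def test_latent_depth_mostly_removed(self, small_run):
        """The latent per-cell depth factor (never exactly observable) is
        suppressed to sampling-noise level."""
        u = small_run["u"]
        latent = np.log(small_run["truth"].cells.depth_factor.to_numpy())
        n = u.shape[0]
        for j in range(u.shape[1]):
            col = u.iloc[:, j].to_numpy()
            if col.std() < 1e-12:
                continue
            assert abs(np.corrcoef(col, latent)[0, 1]) < 6 / np.sqrt(n)

    def test_population_separation_preserved(self, small_run):
        """Between-population mean separation orthogonal to depth survives the
        correction to within 5% of its value in centered log counts."""
        truth = small_run["truth"]
        u = small_run["u"]
        log_c = transform_counts(truth.counts)
        centered = log_c - log_c.mean()
        pops = truth.cells.population
        a, b = "KRAS_clone", "wildtype"
        for ab in ["CD33", "CD3"]:  # markers defining the two populations
            sep_c = centered.loc[pops == a, ab].mean() - centered.loc[pops == b, ab].mean()
            sep_u = u.loc[pops == a, ab].mean() - u.loc[pops == b, ab].mean()
            assert sep_u == pytest.approx(sep_c, rel=0.05)

    def test_fewer_cells_than_design_errors(self):
        q = pd.DataFrame(np.random.default_rng(0).poisson(50, (4, 4)))
        d = build_design(q, 3)
        with pytest.raises(ValueError):
            correct_counts(_df(np.ones((2, 3))), d)


def test_quality_matrix_alignment_checked():
    a = pd.Series([1.0, 2.0], index=["x", "y"])
    b = pd.Series([1.0, 2.0], index=["x", "z"])
    with pytest.raises(ValueError, match="aligned"):
        build_quality_matrix(a, a, a, b)


def test_diagnostics_report_small_correlations(small_run):
    diag = correction_diagnostics(small_run["u"], small_run["design"])
    assert (diag.max_abs_corr < 1e-6).all()
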
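"""Gaussian-process surrogate and calibration machinery tests.

The dense in-package GP is cross-checked against scikit-learn's
GaussianProcessRegressor (an independent implementation) and against a
brute-force likelihood computed with plain inv/slogdet in the test body.
"""

import numpy as np
import pandas as pd
import pytest

from gapcal import koh
from gapcal.koh import (CovarianceSpec, DesignMatrix, covariance,
                        fit_surrogate, gp_predict, lhs_design,
                        resolution_report)
from gapcal.ringproc import FieldBASeries


def _toy_design(n=30, noise=0.0, seed=0, p_extra=1):
    """Small (year, u) design with a smooth response."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 100, n)
    u = rng.uniform(0.2, 0.8, (n, p_extra))
    y = np.sin(t / 15.0) * 10 + 20 * u[:, 0] + noise * rng.standard_normal(n)
    X = np.column_stack([t, u])
    bounds = {"year": (0.0, 100.0)}
    names = [f"u{i+1}" for i in range(p_extra)]
    for nm in names:
        bounds[nm] = (0.2, 0.8)
    return DesignMatrix(X=X, y=y, param_names=names, bounds=bounds, n_sims=n)


class TestLHSDesign:
    def test_marginal_stratification_exact(self):
        """36 points occupy all 36 equal-width strata in every margin."""
        pts = lhs_design({"a": (0.0, 1.0), "b": (10.0, 20.0)}, 36, seed=5)
        assert pts.shape == (36, 2)
        for col, (lo, hi) in [("a", (0, 1)), ("b", (10, 20))]:
            strata = np.floor((pts[col] - lo) / (hi - lo) * 36).astype(int)
            assert sorted(strata) == list(range(36))

    def test_single_point_inside_box(self):
        pts = lhs_design({"a": (2.0, 4.0)}, 1, seed=0)
        assert 2.0 <= pts["a"].iloc[0] <= 4.0

    def test_seeded_reproducibility(self):
        a = lhs_design({"a": (0.0, 1.0), "b": (0.0, 1.0)}, 12, seed=3)
        b = lhs_design({"a": (0.0, 1.0), "b": (0.0, 1.0)}, 12, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_bounds_warn_and_collapse(self):
        with pytest.warns(UserWarning, match="zero-width"):
            pts = lhs_design({"a": (5.0, 5.0), "b": (0.0, 1.0)}, 8, seed=1)
        assert (pts["a"] == 5.0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lhs_design({"a": (0.0, 1.0)}, 0)
        with pytest.raises(ValueError):
            lhs_design({}, 5)


class TestCovariance:
    spec = CovarianceSpec(kernel="sqexp", theta=np.array([1.0]), nu=0.25)

    def test_zero_distance_is_one_plus_nugget(self):
        assert covariance([1.0], [1.0], self.spec) == pytest.approx(1.25)

    def test_unit_distance_sqexp(self):
        spec = CovarianceSpec(kernel="sqexp", theta=np.array([1.0]), nu=0.0)
        assert covariance([0.0], [1.0], spec) == pytest.approx(np.exp(-1.0))

    def test_large_distance_decays_without_nugget(self):
        assert covariance([0.0], [50.0], self.spec) < 1e-12

    def test_matern_zero_distance(self):
        spec = CovarianceSpec(kernel="matern52", theta=np.array([0.5]), nu=0.1)
        assert covariance([2.0], [2.0], spec) == pytest.approx(1.1)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            covariance([0.0, 1.0], [0.0], self.spec)

    def test_per_dimension_ranges(self):
        spec = CovarianceSpec(kernel="sqexp", theta=np.array([1.0, 4.0]), nu=0.0)
        got = covariance([0.0, 0.0], [1.0, 2.0], spec)
        assert got == pytest.approx(np.exp(-(1.0 / 1.0 + 4.0 / 4.0)))


class TestGPAgainstOracles:
    @pytest.mark.parametrize("kernel", ["sqexp", "matern52"])
    def test_predictions_match_sklearn(self, kernel):
        """Fixed-hyperparameter mean/variance agree with an independent GP."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, Matern

        design = _toy_design(n=30)
        gp = koh.GPSurrogate(spec=CovarianceSpec(
            kernel=kernel, theta=np.array([0.05, 0.3]), nu=1e-6, signal_var=1.0,
        ), design=design)
        gp.Xs = gp.standardize(design.X)
        gp.y_mean = float(design.y.mean())
        gp.refit()
        Xq = _toy_design(n=15, seed=9).X
        mean, var = gp_predict(gp, Xq)

        # our theta are squared lengthscales: ell = sqrt(theta)
        ell = np.sqrt(np.array([0.05, 0.3]))
        sk_kernel = (RBF(length_scale=ell / np.sqrt(2.0)) if kernel == "sqexp"
                     else Matern(length_scale=ell, nu=2.5))
        ref = GaussianProcessRegressor(kernel=sk_kernel, alpha=1e-6,
                                       optimizer=None, normalize_y=False)
        yc = design.y - gp.y_mean
        ref.fit(gp.Xs, yc)
        m_ref, sd_ref = ref.predict(gp.standardize(Xq), return_std=True)
        np.testing.assert_allclose(mean, gp.y_mean + m_ref, atol=1e-8)
        np.testing.assert_allclose(var, sd_ref**2, atol=1e-8)

    def test_nll_matches_dense_brute_force(self):
        """Concentrated NLL equals a from-scratch inv/slogdet computation."""
        design = _toy_design(n=25)
        Xs = (design.X - design.X.min(0)) / np.ptp(design.X, axis=0)
        yc = design.y - design.y.mean()
        theta = np.array([0.1, 0.5])
        eta = 1e-3
        A = koh._corr_cross(Xs, Xs, "matern52", theta) + eta * np.eye(25)
        nll, sig2 = koh._nll_concentrated(yc, A)

        Ainv = np.linalg.inv(A)
        sig2_ref = yc @ Ainv @ yc / 25
        K = sig2_ref * A
        sign, logdet = np.linalg.slogdet(K)
        nll_ref = 0.5 * (25 * np.log(2 * np.pi) + logdet
                         + yc @ np.linalg.inv(K) @ yc)
        assert sig2 == pytest.approx(sig2_ref, rel=1e-10)
        assert nll == pytest.approx(nll_ref, rel=1e-10)

    def test_noiseless_interpolation(self):
        """With the nugget at the jitter floor the GP reproduces training data."""
        design = _toy_design(n=25)
        gp = fit_surrogate(design, CovarianceSpec(kernel="matern52"),
                           heteroskedastic=False, fixed_nugget=koh.NUGGET_FLOOR)
        mean, _ = gp_predict(gp, design.X)
        scale = np.ptp(design.y)
        assert np.max(np.abs(mean - design.y)) / scale < 1e-3
        # training-point variance collapses
        _, var = gp_predict(gp, design.X)
        assert (var < 1e-4 * gp.spec.signal_var).all()

    def test_far_field_reverts_to_prior(self):
        design = _toy_design(n=20)
        gp = fit_surrogate(design, CovarianceSpec(kernel="sqexp"),
                           heteroskedastic=False)
        far = np.array([[1e4, 50.0]])
        mean, var = gp_predict(gp, far)
        assert mean[0] == pytest.approx(gp.y_mean, rel=1e-6)
        assert var[0] == pytest.approx(gp.spec.signal_var, rel=1e-6)

    def test_unfitted_surrogate_raises(self):
        design = _toy_design(n=10)
        gp = koh.GPSurrogate(spec=CovarianceSpec(), design=design)
        with pytest.raises(RuntimeError):
            gp_predict(gp, design.X)

    def test_heteroskedastic_noise_grows_with_time(self):
        """With noise SD growing in t, late predictive SD exceeds early."""
        rng = np.random.default_rng(8)
        n = 120
        t = np.sort(rng.uniform(0, 100, n))
        u = rng.uniform(0.2, 0.8, n)
        noise_sd = 0.2 + 4.0 * t / 100.0
        y = 10 + 0.05 * t + rng.standard_normal(n) * noise_sd
        design = DesignMatrix(
            X=np.column_stack([t, u]), y=y, param_names=["u1"],
            bounds={"year": (0.0, 100.0), "u1": (0.2, 0.8)}, n_sims=n,
        )
        gp = fit_surrogate(design, CovarianceSpec(kernel="matern52"),
                           heteroskedastic=True)
        early = np.array([[5.0, 0.5]])
        late = np.array([[95.0, 0.5]])
        _, v_early = gp_predict(gp, early, include_noise=True)
        _, v_late = gp_predict(gp, late, include_noise=True)
        assert v_late[0] > v_early[0]

    def test_affine_rescaling_invariance(self):
        """Rescaling a parameter and its bounds leaves the fit unchanged."""
        design = _toy_design(n=25)
        gp1 = fit_surrogate(design, CovarianceSpec(), heteroskedastic=False)
        X2 = design.X.copy()
        X2[:, 1] = X2[:, 1] * 1000.0 - 7.0
        design2 = DesignMatrix(
            X=X2, y=design.y.copy(), param_names=["u1"],
            bounds={"year": (0.0, 100.0),
                    "u1": (0.2 * 1000 - 7, 0.8 * 1000 - 7)},
            n_sims=design.n_sims,
        )
        gp2 = fit_surrogate(design2, CovarianceSpec(), heteroskedastic=False)
        q1 = gp_predict(gp1, np.array([[50.0, 0.4]]))
        q2 = gp_predict(gp2, np.array([[50.0, 0.4 * 1000 - 7]]))
        np.testing.assert_allclose(q1[0], q2[0], rtol=1e-3)
        np.testing.assert_allclose(q1[1], q2[1], rtol=1e-2, atol=1e-10)


def _two_param_surrogate(seed=0, noise=0.0):
    """Surrogate over (year, u1, u2) with an additive smooth truth."""
    rng = np.random.default_rng(seed)
    n_sims = 30
    t_grid = np.linspace(0, 100, 12)
    u = rng.uniform(0.0, 1.0, (n_sims, 2))
    rows, ys = [], []
    for i in range(n_sims):
        f = _truth_fn(t_grid, u[i, 0], u[i, 1])
        rows.append(np.column_stack([
            t_grid, np.full(12, u[i, 0]), np.full(12, u[i, 1])]))
        ys.append(f + noise * rng.standard_normal(len(t_grid)))
    design = DesignMatrix(
        X=np.vstack(rows), y=np.concatenate(ys), param_names=["u1", "u2"],
        bounds={"year": (0.0, 100.0), "u1": (0.0, 1.0), "u2": (0.0, 1.0)},
        n_sims=n_sims,
    )
    return fit_surrogate(design, CovarianceSpec(kernel="matern52"),
                         heteroskedastic=False,
                         fixed_nugget=koh.NUGGET_FLOOR if noise == 0 else None)


def _truth_fn(t, u1, u2):
    return 50 + 30 * u1 * (t / 100.0) + 20 * u2 * np.sin(t / 20.0)


class TestCalibrate:
    def test_grid_has_400_cells_and_9pct_coverage(self):
        gp = _two_param_surrogate()
        years = np.linspace(0, 100, 12)
        fs = FieldBASeries(site_id="S", species="SP", years=years.astype(int),
                           ba=np.abs(_truth_fn(years, 0.5, 0.5)))
        result = koh.calibrate(gp, fs, grid_res=20)
        assert result.surface.n_cells == 400
        assert result.surface.nll.shape == (20, 20)
        report = resolution_report(36, 20)
        assert report["grid_cells"] == 400
        assert report["coverage_pct"] == pytest.approx(9.0)

    def test_recovers_generating_grid_point(self):
        """Noise-free field from an on-grid u is recovered exactly."""
        gp = _two_param_surrogate()
        grid = np.linspace(0, 1, 20)
        u_true = (grid[7], grid[13])
        years = np.linspace(0, 100, 12)
        fs = FieldBASeries(site_id="S", species="SP", years=years.astype(int),
                           ba=np.abs(_truth_fn(years, *u_true)))
        result = koh.calibrate(gp, fs, grid_res=20)
        assert result.u_hat["u1"] == pytest.approx(u_true[0])
        assert result.u_hat["u2"] == pytest.approx(u_true[1])

    def test_constant_shift_absorbed_by_bias(self):
        """Shifting the field by +c moves b-hat by ~c and leaves u-hat."""
        gp = _two_param_surrogate()
        grid = np.linspace(0, 1, 20)
        years = np.linspace(0, 100, 12)
        base = np.abs(_truth_fn(years, grid[7], grid[13]))
        fs0 = FieldBASeries("S", "SP", years.astype(int), base)
        fs1 = FieldBASeries("S", "SP", years.astype(int), base + 25.0)
        r0 = koh.calibrate(gp, fs0, grid_res=20)
        r1 = koh.calibrate(gp, fs1, grid_res=20)
        assert r1.u_hat == r0.u_hat
        shift = r1.bias["SP"].b_hat - r0.bias["SP"].b_hat
        assert shift.mean() == pytest.approx(25.0, abs=2.5)

    def test_extrapolation_flagged(self):
        gp = _two_param_surrogate()
        years = np.linspace(0, 100, 12)
        fs = FieldBASeries("S", "SP", years.astype(int),
                           np.abs(_truth_fn(years, 0.5, 0.5)))
        with pytest.warns(UserWarning, match="extrapolation"):
            result = koh.calibrate(gp, fs, grid_res=10,
                                   grid_bounds={"u1": (0.0, 1.5), "u2": (0.0, 1.0)})
        assert result.extrapolated_cells > 0


class TestBiasCorrectedPrediction:
    def test_zero_bias_reduces_to_surrogate(self):
        gp = _two_param_surrogate()
        years = np.arange(0, 101, 10)
        bm = koh.BiasModel(years=years, b_hat=np.zeros(len(years)),
                           b_var=np.zeros(len(years)), sigma_eps2=0.0,
                           theta=0.04, signal_var=1.0, nll=0.0)
        result = koh.CalibrationResult(
            surface=None, u_hat={"u1": 0.5, "u2": 0.5},
            bias={"SP": bm}, corrected={}, bias_square_error={},
        )
        out = koh.bias_corrected_prediction(gp, result, species="SP")
        X = np.column_stack([years.astype(float),
                             np.full(len(years), 0.5), np.full(len(years), 0.5)])
        mean, var = gp_predict(gp, X)
        np.testing.assert_allclose(out["mean"], mean)
        np.testing.assert_allclose(out["hi95"] - out["mean"], 1.96 * np.sqrt(var))

    def test_interval_orders_around_mean(self):
        gp = _two_param_surrogate()
        years = np.linspace(0, 100, 12)
        fs = FieldBASeries("S", "SP", years.astype(int),
                           np.abs(_truth_fn(years, 0.3, 0.7)) + 5.0)
        result = koh.calibrate(gp, fs, grid_res=8)
        out = result.corrected["SP"]
        assert (out["lo95"] <= out["mean"]).all()
        assert (out["mean"] <= out["hi95"]).all()
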
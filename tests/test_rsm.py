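import numpy as np
import pytest

from cocoflux.doe import FLUX, FOULING_INDEX, PRESSURE, TEMPERATURE, build_fcd
from cocoflux.rsm import (
    SingularFitError,
    anova,
    fit_quadratic,
    optimize_surface,
    prune_by_significance,
)
from cocoflux.synth import FCDGenSpec, gen_fcd_dataset

# Published reduced-model predictions (condition coded point -> value).
FLUX_PREDICTIONS = {
    (1.0, -1.0): 309.02,
    (-1.0, 1.0): 468.75,
    (1.0, 1.0): 507.45,
    (-1.0, 0.0): 550.10,
    (1.0, 0.0): 550.10,
    (0.0, -1.0): 438.86,
    (0.0, 1.0): 598.59,
    (0.0, 0.0): 660.59,
}
FI_PREDICTIONS = {
    (-1.0, -1.0): 83.97,
    (1.0, -1.0): 94.09,
    (-1.0, 1.0): 82.46,
    (1.0, 1.0): 95.59,
    (-1.0, 0.0): 79.50,
    (1.0, 0.0): 91.12,
    (0.0, -1.0): 89.03,
    (0.0, 1.0): 89.03,
    (0.0, 0.0): 85.31,
}


class TestFit:
    def test_pressure_linear_orthogonal_to_intercept(self, pilot):
        """The balanced design makes the pressure linear column orthogonal
        to the rest, so dropping it leaves the shared coefficients
        unchanged while its own full-model p-value justifies the drop."""
        full = fit_quadratic(pilot, FLUX)
        reduced = prune_by_significance(pilot, FLUX)
        assert full.term_pvalues["x1"] >= 0.05
        shared = [0, 2, 3, 4, 5]  # all terms except x1
        assert np.allclose(full.coefficients[shared], reduced.coefficients[shared],
                           atol=1e-8)

    def test_replicate_weighting_equals_sample_fit(self, pilot):
        """Fitting on 29 samples equals a weighted fit on the 9 unique
        conditions with replicate-count weights."""
        full = fit_quadratic(pilot, FLUX)
        pts = np.array([c.coded for c in pilot.conditions])
        w = np.array([c.n_replicates for c in pilot.conditions], dtype=float)
        ybar = np.array([c.mean(FLUX) for c in pilot.conditions])
        from cocoflux.rsm import _columns

        A = _columns(pts)
        W = np.diag(w)
        beta_w = np.linalg.solve(A.T @ W @ A, A.T @ W @ ybar)
        assert np.allclose(beta_w, full.coefficients, atol=1e-8)

    def test_zero_noise_recovery(self):
        beta = {"flux": (500.0, -20.0, 60.0, -80.0, -120.0, 15.0)}
        ds = gen_fcd_dataset(FCDGenSpec(beta=beta, noise_sd={"flux": 0.0}, seed=1))
        fit = fit_quadratic(ds, "flux")
        assert np.allclose(fit.coefficients, beta["flux"], atol=1e-9)

    def test_rank_deficiency_raises(self):
        ds = build_fcd((PRESSURE, TEMPERATURE), response_names=["y"])
        # populate only 3 conditions: cannot identify 6 terms
        for c in ds.conditions[:3]:
            c.replicate_responses["y"] = [1.0]
        ds.conditions = ds.conditions[:3]
        with pytest.raises(SingularFitError):
            fit_quadratic(ds, "y")


class TestPruning:
    def test_flux_drops_pressure_linear_only(self, pilot):
        surface = prune_by_significance(pilot, FLUX)
        assert set(surface.included_terms) == {"1", "x2", "x1^2", "x2^2", "x1:x2"}

    def test_fouling_drops_temp_linear_and_pressure_quadratic(self, pilot):
        surface = prune_by_significance(pilot, FOULING_INDEX)
        assert set(surface.included_terms) == {"1", "x1", "x2^2", "x1:x2"}
        assert surface.coefficients[0] == pytest.approx(85.31, abs=0.01)

    def test_true_zero_coefficient_dropped_under_tiny_noise(self):
        """A term whose true coefficient is zero is pruned in almost all
        noise realizations."""
        beta = {"y": (500.0, 0.0, 60.0, -80.0, -120.0, 15.0)}
        dropped = 0
        n_runs = 200
        for seed in range(n_runs):
            ds = gen_fcd_dataset(FCDGenSpec(beta=beta, noise_sd={"y": 1.0}, seed=seed))
            surface = prune_by_significance(ds, "y")
            dropped += "x1" not in surface.included_terms
        # nominal retention of a true-zero term is alpha = 5%; allow
        # binomial fluctuation around the 95% drop rate
        assert dropped >= 0.88 * n_runs

    def test_pure_noise_warns_intercept_only(self):
        beta = {"y": (100.0, 0.0, 0.0, 0.0, 0.0, 0.0)}
        ds = gen_fcd_dataset(FCDGenSpec(beta=beta, noise_sd={"y": 50.0}, seed=2))
        with pytest.warns(UserWarning, match="intercept-only"):
            surface = prune_by_significance(ds, "y")
        assert surface.included_terms == ("1",)


class TestPrediction:
    @pytest.mark.parametrize("coded,expected", sorted(FLUX_PREDICTIONS.items()))
    def test_flux_predictions_match_published(self, pilot, coded, expected):
        surface = prune_by_significance(pilot, FLUX)
        value, _ = surface.predict(coded)
        assert value == pytest.approx(expected, abs=0.01)

    def test_flux_corner_known_discrepancy(self, pilot):
        """At (-1,-1) the published table prints 347.53 but the model
        implied by every other row gives 347.73; the recomputed value is
        asserted."""
        surface = prune_by_significance(pilot, FLUX)
        value, _ = surface.predict((-1.0, -1.0))
        assert value == pytest.approx(347.73, abs=0.01)

    @pytest.mark.parametrize("coded,expected", sorted(FI_PREDICTIONS.items()))
    def test_fouling_predictions_match_published(self, pilot, coded, expected):
        surface = prune_by_significance(pilot, FOULING_INDEX)
        value, _ = surface.predict(coded)
        assert value == pytest.approx(expected, abs=0.01)

    def test_validation_setpoint(self, pilot):
        flux_s = prune_by_significance(pilot, FLUX)
        fi_s = prune_by_significance(pilot, FOULING_INDEX)
        assert flux_s.predict_actual(75.0, 30.0)[0] == pytest.approx(611.48, abs=0.01)
        assert fi_s.predict_actual(75.0, 30.0)[0] == pytest.approx(81.43, abs=0.01)

    def test_saturated_model_interpolates_unreplicated_data(self):
        beta = {"y": (10.0, 1.0, -2.0, 3.0, -4.0, 5.0)}
        ds = gen_fcd_dataset(
            FCDGenSpec(beta=beta, noise_sd={"y": 2.0}, replicates=(1, 1), seed=3)
        )
        # 9 conditions, 9 samples: saturated 6-term fit will not interpolate,
        # but the zero-noise case must
        ds0 = gen_fcd_dataset(
            FCDGenSpec(beta=beta, noise_sd={"y": 0.0}, replicates=(1, 1), seed=3)
        )
        surface = fit_quadratic(ds0, "y")
        for c in ds0.conditions:
            assert surface.predict(c.coded)[0] == pytest.approx(
                c.replicate_responses["y"][0], abs=1e-9
            )

    def test_extrapolation_warns(self, pilot):
        surface = prune_by_significance(pilot, FLUX)
        with pytest.warns(UserWarning, match="extrapolates"):
            surface.predict((1.5, 0.0))

    def test_json_round_trip(self, pilot, tmp_path):
        surface = prune_by_significance(pilot, FLUX)
        p = tmp_path / "model.json"
        surface.save_json(p)
        back = type(surface).load_json(p)
        assert np.allclose(back.coefficients, surface.coefficients)
        assert back.predict((0.3, -0.4)) == surface.predict((0.3, -0.4))


class TestOptimize:
    def test_flux_interior_maximum(self, pilot):
        surface = prune_by_significance(pilot, FLUX)
        opt = optimize_surface(surface, "max")
        assert opt.coded[0] == pytest.approx(0.0248, abs=1e-3)
        assert opt.coded[1] == pytest.approx(0.2832, abs=1e-3)
        assert opt.value == pytest.approx(671.9, abs=0.1)
        assert not opt.on_boundary

    def test_fouling_minimum_on_low_pressure_edge(self, pilot):
        surface = prune_by_significance(pilot, FOULING_INDEX)
        opt = optimize_surface(surface, "min")
        assert opt.coded[0] == pytest.approx(-1.0)
        assert opt.on_boundary

    def test_known_vertex_recovered(self, pilot):
        from cocoflux.rsm import QuadraticSurface, TERMS

        coef = np.array([10.0, 0.4, -0.6, -1.0, -1.0, 0.0])  # vertex (0.2, -0.3)
        surface = QuadraticSurface(
            response_name="y", coefficients=coef,
            included=np.ones(6, dtype=bool), covariance=np.zeros((6, 6)),
            residual_variance=0.0, n_samples=9,
        )
        opt = optimize_surface(surface, "max")
        assert opt.coded == pytest.approx((0.2, -0.3), abs=1e-9)

    def test_flat_surface_flagged(self):
        from cocoflux.rsm import QuadraticSurface

        surface = QuadraticSurface(
            response_name="y", coefficients=np.array([5.0, 0, 0, 0, 0, 0.0]),
            included=np.ones(6, dtype=bool), covariance=np.zeros((6, 6)),
            residual_variance=0.0, n_samples=9,
        )
        opt = optimize_surface(surface, "max")
        assert opt.flat
        assert opt.value == 5.0


class TestAnova:
    def test_pilot_flux_adequate(self, pilot):
        surface = prune_by_significance(pilot, FLUX)
        rep = anova(pilot, surface)
        assert rep.r_squared > 0.90
        assert rep.f_cal > rep.f_tab
        assert rep.ss_total == pytest.approx(rep.ss_regression + rep.ss_residual)
        assert rep.ss_residual == pytest.approx(
            rep.ss_lack_of_fit + rep.ss_pure_error
        )

    def test_perfect_fit(self):
        beta = {"y": (500.0, -20.0, 60.0, -80.0, -120.0, 15.0)}
        ds = gen_fcd_dataset(FCDGenSpec(beta=beta, noise_sd={"y": 0.0}, seed=1))
        surface = fit_quadratic(ds, "y")
        rep = anova(ds, surface)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.ss_residual == pytest.approx(0.0, abs=1e-12)

    def test_pure_noise_not_significant(self):
        beta = {"y": (100.0, 0.0, 0.0, 0.0, 0.0, 0.0)}
        ds = gen_fcd_dataset(FCDGenSpec(beta=beta, noise_sd={"y": 30.0}, seed=5))
        surface = fit_quadratic(ds, "y")
        rep = anova(ds, surface)
        assert all(v["p"] > 0.05 for t, v in rep.terms.items() if t != "1")
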
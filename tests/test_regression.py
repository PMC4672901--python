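import math
import warnings

import numpy as np
import pytest
from scipy import linalg

from conftest import oracle_mvn_loglik
from mbmeta.regression import (
    DesignError,
    DriverEffect,
    GLMMSpec,
    _scaled_cov,
    build_frame,
    cellcount_regression,
    fit_glmm,
    generalized_r2,
    glmm_loglik,
    per_cell_model,
    residual_driver_effects,
)
from mbmeta.simulate import ModelFrame, simulate_frame


def random_frame(rng, n_max=30):
    n_studies = int(rng.integers(2, 5))
    per = int(rng.integers(2, max(3, n_max // n_studies)))
    frame, _ = simulate_frame(
        n_studies=n_studies,
        per_study=per,
        tau2=float(rng.uniform(0, 4)),
        rho=float(rng.uniform(0, 0.6)),
        sigma2=float(rng.uniform(0.5, 2)),
        seed=int(rng.integers(0, 2**31)),
    )
    return frame


class TestLoglik:
    def test_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            frame = random_frame(rng)
            params = {
                "beta": rng.normal(size=2),
                "tau2": float(rng.uniform(0, 5)),
                "rho": float(rng.uniform(0, 0.8)),
                "sigma2": float(rng.uniform(0.3, 3)),
            }
            ll = glmm_loglik(params, frame)
            v = params["sigma2"] * _scaled_cov(
                frame, params["tau2"] / params["sigma2"], params["rho"]
            )
            ref = oracle_mvn_loglik(frame.y, frame.X @ params["beta"], v)
            assert ll == pytest.approx(ref, abs=1e-8)

    def test_ols_degenerate_limit(self):
        rng = np.random.default_rng(2)
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        frame = ModelFrame(
            y=y, X=X, columns=["Intercept", "x"], weights=np.ones(n),
            clusters=np.full(n, -1), blocks=np.full(n, -1),
        )
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        s2 = float(r @ r) / n
        ols_ll = -0.5 * n * (math.log(2 * math.pi * s2) + float(r @ r) / (n * s2))
        ll = glmm_loglik({"beta": beta, "tau2": 0.0, "rho": 0.0, "sigma2": s2}, frame)
        assert ll == pytest.approx(ols_ll, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        frame = random_frame(rng)
        params = {"beta": [0.5, 1.0], "tau2": 2.0, "rho": 0.3, "sigma2": 1.0}
        ll = glmm_loglik(params, frame)
        perm = rng.permutation(frame.n)
        shuffled = ModelFrame(
            y=frame.y[perm], X=frame.X[perm], columns=frame.columns,
            weights=frame.weights[perm], clusters=frame.clusters[perm],
            blocks=frame.blocks[perm],
        )
        assert glmm_loglik(params, shuffled) == pytest.approx(ll, abs=1e-9)

    def test_bad_params_rejected(self):
        rng = np.random.default_rng(6)
        frame = random_frame(rng)
        with pytest.raises(ValueError):
            glmm_loglik({"beta": [0, 0], "tau2": -1, "rho": 0, "sigma2": 1}, frame)
        with pytest.raises(ValueError):
            glmm_loglik({"beta": [0, 0], "tau2": 0, "rho": 1.5, "sigma2": 1}, frame)


class TestFit:
    def test_reduces_to_wls_when_variances_fixed_off(self):
        # no cluster, diagonal structure -> exact weighted least squares
        rng = np.random.default_rng(8)
        n = 25
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        w = rng.uniform(0.5, 3.0, size=n)
        y = X @ [1.0, 2.0] + rng.normal(size=n) / np.sqrt(w)
        frame = ModelFrame(
            y=y, X=X, columns=["Intercept", "x"], weights=w,
            clusters=np.full(n, -1), blocks=np.full(n, -1),
        )
        spec = GLMMSpec(covariates=(), cluster=False, residual_structure="diagonal")
        fit = fit_glmm(spec, frame)
        wls = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert fit.beta == pytest.approx(wls, abs=1e-10)
        assert fit.tau2 == 0.0 and fit.rho == 0.0

    def test_simulated_null_variances_close_to_wls(self):
        # with true tau2 = rho = 0 the estimated components shrink towards 0
        # and beta-hat approaches plain WLS (statistical tolerance only; the
        # exact reduction is covered by the fixed-parameter test above)
        frame, _ = simulate_frame(n_studies=30, per_study=6, tau2=0.0, rho=0.0,
                                  sigma2=1.0, seed=33)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = GLMMSpec(covariates=(), cluster=True,
                            residual_structure="block_compound_symmetry")
            fit = fit_glmm(spec, frame, seed=2)
        X, w, y = frame.X, frame.weights, frame.y
        wls = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert fit.tau2 < 0.5 and fit.rho < 0.5
        assert fit.beta == pytest.approx(wls, abs=0.1)
        assert fit.converged

    def test_loglik_not_below_initial_point(self):
        rng = np.random.default_rng(10)
        frame = random_frame(rng)
        spec = GLMMSpec(covariates=(), residual_structure="block_compound_symmetry")
        fit = fit_glmm(spec, frame, seed=3)
        init = glmm_loglik(
            {"beta": fit.beta, "tau2": fit.sigma2, "rho": 0.0, "sigma2": fit.sigma2},
            frame,
        )
        assert fit.loglik >= init - 1e-8

    def test_fit_loglik_consistent_with_loglik_fn(self):
        rng = np.random.default_rng(13)
        frame = random_frame(rng)
        spec = GLMMSpec(covariates=(), residual_structure="block_compound_symmetry")
        fit = fit_glmm(spec, frame, seed=1)
        ll = glmm_loglik(
            {"beta": fit.beta, "tau2": fit.tau2, "rho": fit.rho, "sigma2": fit.sigma2},
            frame,
        )
        assert ll == pytest.approx(fit.loglik, abs=1e-8)

    def test_half_weight_duplication_equivalence(self):
        # duplicating every record at half weight leaves beta-hat unchanged
        rng = np.random.default_rng(11)
        n = 15
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        w = rng.uniform(0.5, 2.0, size=n)
        y = X @ [0.5, -1.0] + rng.normal(size=n)
        spec = GLMMSpec(covariates=(), cluster=False, residual_structure="diagonal")
        single = ModelFrame(y=y, X=X, columns=["Intercept", "x"], weights=w,
                            clusters=np.full(n, -1), blocks=np.full(n, -1))
        doubled = ModelFrame(
            y=np.concatenate([y, y]), X=np.vstack([X, X]),
            columns=["Intercept", "x"], weights=np.concatenate([w / 2, w / 2]),
            clusters=np.full(2 * n, -1), blocks=np.full(2 * n, -1),
        )
        assert fit_glmm(spec, doubled).beta == pytest.approx(
            fit_glmm(spec, single).beta, abs=1e-10
        )

    def test_rank_deficient_design_rejected(self, sim_ds):
        _, ds, _ = sim_ds
        spec = GLMMSpec(covariates=("TIME", "TIME"))
        with pytest.raises(DesignError):
            build_frame(spec, ds)

    def test_bcs_without_blocks_rejected(self, fixture_ds):
        spec = GLMMSpec(residual_structure="block_compound_symmetry")
        with pytest.raises((DesignError, ValueError)):
            build_frame(spec, fixture_ds)  # fixture has no PI values at all


class TestGeneralizedR2:
    def test_full_equals_null_gives_zero(self):
        rng = np.random.default_rng(14)
        frame = random_frame(rng)
        spec = GLMMSpec(covariates=(), residual_structure="diagonal")
        fit = fit_glmm(spec, frame, seed=1)
        assert generalized_r2(fit, fit) == 0.0

    def test_saturation_bound(self, sim_ds):
        cfg, ds, _ = sim_ds
        ds = ds.filter(lambda r: r.driver is not None)
        spec_full = GLMMSpec(covariates=("TIME", "BENZALDEHYDE", "CELL_COUNT"))
        spec_null = GLMMSpec(covariates=())
        full = fit_glmm(spec_full, ds, cell_counts=cfg.cell_counts, seed=1)
        null = fit_glmm(spec_null, ds, seed=1)
        r2 = generalized_r2(full, null)
        assert 0.0 <= r2 <= 1.0
        assert full.loglik >= null.loglik  # nested ML fits

    def test_strong_covariate_matches_formula_oracle(self, sim_ds):
        cfg, ds, _ = sim_ds
        ds = ds.filter(lambda r: r.intervention == "rut_rescue")
        spec_full = GLMMSpec(covariates=("CELL_COUNT",))
        spec_null = GLMMSpec(covariates=())
        full = fit_glmm(spec_full, ds, cell_counts=cfg.cell_counts, seed=1)
        null = fit_glmm(spec_null, ds, seed=1)
        r2 = generalized_r2(full, null)
        expected = 1.0 - math.exp(-2.0 * (full.loglik - null.loglik) / full.n)
        assert r2 == pytest.approx(expected, abs=1e-12)
        assert r2 > 0.3  # cell count is the dominant simulated effect

    def test_bootstrap_ci_brackets_point(self, sim_ds):
        from mbmeta.regression import bootstrap_generalized_r2

        cfg, ds, _ = sim_ds
        rut = ds.filter(lambda r: r.intervention == "rut_rescue")
        out = bootstrap_generalized_r2(
            GLMMSpec(covariates=("CELL_COUNT",)),
            GLMMSpec(covariates=()),
            rut, cell_counts=cfg.cell_counts, n_boot=40, seed=3,
        )
        assert 0.0 <= out["ci_low"] <= out["ci_high"] <= 1.0
        assert out["n_boot"] > 0
        again = bootstrap_generalized_r2(
            GLMMSpec(covariates=("CELL_COUNT",)),
            GLMMSpec(covariates=()),
            rut, cell_counts=cfg.cell_counts, n_boot=40, seed=3,
        )
        assert out == again  # seeded determinism

    def test_different_n_rejected(self):
        rng = np.random.default_rng(15)
        a = fit_glmm(GLMMSpec(covariates=(), residual_structure="diagonal"),
                     random_frame(rng), seed=1)
        frame2, _ = simulate_frame(n_studies=3, per_study=7, seed=99)
        b = fit_glmm(GLMMSpec(covariates=(), residual_structure="diagonal"),
                     frame2, seed=1)
        if a.n != b.n:
            with pytest.raises(ValueError):
                generalized_r2(a, b)


class TestDriverEffects:
    def test_counts_and_reference_shift(self, sim_ds):
        cfg, ds, _ = sim_ds
        spec = GLMMSpec(covariates=("TIME", "BENZALDEHYDE"),
                        residual_structure="block_compound_symmetry")
        fit = fit_glmm(spec, ds, seed=1)
        effects = residual_driver_effects(fit, cfg.mutant_learning,
                                          cell_counts=cfg.cell_counts)
        per_driver = {e.driver: e for e in effects}
        counts = {}
        for r in fit.frame.records:
            counts[r.driver] = counts.get(r.driver, 0) + 1
        for driver, e in per_driver.items():
            assert e.n_experiments == counts[driver]
            assert e.cell_count == cfg.cell_counts[driver]
        lowered = residual_driver_effects(fit, cfg.mutant_learning + 10.0,
                                          cell_counts=cfg.cell_counts)
        for a, b in zip(effects, lowered):
            assert b.effect == pytest.approx(a.effect - 10.0)

    def test_cross_module_consistency_with_heat_scale(self):
        # zero-noise toy input: residual effect with reference 83 must equal
        # the effect-size module's heat adjustment of the same learning level
        from mbmeta.effects import EffectSize, heat_adjusted
        from mbmeta.simulate import SimConfig, simulate_dataset

        cfg = SimConfig(seed=5, n_studies=2, experiments_per_study=(4, 4),
                        tau=0.0, rho=0.0, sigma_effect=0.0, sigma_iter=0.0,
                        control_pi_sd=0.0, slope_per_cell=0.02,
                        include_mutants=False, include_shi=False)
        ds, truth = simulate_dataset(cfg)
        spec = GLMMSpec(covariates=(), cluster=False, residual_structure="diagonal")
        # zero SEM records are unusable for weighting; give them tiny SEs
        import dataclasses

        from mbmeta.corpus import Dataset
        records = [
            dataclasses.replace(r, pi_exp_sem=1e-6, pi_ctrl_sem=1e-6)
            for r in ds.records
        ]
        fit = fit_glmm(spec, Dataset(records), seed=1)
        effects = residual_driver_effects(fit, 83.0, cell_counts=cfg.cell_counts,
                                          mode="fitted_plus_residual")
        for e in effects:
            truth_pct = cfg.mutant_learning + cfg.slope_per_cell * e.cell_count - 100.0
            learning = EffectSize(truth_pct, 0.0, "percent_change")
            expected = heat_adjusted(
                __import__("mbmeta.effects", fromlist=["to_learning_scale"])
                .to_learning_scale(learning),
                83.0,
            ).estimate
            assert e.effect == pytest.approx(expected, abs=0.5)

    def test_unconverged_fit_rejected(self, sim_ds):
        cfg, ds, _ = sim_ds
        spec = GLMMSpec(covariates=())
        fit = fit_glmm(spec, ds, seed=1)
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            residual_driver_effects(fit, 40.0)


class TestCellCountRegression:
    def drivers_on_line(self, slope, n=6, intercept=0.0):
        return [
            DriverEffect(driver=f"d{i}", effect=intercept + slope * c, se=1.0,
                         n_experiments=3, lobe_category="gamma", cell_count=c)
            for i, c in enumerate(np.linspace(100, 2000, n).astype(int))
        ]

    def test_exact_line_recovered(self):
        out = cellcount_regression(self.drivers_on_line(0.03))
        assert out["slope"] == pytest.approx(0.03, abs=1e-12)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert out["r2_generalized"] == pytest.approx(1.0, abs=1e-6)

    def test_weight_scale_invariance(self):
        effects = self.drivers_on_line(0.02)
        noisy = [
            DriverEffect(e.driver, e.effect + dy, e.se, e.n_experiments,
                         e.lobe_category, e.cell_count)
            for e, dy in zip(effects, [1, -2, 0.5, 1.5, -1, 0.3])
        ]
        doubled = [
            DriverEffect(e.driver, e.effect, e.se, 2 * e.n_experiments,
                         e.lobe_category, e.cell_count)
            for e in noisy
        ]
        a = cellcount_regression(noisy)
        b = cellcount_regression(doubled)
        assert a["slope"] == pytest.approx(b["slope"], rel=1e-12)
        assert a["r2_generalized"] == pytest.approx(b["r2_generalized"], rel=1e-9)

    def test_too_few_drivers_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            cellcount_regression(self.drivers_on_line(0.02, n=2))

    def test_equal_counts_rejected(self):
        effects = [
            DriverEffect(f"d{i}", float(i), 1.0, 2, "gamma", 500)
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="cell counts equal"):
            cellcount_regression(effects)


class TestPerCellModel:
    def test_single_category_identical_effects(self):
        effects = [
            DriverEffect(f"d{i}", 0.02 * c, 0.001 * c, 3, "gamma", c)
            for i, c in enumerate([200, 500, 900])
        ]
        out = per_cell_model(effects)
        cat = out["categories"]["gamma"]
        assert cat["estimate"] == pytest.approx(0.02)
        tight = [
            DriverEffect(f"d{i}", 0.02 * c, 1e-8 * c, 3, "gamma", c)
            for i, c in enumerate([200, 500, 900])
        ]
        width = per_cell_model(tight)["categories"]["gamma"]
        assert width["ci_high"] - width["ci_low"] < 1e-7

    def test_one_driver_per_category_passthrough(self):
        effects = [
            DriverEffect("a", 10.0, 1.0, 2, "gamma", 500),
            DriverEffect("b", 30.0, 1.0, 2, "alphabeta", 1000),
        ]
        out = per_cell_model(effects)
        assert out["categories"]["gamma"]["estimate"] == pytest.approx(0.02)
        assert out["categories"]["alphabeta"]["estimate"] == pytest.approx(0.03)

    def test_null_simulation_differences_cover_zero(self):
        # equal per-cell potency in every category: difference CIs cover 0
        rng = np.random.default_rng(17)
        covered = 0
        reps = 50
        for _ in range(reps):
            effects = []
            for i, (cat, c) in enumerate(
                [("gamma", 300), ("gamma", 600), ("alphabeta", 900),
                 ("alphabeta", 1200), ("alphabeta_gamma", 1500),
                 ("alphabeta_gamma", 1800)]
            ):
                true = 0.02 * c
                se = 0.1 * c / 300
                effects.append(
                    DriverEffect(f"d{i}", true + rng.normal(0, se), se, 3, cat, c)
                )
            out = per_cell_model(effects)
            ok = all(
                d["ci_low"] <= 0.0 <= d["ci_high"]
                for d in out["differences"].values()
            )
            covered += ok
        assert covered / reps >= 0.8

    def test_zero_cell_count_excluded_with_warning(self):
        effects = [
            DriverEffect("a", 10.0, 1.0, 2, "gamma", 500),
            DriverEffect("b", 30.0, 1.0, 2, "gamma", 0),
        ]
        with pytest.warns(UserWarning, match="no cell count"):
            out = per_cell_model(effects)
        assert out["categories"]["gamma"]["k"] == 1
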
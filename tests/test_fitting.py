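"""Generalized non-linear least squares: covariance blocks, likelihood,
optimization, starting values and asymptotic inference."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm

import seedlingfit as sf
from seedlingfit.fitting import build_plant_covariance

from conftest import make_dataset


class TestCovarianceBlock:
    def test_ar1_correlation_rows(self):
        V = build_plant_covariance(
            sf.CovarianceSpec("ar1", "constant"), [2.0, 4.0, 6.0],
            sigma=1.0, rho=0.5)
        np.testing.assert_allclose(V, [[1, .5, .25], [.5, 1, .5],
                                       [.25, .5, 1]])

    def test_zero_delta_is_homoscedastic(self):
        V = build_plant_covariance(
            sf.CovarianceSpec("ar1", "exponential"), [2.0, 4.0, 6.0],
            sigma=2.0, rho=0.3, delta=0.0)
        V0 = build_plant_covariance(
            sf.CovarianceSpec("ar1", "constant"), [2.0, 4.0, 6.0],
            sigma=2.0, rho=0.3)
        np.testing.assert_allclose(V, V0)

    def test_rho_bound(self):
        with pytest.raises(ValueError, match="rho"):
            build_plant_covariance(sf.CovarianceSpec("ar1", "constant"),
                                   [1.0, 2.0], rho=1.0)

    def test_per_stratum_ratios(self):
        V = build_plant_covariance(
            sf.CovarianceSpec("independent", "per_stratum"), [2.0, 4.0],
            sigma=2.0, ratios={2.0: 1.0, 4.0: 0.5})
        np.testing.assert_allclose(np.diag(V), [4.0, 1.0])
        assert V[0, 1] == 0.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_positive_definite(self, seed):
        rng = np.random.default_rng(seed)
        days = np.sort(rng.choice(np.arange(1.0, 15.0), size=5,
                                  replace=False))
        V = build_plant_covariance(
            sf.CovarianceSpec("ar1", "exponential"), days,
            sigma=rng.uniform(0.1, 10), rho=rng.uniform(-0.95, 0.95),
            delta=rng.uniform(-0.3, 0.3))
        np.linalg.cholesky(V)  # raises if not PD


class TestLikelihood:
    def _spec(self, maphe, cov=None):
        return sf.ModelSpec("TRL", "expolinear", maphe,
                            cov or sf.CovarianceSpec("ar1", "exponential"))

    def test_zero_residual_closed_form(self, maphe):
        """With zero residuals, independence and constant variance the
        NLL reduces to (n/2) ln(2 pi sigma^2)."""
        p = sf.ExpolinearParams(10.0, 0.5, 5.0)
        rows = []
        for i in range(3):
            for d in (2.0, 4.0, 6.0):
                rows.append((f"p{i}", "G19833", d, "TRL",
                             float(sf.expolinear_value(p, d))))
        ds = make_dataset(rows)
        uni = sf.make_scheme("UNI", sf.default_lines())
        spec = sf.ModelSpec("TRL", "expolinear", uni,
                            sf.CovarianceSpec("independent", "constant"))
        sigma = 1.7
        nll = sf.negative_log_likelihood(
            spec, {"levels": {"all": p}, "sigma": sigma}, ds)
        assert nll == pytest.approx(
            9 / 2 * math.log(2 * math.pi * sigma ** 2), rel=1e-12)

    def test_independence_limit_sums_univariate_densities(self, maphe,
                                                          tiny_dataset):
        spec = self._spec(maphe, sf.CovarianceSpec("ar1", "constant"))
        levels = {"large": sf.ExpolinearParams(30.0, 0.8, 5.0),
                  "small": sf.ExpolinearParams(20.0, 0.6, 5.0)}
        sigma = 2.5
        nll = sf.negative_log_likelihood(
            spec, {"levels": levels, "sigma": sigma, "rho": 0.0},
            tiny_dataset)
        expected = 0.0
        for _, r in tiny_dataset.records.iterrows():
            lev = maphe.level_of[r.line_id]
            mu = float(sf.expolinear_value(levels[lev], r.day))
            expected -= norm.logpdf(r.value, mu, sigma)
        assert nll == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_mvn_oracle(self, maphe, tiny_dataset):
        """Block likelihood equals a single dense multivariate-normal
        density over the stacked observation vector."""
        spec = self._spec(maphe)
        levels = {"large": sf.ExpolinearParams(30.0, 0.8, 5.0),
                  "small": sf.ExpolinearParams(20.0, 0.6, 5.0)}
        params = {"levels": levels, "sigma": 2.3, "rho": 0.4, "delta": 0.1}
        nll = sf.negative_log_likelihood(spec, params, tiny_dataset)

        sub = tiny_dataset.records.sort_values(
            ["plant_id", "day"]).reset_index(drop=True)
        n = len(sub)
        block = build_plant_covariance(
            spec.covariance, [2.0, 4.0, 6.0, 8.0], sigma=2.3, rho=0.4,
            delta=0.1)
        Sigma = np.zeros((n, n))
        for b in range(n // 4):
            Sigma[b * 4:(b + 1) * 4, b * 4:(b + 1) * 4] = block
        mu = np.array([
            float(sf.expolinear_value(levels[maphe.level_of[r.line_id]],
                                      r.day))
            for _, r in sub.iterrows()])
        oracle = -multivariate_normal.logpdf(sub["value"].to_numpy(), mu,
                                             Sigma)
        assert nll == pytest.approx(oracle, abs=1e-8)

    def test_missing_level_rejected(self, maphe, tiny_dataset):
        spec = self._spec(maphe)
        with pytest.raises(ValueError, match="missing"):
            sf.negative_log_likelihood(
                spec, {"levels": {"large": sf.ExpolinearParams(1, 1, 0)},
                       "sigma": 1.0, "rho": 0.0, "delta": 0.0},
                tiny_dataset)


class TestFitGnls:
    def test_noise_free_recovery(self, maphe):
        cfg = sf.default_config("TRL", plants_per_line=5, seed=1,
                                sigma=1e-6)
        ds = sf.simulate_trajectories(cfg)
        spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
        fit = sf.fit_gnls(spec, ds)
        assert fit.converged
        for level, truth in cfg.truth.items():
            est = fit.estimates[level].to_array()
            np.testing.assert_allclose(est, truth.to_array(), rtol=1e-3)

    def test_single_day_rejected(self, maphe):
        rows = [(f"p{i}", l, 6.0, "TRL", float(i + 1))
                for i, l in enumerate(["G19833", "G23419"])]
        ds = make_dataset(rows)
        spec = sf.ModelSpec("TRL", "expolinear", maphe,
                            sf.CovarianceSpec("independent", "constant"))
        with pytest.raises(ValueError, match="2 distinct days"):
            sf.fit_gnls(spec, ds)

    def test_ar1_rejected_for_destructive_data(self, maphe):
        cfg = sf.default_config("CDW", plants_per_line=4, seed=2)
        ds = sf.simulate_destructive(cfg)
        spec = sf.ModelSpec("CDW", "decay", maphe,
                            sf.CovarianceSpec("ar1", "per_stratum"))
        with pytest.raises(ValueError, match="AR1.*not identifiable"):
            sf.fit_gnls(spec, ds)

    def test_refit_from_optimum_does_not_improve(self, maphe, trl_dataset):
        spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
        fit = sf.fit_gnls(spec, trl_dataset)
        refit = sf.fit_gnls(spec, trl_dataset, init=fit.estimates)
        assert refit.loglik <= fit.loglik + 1e-4 * abs(fit.loglik)

    def test_profile_sigma_consistency(self, maphe, trl_dataset):
        """The analytically profiled sigma maximizes the full likelihood:
        perturbing sigma around the estimate only lowers logL."""
        spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
        fit = sf.fit_gnls(spec, trl_dataset)
        base = {"levels": fit.estimates, "rho": fit.rho, "delta": fit.delta}
        nll_hat = sf.negative_log_likelihood(
            spec, {**base, "sigma": fit.sigma}, trl_dataset)
        assert nll_hat == pytest.approx(-fit.loglik, rel=1e-9)
        for factor in (0.9, 0.99, 1.01, 1.1):
            nll = sf.negative_log_likelihood(
                spec, {**base, "sigma": fit.sigma * factor}, trl_dataset)
            assert nll >= nll_hat - 1e-9

    def test_destructive_decay_fit_counts_identifiable_nuisance(self,
                                                                maphe):
        cfg = sf.default_config("CDW", plants_per_line=6, seed=3)
        ds = sf.simulate_destructive(cfg)
        spec = sf.ModelSpec("CDW", "decay", maphe,
                            sf.CovarianceSpec("independent", "per_stratum"))
        fit = sf.fit_gnls(spec, ds)
        assert fit.converged
        # 2 levels x 3 curve parameters + sigma + 5 free harvest ratios
        assert fit.n_params == 12
        assert fit.stratum_ratios[2.0] == 1.0

    def test_estimates_bracketed_by_ci(self, maphe, trl_dataset):
        spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
        fit = sf.fit_gnls(spec, trl_dataset)
        tab = fit.estimates_table()
        assert (tab["ll95"] < tab["estimate"]).all()
        assert (tab["estimate"] < tab["ul95"]).all()
        assert (tab["se"] >= 0).all()
        assert fit.n_params == sf.param_count(maphe, "expolinear", 3)

    def test_parameter_recovery_improves_with_sample_size(self, maphe):
        errs = {}
        for plants in (10, 200):
            cfg = sf.default_config("TRL", plants_per_line=plants // 2,
                                    seed=99)
            ds = sf.simulate_trajectories(cfg)
            spec = sf.ModelSpec("TRL", "expolinear", maphe,
                                sf.CovarianceSpec())
            fit = sf.fit_gnls(spec, ds)
            rel = []
            for level, truth in cfg.truth.items():
                tr = truth.to_array()
                rel.append(np.abs(fit.estimates[level].to_array() - tr)
                           / np.abs(tr))
            errs[plants] = float(np.mean(rel))
        assert errs[200] < errs[10]
        assert errs[200] < 0.02


class TestInitialValues:
    def test_exact_expolinear_start_close(self):
        p = sf.ExpolinearParams(149.52, 0.92, 6.22)
        t = np.repeat([2.0, 4.0, 6.0, 8.0, 10.0, 12.0], 4)
        y = sf.expolinear_value(p, t)
        init = sf.initial_values("expolinear", {"large": (t, y)})["large"]
        assert abs(init.cm - p.cm) / p.cm < 0.25

    def test_constant_data_gompertz_wf(self):
        t = np.repeat([2.0, 6.0, 10.0], 3)
        y = np.full_like(t, 7.0)
        init = sf.initial_values("gompertz", {"x": (t, y)})["x"]
        assert init.wf == pytest.approx(7.0, rel=0.1)

    def test_decay_flat_tail_min(self):
        p = sf.DecayParams(0.4, 0.05, 5.0)
        t = np.repeat([2.0, 4.0, 6.0, 8.0, 10.0, 12.0], 2)
        y = sf.decay_value(p, t)
        init = sf.initial_values("decay", {"x": (t, y)})["x"]
        assert init.minimum == pytest.approx(
            y[t >= 10.0].mean(), rel=0.2)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="3 observations"):
            sf.initial_values("gompertz",
                              {"x": (np.array([1.0, 2.0]),
                                     np.array([1.0, 2.0]))})


class TestAsymptoticCi:
    def test_matches_stored_95(self, maphe, trl_dataset):
        spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
        fit = sf.fit_gnls(spec, trl_dataset)
        tab = sf.asymptotic_ci(fit, 0.95)
        for (_, row), key in zip(tab.iterrows(), fit.param_index):
            lo, hi = fit.ci95[key]
            assert row["lower"] == pytest.approx(lo, rel=1e-9)
            assert row["upper"] == pytest.approx(hi, rel=1e-9)

    def test_wider_level_wider_interval(self, maphe, trl_dataset):
        spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
        fit = sf.fit_gnls(spec, trl_dataset)
        w95 = sf.asymptotic_ci(fit, 0.95)
        w99 = sf.asymptotic_ci(fit, 0.99)
        assert ((w99["upper"] - w99["lower"])
                > (w95["upper"] - w95["lower"])).all()

    def test_degenerate_zero_se(self, maphe, trl_dataset):
        spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
        fit = sf.fit_gnls(spec, trl_dataset)
        key = fit.param_index[0]
        fit.se[key] = 0.0
        tab = sf.asymptotic_ci(fit)
        row = tab.iloc[0]
        assert row["lower"] == row["upper"] == row["estimate"]

    def test_requires_convergence(self, maphe, trl_dataset):
        spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
        fit = sf.fit_gnls(spec, trl_dataset)
        fit.converged = False
        with pytest.raises(ValueError, match="converged"):
            sf.asymptotic_ci(fit)

    def test_se_order_of_magnitude_at_study_scale(self, maphe):
        """At study-like replication the large-seed Cm standard error is
        the same order as the published 6.89."""
        cfg = sf.default_config("TRL", plants_per_line=10, seed=77)
        ds = sf.simulate_trajectories(cfg)
        spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
        fit = sf.fit_gnls(spec, ds)
        se = fit.se[("large", "cm")]
        assert 6.89 / 10 < se < 6.89 * 10


def test_matches_r_nlme_gnls_reference(tmp_path, maphe):
    """Cross-check against the reference generalized non-linear
    least-squares implementation (nlme::gnls) on a small fixture:
    maximized logL and coefficients must agree."""
    cfg = sf.default_config("TRL", plants_per_line=6, seed=42)
    ds = sf.simulate_trajectories(cfg)
    spec = sf.ModelSpec("TRL", "expolinear", maphe, sf.CovarianceSpec())
    fit = sf.fit_gnls(spec, ds)

    df = ds.records.copy()
    df["cls"] = [maphe.level_of[l] for l in df["line_id"]]
    csv = tmp_path / "trl.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "gnls.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(nlme))
        d <- read.csv("{csv}")
        d$cls <- factor(d$cls, levels=c("large", "small"))
        fit <- gnls(value ~ (cm/rm)*log(1+exp(rm*(day-tb))), data=d,
          params=list(cm ~ cls - 1, rm ~ cls - 1, tb ~ cls - 1),
          start=c(140, 90, 1.0, 0.7, 6.0, 6.0),
          correlation=corAR1(form=~1|plant_id),
          weights=varExp(form=~day),
          control=gnlsControl(nlsTol=0.01))
        cat(sprintf("%.6f\\n", logLik(fit)))
        cat(sprintf("%.6f\\n", coef(fit)))
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    values = [float(v) for v in out.stdout.split()]
    r_logl, r_coef = values[0], values[1:]
    assert fit.loglik == pytest.approx(r_logl, abs=1e-3)
    ours = [fit.estimate_of("large", "cm"), fit.estimate_of("small", "cm"),
            fit.estimate_of("large", "rm"), fit.estimate_of("small", "rm"),
            fit.estimate_of("large", "tb"), fit.estimate_of("small", "tb")]
    np.testing.assert_allclose(ours, r_coef, rtol=2e-3)
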
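"""Replicate mixed model: likelihood oracles, filters, fitting, BLUPs."""

import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from mbwsigh import (
    ModelParams,
    make_design,
    simulate_outcomes,
    exclude_outliers,
    drop_sparse_scenarios,
    loglik,
    fit_ml,
    blups,
)


def _full_cov(df, p):
    """Brute-force whole-cohort covariance matrix (test oracle)."""
    ids = df["individual_id"].to_numpy()
    scen = df["scenario"].to_numpy()
    n = len(df)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if ids[i] == ids[j]:
                V[i, j] += p.omega**2
                if scen[i] == scen[j]:
                    V[i, j] += p.tau**2
            if i == j:
                V[i, j] += p.sigma[scen[i]] ** 2
    return V


class TestLoglik:
    def test_single_standard_normal_observation(self):
        p = ModelParams(mu=0.0, alpha={"none": 0.0}, omega=0.0, tau=0.0,
                        sigma={"none": 1.0})
        df = pd.DataFrame(
            {"individual_id": ["A"], "test_id": ["T0"], "scenario": ["none"],
             "lci": [0.0]}
        )
        assert loglik(p, df) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_iid_limit_sums_univariate_densities(self, lci_params):
        p = ModelParams(mu=6.82, alpha=dict(lci_params.alpha), omega=0.0, tau=0.0,
                        sigma=dict(lci_params.sigma))
        design = make_design({"none": 20, "washout-pre": 10}, 10, seed=0)
        df = simulate_outcomes(p, design, seed=1)
        expected = sum(
            norm.logpdf(y, p.mu + p.alpha.get(s, 0.0), p.sigma[s])
            for y, s in zip(df["lci"], df["scenario"])
        )
        assert loglik(p, df) == pytest.approx(expected, rel=1e-10)

    def test_matches_brute_force_joint_density(self, lci_params):
        design = make_design({"none": 4, "washin-pre": 1, "washout-pre": 1}, 3, seed=2)
        df = simulate_outcomes(lci_params, design, seed=3)
        mean = np.array(
            [lci_params.mu + lci_params.alpha.get(s, 0.0) for s in df["scenario"]]
        )
        oracle = multivariate_normal.logpdf(
            df["lci"].to_numpy(), mean, _full_cov(df, lci_params)
        )
        assert loglik(lci_params, df) == pytest.approx(oracle, abs=1e-8)

    def test_singular_covariance_rejected(self):
        p = ModelParams(mu=0.0, alpha={"none": 0.0}, omega=0.0, tau=0.0,
                        sigma={"none": 0.0})
        df = pd.DataFrame(
            {"individual_id": ["A", "A"], "test_id": ["T0", "T1"],
             "scenario": ["none", "none"], "lci": [0.0, 0.1]}
        )
        with pytest.raises(np.linalg.LinAlgError):
            loglik(p, df)

    def test_missing_scenario_params_rejected(self, lci_params):
        df = pd.DataFrame(
            {"individual_id": ["A"], "test_id": ["T0"], "scenario": ["yawn"],
             "lci": [6.0]}
        )
        with pytest.raises(KeyError):
            loglik(lci_params, df)


class TestFilters:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["test_id", "scenario", "lci", "cev_l"])

    def test_outlier_rules(self):
        df = self._table(
            [("a", "washin-pre", 9.6, 1.0),   # lci > 9.5
             ("b", "washin-pre", 9.2, 1.5),   # cev > 1.4 and lci > 9
             ("c", "none", 8.0, 1.5),         # conjunction not met
             ("d", "none", 6.8, 0.7)]
        )
        kept, log = exclude_outliers(df)
        assert sorted(kept["test_id"]) == ["c", "d"]
        assert {e["test_id"] for e in log} == {"a", "b"}

    def test_rules_with_missing_columns_skipped(self):
        df = pd.DataFrame({"test_id": ["a"], "scenario": ["none"], "lci": [9.6]})
        kept, log = exclude_outliers(df)
        assert kept.empty and log[0]["reason"] == "lci > 9.5"

    def test_sparse_scenarios_dropped(self):
        counts = {"none": 648, "washin-pre": 50, "washin-post": 3,
                  "washout-pre": 56, "washout-post": 10}
        rows = []
        k = 0
        for s, c in counts.items():
            for _ in range(c):
                rows.append((f"t{k}", s, 7.0, 0.7))
                k += 1
        df = self._table(rows)
        kept = drop_sparse_scenarios(df, min_n=20)
        assert set(kept["scenario"]) == {"none", "washin-pre", "washout-pre"}
        assert len(kept) == 754
        assert len(drop_sparse_scenarios(df, min_n=1)) == len(df)
        assert drop_sparse_scenarios(df, min_n=1000).empty


class TestFitML:
    def test_collapses_to_iid_normal(self):
        p = ModelParams(mu=5.0, alpha={"none": 0.0}, omega=0.0, tau=0.0,
                        sigma={"none": 0.3})
        design = make_design({"none": 1500}, 500, seed=0)
        df = simulate_outcomes(p, design, seed=4)
        res = fit_ml(df, seed=0, n_starts=2)
        assert res.params.mu == pytest.approx(df["lci"].mean(), abs=0.01)
        total_sd = math.sqrt(
            res.params.omega**2 + res.params.tau**2 + res.params.sigma["none"] ** 2
        )
        assert total_sd == pytest.approx(df["lci"].std(ddof=0), rel=0.05)
        assert res.params.sigma["none"] == pytest.approx(0.3, rel=0.05)

    def test_shift_invariance(self, lci_params):
        design = make_design({"none": 90, "washout-pre": 30}, 40, seed=1)
        df = simulate_outcomes(lci_params, design, seed=5)
        res0 = fit_ml(df, seed=0, n_starts=2)
        shifted = df.assign(lci=df["lci"] + 10.0)
        res1 = fit_ml(shifted, seed=0, n_starts=2)
        assert res1.params.mu - res0.params.mu == pytest.approx(10.0, abs=1e-3)
        assert res1.params.omega == pytest.approx(res0.params.omega, abs=1e-4)
        assert res1.params.sigma["none"] == pytest.approx(
            res0.params.sigma["none"], abs=1e-4
        )

    def test_wald_intervals_bracket_estimates(self, lci_params):
        design = make_design({"none": 300, "washin-pre": 50, "washout-pre": 50},
                             130, seed=2)
        df = simulate_outcomes(lci_params, design, seed=6)
        res = fit_ml(df, seed=0, n_starts=2)
        est = {
            "mu": res.params.mu,
            "alpha:washout-pre": res.params.alpha["washout-pre"],
            "omega": res.params.omega,
            "sigma:none": res.params.sigma["none"],
            "sigma_ratio:washout-pre": res.params.sd_ratio("washout-pre"),
        }
        for name, value in est.items():
            lo, hi = res.ci[name]
            assert lo <= value <= hi

    def test_init_near_truth_reaches_same_optimum(self, lci_params):
        design = make_design({"none": 120, "washout-pre": 40}, 50, seed=3)
        df = simulate_outcomes(lci_params, design, seed=7)
        p = ModelParams(mu=6.82, alpha={"none": 0.0, "washout-pre": 0.362},
                        omega=0.296, tau=0.186,
                        sigma={"none": 0.437, "washout-pre": 0.89})
        res_a = fit_ml(df, seed=0, n_starts=3)
        res_b = fit_ml(df, init=p, seed=1, n_starts=1)
        assert res_b.loglik == pytest.approx(res_a.loglik, abs=1e-4)

    def test_matches_nlme_maximum_likelihood(self, tmp_path, lci_params):
        """Independent oracle: R's nlme lme() with nested random intercepts
        and per-scenario residual variances finds the same ML optimum."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        design = make_design({"none": 160, "washin-pre": 40, "washout-pre": 40},
                             80, seed=5)
        df = simulate_outcomes(lci_params, design, seed=5)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            library(nlme)
            d <- read.csv("{csv}")
            d$scenario <- factor(d$scenario,
                                 levels = c("none", "washin-pre", "washout-pre"))
            fit <- lme(lci ~ scenario, random = ~1 | individual_id/scenario,
                       weights = varIdent(form = ~1 | scenario),
                       data = d, method = "ML",
                       control = lmeControl(maxIter = 200, msMaxIter = 200))
            w <- coef(fit$modelStruct$varStruct, unconstrained = FALSE,
                      allCoef = TRUE)
            out <- list(beta = as.numeric(fixef(fit)),
                        loglik = as.numeric(logLik(fit)),
                        sigma = as.numeric(fit$sigma * w),
                        sigma_names = names(w))
            cat(jsonlite::toJSON(out, digits = 10))
            """
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        r = json.loads(proc.stdout)
        res = fit_ml(df, seed=5)
        beta = r["beta"]
        assert res.params.mu == pytest.approx(beta[0], abs=2e-3)
        assert res.params.alpha["washin-pre"] == pytest.approx(beta[1], abs=5e-3)
        assert res.params.alpha["washout-pre"] == pytest.approx(beta[2], abs=5e-3)
        r_sigma = dict(zip(r["sigma_names"], r["sigma"]))
        for s in ("none", "washin-pre", "washout-pre"):
            assert res.params.sigma[s] == pytest.approx(r_sigma[s], rel=0.02)
        # our optimum is at least as good as nlme's
        assert res.loglik >= r["loglik"][0] - 1e-3

    def test_reml_flag_runs_and_increases_variance_estimates(self, lci_params):
        design = make_design({"none": 120, "washout-pre": 40}, 60, seed=4)
        df = simulate_outcomes(lci_params, design, seed=8)
        ml = fit_ml(df, seed=0, n_starts=2)
        reml = fit_ml(df, seed=0, n_starts=2, reml=True)
        assert reml.method == "reml"
        assert np.isfinite(reml.loglik)
        # REML corrects the downward ML bias of the residual variance
        assert reml.params.sigma["none"] >= ml.params.sigma["none"] - 1e-6


class TestBlups:
    def test_shrinkage_toward_zero(self, lci_params):
        design = make_design({"none": 60}, 20, seed=6)
        df = simulate_outcomes(lci_params, design, seed=9)
        b = blups(lci_params, df)
        indiv = b[b["effect"] == "individual"].set_index("individual_id")["blup"]
        raw = df.groupby("individual_id")["lci"].mean() - lci_params.mu
        assert (indiv.abs() <= raw.abs() + 1e-9).all()
        assert np.sign(indiv).equals(np.sign(raw))
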
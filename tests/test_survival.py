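"""Survival machinery against hand-computed and brute-force oracles."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from hccscreen.survival import (
    apply_exclusions,
    cumulative_incidence,
    fit_cox,
    fit_subdistribution,
    km_estimate,
    logrank_test,
)


class TestExclusions:
    def test_no_zero_rows_noop(self):
        df = pd.DataFrame({"time_months": [1, 2, 3], "event": [1, 0, 1]})
        out, n = apply_exclusions(df)
        assert n == 0
        pd.testing.assert_frame_equal(out, df)

    def test_zero_rows_removed_and_counted(self):
        df = pd.DataFrame({"time_months": [0] * 5 + [3] * 95,
                           "event": [1] * 100})
        out, n = apply_exclusions(df)
        assert n == 5
        assert len(out) == 95

    def test_zero_rows_remapped_when_included(self):
        df = pd.DataFrame({"time_months": [0.0, 4.0], "event": [1, 1]})
        out, n = apply_exclusions(df, include_zero_month=True)
        assert n == 0
        assert list(out["time_months"]) == [0.5, 4.0]


class TestKaplanMeier:
    def test_hand_product_limit_all_events(self):
        km = km_estimate([2, 4, 6], [1, 1, 1])
        np.testing.assert_allclose(
            km.table["survival"], [2 / 3, 1 / 3, 0.0], atol=1e-12
        )

    def test_all_censored_survival_one(self):
        km = km_estimate([2, 4, 6], [0, 0, 0])
        assert (km.table["survival"] == 1.0).all()
        assert not km.median_defined

    def test_median_and_ci_ordering(self, rng):
        t = rng.exponential(12, 400)
        e = rng.random(400) < 0.8
        km = km_estimate(t, e)
        assert km.median_ci[0] <= km.median <= km.median_ci[1]
        assert (km.table["ci_low"] <= km.table["survival"] + 1e-12).all()
        assert (km.table["survival"] <= km.table["ci_high"] + 1e-12).all()

    def test_brute_force_risk_sets_random_rows(self, rng):
        """Product-limit on 50 random rows equals explicit risk-set
        enumeration to 1e-12."""
        t = rng.integers(1, 20, 50).astype(float)
        e = (rng.random(50) < 0.6).astype(int)
        km = km_estimate(t, e)
        s = 1.0
        expected = {}
        for u in sorted(set(t)):
            n_risk = np.sum(t >= u)
            d = np.sum((t == u) & (e == 1))
            s *= 1 - d / n_risk
            expected[u] = s
        got = dict(zip(km.table["time"], km.table["survival"]))
        for u, sv in expected.items():
            assert got[u] == pytest.approx(sv, abs=1e-12)

    def test_monotone_nonincreasing(self, rng):
        t = rng.exponential(10, 500)
        e = rng.random(500) < 0.5
        km = km_estimate(t, e)
        assert np.all(np.diff(km.table["survival"]) <= 1e-12)
        assert km.survival_at(0) == 1.0

    def test_zero_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0, 1, 2], [1, 1, 1])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [3, 5, 7, 9, 11, 13]
        e = [1, 1, 0, 1, 0, 1]
        chi2, df, p = logrank_test(t + t, e + e, ["a"] * 6 + ["b"] * 6)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1

    def test_hand_computed_two_group_toy(self):
        """Group A events at 1, 2; group B events at 3, 4.

        Observed-minus-expected by hand over the pooled event times:
        t=1: n=4, nA=2, d=1, E_A=0.5, V=0.25
        t=2: n=3, nA=1, d=1, E_A=1/3, V=2/9
        t=3: n=2, nA=0, d=1, E_A=0,   V=0
        t=4: n=1, nA=0, d=1, E_A=0,   V=0
        O_A - E_A = 2 - 5/6; chi2 = (7/6)^2 / (0.25 + 2/9).
        """
        chi2, df, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1],
                                   ["A", "A", "B", "B"])
        expected = (7 / 6) ** 2 / (0.25 + 2 / 9)
        assert chi2 == pytest.approx(expected, rel=1e-10)
        assert df == 1

    def test_three_groups_df_two(self, rng):
        t = rng.exponential(10, 90)
        e = np.ones(90, int)
        g = np.repeat(["a", "b", "c"], 30)
        _, df, _ = logrank_test(t, e, g)
        assert df == 2

    def test_relabeling_invariance(self, rng):
        t = rng.exponential(10, 60)
        e = (rng.random(60) < 0.7).astype(int)
        g = np.repeat(["x", "y"], 30)
        chi_a, _, _ = logrank_test(t, e, g)
        chi_b, _, _ = logrank_test(t, e, np.where(g == "x", "y", "x"))
        assert chi_a == pytest.approx(chi_b, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCox:
    def test_score_equation_oracle_small_data(self):
        """Four subjects, one binary covariate, no ties: the fitted
        coefficient solves the partial-likelihood score equation, found
        independently by bisection."""
        df = pd.DataFrame(
            {
                "time_months": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 1, 1, 1],
                "x": [1.0, 0.0, 1.0, 0.0],
            }
        )
        from scipy.optimize import brentq

        t = df["time_months"].to_numpy()
        x = df["x"].to_numpy()

        def score(beta):
            s = 0.0
            for i in range(4):
                risk = t >= t[i]
                w = np.exp(beta * x[risk])
                s += x[i] - np.sum(w * x[risk]) / np.sum(w)
            return s

        beta_star = brentq(score, -5, 5, xtol=1e-12)
        m = fit_cox(df, covariates=["x"])
        assert m.coef("x") == pytest.approx(beta_star, abs=1e-4)

    def test_recovers_simulated_log_hr(self, rng):
        """Exponential data with log-HR -0.4 at n=20,000: estimate within
        3 SE of truth."""
        n = 20000
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(-0.4 * x)))
        c = rng.uniform(0, 60, n)
        df = pd.DataFrame(
            {
                "time_months": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "x": x,
            }
        )
        m = fit_cox(df, covariates=["x"])
        assert abs(m.coef("x") - (-0.4)) < 3 * m.se("x")

    def test_constant_covariate_dropped_and_flagged(self, rng):
        df = pd.DataFrame(
            {
                "time_months": rng.exponential(10, 100),
                "event": np.ones(100, int),
                "x": rng.binomial(1, 0.5, 100).astype(float),
                "z": np.zeros(100),
            }
        )
        m = fit_cox(df, covariates=["x", "z"])
        assert "z" in m.dropped_terms
        assert list(m.terms["term"]) == ["x"]

    def test_centering_invariance(self, rng):
        n = 500
        df = pd.DataFrame(
            {
                "time_months": rng.exponential(10, n),
                "event": (rng.random(n) < 0.8).astype(int),
                "x": rng.normal(0, 1, n),
            }
        )
        m1 = fit_cox(df, covariates=["x"])
        df2 = df.assign(x=df["x"] + 100.0)
        m2 = fit_cox(df2, covariates=["x"])
        assert m1.coef("x") == pytest.approx(m2.coef("x"), abs=1e-6)

    def test_group_model_reference_is_no_imaging(self, default_cohort):
        from hccscreen.exposure import build_exposure_table

        exp = build_exposure_table(default_cohort.patients, default_cohort.imaging)
        df = default_cohort.patients.merge(exp, on="patient_id")
        ana, _ = apply_exclusions(df)
        m = fit_cox(ana, specification="group_model")
        terms = set(m.terms["term"])
        assert terms == {"group[ultrasound]", "group[ctmri]"}

    def test_ptc_model_per_ten_percent_scaling(self, default_cohort):
        from hccscreen.exposure import build_exposure_table

        exp = build_exposure_table(default_cohort.patients, default_cohort.imaging)
        df = default_cohort.patients.merge(exp, on="patient_id")
        ana, _ = apply_exclusions(df)
        m = fit_cox(ana, specification="ptc_model")
        assert set(m.terms["term"]) == {"ptc_us_per10", "ptc_ctmri_per10"}
        # refit on raw [0,1] PTC: coefficient should be 10x the per-10% one
        m_raw = fit_cox(ana, covariates=["ptc_us", "ptc_ctmri"])
        assert m_raw.coef("ptc_us") == pytest.approx(
            10 * m.coef("ptc_us_per10"), rel=1e-4
        )


class TestCumulativeIncidence:
    def test_single_cause_reduces_to_one_minus_km(self, rng):
        t = rng.integers(1, 30, 200).astype(float)
        cens = rng.random(200) < 0.3
        causes = np.where(cens, "censored", "hcc_death")
        cif = cumulative_incidence(t, causes)
        km = km_estimate(t, ~cens)
        grid = km.table["time"].to_numpy()
        cif_at = (
            cif["hcc_death"].set_index("time")["cif"].reindex(grid).to_numpy()
        )
        np.testing.assert_allclose(cif_at, 1 - km.table["survival"], atol=1e-10)
        assert (cif["other_death"]["cif"] == 0).all()

    def test_all_censored_cif_zero(self):
        cif = cumulative_incidence([1.0, 2.0, 3.0], ["censored"] * 3)
        for tab in cif.values():
            assert (tab["cif"] == 0).all()

    def test_equal_hazard_causes_agree(self, rng):
        n = 20000
        t1 = rng.exponential(20, n)
        t2 = rng.exponential(20, n)
        t = np.minimum(t1, t2)
        causes = np.where(t1 <= t2, "hcc_death", "other_death")
        cif = cumulative_incidence(t, causes)
        final = [tab["cif"].iloc[-1] for tab in cif.values()]
        assert abs(final[0] - final[1]) < 3 * np.sqrt(0.25 / n) * 2

    def test_cif_sum_bounded_and_monotone(self, default_cohort):
        ana, _ = apply_exclusions(default_cohort.patients)
        cif = cumulative_incidence(ana["time_months"], ana["cause"])
        total = sum(tab["cif"].to_numpy() for tab in cif.values())
        assert (total <= 1.0 + 1e-9).all()
        for tab in cif.values():
            assert np.all(np.diff(tab["cif"]) >= -1e-12)

    def test_unknown_cause_rejected(self):
        with pytest.raises(ValueError):
            cumulative_incidence([1.0], ["mystery"])


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self, rng):
        n = 300
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.08 * np.exp(0.5 * x)))
        c = rng.uniform(1, 30, n)
        df = pd.DataFrame(
            {
                "time_months": np.minimum(t, c),
                "cause": np.where(t <= c, "hcc_death", "censored"),
                "event": (t <= c).astype(int),
                "x": x,
            }
        )
        fg = fit_subdistribution(df, "hcc_death", covariates=["x"])
        cox = fit_cox(df, covariates=["x"])
        assert fg.coef("x") == pytest.approx(cox.coef("x"), abs=1e-6)

    def test_matches_r_cmprsk_crr(self, rng):
        """Independent oracle: R's cmprsk::crr on the same data."""
        n = 150
        x = rng.binomial(1, 0.5, n).astype(float)
        t1 = rng.exponential(1 / (0.08 * np.exp(0.6 * x)))
        t2 = rng.exponential(1 / 0.05, n)
        c = rng.uniform(5, 40, n)
        t = np.minimum(np.minimum(t1, t2), c)
        cause = np.where(t == c, "censored",
                         np.where(t == t1, "hcc_death", "other_death"))
        df = pd.DataFrame({"time_months": t, "cause": cause, "x": x})
        fg = fit_subdistribution(df, "hcc_death", covariates=["x"])
        import os
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "d.csv")
            df.to_csv(csv, index=False)
            script = (
                "suppressMessages(library(cmprsk));"
                f"d <- read.csv('{csv}');"
                "status <- ifelse(d$cause=='hcc_death',1,"
                "ifelse(d$cause=='other_death',2,0));"
                "f <- crr(d$time_months, status, cov1=cbind(x=d$x),"
                "failcode=1, cencode=0);"
                "cat(sprintf('%.8f', f$coef))"
            )
            out = subprocess.run(["Rscript", "-e", script],
                                 capture_output=True, text=True, timeout=300)
            assert out.returncode == 0, out.stderr
            beta_r = float(out.stdout.strip())
        assert fg.coef("x") == pytest.approx(beta_r, abs=0.02)

    def test_effect_on_competing_cause_drifts_opposite(self, rng):
        """A covariate that only raises the competing hazard lowers the
        subdistribution hazard of the cause of interest."""
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        t1 = rng.exponential(1 / 0.04, n)
        t2 = rng.exponential(1 / (0.04 * np.exp(1.0 * x)))
        t = np.minimum(np.minimum(t1, t2), 60.0)
        cause = np.where(t == 60.0, "censored",
                         np.where(t == t1, "hcc_death", "other_death"))
        # month-granular follow-up keeps the IPCW risk-set expansion compact
        t = np.ceil(t)
        df = pd.DataFrame({"time_months": t, "cause": cause, "x": x})
        fg = fit_subdistribution(df, "hcc_death", covariates=["x"])
        assert fg.coef("x") < 0
        assert fg.ci("x")[1] < 1.0

    def test_no_events_of_interest_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0],
                           "cause": ["other_death", "censored"],
                           "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            fit_subdistribution(df, "hcc_death", covariates=["x"])
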
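"""Heteroskedastic GLS, sequential F-tests, and stage summaries."""

import numpy as np
import pandas as pd
import pytest

from thermodev.gls import (
    fit_gls_varident,
    individual_rates,
    mass_analysis,
    summarize_stages,
)
from thermodev.records import IndividualRecord
from thermodev.simulate import SimConfig, default_config, simulate_cohort


def make_oracle_dataset():
    """Deterministic heteroskedastic dataset; fitted once with R nlme::gls."""
    rng = np.random.default_rng(2024)
    rows = []
    for t in (20.0, 26.0, 32.0):
        for sex in ("male", "female"):
            sd = 0.8 if sex == "male" else 1.6
            y = (
                2.0
                - 0.04 * (t - 26)
                + (0.5 if sex == "female" else 0.0)
                + 0.01 * (t - 26) * (1 if sex == "female" else -1)
                + rng.normal(0, sd, 25)
            )
            rows += [{"temp_c": t, "sex": sex, "y": v} for v in y]
    return pd.DataFrame(rows)


class TestAgainstIndependentGLSOracle:
    """Frozen reference values from nlme::gls(y ~ tc*sx, varIdent, REML)."""

    # gls(y ~ tc + sx + tc:sx, weights = varIdent(form = ~1 | stratum))
    R_COEF = (2.2735231271, -0.0577813735, 0.5799697461, 0.0356810728)
    R_SE = (0.0940314439, 0.0215584558, 0.1880628879, 0.0431169116)
    R_LOGLIK = -227.411388
    R_F = (16.2203, 9.1939, 0.6848)  # sequential: temperature, sex, interaction
    # varIdent SD ratios relative to 20.male
    R_SD_RATIO_20F_OVER_20M = 1.8326023

    def test_coefficients_and_ses(self):
        fit = fit_gls_varident(make_oracle_dataset(), "y")
        assert fit.coefficients.to_numpy() == pytest.approx(self.R_COEF, abs=1e-6)
        assert fit.se.to_numpy() == pytest.approx(self.R_SE, abs=1e-6)

    def test_reml_loglik(self):
        fit = fit_gls_varident(make_oracle_dataset(), "y")
        assert fit.reml_loglik == pytest.approx(self.R_LOGLIK, abs=1e-4)

    def test_sequential_f_statistics(self):
        fit = fit_gls_varident(make_oracle_dataset(), "y")
        assert fit.anova["F"].to_numpy() == pytest.approx(self.R_F, abs=2e-3)
        assert (fit.anova["df2"] == 150 - 4).all()

    def test_variance_structure(self):
        fit = fit_gls_varident(make_oracle_dataset(), "y")
        m = fit.variance_multipliers
        sd_ratio = np.sqrt(m["20.0:female"] / m["20.0:male"])
        assert sd_ratio == pytest.approx(self.R_SD_RATIO_20F_OVER_20M, abs=1e-4)


class TestModelContracts:
    def test_homoskedastic_reduction_equals_ols(self):
        df = make_oracle_dataset()
        fit = fit_gls_varident(df, "y", homoskedastic=True)
        tc = df["temp_c"] - df["temp_c"].mean()
        sx = df["sex"].map({"female": 0.5, "male": -0.5})
        X = np.column_stack([np.ones(len(df)), tc, sx, tc * sx])
        beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        assert fit.coefficients.to_numpy() == pytest.approx(beta, abs=1e-10)
        assert (fit.variance_multipliers == 1.0).all()

    def test_coefficients_invariant_to_common_variance_scale(self):
        df = make_oracle_dataset()
        fit1 = fit_gls_varident(df, "y")
        df2 = df.assign(y=df["y"] * 10.0)
        fit2 = fit_gls_varident(df2, "y")
        assert fit2.coefficients.to_numpy() == pytest.approx(
            10.0 * fit1.coefficients.to_numpy(), rel=1e-8
        )
        assert fit2.variance_multipliers.to_numpy() == pytest.approx(
            fit1.variance_multipliers.to_numpy(), rel=1e-6
        )

    def test_f_matches_nested_rss_oracle(self):
        df = make_oracle_dataset()
        fit = fit_gls_varident(df, "y")
        # brute-force nested weighted regressions with the fitted weights
        strata = df["temp_c"].round(6).astype(str) + ":" + df["sex"]
        w = 1.0 / (fit.sigma2 * fit.variance_multipliers[strata].to_numpy())
        tc = (df["temp_c"] - fit.temp_center).to_numpy()
        sx = df["sex"].map({"female": 0.5, "male": -0.5}).to_numpy()
        X = np.column_stack([np.ones(len(df)), tc, sx, tc * sx])
        y = df["y"].to_numpy()

        def rss(cols):
            Xw = X[:, cols] * np.sqrt(w)[:, None]
            coef, *_ = np.linalg.lstsq(Xw, y * np.sqrt(w), rcond=None)
            return np.sum((y * np.sqrt(w) - Xw @ coef) ** 2)

        r = [rss(list(range(k))) for k in (1, 2, 3, 4)]
        df_resid = len(df) - 4
        for j, term in enumerate(("temperature", "sex", "temperature:sex")):
            F = (r[j] - r[j + 1]) / (r[3] / df_resid)
            got = fit.anova.loc[fit.anova.term == term, "F"].iloc[0]
            assert got == pytest.approx(F, rel=1e-8)

    def test_df_bookkeeping_matches_study_pattern(self):
        # 574 individuals and 4 fixed-effect coefficients give 570 residual df
        cfg = default_config(n_individuals_per_temp=115)
        cfg = SimConfig(**{**cfg.__dict__, "schedule": ()})
        _, records = simulate_cohort(cfg, seed=0)
        rates = individual_rates(records[:574])
        fit = fit_gls_varident(rates, "pupal_rate")
        assert fit.nobs == 574
        assert fit.df_resid == 570
        assert (fit.anova["df2"] == 570).all()

    def test_empty_stratum_rejected(self):
        df = pd.DataFrame(
            {"temp_c": [20.0] * 5 + [26.0], "sex": ["male"] * 5 + ["female"],
             "y": np.arange(6.0)}
        )
        with pytest.raises(ValueError, match="<2 observations"):
            fit_gls_varident(df, "y")


class TestIndividualRates:
    def test_rates_are_inverse_durations(self):
        rec = IndividualRecord(id="x", temp_c=20.0, sex="female",
                               larval_d=38.9, pupal_d=10.3, teneral_d=6.8,
                               mass_mg=6.9)
        df = individual_rates([rec])
        assert df["pupal_rate"].iloc[0] == pytest.approx(1 / 10.3)
        assert df["larval_rate"].iloc[0] == pytest.approx(1 / 38.9)

    def test_flagged_records_excluded(self):
        good = IndividualRecord(id="a", temp_c=20.0, sex="male", larval_d=30.0,
                                pupal_d=10.0, teneral_d=1.0, mass_mg=5.0)
        bad = IndividualRecord(id="b", temp_c=20.0, sex="male", larval_d=30.0,
                               pupal_d=10.0, teneral_d=1.0, mass_mg=5.0,
                               flags=frozenset({"overlooked"}))
        df = individual_rates([good, bad])
        assert len(df) == 1
        assert df.attrs["n_excluded"] == 1


class TestSummaries:
    def test_quartiles_by_linear_interpolation(self):
        recs = [
            IndividualRecord(id=str(i), temp_c=20.0, sex="male", pupal_d=d,
                             larval_d=30.0, teneral_d=5.0)
            for i, d in enumerate([9.8, 10.3, 10.8])
        ]
        s = summarize_stages(recs)
        row = s[(s.stage == "pupa")].iloc[0]
        assert row["median_d"] == pytest.approx(10.3)
        assert row["q1_d"] == pytest.approx(10.05)
        assert row["q3_d"] == pytest.approx(10.55)

    def test_single_record_degenerate(self):
        recs = [IndividualRecord(id="a", temp_c=20.0, sex="male", pupal_d=10.0,
                                 larval_d=30.0, teneral_d=5.0)]
        row = summarize_stages(recs)
        row = row[row.stage == "pupa"].iloc[0]
        assert row["median_d"] == row["q1_d"] == row["q3_d"] == 10.0

    def test_lognormal_median_recovered(self):
        rng = np.random.default_rng(0)
        true_med = 10.0
        recs = [
            IndividualRecord(id=str(i), temp_c=26.0, sex="male",
                             pupal_d=float(true_med * np.exp(rng.normal(0, 0.2))),
                             larval_d=30.0, teneral_d=5.0)
            for i in range(1000)
        ]
        s = summarize_stages(recs)
        med = s[s.stage == "pupa"]["median_d"].iloc[0]
        assert med == pytest.approx(true_med, rel=0.02)


class TestMassAnalysis:
    def _records(self, seed, n=100, offset=1.9, noise=0.5, temp_slope=0.0):
        rng = np.random.default_rng(seed)
        recs = []
        for t in (20.0, 26.0, 32.0):
            for i in range(n):
                sex = "female" if rng.random() < 0.5 else "male"
                mass = 5.0 + (offset if sex == "female" else 0.0)
                mass += temp_slope * (t - 26.0)
                mass += rng.normal(0, noise) if noise else 0.0
                recs.append(
                    IndividualRecord(id=f"{t}-{i}", temp_c=t, sex=sex,
                                     larval_d=30.0, pupal_d=10.0, teneral_d=5.0,
                                     mass_mg=float(max(mass, 0.1)))
                )
        return recs

    def test_sex_offset_recovered_exactly_without_noise(self):
        fit, _ = mass_analysis(self._records(0, noise=0.0))
        assert fit.coefficients["sex"] == pytest.approx(1.9, abs=1e-9)

    def test_sex_effect_detected(self):
        fit, summary = mass_analysis(self._records(1))
        p = fit.anova.loc[fit.anova.term == "sex", "p"].iloc[0]
        assert p < 1e-6
        means = summary.set_index(["temp_c", "sex"])["mean_mg"]
        assert means[(26.0, "female")] > means[(26.0, "male")]

    def test_temperature_size_rule_sign(self):
        fit, _ = mass_analysis(self._records(2, temp_slope=-0.1))
        assert fit.coefficients["temperature"] < 0
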
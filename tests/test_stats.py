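"""Cohort statistics: model fitting, adjusted group differences, percent
change, decade-partitioned ANOVA."""

import numpy as np
import pandas as pd
import pytest

from handquant.core import ModelError
from handquant.stats import (
    ModelSpec,
    decade_anova,
    fit_model,
    group_difference,
    percent_change_over_window,
)
from handquant.synthetic import CohortSpec, generate_cohort


def _linear_cohort(n=120, intercept=1.0, slope=-0.005, sex="male", seed=0):
    """Exactly linear vmrel in age, no noise; vh constant."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 80, n)
    vmrel = intercept + slope * (ages - 40.0)
    diag = rng.choice(["Pso", "PsA", "RA"], n)
    return pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "sex": [sex] * n,
            "diagnosis": diag,
            "age": ages,
            "bmi": 25.0,
            "vh": 300.0,
            "vmrel": np.clip(vmrel, 1e-6, 1.0),
        }
    )


class TestFitModel:
    def test_noise_free_coefficients_recovered(self):
        df, coef = generate_cohort(CohortSpec(seed=10, vmrel_sd=0.0))
        for sex in ("male", "female"):
            fitted = fit_model(df, ModelSpec(response="vmrel", sex=sex))
            slope = coef["vmrel"]["age_slope"][sex]
            assert fitted.params["age_term"] == pytest.approx(slope, abs=1e-9)
            assert fitted.params["diag_RA"] == pytest.approx(
                coef["vmrel"]["offsets"]["RA"], abs=1e-9
            )

    def test_bmi_spec_drops_missing_records_only(self):
        df, _ = generate_cohort(CohortSpec(seed=11, bmi_fraction=0.6))
        window = (20.0, 80.0)
        with_bmi = fit_model(df, ModelSpec(include_bmi=True, sex="male", window=window))
        without = fit_model(df, ModelSpec(include_bmi=False, sex="male", window=window))
        males = df[df["sex"] == "male"]
        assert with_bmi.n == int(males["bmi"].notna().sum())
        assert without.n == len(males)

    def test_complete_bmi_means_same_records_either_way(self):
        df, _ = generate_cohort(CohortSpec(seed=12, bmi_fraction=1.0))
        a = fit_model(df, ModelSpec(include_bmi=True, sex="female"))
        b = fit_model(df, ModelSpec(include_bmi=False, sex="female"))
        assert a.n == b.n
        assert set(a.data["id"]) == set(b.data["id"])

    def test_age3_equals_age_when_response_constant_in_age(self):
        df = _linear_cohort(slope=0.0)
        fa = fit_model(df, ModelSpec(age_term="age"))
        fc = fit_model(df, ModelSpec(age_term="age3"))
        assert fa.params["age_term"] == pytest.approx(0.0, abs=1e-12)
        assert fc.params["age_term"] == pytest.approx(0.0, abs=1e-12)
        assert fa.params["Intercept"] == pytest.approx(fc.params["Intercept"], abs=1e-9)

    def test_missing_group_level_raises(self):
        df = _linear_cohort()
        df = df[df["diagnosis"] != "RA"]
        with pytest.raises(ModelError):
            fit_model(df, ModelSpec())

    def test_too_few_records_rejected(self):
        df = _linear_cohort(n=5)
        with pytest.raises(ModelError):
            fit_model(df, ModelSpec())

    def test_slope_coverage_at_cohort_scale(self):
        hits = 0
        for seed in range(30):
            df, coef = generate_cohort(CohortSpec(seed=seed))
            fitted = fit_model(df, ModelSpec(response="vmrel", sex="male"))
            lo, hi = fitted.result.conf_int().loc["age_term"]
            hits += lo <= coef["vmrel"]["age_slope"]["male"] <= hi
        assert hits >= 25  # ~95% nominal coverage; loose binomial bound


class TestGroupDifference:
    def test_generating_offset_recovered_exactly(self):
        spec = CohortSpec(
            seed=13, vmrel_sd=0.0, vmrel_offsets={"Pso": 0.0, "PsA": -0.01, "RA": -0.04}
        )
        df, _ = generate_cohort(spec)
        fitted = fit_model(df, ModelSpec(response="vmrel", sex="male"))
        gd = group_difference(fitted, ("RA", "Pso"))
        assert gd.delta == pytest.approx(-0.04, abs=1e-9)

    def test_contrast_with_itself_is_zero_flagged(self):
        fitted = fit_model(_linear_cohort(), ModelSpec())
        gd = group_difference(fitted, ("RA", "RA"))
        assert gd.delta == 0.0
        assert np.isnan(gd.p_value)

    def test_transitivity_in_parallel_slopes_model(self):
        df, _ = generate_cohort(CohortSpec(seed=14))
        fitted = fit_model(df, ModelSpec(response="vmrel", sex="female"))
        d_ra_pso = group_difference(fitted, ("RA", "Pso")).delta
        d_psa_pso = group_difference(fitted, ("PsA", "Pso")).delta
        d_ra_psa = group_difference(fitted, ("RA", "PsA")).delta
        assert d_ra_psa == pytest.approx(d_ra_pso - d_psa_pso, abs=1e-9)

    def test_interaction_model_delta_is_window_average(self):
        df, _ = generate_cohort(CohortSpec(seed=15))
        spec = ModelSpec(response="vmrel", sex="male", interaction=True)
        fitted = fit_model(df, spec)
        gd = group_difference(fitted, ("RA", "Pso"))
        beta = fitted.result.params
        ages = np.linspace(20, 80, 81)
        manual = np.mean(beta["diag_RA"] + beta["agex_RA"] * ages)
        assert gd.delta == pytest.approx(manual, abs=1e-9)

    def test_model_without_group_rejected(self):
        fitted = fit_model(_linear_cohort(), ModelSpec(group=None))
        with pytest.raises(ModelError):
            group_difference(fitted, ("RA", "Pso"))


class TestPercentChange:
    def test_zero_slope_gives_zero_percent(self):
        fitted = fit_model(_linear_cohort(slope=0.0), ModelSpec())
        assert percent_change_over_window(fitted, (40, 80)) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_linear_loss(self):
        # prediction 0.8 at age 40, slope -0.004/yr -> -20% over [40, 80]
        fitted = fit_model(
            _linear_cohort(intercept=0.8, slope=-0.004), ModelSpec(group=None)
        )
        assert percent_change_over_window(fitted, (40, 80)) == pytest.approx(-20.0, abs=1e-6)

    def test_negative_slope_gives_negative_percent(self):
        fitted = fit_model(_linear_cohort(slope=-0.002), ModelSpec())
        assert percent_change_over_window(fitted, (40, 80)) < 0


class TestDecadeAnova:
    def _decade_cohort(self, seed=0, shift=0.0, n_per=20):
        rng = np.random.default_rng(seed)
        rows = []
        for decade_lo in (40, 50, 60, 70):
            for diag in ("Pso", "PsA", "RA"):
                for i in range(n_per):
                    mu = 0.2 + (shift if diag == "RA" else 0.0)
                    rows.append(
                        {
                            "id": f"{diag}{decade_lo}{i}",
                            "sex": "male",
                            "diagnosis": diag,
                            "age": rng.uniform(decade_lo, decade_lo + 9.99),
                            "vh": 300.0,
                            "vmrel": rng.normal(mu, 0.01),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_values_give_no_signal(self):
        df = self._decade_cohort()
        df["vmrel"] = 0.2
        res = decade_anova(df, "vmrel")
        for dec in res.decades:
            assert dec.testable
            assert dec.anova_f == 0.0
            assert dec.anova_p == pytest.approx(1.0)
            for (_, _, md, _) in dec.pairwise:
                assert md == 0.0

    def test_overwhelming_separation_detected(self):
        df = self._decade_cohort(seed=1, shift=0.05)  # 5 pooled SDs
        res = decade_anova(df, "vmrel")
        for dec in res.decades:
            assert dec.anova_p < 0.001
            pair = {frozenset((a, b)): p for a, b, _, p in dec.pairwise}
            assert pair[frozenset(("RA", "Pso"))] < 0.001

    def test_pairwise_mean_differences_match_group_means(self):
        df = self._decade_cohort(seed=2, shift=0.03)
        res = decade_anova(df, "vmrel")
        for dec in res.decades:
            for a, b, md, _ in dec.pairwise:
                assert md == pytest.approx(
                    dec.group_means[a] - dec.group_means[b], abs=1e-12
                )

    def test_decade_partition_and_boundaries(self):
        df = self._decade_cohort(seed=3)
        # subjects exactly at 50 fall in the 6th decade; 80 in the 8th
        extra = pd.DataFrame(
            [
                {"id": "x50", "sex": "male", "diagnosis": "Pso", "age": 50.0,
                 "vh": 300.0, "vmrel": 0.2},
                {"id": "x80", "sex": "male", "diagnosis": "Pso", "age": 80.0,
                 "vh": 300.0, "vmrel": 0.2},
            ]
        )
        res = decade_anova(pd.concat([df, extra], ignore_index=True), "vmrel")
        decades = {tuple(d.decade): d for d in res.decades}
        assert sum(decades[(40, 50)].group_n.values()) == 60
        assert sum(decades[(50, 60)].group_n.values()) == 61
        assert sum(decades[(70, 80)].group_n.values()) == 61

    def test_sparse_decade_reported_not_testable(self):
        df = self._decade_cohort(seed=4)
        df = df[(df["age"] < 70) | (df["diagnosis"] == "Pso")]
        df = pd.concat([df[df["age"] < 70], df[(df["age"] >= 70)].head(3)])
        res = decade_anova(df, "vmrel")
        last = [d for d in res.decades if tuple(d.decade) == (70, 80)][0]
        assert not last.testable
        assert last.reason
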
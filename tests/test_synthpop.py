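import numpy as np
import pandas as pd
import pytest

from t2dsim.constants import BMI_CLASSES, WAIST_CLASSES
from t2dsim.synthpop import (
    InfeasibleCorrelationError,
    MarginalSpec,
    expand_population,
    generate_survey_fixture,
    ipf_joint,
    population_summary,
)


def one_group_spec(t2d_p=0.062, bmi=None, waist=None, n_target=500):
    """Single adult age group (35-64), one sex/province stratum."""
    counts = pd.DataFrame(
        [{"age_group": "35-64", "sex": "male", "province": "Antwerp", "count": n_target}]
    )
    bmi = bmi or [0.5, 0.3, 0.2]
    waist = waist or [0.4, 0.3, 0.3]
    prevalence = {
        "education": pd.DataFrame(
            [
                {"age_group": "35-64", "category": c, "p": p}
                for c, p in zip(["low", "intermediate", "high"], [0.2, 0.3, 0.5])
            ]
        ),
        "income": pd.DataFrame(
            [
                {"age_group": "35-64", "category": f"Q{i+1}", "p": 0.2}
                for i in range(5)
            ]
        ),
        "bmi_class": pd.DataFrame(
            [{"age_group": "35-64", "category": c, "p": p} for c, p in zip(BMI_CLASSES, bmi)]
        ),
        "waist_class": pd.DataFrame(
            [{"age_group": "35-64", "category": c, "p": p} for c, p in zip(WAIST_CLASSES, waist)]
        ),
        "bp_medication": pd.DataFrame(
            [{"age_group": "35-64", "category": c, "p": p} for c, p in zip(["no", "yes"], [0.85, 0.15])]
        ),
        "high_glucose_history": pd.DataFrame(
            [{"age_group": "35-64", "category": c, "p": p} for c, p in zip(["no", "yes"], [0.95, 0.05])]
        ),
        "t2d": pd.DataFrame(
            [{"age_group": "35-64", "category": c, "p": p} for c, p in zip(["no", "yes"], [1 - t2d_p, t2d_p])]
        ),
    }
    return MarginalSpec(counts=counts, prevalence=prevalence, year=2018)


class TestSurveyFixture:
    def test_t2d_marginal_within_monte_carlo_error(self):
        spec = one_group_spec(t2d_p=0.062)
        survey = generate_survey_fixture(spec, None, 10_000, seed=5)
        frac = survey["t2d"].mean()
        se = np.sqrt(0.062 * (1 - 0.062) / 10_000)
        assert abs(frac - 0.062) < 3 * se

    def test_degenerate_distributions_yield_identical_individuals(self):
        spec = one_group_spec(t2d_p=0.0, bmi=[1.0, 0.0, 0.0], waist=[1.0, 0.0, 0.0])
        spec.prevalence["education"] = pd.DataFrame(
            [{"age_group": "35-64", "category": "high", "p": 1.0}]
        )
        survey = generate_survey_fixture(spec, None, 200, seed=1)
        for col in ["education", "bmi_class", "waist_class", "t2d"]:
            assert survey[col].nunique() == 1

    def test_configured_odds_ratio_against_joint_oracle(self):
        bmi_p = np.array([0.5, 0.3, 0.2])
        waist_p = np.array([0.4, 0.3, 0.3])
        spec = one_group_spec(bmi=list(bmi_p), waist=list(waist_p))
        config = [{"source": "bmi_class", "target": "waist_class", "odds": 3.0}]
        n = 60_000
        survey = generate_survey_fixture(spec, config, n, seed=7)

        # independent brute-force construction of the configured joint:
        # proportional fitting of seed odds**(s_i*t_j) to the two margins
        seed_mat = np.array([[3.0 ** (si * tj / 4.0) for tj in range(3)] for si in range(3)])
        joint = seed_mat * np.outer(bmi_p, waist_p)
        for _ in range(2000):
            joint *= (bmi_p / joint.sum(axis=1))[:, None]
            joint *= (waist_p / joint.sum(axis=0))[None, :]
        # extreme-cell odds ratio of the oracle joint equals the config
        oracle_or = (joint[2, 2] * joint[0, 0]) / (joint[2, 0] * joint[0, 2])
        assert oracle_or == pytest.approx(3.0, rel=1e-6)

        tab = pd.crosstab(survey["bmi_class"], survey["waist_class"])
        a = tab.loc["gt30", "high"]
        b = tab.loc["gt30", "low"]
        c = tab.loc["lt25", "high"]
        d = tab.loc["lt25", "low"]
        sample_or = (a * d) / (b * c)
        assert sample_or > 1
        se_log_or = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(np.log(sample_or) - np.log(oracle_or)) < 3 * se_log_or
        # marginals preserved despite the association
        se = np.sqrt(waist_p[2] * (1 - waist_p[2]) / n)
        assert abs((survey["waist_class"] == "high").mean() - waist_p[2]) < 3 * se

    def test_infeasible_correlation_names_the_cell(self):
        spec = one_group_spec(bmi=[1.0, 0.0, 0.0])
        config = [{"source": "bmi_class", "target": "waist_class", "odds": 3.0}]
        with pytest.raises(InfeasibleCorrelationError, match="bmi_class=lt25"):
            generate_survey_fixture(spec, config, 500, seed=1)

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError, match="n must be"):
            generate_survey_fixture(one_group_spec(), None, 50, seed=0)

    def test_determinism(self):
        spec = one_group_spec()
        a = generate_survey_fixture(spec, None, 500, seed=3)
        b = generate_survey_fixture(spec, None, 500, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestIpfJoint:
    def test_margins_exact(self):
        j = ipf_joint([0.2, 0.8], [0.5, 0.5], odds=4.0)
        assert np.allclose(j.sum(axis=1), [0.2, 0.8], atol=1e-10)
        assert np.allclose(j.sum(axis=0), [0.5, 0.5], atol=1e-10)

    def test_odds_one_gives_independence(self):
        j = ipf_joint([0.3, 0.7], [0.6, 0.4], odds=1.0)
        assert np.allclose(j, np.outer([0.3, 0.7], [0.6, 0.4]))


class TestExpandPopulation:
    def test_exact_count_conservation(self):
        spec = one_group_spec(n_target=5)
        survey = generate_survey_fixture(spec, None, 200, seed=2)
        pop = expand_population(survey.head(2), spec, seed=4)
        assert len(pop) == 5
        donor_ages = set(survey.head(2)["age"])
        assert set(pop["age"]).issubset(donor_ages)

    def test_single_donor_weight_irrelevant(self):
        spec = one_group_spec(n_target=100)
        survey = generate_survey_fixture(spec, None, 200, seed=2).head(1).copy()
        survey["weight"] = 7.3
        pop = expand_population(survey, spec, seed=0)
        assert len(pop) == 100
        assert pop["age"].nunique() == 1
        assert pop["id"].is_unique

    def test_weighted_sampling_binomial_oracle(self):
        spec = one_group_spec(n_target=10_000)
        survey = generate_survey_fixture(spec, None, 200, seed=2).head(2).copy()
        survey["weight"] = [3.0, 1.0]
        survey["age"] = [40, 50]  # distinguishable donors
        pop = expand_population(survey, spec, seed=9)
        frac = (pop["age"] == 40).mean()
        se = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(frac - 0.75) < 3 * se

    def test_empty_stratum_fails_with_name(self):
        spec = one_group_spec()
        survey = generate_survey_fixture(spec, None, 200, seed=2)
        survey["age"] = 20  # move every donor out of the target stratum
        with pytest.raises(ValueError, match="35-64"):
            expand_population(survey, spec, seed=0)

    def test_determinism_byte_identical(self):
        spec = one_group_spec(n_target=300)
        survey = generate_survey_fixture(spec, None, 200, seed=2)
        a = expand_population(survey, spec, seed=8)
        b = expand_population(survey, spec, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestPopulationSummary:
    def test_shares_sum_to_one(self, small_population):
        s = population_summary(small_population, ["age_group", "sex"])
        sums = s.groupby(["age_group", "sex", "variable"])["share"].sum()
        assert np.allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_unknown_grouping_rejected(self, small_population):
        with pytest.raises(ValueError, match="unknown grouping"):
            population_summary(small_population, ["shoe_size"])

    def test_single_individual_shares_are_unit(self, small_population):
        s = population_summary(small_population.head(1), [])
        assert set(s["share"]) == {1.0}

    def test_empty_strata_absent_not_zero(self, small_population):
        sub = small_population[small_population["region"] == "Flanders"]
        s = population_summary(sub, ["region"])
        assert set(s["region"]) == {"Flanders"}


class TestCalibrationAgreement:
    def test_marginal_recovery_large_n(self):
        from t2dsim.defaults import default_marginals
        from t2dsim.synthpop import generate_survey_fixture

        spec = default_marginals(scale=100)
        survey = generate_survey_fixture(spec, None, 20_000, seed=21)
        pop = expand_population(survey, spec, seed=22)
        assert len(pop) == spec.counts["count"].sum()
        # expanded prevalence tracks the donor sample's weighted prevalence
        for var in ["bmi_class", "t2d"]:
            survey_s = population_summary(survey, ["age_group"], [var], weight_col="weight")
            pop_s = population_summary(pop, ["age_group"], [var])
            merged = survey_s.merge(
                pop_s, on=["age_group", "variable", "category"], suffixes=("_survey", "_pop")
            )
            for row in merged.itertuples():
                p = row.share_survey
                se = max(np.sqrt(p * (1 - p) / 20_000), 1e-4)
                assert abs(row.share_pop - p) < 6 * se

    def test_icc_generated_vs_target_above_095(self):
        from t2dsim.defaults import DEFAULT_CORRELATION, default_marginals
        from t2dsim.inequality import icc_agreement

        spec = default_marginals(scale=500)
        survey = generate_survey_fixture(spec, DEFAULT_CORRELATION, 8_000, seed=31)
        pop = expand_population(survey, spec, seed=32)
        summary = population_summary(pop, ["age_group"])
        gen, target = [], []
        for row in summary.itertuples():
            if row.variable not in spec.prevalence:
                continue
            sub = spec.prevalence[row.variable]
            match = sub[(sub["age_group"] == row.age_group) & (sub["category"] == row.category)]
            if len(match):
                gen.append(row.share)
                target.append(float(match["p"].iloc[0]))
        icc, _ = icc_agreement(np.array(gen), np.array(target))
        assert icc > 0.95
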
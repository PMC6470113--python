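"""Steps 1-4 of the estimation procedure and the full weighted pipeline."""

import numpy as np
import pandas as pd
import pytest

import fifteend as f
from conftest import random_truth


def means_table(per_dim: dict) -> pd.DataFrame:
    """Build a level-means frame from {dim: (m2, m3, m4, m5, m_dead)}."""
    idx = pd.Index([1, 2, 3, 4, 5, f.DEAD], name="level")
    data = {d: [100.0, *vals] for d, vals in per_dim.items()}
    return pd.DataFrame(data, index=idx)


class TestRelativeScores:
    def test_direct_substitution(self):
        S = f.relative_scores(means_table({"mobility": (50, 50, 50, 50, 0)}))
        assert S.at[2, "mobility"] == pytest.approx(0.5)

    def test_level_at_100_scores_zero(self):
        S = f.relative_scores(means_table({"vision": (100, 90, 80, 70, 60)}))
        assert S.at[2, "vision"] == 0.0

    def test_level_below_dead_exceeds_one(self):
        S = f.relative_scores(means_table({"hearing": (50, 40, 20, 5, 10)}))
        assert S.at[5, "hearing"] == pytest.approx(95 / 90)

    def test_dead_near_100_rejected(self):
        with pytest.raises(ValueError, match="sleep"):
            f.relative_scores(means_table({"sleep": (50, 40, 30, 20, 99.5)}))


class TestPitsEstimate:
    @staticmethod
    def pits_frame(pairs):
        return pd.DataFrame(
            {
                "respondent_id": [f"p{i}" for i in range(len(pairs))],
                "score_pits": [p for p, _ in pairs],
                "score_dead": [d for _, d in pairs],
            }
        )

    def test_direct_substitution(self):
        est = f.pits_estimate(self.pits_frame([(20, 10)]))
        assert est.v_pits == pytest.approx(80 / 90)

    def test_pits_at_dead_gives_one(self):
        est = f.pits_estimate(self.pits_frame([(10, 10)]))
        assert est.v_pits == pytest.approx(1.0)

    def test_pits_below_dead_exceeds_one(self):
        est = f.pits_estimate(self.pits_frame([(5, 10)]))
        assert est.v_pits > 1

    def test_incomplete_responses_do_not_contribute(self):
        frame = self.pits_frame([(20, 10), (np.nan, 50), (60, np.nan)])
        est = f.pits_estimate(frame)
        assert est.n_complete == 1 and est.n_excluded == 2
        assert est.v_pits == pytest.approx(80 / 90)


class TestCompletenessFilter:
    def test_two_of_120_dropped(self):
        frame = TestPitsEstimate.pits_frame([(30.0, 10.0)] * 120)
        frame.loc[5, "score_pits"] = np.nan
        frame.loc[17, "score_dead"] = np.nan
        complete, excluded = f.filter_complete_pits(frame)
        assert len(complete) == 118 and excluded == 2

    def test_all_complete_is_identity(self):
        frame = TestPitsEstimate.pits_frame([(30.0, 10.0)] * 7)
        complete, excluded = f.filter_complete_pits(frame)
        assert len(complete) == 7 and excluded == 0

    def test_all_incomplete_gives_empty(self):
        frame = TestPitsEstimate.pits_frame([(np.nan, 10.0)] * 4)
        complete, excluded = f.filter_complete_pits(frame)
        assert complete.empty and excluded == 4


class TestWeightedLevelMeans:
    @staticmethod
    def within_frame(rows):
        return pd.DataFrame(
            rows,
            columns=["respondent_id", "dimension", "score_L2", "score_L3",
                     "score_L4", "score_L5", "score_dead"],
        )

    def test_equal_weights_arithmetic_mean(self):
        frame = self.within_frame(
            [("a", "mobility", 80, 40, 30, 20, 10), ("b", "mobility", 80, 60, 30, 20, 10)]
        )
        means = f.weighted_level_means(frame)
        assert means.at[3, "mobility"] == pytest.approx(50)
        assert means.at[1, "mobility"] == 100.0

    def test_unequal_weights(self):
        frame = self.within_frame(
            [("a", "mobility", 0, 0, 0, 0, 0), ("b", "mobility", 100, 100, 100, 100, 0)]
        )
        weights = pd.DataFrame(
            {"task_id": ["mobility"] * 2, "respondent_id": ["a", "b"], "weight": [3.0, 1.0]}
        )
        means = f.weighted_level_means(frame, weights)
        assert means.at[2, "mobility"] == pytest.approx(25)

    def test_partial_responses_contribute_to_answered_cells(self):
        frame = self.within_frame(
            [("a", "vision", 80, np.nan, 30, 20, 10), ("b", "vision", 60, 50, 30, 20, 10)]
        )
        means = f.weighted_level_means(frame)
        assert means.at[2, "vision"] == pytest.approx(70)
        assert means.at[3, "vision"] == pytest.approx(50)
        # complete-case mode drops respondent "a" everywhere
        cc = f.weighted_level_means(frame, complete_case=True)
        assert cc.at[2, "vision"] == pytest.approx(60)

    def test_empty_cell_is_an_error(self):
        frame = self.within_frame([("a", "vision", 80, np.nan, 30, 20, 10)])
        with pytest.raises(ValueError, match="vision"):
            f.weighted_level_means(frame)


class TestBuildAlgorithm:
    def test_closed_form_rescaling(self):
        S = pd.DataFrame(
            1.0, index=[2, 3, 4, 5], columns=list(f.DIMENSIONS)
        ).reindex([1, 2, 3, 4, 5], fill_value=0.0)
        algo = f.build_algorithm(S, 1.5)
        assert algo.omega == pytest.approx(0.1)
        assert algo.T.at[5, "mobility"] == pytest.approx(0.1)

    def test_identity_when_v_pits_equals_s5_sum(self, norwegian):
        S = norwegian.T
        algo = f.build_algorithm(S, float(S.loc[5].sum()))
        assert algo.omega == pytest.approx(1.0)
        pd.testing.assert_frame_equal(algo.T, S)

    def test_level5_row_reproduces_v_pits(self):
        S = random_truth(9).T
        algo = f.build_algorithm(S, 1.23)
        assert algo.level5_sum == pytest.approx(1.23, abs=1e-12)


def test_scale_equivariance_of_relative_scores():
    """S is invariant under score -> 100 - c*(100 - score) on a whole task."""
    base = means_table({"eating": (80.0, 60.0, 40.0, 20.0, 30.0)})
    S0 = f.relative_scores(base)
    for c in (0.25, 0.5, 0.9):
        mapped = means_table(
            {"eating": tuple(100 - c * (100 - v) for v in (80.0, 60.0, 40.0, 20.0, 30.0))}
        )
        S1 = f.relative_scores(mapped)
        pd.testing.assert_frame_equal(S0, S1)


@pytest.fixture(scope="module")
def noise_free(norwegian):
    config = f.GeneratorConfig(
        truth=norwegian, seed=20, n_respondents=250, n_pits=120,
        noise_sd=0.0, missing_rate=0.0,
    )
    return f.simulate_dataset(config)


class TestFullPipeline:
    def test_noise_free_recovery(self, noise_free, norwegian, population):
        result = f.estimate_algorithm(
            noise_free.within, noise_free.pits, noise_free.demographics,
            population, scheme="marginal",
        )
        err = (result.algorithm.T - norwegian.T).abs().to_numpy().max()
        assert err < 1e-9

    def test_anchoring_identities(self, noise_free, population):
        result = f.estimate_algorithm(
            noise_free.within, noise_free.pits, noise_free.demographics,
            population, scheme="marginal",
        )
        algo = result.algorithm
        assert f.score_state(f.PERFECT_HEALTH, algo).value == 1.0
        pits_value = f.score_state(f.PITS_STATE, algo).value
        assert pits_value == pytest.approx(1 - result.pits.v_pits, abs=1e-9)

    def test_duplicating_every_respondent_changes_nothing(self, noise_free, population):
        def dup(df):
            copy = df.copy()
            copy["respondent_id"] = copy["respondent_id"] + "_dup"
            return pd.concat([df, copy], ignore_index=True)

        base = f.estimate_algorithm(
            noise_free.within, noise_free.pits, noise_free.demographics,
            population, scheme="marginal",
        )
        doubled = f.estimate_algorithm(
            dup(noise_free.within), dup(noise_free.pits), dup(noise_free.demographics),
            population, scheme="marginal",
        )
        pd.testing.assert_frame_equal(base.algorithm.T, doubled.algorithm.T)

    def test_missing_dimension_task_named_in_error(self, noise_free, population):
        within = noise_free.within[noise_free.within["dimension"] != "speech"]
        with pytest.raises(ValueError, match="speech"):
            f.estimate_algorithm(
                within, noise_free.pits, noise_free.demographics,
                population, scheme="marginal",
            )

    def test_log_records_audit_trail(self, noise_free, population):
        result = f.estimate_algorithm(
            noise_free.within, noise_free.pits, noise_free.demographics,
            population, scheme="marginal",
        )
        log = result.log
        assert log["completers_per_task"]["mobility"] == 250
        assert log["pits_complete"] == 120
        assert log["pits_weight_variables"] == ["gender", "age_group"]
        assert log["omega"] > 0 and log["v_pits"] > 0


def test_weighting_brings_estimate_closer_to_population_mixture(norwegian, population):
    """With education-specific preferences and a skewed sample, weighted
    estimates land nearer the population-mixture truth than unweighted ones."""
    skew = population.copy()
    skew.loc[skew["variable"] == "education", "count"] = [100, 300, 800, 700, 50]
    scaled_dims = ("mental_function", "depression", "distress")
    scales = {"university_ba": 1.5, "university_ma": 1.5}
    config = f.GeneratorConfig(
        truth=norwegian, seed=3, n_respondents=2000, n_pits=1000,
        noise_sd=0.0, dead_location=50.0, demographics_margins=skew,
        preference_scale_by_education=scales, scaled_dimensions=scaled_dims,
    )
    data = f.simulate_dataset(config)
    weighted = f.estimate_algorithm(
        data.within, data.pits, data.demographics, population, scheme="marginal"
    )
    unweighted = f.estimate_algorithm(
        data.within, data.pits, data.demographics, skew, scheme="marginal"
    )
    edu = f.population_margins(population)["education"]
    mean_scale = sum(edu[e] * scales.get(e, 1.0) for e in edu.index)
    mixture = norwegian.T.copy()
    for dim in scaled_dims:
        mixture[dim] = mixture[dim] * mean_scale

    def rmse(result):
        return float(np.sqrt(((result.algorithm.T - mixture) ** 2).to_numpy().mean()))

    assert rmse(weighted) < rmse(unweighted)
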
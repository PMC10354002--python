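"""Synthetic choice data, the conditional-logit MLE, and parameter recovery."""

import math

import numpy as np
import pytest

import dce_cea as dc
from dce_cea.choice_model import InputError
from dce_cea.synthetic import DesignError, EstimationError


@pytest.fixture(scope="module")
def small_dataset(coeffs):
    design = dc.generate_design(coeffs, n_respondents=200, n_tasks=8, seed=11)
    return dc.simulate_choices(design, coeffs, seed=12)


class TestGenerateDesign:
    def test_deterministic_given_seed(self, coeffs):
        a = dc.generate_design(coeffs, 20, 4, seed=5)
        b = dc.generate_design(coeffs, 20, 4, seed=5)
        assert np.array_equal(a.X, b.X)
        c = dc.generate_design(coeffs, 20, 4, seed=6)
        assert not np.array_equal(a.X, c.X)

    def test_task_count_is_respondents_times_tasks(self, coeffs):
        design = dc.generate_design(coeffs, 805, 8, seed=1)
        assert len(design) == 6440
        assert design.X.shape == (6440, 2, 6)

    def test_no_task_has_identical_alternatives(self, coeffs):
        design = dc.generate_design(coeffs, 300, 8, seed=2)
        identical = (design.X == design.X[:, :1, :]).all(axis=(1, 2))
        assert not identical.any()

    def test_degenerate_design_space_rejected(self):
        cs = dc.CoefficientSet([])
        with pytest.raises(DesignError):
            dc.generate_design(cs, 10, 2, seed=0)

    def test_fewer_than_two_alternatives_rejected(self, coeffs):
        with pytest.raises(InputError):
            dc.generate_design(coeffs, 10, 2, n_alternatives=1, seed=0)


class TestSimulateChoices:
    def test_null_coefficients_give_uniform_shares(self):
        cs = dc.CoefficientSet(
            [dc.AttributeLevel(f"a{i}", f"l{i}", 0.0, 0.01) for i in range(3)]
        )
        design = dc.generate_design(cs, 2500, 2, n_alternatives=2, seed=3)
        dataset = dc.simulate_choices(design, cs, seed=4)
        share = (dataset.chosen == 0).mean()
        n = len(dataset)
        assert abs(share - 0.5) <= 3 * math.sqrt(0.25 / n)

    def test_dominant_alternative_always_chosen(self):
        cs = dc.CoefficientSet([dc.AttributeLevel("x", "on", 10.0, 0.1)])
        X = np.zeros((2000, 2, 1))
        X[:, 0, 0] = 1.0  # alternative 0 carries utility +10
        design = dc.ChoiceDesign(
            X=X, column_names=("x:on",), n_respondents=2000, tasks_per_respondent=1, seed=0
        )
        dataset = dc.simulate_choices(design, cs, seed=5)
        assert (dataset.chosen == 0).mean() >= 0.9999

    def test_binary_contrast_matches_inverse_logit(self):
        cs = dc.CoefficientSet([dc.AttributeLevel("x", "on", 0.19, 0.1)])
        n = 40_000
        X = np.zeros((n, 2, 1))
        X[:, 0, 0] = 1.0
        design = dc.ChoiceDesign(
            X=X, column_names=("x:on",), n_respondents=n, tasks_per_respondent=1, seed=0
        )
        dataset = dc.simulate_choices(design, cs, seed=6)
        expected = 1 / (1 + math.exp(-0.19))  # ~0.547
        share = (dataset.chosen == 0).mean()
        assert abs(share - expected) <= 3 * math.sqrt(expected * (1 - expected) / n)

    def test_long_format_round_trips_choices(self, small_dataset):
        df = small_dataset.to_frame()
        assert df["chosen"].sum() == len(small_dataset)
        assert set(df.columns) >= {"respondent", "task", "alternative", "chosen"}


class TestLoglik:
    @pytest.mark.parametrize("n_alt", [2, 3])
    def test_null_loglik_closed_form(self, coeffs, n_alt):
        design = dc.generate_design(coeffs, 50, 4, n_alternatives=n_alt, seed=7)
        dataset = dc.simulate_choices(design, coeffs, seed=8)
        ll = dc.conditional_logit_loglik(np.zeros(len(coeffs)), dataset)
        assert ll == pytest.approx(-len(dataset) * math.log(n_alt))

    def test_truth_beats_a_distant_shift(self, small_dataset, coeffs):
        truth = np.array([lv.coefficient for lv in coeffs.levels])
        shifted = truth.copy()
        shifted[0] += 5.0
        assert dc.conditional_logit_loglik(
            truth, small_dataset
        ) > dc.conditional_logit_loglik(shifted, small_dataset)

    def test_shift_invariance_within_task(self, small_dataset, coeffs):
        # adding a constant to every alternative's utility in a task cannot
        # change the likelihood; emulate via a column shared by all
        # alternatives and an arbitrary coefficient on it
        X = small_dataset.design.X
        ones = np.ones((*X.shape[:2], 1))
        design2 = dc.ChoiceDesign(
            X=np.concatenate([X, ones], axis=2),
            column_names=(*small_dataset.design.column_names, "const"),
            n_respondents=small_dataset.design.n_respondents,
            tasks_per_respondent=small_dataset.design.tasks_per_respondent,
            seed=0,
        )
        ds2 = dc.ChoiceDataset(design=design2, chosen=small_dataset.chosen)
        beta = np.array([lv.coefficient for lv in coeffs.levels])
        for const in (0.0, 1.7, -3.2):
            assert dc.conditional_logit_loglik(
                np.append(beta, const), ds2
            ) == pytest.approx(dc.conditional_logit_loglik(beta, small_dataset))

    def test_dimension_mismatch_rejected(self, small_dataset):
        with pytest.raises(InputError):
            dc.conditional_logit_loglik(np.zeros(2), small_dataset)


class TestFit:
    def test_null_data_recovers_zero(self):
        cs = dc.CoefficientSet(
            [dc.AttributeLevel(f"a{i}", f"l{i}", 0.0, 0.01) for i in range(4)]
        )
        design = dc.generate_design(cs, 600, 8, seed=21)
        dataset = dc.simulate_choices(design, cs, seed=22)
        fit = dc.fit_conditional_logit(dataset)
        for lv in fit.estimates.levels:
            assert abs(lv.coefficient) <= 3 * lv.std_error

    def test_matches_statsmodels_binary_logit(self, small_dataset):
        # for 2-alternative tasks the conditional logit equals a binary
        # logit on differenced covariates — independent cross-check
        sm = pytest.importorskip("statsmodels.api")
        X = small_dataset.design.X
        diff = X[:, 0, :] - X[:, 1, :]
        y = (small_dataset.chosen == 0).astype(int)
        reference = sm.Logit(y, diff).fit(disp=0)
        fit = dc.fit_conditional_logit(small_dataset)
        ours = np.array([lv.coefficient for lv in fit.estimates.levels])
        ses = np.array([lv.std_error for lv in fit.estimates.levels])
        assert ours == pytest.approx(reference.params, abs=1e-6)
        assert ses == pytest.approx(reference.bse, abs=1e-6)

    def test_coding_flip_negates_estimate(self, coeffs):
        design = dc.generate_design(coeffs, 300, 8, seed=31)
        dataset = dc.simulate_choices(design, coeffs, seed=32)
        fit = dc.fit_conditional_logit(dataset)
        flipped_X = dataset.design.X.copy()
        flipped_X[:, :, 0] = 1.0 - flipped_X[:, :, 0]
        flipped = dc.ChoiceDataset(
            design=dc.ChoiceDesign(
                X=flipped_X,
                column_names=dataset.design.column_names,
                n_respondents=dataset.design.n_respondents,
                tasks_per_respondent=dataset.design.tasks_per_respondent,
                seed=0,
            ),
            chosen=dataset.chosen,
        )
        refit = dc.fit_conditional_logit(flipped)
        assert refit.estimates.levels[0].coefficient == pytest.approx(
            -fit.estimates.levels[0].coefficient, abs=1e-6
        )

    def test_collinear_columns_named(self, small_dataset):
        X = small_dataset.design.X
        doubled = np.concatenate([X, X[:, :, :1]], axis=2)
        dataset = dc.ChoiceDataset(
            design=dc.ChoiceDesign(
                X=doubled,
                column_names=(*small_dataset.design.column_names, "copy"),
                n_respondents=small_dataset.design.n_respondents,
                tasks_per_respondent=small_dataset.design.tasks_per_respondent,
                seed=0,
            ),
            chosen=small_dataset.chosen,
        )
        with pytest.raises(EstimationError, match="rank deficient"):
            dc.fit_conditional_logit(dataset)

    def test_perfect_separation_raises_not_diverges(self):
        cs = dc.CoefficientSet([dc.AttributeLevel("x", "on", 1.0, 0.1)])
        X = np.zeros((200, 2, 1))
        X[:, 0, 0] = 1.0
        design = dc.ChoiceDesign(
            X=X, column_names=("x:on",), n_respondents=200, tasks_per_respondent=1, seed=0
        )
        dataset = dc.ChoiceDataset(design=design, chosen=np.zeros(200, dtype=int))
        with pytest.raises(EstimationError):
            dc.fit_conditional_logit(dataset)


class TestRecovery:
    def test_summary_deterministic_given_seed(self, coeffs):
        a = dc.recovery_experiment(coeffs, n_reps=3, seed=9, n_respondents=100, n_tasks=4)
        b = dc.recovery_experiment(coeffs, n_reps=3, seed=9, n_respondents=100, n_tasks=4)
        assert a.equals(b)

    def test_bias_shrinks_with_sample_size(self, coeffs):
        small = dc.recovery_experiment(
            coeffs, n_reps=30, seed=13, n_respondents=100, n_tasks=4
        )
        large = dc.recovery_experiment(
            coeffs, n_reps=30, seed=13, n_respondents=400, n_tasks=4
        )
        # root-n consistency: the empirical SE roughly halves
        ratio = large["empirical_se"].mean() / small["empirical_se"].mean()
        assert 0.35 <= ratio <= 0.65

    def test_fewer_than_two_reps_rejected(self, coeffs):
        with pytest.raises(InputError):
            dc.recovery_experiment(coeffs, n_reps=1, seed=1)
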
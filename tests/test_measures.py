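"""The nine relevance measures, the scaling function, and the registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epirel.beliefs import BetaBelief, MeasureParams
from epirel.measures import (
    DEFAULT_PARAMS,
    MEASURE_NAMES,
    bayes_factor_polar,
    bayes_factor_utility,
    commitment_change,
    concentration_change,
    entropy_change,
    evaluate_all_measures,
    evaluate_measure,
    generalized_bayes_factor_utility,
    kl_utility,
    probability_change,
    scale_g,
    second_order_bayes_factor_utility,
    second_order_entropy_change,
    second_order_kl_utility,
)

E = math.e


class TestScaleG:
    def test_anchors(self):
        assert scale_g(0.0, 2.0) == 0.0
        assert scale_g(1.0, E) == pytest.approx(1 - 1 / E)
        assert scale_g(np.inf, 2.0) == 1.0

    def test_strictly_increasing(self):
        assert scale_g(2.0, 2.0) > scale_g(1.0, 2.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            scale_g(-0.1, 2.0)
        with pytest.raises(ValueError):
            scale_g(1.0, 1.0)


class TestPureMeasures:
    def test_probability_change(self):
        assert probability_change(0.63, 0.76) == pytest.approx(0.13)
        assert probability_change(0.4, 0.4) == 0.0
        assert probability_change(0.0, 1.0) == 1.0
        with pytest.raises(ValueError):
            probability_change(1.2, 0.5)

    def test_commitment_change(self):
        assert commitment_change(3, 4) == 1.0
        assert commitment_change(5, 5) == 0.0
        assert commitment_change(1, 7) == 6.0
        with pytest.raises(ValueError):
            commitment_change(0, 4)

    def test_concentration_change(self):
        b = BetaBelief(3, 2)
        assert concentration_change(b, b, 1.19) == 0.0
        prior = BetaBelief(2, 2)  # kappa 4
        post = BetaBelief(6, 4)  # kappa 10
        expected = 1.0 - 1.19 ** -6.0
        assert concentration_change(prior, post, 1.19) == pytest.approx(expected)
        assert concentration_change(post, prior, 1.19) == pytest.approx(expected)


class TestEntropyChange:
    def test_swapped_probabilities_are_invisible(self):
        # mirrored distributions keep the entropy: a known failure mode
        for p in (0.1, 0.3, 0.42):
            assert entropy_change([p, 1 - p], [1 - p, p], 2.0) == 0.0

    def test_closed_form_binary(self):
        val = entropy_change([0.5, 0.5], [1.0, 0.0], E)
        assert val == pytest.approx(1 - math.exp(-math.log(2)))  # = 0.5

    def test_second_order_variant(self):
        b = BetaBelief(3, 3)
        assert second_order_entropy_change(b, b, 2.0) == 0.0
        v = second_order_entropy_change(BetaBelief(2, 2), BetaBelief(10, 10), 2.0)
        assert v > 0.0
        assert second_order_entropy_change(
            BetaBelief(10, 10), BetaBelief(2, 2), 2.0
        ) == pytest.approx(v)


class TestKLUtility:
    def test_identical_is_zero(self):
        assert kl_utility([0.3, 0.7], [0.3, 0.7], 2.0) == 0.0

    def test_certain_prior_is_maximal(self):
        assert kl_utility([1.0, 0.0], [0.5, 0.5], 2.0) == 1.0
        assert kl_utility([0.0, 1.0], [0.5, 0.5], 2.0) == 1.0

    def test_hand_summed_divergence(self):
        kl = 0.9 * math.log(0.9 / 0.5) + 0.1 * math.log(0.1 / 0.5)
        val = kl_utility([0.5, 0.5], [0.9, 0.1], E)
        assert kl == pytest.approx(0.36806, abs=1e-5)
        assert val == pytest.approx(1 - math.exp(-kl))

    def test_second_order_variant(self):
        b = BetaBelief(2, 2)
        assert second_order_kl_utility(b, b, 2.0) == 0.0
        assert second_order_kl_utility(b, BetaBelief(6, 2), 2.0) > 0.0
        x, y = BetaBelief(5, 2), BetaBelief(2, 2)
        assert second_order_kl_utility(x, y, 2.0) != pytest.approx(
            second_order_kl_utility(y, x, 2.0)
        )


class TestBayesFactor:
    def test_polar_odds(self):
        assert bayes_factor_polar(0.5, 0.75) == pytest.approx(3.0)
        assert bayes_factor_polar(0.75, 0.5) == pytest.approx(1 / 3)
        assert math.log(bayes_factor_polar(0.25, 0.25)) == 0.0

    def test_polar_boundary_raises(self):
        with pytest.raises(ValueError):
            bayes_factor_polar(0.0, 0.5)

    def test_utility_values(self):
        assert bayes_factor_utility(0.5, 0.75) == pytest.approx(2 / 3)
        assert bayes_factor_utility(0.4, 0.4) == 0.0
        assert bayes_factor_utility(0.3, 1.0) == 1.0
        assert bayes_factor_utility(0.0, 0.6) == 1.0

    def test_utility_symmetric_and_boundary_ties(self):
        assert bayes_factor_utility(0.2, 0.9) == pytest.approx(
            bayes_factor_utility(0.9, 0.2)
        )
        # no belief change dominates the resolved-boundary rule
        assert bayes_factor_utility(1.0, 1.0) == 0.0
        assert bayes_factor_utility(0.0, 0.0) == 0.0

    def test_second_order_inner_quantity(self):
        b = BetaBelief(3, 2)
        assert second_order_bayes_factor_utility(b, b, 1.14) == 0.0
        val = second_order_bayes_factor_utility(b, BetaBelief(6, 2), 1.14)
        assert val == pytest.approx(1 - 1.14 ** -math.log(4.0))
        assert second_order_bayes_factor_utility(
            BetaBelief(6, 2), b, 1.14
        ) == pytest.approx(val)

    def test_table_literal_variant(self):
        b = BetaBelief(3, 2)
        val = second_order_bayes_factor_utility(b, BetaBelief(6, 2), 1.14)
        lit = second_order_bayes_factor_utility(
            b, BetaBelief(6, 2), 1.14, table_literal=True
        )
        assert lit == pytest.approx(1 - val)


class TestGeneralizedBayesFactor:
    @pytest.mark.parametrize("p", [0.1, 0.35, 0.5, 0.8])
    @pytest.mark.parametrize("q", [0.05, 0.5, 0.9])
    def test_reduces_to_polar_for_two_alternatives(self, p, q):
        assert generalized_bayes_factor_utility(
            [p, 1 - p], [q, 1 - q]
        ) == pytest.approx(bayes_factor_utility(p, q))

    def test_resolved_four_alternative_question(self):
        assert generalized_bayes_factor_utility([0.25] * 4, [1, 0, 0, 0]) == 1.0

    def test_identical_vectors_give_zero(self):
        assert generalized_bayes_factor_utility([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            generalized_bayes_factor_utility([0.5, 0.5], [0.2, 0.3, 0.5])


NULL_TRIAL = {"p": 0.63, "c": 4, "q": 0.63, "d": 4}


class TestRegistry:
    def test_null_update_gives_all_zero(self):
        results = evaluate_all_measures(NULL_TRIAL)
        assert len(results) == 9
        for res in results:
            assert res.value == pytest.approx(0.0, abs=1e-12), res.name

    def test_worked_quintuple(self):
        trial = {"p": 0.63, "c": 3, "q": 0.76, "d": 4}
        values = {r.name: r.value for r in evaluate_all_measures(trial)}
        assert values["probability_change"] == pytest.approx(0.13)
        assert values["commitment_change"] == pytest.approx(1.0)

    def test_values_bounded(self):
        trial = {"p": 0.2, "c": 2, "q": 0.95, "d": 7}
        for res in evaluate_all_measures(trial):
            upper = 6.0 if res.name == "commitment_change" else 1.0
            assert 0.0 <= res.value <= upper, res.name

    def test_missing_fields_raise(self):
        with pytest.raises(ValueError):
            evaluate_all_measures({"p": 0.5, "q": 0.6})


@st.composite
def trials(draw):
    return dict(
        p=draw(st.floats(0.01, 0.99)),
        c=draw(st.integers(1, 7)),
        q=draw(st.floats(0.01, 0.99)),
        d=draw(st.integers(1, 7)),
    )


class TestProperties:
    @settings(deadline=None, max_examples=60)
    @given(trials())
    def test_null_update_law(self, trial):
        null = dict(p=trial["p"], c=trial["c"], q=trial["p"], d=trial["c"])
        for res in evaluate_all_measures(null):
            assert res.value == pytest.approx(0.0, abs=1e-9), res.name

    @settings(deadline=None, max_examples=60)
    @given(trials())
    def test_boundedness(self, trial):
        for res in evaluate_all_measures(trial):
            upper = 6.0 if res.name == "commitment_change" else 1.0
            assert -1e-12 <= res.value <= upper + 1e-12, res.name

    @settings(deadline=None, max_examples=60)
    @given(trials())
    def test_symmetry_classes(self, trial):
        swapped = dict(p=trial["q"], c=trial["d"], q=trial["p"], d=trial["c"])
        fwd = {r.name: r.value for r in evaluate_all_measures(trial)}
        rev = {r.name: r.value for r in evaluate_all_measures(swapped)}
        symmetric = (
            "probability_change",
            "commitment_change",
            "concentration_change",
            "entropy_change",
            "second_order_entropy_change",
            "bayes_factor_utility",
            "second_order_bayes_factor_utility",
        )
        for name in symmetric:
            assert fwd[name] == pytest.approx(rev[name], abs=1e-9), name

    def test_kl_asymmetry_witness(self):
        fwd = evaluate_measure("kl_utility", 0.9, 4, 0.5, 4)
        rev = evaluate_measure("kl_utility", 0.5, 4, 0.9, 4)
        assert fwd != pytest.approx(rev)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0.1, 5.0), st.floats(0.1, 5.0), st.floats(1.1, 10.0))
    def test_monotone_scaling(self, x1, dx, r):
        assert scale_g(x1 + dx, r) > scale_g(x1, r)
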
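"""Beta/Dirichlet belief algebra: conversions, entropies, divergences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from epirel.beliefs import (
    BetaBelief,
    FirstOrderBelief,
    MeasureParams,
    beta_from_mode_concentration,
    beta_mean,
    dirichlet_entropy,
    dirichlet_kl,
    link_commitment,
    shannon_entropy,
)

GRID = [1.5, 2.0, 3.0, 5.0, 10.0]


def quad_entropy(a, b):
    """Quadrature oracle for beta differential entropy."""
    pdf = stats.beta(a, b).pdf

    def integrand(x):
        f = pdf(x)
        return -f * np.log(f) if f > 0 else 0.0

    val, _ = integrate.quad(integrand, 0, 1, limit=200)
    return val


def quad_kl(post, prior):
    """Quadrature oracle for KL(post || prior) between beta densities."""
    f = stats.beta(*post).pdf
    g = stats.beta(*prior).pdf

    def integrand(x):
        fx = f(x)
        return fx * np.log(fx / g(x)) if fx > 0 else 0.0

    val, _ = integrate.quad(integrand, 0, 1, limit=200)
    return val


class TestModeConcentration:
    def test_symmetric_case(self):
        b = beta_from_mode_concentration(0.5, 4.0)
        assert b.alpha == pytest.approx(2.0) and b.beta == pytest.approx(2.0)

    def test_round_trip_example(self):
        b = beta_from_mode_concentration(0.6, 5.0)
        assert b.mode == pytest.approx(0.6, abs=1e-12)
        assert b.concentration == pytest.approx(5.0, abs=1e-12)

    def test_linked_concentration_inversion(self):
        # kappa = 1.49 * 1.52**3 = 5.23266592, alpha = 1 + 0.63*(kappa-2)
        kappa = 1.49 * 1.52**3
        b = beta_from_mode_concentration(0.63, kappa)
        assert b.alpha == pytest.approx(1.0 + 0.63 * (kappa - 2.0), rel=1e-12)
        assert b.beta == pytest.approx(1.0 + 0.37 * (kappa - 2.0), rel=1e-12)

    @pytest.mark.parametrize(
        "omega,kappa", [(0.5, 2.0), (0.5, 1.0), (1.5, 4.0), (-0.1, 4.0)]
    )
    def test_invalid_inputs_raise(self, omega, kappa):
        with pytest.raises(ValueError):
            beta_from_mode_concentration(omega, kappa)

    @settings(deadline=None, max_examples=200)
    @given(
        omega=st.floats(1e-3, 1 - 1e-3),
        kappa=st.floats(2.001, 500.0),
    )
    def test_round_trip_property(self, omega, kappa):
        b = beta_from_mode_concentration(omega, kappa, clamp=False)
        assert b.mode == pytest.approx(omega, abs=1e-12)
        assert b.concentration == pytest.approx(kappa, abs=1e-12)


class TestLinkCommitment:
    def test_arithmetic(self):
        assert link_commitment(3, MeasureParams(a_link=2.0, b_link=2.0)) == 16.0

    def test_table_parameters(self):
        # second-order Bayes factor linking at c = 2: 3.20 * 5.19**2
        val = link_commitment(2, MeasureParams(a_link=3.20, b_link=5.19))
        assert val == pytest.approx(3.20 * 5.19**2)

    def test_strictly_increasing(self):
        params = MeasureParams(a_link=1.49, b_link=1.52)
        vals = [link_commitment(c, params) for c in range(1, 8)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_floor_keeps_unimodality(self):
        # tiny a forces the raw kappa below 2; the floor rescues it
        assert link_commitment(1, MeasureParams(a_link=0.2, b_link=1.1)) > 2.0

    def test_out_of_scale_raises(self):
        with pytest.raises(ValueError):
            link_commitment(0, MeasureParams(a_link=2.0, b_link=2.0))


class TestBetaMoments:
    def test_mean_values(self):
        assert beta_mean(BetaBelief(3, 2)) == pytest.approx(0.6)
        assert beta_mean(BetaBelief(5, 3)) == pytest.approx(0.625)
        for k in (2, 3.7, 10):
            assert beta_mean(BetaBelief(k, k)) == pytest.approx(0.5)

    def test_mle_is_mode(self):
        # two red of three draws: mode of Beta(3, 2) is the frequency 2/3
        assert BetaBelief(3, 2).mode == pytest.approx(2 / 3)


class TestShannonEntropy:
    def test_values(self):
        assert shannon_entropy(FirstOrderBelief([1.0, 0.0])) == 0.0
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(np.log(2))
        assert shannon_entropy([0.1, 0.9]) == pytest.approx(0.3250829733914482)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_permutation_invariant_and_bounded(self, weights):
        probs = np.array(weights) / np.sum(weights)
        h = shannon_entropy(probs)
        rng = np.random.default_rng(0)
        assert shannon_entropy(rng.permutation(probs)) == pytest.approx(h)
        assert 0.0 <= h <= np.log(probs.size) + 1e-12


class TestDirichletEntropy:
    def test_uniform_density(self):
        assert dirichlet_entropy(BetaBelief(1, 1, strict=False)) == pytest.approx(0.0)

    @pytest.mark.parametrize("a", GRID)
    @pytest.mark.parametrize("b", GRID)
    def test_matches_quadrature(self, a, b):
        assert dirichlet_entropy(BetaBelief(a, b)) == pytest.approx(
            quad_entropy(a, b), abs=1e-6
        )


class TestDirichletKL:
    def test_zero_iff_identical(self):
        assert dirichlet_kl(BetaBelief(3, 2), BetaBelief(3, 2)) == 0.0
        for a in GRID:
            for b in GRID:
                kl = dirichlet_kl(BetaBelief(a, b), BetaBelief(3, 3))
                assert kl >= 0.0
                if (a, b) != (3, 3):
                    assert kl > 0.0

    def test_matches_quadrature(self):
        assert dirichlet_kl(BetaBelief(4, 2), BetaBelief(2, 2)) == pytest.approx(
            quad_kl((4, 2), (2, 2)), abs=1e-6
        )

    def test_asymmetry(self):
        fwd = dirichlet_kl(BetaBelief(2, 4), BetaBelief(4, 2))
        rev = dirichlet_kl(BetaBelief(4, 2), BetaBelief(2, 4))
        assert fwd == pytest.approx(quad_kl((2, 4), (4, 2)), abs=1e-6)
        assert rev == pytest.approx(quad_kl((4, 2), (2, 4)), abs=1e-6)
        assert fwd == pytest.approx(rev)  # this particular mirrored pair is equal
        other = dirichlet_kl(BetaBelief(5, 2), BetaBelief(2, 2))
        assert other != pytest.approx(dirichlet_kl(BetaBelief(2, 2), BetaBelief(5, 2)))


class TestValidation:
    def test_first_order_invariants(self):
        with pytest.raises(ValueError):
            FirstOrderBelief([0.5, 0.6])
        with pytest.raises(ValueError):
            FirstOrderBelief([1.2, -0.2])
        assert FirstOrderBelief.polar(0.3).probs == pytest.approx([0.3, 0.7])

    def test_beta_unimodality(self):
        with pytest.raises(ValueError):
            BetaBelief(0.9, 2.0)
        BetaBelief(0.9, 2.0, strict=False)  # boundary allowed when relaxed
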
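"""First- and second-order belief states and the beta/Dirichlet algebra.

A listener's first-order belief about a polar question is a probability
vector over the answer alternatives (for ``n = 2``, entry 0 is the
probability of 'yes').  Their second-order belief — uncertainty about that
probability itself — is modelled as a unimodal beta distribution,
parameterized either by the shapes ``(alpha, beta)`` or by its mode
``omega = (alpha - 1) / (alpha + beta - 2)`` and concentration
``kappa = alpha + beta``.  The mode is identified with the reported point
probability; the concentration is linked to a 7-point commitment rating
through ``kappa = a * b**c``.

All entropies and divergences are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, digamma, gammaln, rel_entr

__all__ = [
    "FirstOrderBelief",
    "BetaBelief",
    "MeasureParams",
    "PROB_EPS",
    "OMEGA_EPS",
    "KAPPA_FLOOR",
    "beta_from_mode_concentration",
    "link_commitment",
    "beta_mean",
    "shannon_entropy",
    "dirichlet_entropy",
    "dirichlet_kl",
    "clamp_probability",
]

#: Numeric guard for slider probabilities entering log/odds computations.
PROB_EPS = 1e-6
#: Modes are clamped into [OMEGA_EPS, 1 - OMEGA_EPS] before shape inversion.
OMEGA_EPS = 1e-4
#: Concentrations from the linking function are floored here (unimodality).
KAPPA_FLOOR = 2.01


def clamp_probability(p, eps: float = PROB_EPS):
    """Clamp probabilities into [eps, 1 - eps] as a numeric guard."""
    return np.clip(p, eps, 1.0 - eps)


@dataclass(frozen=True)
class FirstOrderBelief:
    """Probability vector over ``n >= 2`` answer alternatives.

    For a polar question entry 0 is the probability of 'yes' and entry 1
    its complement.
    """

    probs: np.ndarray

    def __init__(self, probs) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 1 or probs.size < 2:
            raise ValueError("belief needs a 1-d vector over >= 2 alternatives")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError(f"probabilities outside [0, 1]: {probs}")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {probs.sum()!r}")
        object.__setattr__(self, "probs", np.clip(probs, 0.0, 1.0))

    @classmethod
    def polar(cls, p: float) -> "FirstOrderBelief":
        """Belief <p, 1 - p> over the 'yes'/'no' answers."""
        return cls([p, 1.0 - p])

    @property
    def n(self) -> int:
        return self.probs.size

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class BetaBelief:
    """Unimodal beta distribution over the probability of 'yes'.

    Unimodality requires ``alpha > 1`` and ``beta > 1``; the boundary
    (e.g. the flat Beta(1, 1)) is tolerated with ``strict=False`` for
    worked examples and testing.
    """

    alpha: float
    beta: float

    def __init__(self, alpha: float, beta: float, *, strict: bool = True) -> None:
        alpha = float(alpha)
        beta = float(beta)
        if not (np.isfinite(alpha) and np.isfinite(beta)):
            raise ValueError("beta shape parameters must be finite")
        lo = 1.0 if strict else 0.0
        if alpha <= lo or beta <= lo:
            raise ValueError(
                f"need alpha, beta > {lo} for a {'unimodal ' if strict else ''}"
                f"beta belief, got ({alpha}, {beta})"
            )
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @property
    def mode(self) -> float:
        """omega = (alpha - 1) / (alpha + beta - 2)."""
        denom = self.alpha + self.beta - 2.0
        if denom <= 0:
            raise ValueError("mode undefined for alpha + beta <= 2")
        return (self.alpha - 1.0) / denom

    @property
    def concentration(self) -> float:
        """kappa = alpha + beta."""
        return self.alpha + self.beta

    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class MeasureParams:
    """Free parameters of a relevance measure.

    r_scale
        Base of the scaling function g(x) = 1 - r_scale**(-x); must be > 1.
    a_link, b_link
        Coefficient and base of the commitment-to-concentration linking
        function kappa = a_link * b_link**c (second-order measures only).
    """

    r_scale: float | None = None
    a_link: float | None = None
    b_link: float | None = None

    def __post_init__(self) -> None:
        if self.r_scale is not None and not self.r_scale > 1.0:
            raise ValueError(f"r_scale must be > 1, got {self.r_scale}")
        if self.a_link is not None and not self.a_link > 0.0:
            raise ValueError(f"a_link must be > 0, got {self.a_link}")
        if self.b_link is not None and not self.b_link > 1.0:
            raise ValueError(f"b_link must be > 1, got {self.b_link}")


def beta_from_mode_concentration(omega, kappa, *, clamp: bool = True):
    """Invert the mode/concentration parameterization to a :class:`BetaBelief`.

    alpha = 1 + omega * (kappa - 2), beta = 1 + (1 - omega) * (kappa - 2).

    Scalar inputs return a BetaBelief; array inputs return an
    ``(alpha, beta)`` pair of arrays (used by vectorized measure code).
    """
    omega_arr = np.asarray(omega, dtype=float)
    kappa_arr = np.asarray(kappa, dtype=float)
    if np.any(kappa_arr <= 2.0):
        raise ValueError("concentration kappa must exceed 2 for a unimodal beta")
    if np.any(omega_arr < 0.0) or np.any(omega_arr > 1.0):
        raise ValueError("mode omega must lie in [0, 1]")
    if clamp:
        omega_arr = np.clip(omega_arr, OMEGA_EPS, 1.0 - OMEGA_EPS)
    alpha = 1.0 + omega_arr * (kappa_arr - 2.0)
    beta = 1.0 + (1.0 - omega_arr) * (kappa_arr - 2.0)
    if np.isscalar(omega) and np.isscalar(kappa):
        return BetaBelief(float(alpha), float(beta))
    return alpha, beta


def link_commitment(c, params: MeasureParams, *, floor: float = KAPPA_FLOOR):
    """Map a commitment rating to a concentration, kappa = a * b**c.

    Accepts integer Likert levels 1..7 (or real-valued item means on that
    interval).  The result is floored at ``floor`` (just above 2) so the
    implied beta belief stays unimodal.  Because commitments are bounded
    above by 7, the linking function itself imposes the practical upper
    bound kappa <= a * b**7.
    """
    if params.a_link is None or params.b_link is None:
        raise ValueError("linking requires a_link and b_link")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 1.0) or np.any(c_arr > 7.0):
        raise ValueError(f"commitment outside the 7-point scale: {c!r}")
    kappa = params.a_link * params.b_link ** c_arr
    kappa = np.maximum(kappa, floor)
    if np.isscalar(c):
        return float(kappa)
    return kappa


def beta_mean(b: BetaBelief) -> float:
    """Mean alpha / (alpha + beta) of a beta belief."""
    return b.mean()


def shannon_entropy(x) -> float:
    """Shannon entropy -sum x_i log x_i in nats; 0 log 0 := 0."""
    probs = x.probs if isinstance(x, FirstOrderBelief) else np.asarray(x, float)
    probs = probs[probs > 0]
    return float(-np.sum(probs * np.log(probs)))


def _shapes(b):
    if isinstance(b, BetaBelief):
        return b.alpha, b.beta
    a, bb = b
    return np.asarray(a, float), np.asarray(bb, float)


def dirichlet_entropy(b):
    """Differential entropy of a beta belief (k = 2 Dirichlet) in nats.

    H = log B(a, b) + (a + b - 2) psi(a + b) - (a - 1) psi(a) - (b - 1) psi(b).
    May be negative for concentrated densities.
    """
    a, bb = _shapes(b)
    h = (
        betaln(a, bb)
        + (a + bb - 2.0) * digamma(a + bb)
        - (a - 1.0) * digamma(a)
        - (bb - 1.0) * digamma(bb)
    )
    return float(h) if np.ndim(h) == 0 else h


def dirichlet_kl(post, prior):
    """KL(post || prior) between two beta beliefs, closed form, in nats.

    The k = 2 case of the Dirichlet KL divergence:
    log G(a0) - log G(a1) - log G(a2) - [same for prior shapes]
    + sum (a_i - b_i)(psi(a_i) - psi(a0)).
    Nonnegative; zero iff the parameters coincide.
    """
    a1, a2 = _shapes(post)
    b1, b2 = _shapes(prior)
    a0 = a1 + a2
    b0 = b1 + b2
    kl = (
        gammaln(a0)
        - gammaln(a1)
        - gammaln(a2)
        - gammaln(b0)
        + gammaln(b1)
        + gammaln(b2)
        + (a1 - b1) * (digamma(a1) - digamma(a0))
        + (a2 - b2) * (digamma(a2) - digamma(a0))
    )
    kl = np.maximum(kl, 0.0)  # guard tiny negative round-off
    # identical parameters give exactly 0 (intermediate rounding otherwise
    # leaves ~1e-16 residue)
    kl = np.where((a1 == b1) & (a2 == b2), 0.0, kl)
    return float(kl) if np.ndim(kl) == 0 else kl


def kl_divergence_vectors(q_vec, p_vec) -> float:
    """Discrete KL(q || p) for probability vectors, in nats.

    Terms with q_i = 0 contribute 0; a term with q_i > 0 and p_i = 0 makes
    the divergence infinite.
    """
    q = q_vec.probs if isinstance(q_vec, FirstOrderBelief) else np.asarray(q_vec, float)
    p = p_vec.probs if isinstance(p_vec, FirstOrderBelief) else np.asarray(p_vec, float)
    if q.shape != p.shape:
        raise ValueError("beliefs must range over the same alternatives")
    return float(np.sum(rel_entr(q, p)))
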
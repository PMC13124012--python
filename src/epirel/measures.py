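"""Candidate measures of epistemic relevance for answers to polar questions.

Every measure maps a (prior, posterior) pair of belief states to a utility,
0 when nothing changed and larger the more the answer moved the listener's
beliefs.  First-order measures consume the probability pair (p, q);
second-order measures consume beta beliefs built from (p, c) and (q, d)
via the mode/concentration construction in :mod:`epirel.beliefs`.

The registry (``MEASURES``) holds the nine measures compared against human
relevance judgments, in the canonical order used for ranking tie-breaks:

==============================  =====  ==========================================
name                            order  definition
==============================  =====  ==========================================
probability_change              1st    ``|p - q|``
commitment_change               2nd    ``|c - d|``  (raw, on 0..6)
concentration_change            2nd    ``g(|kappa0 - kappa1|)``
entropy_change                  1st    ``g(|H(q) - H(p)|)``
second_order_entropy_change     2nd    ``g(|H(B1) - H(B0)|)``
kl_utility                      1st    ``g(KL(q || p))``
second_order_kl_utility         2nd    ``g(KL(B1 || B0))``
bayes_factor_utility            1st    ``1 - BF_polar(p, q)**a``  (parameter-free)
second_order_bayes_factor_...   2nd    ``g(log(|da| + |db| + 1))``
==============================  =====  ==========================================

where ``g(x) = 1 - r**(-x)`` rescales unbounded measures onto [0, 1).

All measure functions broadcast over numpy arrays; scalars in give floats
out.  Boundary conventions (resolved questions, degenerate priors) follow
the limiting-behaviour definitions rather than the numeric guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beliefs import (
    PROB_EPS,
    BetaBelief,
    FirstOrderBelief,
    MeasureParams,
    beta_from_mode_concentration,
    clamp_probability,
    dirichlet_entropy,
    dirichlet_kl,
    link_commitment,
)

__all__ = [
    "MEASURE_NAMES",
    "FIRST_ORDER",
    "SECOND_ORDER",
    "DEFAULT_PARAMS",
    "MeasureResult",
    "scale_g",
    "probability_change",
    "commitment_change",
    "concentration_change",
    "entropy_change",
    "second_order_entropy_change",
    "kl_utility",
    "second_order_kl_utility",
    "bayes_factor_polar",
    "bayes_factor_utility",
    "second_order_evidence",
    "second_order_bayes_factor_utility",
    "generalized_bayes_factor_utility",
    "evaluate_measure",
    "evaluate_all_measures",
    "second_order_shapes",
]

MEASURE_NAMES = (
    "probability_change",
    "commitment_change",
    "concentration_change",
    "entropy_change",
    "second_order_entropy_change",
    "kl_utility",
    "second_order_kl_utility",
    "bayes_factor_utility",
    "second_order_bayes_factor_utility",
)

FIRST_ORDER = ("probability_change", "entropy_change", "kl_utility", "bayes_factor_utility")
SECOND_ORDER = tuple(m for m in MEASURE_NAMES if m not in FIRST_ORDER)

#: Measures whose definition involves the scaling function g (fit r_scale).
G_SCALED = (
    "concentration_change",
    "entropy_change",
    "second_order_entropy_change",
    "kl_utility",
    "second_order_kl_utility",
    "second_order_bayes_factor_utility",
)

#: Parameter-free measures (nothing to fit beyond reporting their MSE).
PARAMETER_FREE = ("probability_change", "commitment_change", "bayes_factor_utility")

#: Best-fit parameters from the study's pilot data; used as defaults for
#: evaluation and as the generating truth of the synthetic experiment.
DEFAULT_PARAMS: dict[str, MeasureParams] = {
    "probability_change": MeasureParams(),
    "commitment_change": MeasureParams(),
    "concentration_change": MeasureParams(r_scale=1.19, a_link=1.49, b_link=1.52),
    "entropy_change": MeasureParams(r_scale=1154.73),
    "second_order_entropy_change": MeasureParams(r_scale=2.18, a_link=2.00, b_link=2.01),
    "kl_utility": MeasureParams(r_scale=885603.86),
    "second_order_kl_utility": MeasureParams(r_scale=2.73, a_link=2.09, b_link=1.89),
    "bayes_factor_utility": MeasureParams(),
    "second_order_bayes_factor_utility": MeasureParams(r_scale=1.14, a_link=3.20, b_link=5.19),
}


@dataclass(frozen=True)
class MeasureResult:
    """One measure's value on one trial."""

    name: str
    value: float
    order: str  # "first" or "second"

    def __post_init__(self) -> None:
        if self.name not in MEASURE_NAMES and self.name != "generalized_bayes_factor_utility":
            raise ValueError(f"unknown measure {self.name!r}")


def _as_float(x, *scalars):
    """Return float for scalar inputs, ndarray otherwise."""
    if all(np.isscalar(s) or np.ndim(s) == 0 for s in scalars):
        return float(x)
    return np.asarray(x)


def scale_g(x, r_scale):
    """Scaling function g(x) = 1 - r**(-x), mapping [0, inf) onto [0, 1).

    Strictly increasing for r > 1, with g(0) = 0.  Infinite x maps to 1.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("g is defined on nonnegative arguments only")
    r = np.asarray(r_scale, dtype=float)
    if np.any(r <= 1.0):
        raise ValueError("scale base r must exceed 1")
    out = -np.expm1(-x_arr * np.log(r))
    out = np.where(np.isinf(x_arr), 1.0, out)
    return _as_float(out, x, r_scale)


def _check_prob(*vals):
    for v in vals:
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"probability outside [0, 1]: {v!r}")


def _check_likert(*vals):
    for v in vals:
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 1) or np.any(arr > 7):
            raise ValueError(f"commitment outside 1..7: {v!r}")


def probability_change(p, q):
    """|p - q|: absolute first-order belief change."""
    _check_prob(p, q)
    return _as_float(np.abs(np.asarray(p, float) - np.asarray(q, float)), p, q)


def commitment_change(c, d):
    """|c - d|: absolute change in commitment rating, raw on 0..6."""
    _check_likert(c, d)
    return _as_float(np.abs(np.asarray(c, float) - np.asarray(d, float)), c, d)


def second_order_shapes(p, c, q, d, params: MeasureParams):
    """Beta shapes ((a0, b0), (a1, b1)) for prior (p, c) and posterior (q, d).

    The mode is the point probability (clamped away from 0/1), the
    concentration comes from the commitment linking function.
    """
    kappa0 = link_commitment(c, params)
    kappa1 = link_commitment(d, params)
    prior = beta_from_mode_concentration(np.asarray(p, float), np.asarray(kappa0, float) + 0.0)
    post = beta_from_mode_concentration(np.asarray(q, float), np.asarray(kappa1, float) + 0.0)
    return prior, post


def concentration_change(prior, post, r_scale):
    """g(|kappa0 - kappa1|): change in how peaked the second-order belief is."""
    a0, b0 = _beta_pair(prior)
    a1, b1 = _beta_pair(post)
    return scale_g(np.abs((a0 + b0) - (a1 + b1)), r_scale)


def entropy_change(p_vec, q_vec, r_scale):
    """g(|H(q) - H(p)|): absolute change in first-order Shannon entropy."""
    p = _vec(p_vec)
    q = _vec(q_vec)
    if p.shape[-1] != q.shape[-1]:
        raise ValueError("beliefs must range over the same alternatives")
    return scale_g(np.abs(_entropy_rows(q) - _entropy_rows(p)), r_scale)


def second_order_entropy_change(prior, post, r_scale):
    """g(|H(B1) - H(B0)|): absolute change in beta differential entropy."""
    h0 = dirichlet_entropy(_beta_pair(prior))
    h1 = dirichlet_entropy(_beta_pair(post))
    return scale_g(np.abs(h1 - h0), r_scale)


def kl_utility(p_vec, q_vec, r_scale):
    """g(KL(q || p)): scaled divergence of the posterior from the prior.

    Defined as 1 when the prior is degenerate on some alternative and the
    posterior differs (the divergence diverges; the limit of g is 1).
    """
    p = _vec(p_vec)
    q = _vec(q_vec)
    if p.shape[-1] != q.shape[-1]:
        raise ValueError("beliefs must range over the same alternatives")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * (np.log(np.where(q > 0, q, 1.0)) - np.log(p)), 0.0)
    kl = terms.sum(axis=-1)
    out = np.where(np.isfinite(kl), scale_g(np.where(np.isfinite(kl), kl, 0.0), r_scale), 1.0)
    return _as_float(out, kl)


def second_order_kl_utility(prior, post, r_scale):
    """g(KL(B1 || B0)): scaled beta-belief divergence, posterior from prior."""
    kl = dirichlet_kl(_beta_pair(post), _beta_pair(prior))
    return scale_g(kl, r_scale)


def bayes_factor_polar(p, q):
    """Posterior-to-prior odds ratio for 'yes': [q/(1-q)] * [(1-p)/p].

    Defined on interior probabilities only; boundary inputs raise so the
    caller (``bayes_factor_utility``) can apply the limiting convention.
    """
    p_arr = np.asarray(p, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    _check_prob(p_arr, q_arr)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1) or np.any(q_arr <= 0) or np.any(q_arr >= 1):
        raise ValueError("polar Bayes factor needs interior probabilities")
    out = (q_arr / (1.0 - q_arr)) * ((1.0 - p_arr) / p_arr)
    return _as_float(out, p, q)


def bayes_factor_utility(p, q):
    """1 - BF_polar(p, q)**a with a = -1 if p > q else 1.

    Parameter-free (the scale base of g cancels against the log base).
    Equals 0 iff p = q; equals 1 if either p or q is 0 or 1 with p != q
    (a resolved question); symmetric under swapping prior and posterior.
    Interior values are computed on eps-clamped probabilities.
    """
    p_arr = np.asarray(p, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    _check_prob(p_arr, q_arr)
    resolved = ((p_arr <= 0) | (p_arr >= 1) | (q_arr <= 0) | (q_arr >= 1)) & (p_arr != q_arr)
    pc = clamp_probability(p_arr, PROB_EPS)
    qc = clamp_probability(q_arr, PROB_EPS)
    bf = (qc / (1.0 - qc)) * ((1.0 - pc) / pc)
    # 1 - BF**a with the exponent sign chosen so BF**a <= 1; equivalently
    # g(|log BF|) with the scale base equal to the log base.
    util = 1.0 - np.minimum(bf, 1.0 / bf)
    util = np.where(p_arr == q_arr, 0.0, util)
    util = np.where(resolved, 1.0, util)
    util = np.clip(util, 0.0, 1.0)
    return _as_float(util, p, q)


def second_order_evidence(prior, post):
    """Inner evidence quantity |a1 - a0| + |b1 - b0| + 1 of the
    second-order Bayes factor utility; 1 exactly when nothing changed."""
    a0, b0 = _beta_pair(prior)
    a1, b1 = _beta_pair(post)
    out = np.abs(a1 - a0) + np.abs(b1 - b0) + 1.0
    return _as_float(out, out)


def second_order_bayes_factor_utility(prior, post, r_scale, *, table_literal: bool = False):
    """g(log(|a1 - a0| + |b1 - b0| + 1)): second-order evidence strength.

    The inner quantity counts the pseudo-observations separating posterior
    from prior shapes, plus 1 so that no belief change gives log 1 = 0 and
    utility 0.  ``table_literal=True`` returns ``1 - g(...)`` instead (a
    printed variant that violates the null-update convention; exposed for
    comparison only).
    """
    a0, b0 = _beta_pair(prior)
    a1, b1 = _beta_pair(post)
    inner = np.abs(a1 - a0) + np.abs(b1 - b0) + 1.0
    out = scale_g(np.log(inner), r_scale)
    if table_literal:
        out = 1.0 - np.asarray(out)
        return _as_float(out, inner)
    return out


def generalized_bayes_factor_utility(p_vec, q_vec):
    """Posterior-weighted average of per-alternative Bayes factor utility.

    For a question with n alternatives, sum_i q_i * BFU(p_i, q_i), each
    term using the polar boundary conventions.  Reduces exactly to
    ``bayes_factor_utility(p, q)`` for n = 2, and equals 1 whenever the
    prior or posterior puts all mass on one alternative (a resolved
    question), except in the pathological case of disjoint supports.
    """
    p = _vec(p_vec)
    q = _vec(q_vec)
    if p.shape != q.shape:
        raise ValueError("beliefs must range over the same alternatives")
    per_alt = bayes_factor_utility(p, q)
    out = np.sum(q * np.asarray(per_alt), axis=-1)
    return _as_float(out, out)


# --- registry dispatch -----------------------------------------------------


def _vec(x) -> np.ndarray:
    if isinstance(x, FirstOrderBelief):
        return x.probs
    return np.asarray(x, dtype=float)


def _beta_pair(b):
    if isinstance(b, BetaBelief):
        return np.asarray(b.alpha), np.asarray(b.beta)
    a, bb = b
    return np.asarray(a, dtype=float), np.asarray(bb, dtype=float)


def _entropy_rows(probs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, -probs * np.log(np.where(probs > 0, probs, 1.0)), 0.0)
    return terms.sum(axis=-1)


def evaluate_measure(name: str, p, c, q, d, params: MeasureParams | None = None):
    """Evaluate one registry measure on quintuple components (broadcasting).

    ``p``/``q`` are prior/posterior probabilities of 'yes'; ``c``/``d`` the
    commitment ratings.  ``params`` defaults to the measure's best-fit
    values in :data:`DEFAULT_PARAMS`.
    """
    if name not in MEASURE_NAMES:
        raise KeyError(f"unknown measure {name!r}; registry: {MEASURE_NAMES}")
    if params is None:
        params = DEFAULT_PARAMS[name]
    p_arr = np.asarray(p, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    if name == "probability_change":
        return probability_change(p, q)
    if name == "commitment_change":
        return commitment_change(c, d)
    if name == "bayes_factor_utility":
        return bayes_factor_utility(p, q)
    if name == "entropy_change":
        pv = np.stack([p_arr, 1.0 - p_arr], axis=-1)
        qv = np.stack([q_arr, 1.0 - q_arr], axis=-1)
        return entropy_change(pv, qv, params.r_scale)
    if name == "kl_utility":
        pv = np.stack([p_arr, 1.0 - p_arr], axis=-1)
        qv = np.stack([q_arr, 1.0 - q_arr], axis=-1)
        return kl_utility(pv, qv, params.r_scale)
    # second-order measures share the belief construction
    prior, post = second_order_shapes(
        clamp_probability(p_arr), c, clamp_probability(q_arr), d, params
    )
    if name == "concentration_change":
        return concentration_change(prior, post, params.r_scale)
    if name == "second_order_entropy_change":
        return second_order_entropy_change(prior, post, params.r_scale)
    if name == "second_order_kl_utility":
        return second_order_kl_utility(prior, post, params.r_scale)
    if name == "second_order_bayes_factor_utility":
        return second_order_bayes_factor_utility(prior, post, params.r_scale)
    raise AssertionError("unreachable")


def evaluate_all_measures(trial, params: dict[str, MeasureParams] | None = None):
    """All nine registry measures on one trial (mapping or object with p,c,q,d).

    Returns a list of :class:`MeasureResult` in registry order.
    """
    get = trial.get if hasattr(trial, "get") else lambda k: getattr(trial, k)
    try:
        p, c, q, d = (get(k) for k in ("p", "c", "q", "d"))
        p, c, q, d = float(p), float(c), float(q), float(d)
    except (KeyError, AttributeError, TypeError) as exc:
        raise ValueError("trial must carry p, c, q, d") from exc
    params = params or {}
    results = []
    for name in MEASURE_NAMES:
        value = evaluate_measure(name, p, c, q, d, params.get(name))
        order = "first" if name in FIRST_ORDER else "second"
        results.append(MeasureResult(name=name, value=float(value), order=order))
    return results
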
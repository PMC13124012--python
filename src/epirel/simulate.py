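"""Synthetic polar-question experiments with the study's trial structure.

Each simulated participant works through 14 trials in a fixed sequence —
10 main trials interleaved with 2 attention checks and 2 reasoning checks.
Main trials cross three manipulations: ContextType (negative / neutral /
positive prior bias), AnswerCertainty (exhaustive / high-certainty /
low-certainty / non-answer), and AnswerPolarity (positive / negative;
non-answers are always coded positive).

The generative participant model works in log-odds space: the prior
probability of 'yes' is drawn from a context-dependent beta distribution,
and the posterior log-odds equal the prior log-odds plus a trust-weighted
evidence term whose size is set by AnswerCertainty and whose sign by
AnswerPolarity.  Exhaustive answers cap the posterior at the slider
extremes (0.01 / 0.99 by default).  Commitment ratings are a monotone map
of distance-from-1/2 plus evidence strength, jittered and clipped to the
7-point scale.  Relevance is the value of a chosen generating measure on
the trial's beliefs plus truncated-Gaussian noise, so that downstream
fitting has a known ground truth.

The model is a stand-in for human raters: it encodes the orderings the
study design manipulates (prior by context, belief change by certainty)
but none of the non-epistemic factors real judgments mix in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import (
    ANSWER_CERTAINTIES,
    ANSWER_POLARITIES,
    CONTEXT_TYPES,
    ExperimentDataset,
)
from .measures import DEFAULT_PARAMS, MEASURE_NAMES, MeasureParams, evaluate_measure

__all__ = [
    "Condition",
    "ParticipantProfile",
    "TRIAL_SEQUENCE",
    "ATTENTION_TARGETS",
    "sample_design",
    "generate_beliefs",
    "generate_relevance",
    "generate_check_trials",
    "generate_experiment",
]

#: Fixed order of trial types within a session (1-based trial_index).
TRIAL_SEQUENCE = (
    "main", "reasoning", "main", "main", "attention", "main", "main",
    "reasoning", "main", "main", "main", "main", "attention", "main",
)
N_MAIN = TRIAL_SEQUENCE.count("main")

#: Instructed (probability, commitment) pairs for the two attention checks.
ATTENTION_TARGETS = ((0.30, 6), (0.80, 2))

#: Mean prior probability of 'yes' induced by each ContextType.
CONTEXT_PRIOR_MEAN = {"negative": 0.30, "neutral": 0.50, "positive": 0.70}
#: Concentration of the context prior distribution (beta pseudo-counts).
CONTEXT_PRIOR_STRENGTH = 12.0

#: Magnitude of the answer's evidence, in log-odds, by AnswerCertainty.
EVIDENCE_LOGODDS = {
    "exhaustive": np.inf,
    "high-certainty": 2.0,
    "low-certainty": 0.8,
    "non-answer": 0.0,
}
#: Slider cap for exhaustive answers (sliders rarely hit exact endpoints).
EXHAUSTIVE_CAP = 0.99
SLIDER_DP = 2  # slider granularity: probabilities round to 2 decimals


@dataclass(frozen=True)
class Condition:
    """Condition labels of one main trial."""

    context_type: str
    answer_certainty: str
    answer_polarity: str
    vignette_id: int

    def __post_init__(self) -> None:
        if self.context_type not in CONTEXT_TYPES:
            raise ValueError(f"bad context_type {self.context_type!r}")
        if self.answer_certainty not in ANSWER_CERTAINTIES:
            raise ValueError(f"bad answer_certainty {self.answer_certainty!r}")
        if self.answer_polarity not in ANSWER_POLARITIES:
            raise ValueError(f"bad answer_polarity {self.answer_polarity!r}")
        if self.answer_certainty == "non-answer" and self.answer_polarity != "positive":
            raise ValueError("non-answer trials carry no polarity variation")
        if not 1 <= self.vignette_id <= 12:
            raise ValueError(f"vignette_id must be 1..12, got {self.vignette_id}")


@dataclass(frozen=True)
class ParticipantProfile:
    """Heterogeneity knobs of one simulated participant."""

    slider_noise_sd: float = 0.03
    trust: float = 1.0          # multiplier on evidence strength, in (0, 1]
    commitment_noise: float = 0.5
    compliance: float = 1.0     # P(pass) per attention/reasoning judgment

    def __post_init__(self) -> None:
        if self.slider_noise_sd < 0 or self.commitment_noise < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if not 0 < self.trust <= 1:
            raise ValueError("trust must lie in (0, 1]")
        if not 0 <= self.compliance <= 1:
            raise ValueError("compliance must lie in [0, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_design(n_participants: int, seed) -> list[list[Condition]]:
    """Per-participant lists of 10 main-trial conditions.

    Quotas per participant: at least two exhaustive, two high-certainty,
    two low-certainty, one non-answer (the remaining three certainty
    levels sampled uniformly without replacement); at least one positive
    and one negative polarity within each informative certainty level;
    at least three of each ContextType; 10 vignettes drawn without
    replacement from 12.  ContextType is sampled independently of the
    answer factors.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = _rng(seed)
    all_designs = []
    for _ in range(n_participants):
        certainties = ["exhaustive"] * 2 + ["high-certainty"] * 2 + ["low-certainty"] * 2 + [
            "non-answer"
        ]
        certainties += list(rng.choice(ANSWER_CERTAINTIES, size=3, replace=False))
        rng.shuffle(certainties)

        polarities = [""] * N_MAIN
        for level in ("exhaustive", "high-certainty", "low-certainty"):
            slots = [i for i, c in enumerate(certainties) if c == level]
            assigned = ["positive", "negative"] + list(
                rng.choice(ANSWER_POLARITIES, size=len(slots) - 2)
            )
            rng.shuffle(assigned)
            for i, pol in zip(slots, assigned):
                polarities[i] = pol
        for i, c in enumerate(certainties):
            if c == "non-answer":
                polarities[i] = "positive"

        contexts = list(CONTEXT_TYPES) * 3 + [rng.choice(CONTEXT_TYPES)]
        rng.shuffle(contexts)

        vignettes = rng.choice(np.arange(1, 13), size=N_MAIN, replace=False)

        all_designs.append(
            [
                Condition(
                    context_type=str(contexts[i]),
                    answer_certainty=str(certainties[i]),
                    answer_polarity=str(polarities[i]),
                    vignette_id=int(vignettes[i]),
                )
                for i in range(N_MAIN)
            ]
        )
    return all_designs


def _round_slider(x: float) -> float:
    return float(np.clip(np.round(x, SLIDER_DP), 0.01, 0.99))


def _commit(level: float, noise: float, rng) -> int:
    jitter = rng.normal(0.0, noise) if noise > 0 else 0.0
    return int(np.clip(np.round(level + jitter), 1, 7))


def generate_beliefs(condition: Condition, profile: ParticipantProfile, seed):
    """Draw one trial's quintuple precursors (p, c, q, d) plus the true
    evidence applied, following the log-odds participant model."""
    rng = _rng(seed)
    mu = CONTEXT_PRIOR_MEAN[condition.context_type]
    k = CONTEXT_PRIOR_STRENGTH
    p_raw = rng.beta(mu * k, (1.0 - mu) * k)
    if profile.slider_noise_sd > 0:
        p_raw += rng.normal(0.0, profile.slider_noise_sd)
    p = _round_slider(p_raw)

    sign = 1.0 if condition.answer_polarity == "positive" else -1.0
    strength = EVIDENCE_LOGODDS[condition.answer_certainty]
    evidence = sign * strength

    if np.isinf(strength):
        q_raw = EXHAUSTIVE_CAP if sign > 0 else 1.0 - EXHAUSTIVE_CAP
        applied = sign * 6.0  # effective strength driving commitment
    else:
        applied = profile.trust * evidence
        logit = np.log(p / (1.0 - p)) + applied
        q_raw = 1.0 / (1.0 + np.exp(-logit))
        if profile.slider_noise_sd > 0 and strength > 0:
            q_raw += rng.normal(0.0, profile.slider_noise_sd)
    q = p if strength == 0 and profile.slider_noise_sd == 0 else _round_slider(q_raw)

    c = _commit(2.0 + 8.0 * abs(p - 0.5), profile.commitment_noise, rng)
    d = _commit(
        2.0 + 8.0 * abs(q - 0.5) + 0.5 * min(abs(applied), 4.0),
        profile.commitment_noise,
        rng,
    )
    return p, c, q, d, float(evidence)


def generate_relevance(
    p, c, q, d, generating_measure: str, noise_sd: float, seed, params: MeasureParams | None = None
):
    """Relevance judgment: generating-measure value plus truncated noise.

    Commitment change (raw 0..6) is mapped onto the unit slider by its
    maximum, 6, so generated relevance always lives on [0, 1].  With
    ``noise_sd = 0`` the measure value is returned exactly.
    """
    if generating_measure not in MEASURE_NAMES:
        raise KeyError(f"unknown generating measure {generating_measure!r}")
    rng = _rng(seed)
    value = float(evaluate_measure(generating_measure, p, c, q, d, params))
    if generating_measure == "commitment_change":
        value /= 6.0
    if noise_sd > 0:
        value = float(np.clip(value + rng.normal(0.0, noise_sd), 0.0, 1.0))
    return value, float(evaluate_measure(generating_measure, p, c, q, d, params))


def generate_check_trials(profile: ParticipantProfile, seed):
    """Attention and reasoning check rows for one participant.

    Attention checks reproduce the instructed (probability, commitment)
    pair per judgment with probability ``compliance``, else deviate by at
    least one slider/scale step.  Reasoning checks are abstract
    pass/fail events per judgment (the scenarios themselves are not
    modelled); correctness flags are recorded in truth_* columns.
    """
    rng = _rng(seed)
    rows = []
    for check_i, (tp, tc) in enumerate(ATTENTION_TARGETS):
        p = tp if rng.random() < profile.compliance else _round_slider(
            tp + rng.choice([-1, 1]) * rng.uniform(0.05, 0.3)
        )
        c = tc if rng.random() < profile.compliance else int(
            np.clip(tc + rng.choice([-2, -1, 1, 2]), 1, 7)
        )
        rows.append(
            {
                "trial_type": "attention",
                "check_number": check_i + 1,
                "prior_prob": p,
                "prior_commit": c,
            }
        )
    for check_i in range(2):
        correct = rng.random(4) < profile.compliance
        rows.append(
            {
                "trial_type": "reasoning",
                "check_number": check_i + 1,
                "truth_correct_prior_prob": int(correct[0]),
                "truth_correct_prior_commit": int(correct[1]),
                "truth_correct_post_prob": int(correct[2]),
                "truth_correct_post_commit": int(correct[3]),
            }
        )
    return rows


def generate_experiment(
    n_participants: int = 220,
    seed: int = 0,
    *,
    generating_measure: str = "bayes_factor_utility",
    noise_sd: float = 0.05,
    params: MeasureParams | None = None,
    profile: ParticipantProfile | None = None,
    trust_range: tuple[float, float] = (0.75, 1.0),
    relevance_only: bool = False,
    exact_boundaries: bool = False,
) -> ExperimentDataset:
    """Simulate a full experiment dataset.

    Defaults mirror the study's conditions: 220 analyzed participants,
    14 trials each in the fixed sequence, relevance generated from Bayes
    factor utility with noise sd 0.05, participant trust varying on
    ``trust_range``.  ``relevance_only`` empties the belief columns of
    main trials (the follow-up protocol); ``exact_boundaries`` lets
    exhaustive answers reach probabilities exactly 0/1.

    Deterministic: the same arguments and seed give a byte-identical
    table.
    """
    rng = _rng(seed)
    base_profile = profile or ParticipantProfile()
    if params is None:
        params = DEFAULT_PARAMS[generating_measure]
    designs = sample_design(n_participants, rng)
    records = []
    cap = 1.0 if exact_boundaries else EXHAUSTIVE_CAP

    for pid in range(n_participants):
        trust = float(rng.uniform(*trust_range))
        prof = replace(base_profile, trust=trust)
        checks = generate_check_trials(prof, rng)
        attention = [r for r in checks if r["trial_type"] == "attention"]
        reasoning = [r for r in checks if r["trial_type"] == "reasoning"]
        main_iter = iter(designs[pid])
        att_iter = iter(attention)
        reas_iter = iter(reasoning)
        for t_idx, t_type in enumerate(TRIAL_SEQUENCE, start=1):
            row = {
                "participant_id": f"P{pid + 1:04d}",
                "trial_index": t_idx,
                "trial_type": t_type,
                "vignette_id": np.nan,
                "context_type": "",
                "answer_certainty": "",
                "answer_polarity": "",
                "prior_prob": np.nan,
                "prior_commit": np.nan,
                "post_prob": np.nan,
                "post_commit": np.nan,
                "relevance": np.nan,
                "truth_log_evidence": np.nan,
                "truth_measure_value": np.nan,
                "truth_correct_prior_prob": np.nan,
                "truth_correct_prior_commit": np.nan,
                "truth_correct_post_prob": np.nan,
                "truth_correct_post_commit": np.nan,
            }
            if t_type == "main":
                cond = next(main_iter)
                p, c, q, d, evidence = _generate_main(cond, prof, rng, cap)
                r, truth_value = generate_relevance(
                    p, c, q, d, generating_measure, noise_sd, rng, params
                )
                row.update(
                    vignette_id=cond.vignette_id,
                    context_type=cond.context_type,
                    answer_certainty=cond.answer_certainty,
                    answer_polarity=cond.answer_polarity,
                    relevance=r,
                    truth_log_evidence=evidence,
                    truth_measure_value=truth_value,
                )
                if not relevance_only:
                    row.update(prior_prob=p, prior_commit=c, post_prob=q, post_commit=d)
            elif t_type == "attention":
                a = next(att_iter)
                row.update(prior_prob=a["prior_prob"], prior_commit=a["prior_commit"])
            else:
                rr = next(reas_iter)
                row.update({k: v for k, v in rr.items() if k.startswith("truth_correct")})
                if relevance_only:  # follow-up protocol records only two judgments
                    row.update(
                        truth_correct_post_prob=np.nan, truth_correct_post_commit=np.nan
                    )
            records.append(row)

    df = pd.DataFrame.from_records(records)
    config = {
        "n_participants": n_participants,
        "generating_measure": generating_measure,
        "noise_sd": noise_sd,
        "trust_range": list(trust_range),
        "relevance_only": relevance_only,
        "exact_boundaries": exact_boundaries,
        "slider_noise_sd": base_profile.slider_noise_sd,
        "commitment_noise": base_profile.commitment_noise,
        "compliance": base_profile.compliance,
        "attention_targets": [list(t) for t in ATTENTION_TARGETS],
    }
    return ExperimentDataset(df, seed=seed if isinstance(seed, int) else None, config=config)


def _generate_main(cond, prof, rng, cap):
    """generate_beliefs with a configurable exhaustive cap."""
    p, c, q, d, evidence = generate_beliefs(cond, prof, rng)
    if cond.answer_certainty == "exhaustive" and cap != EXHAUSTIVE_CAP:
        q = cap if cond.answer_polarity == "positive" else 1.0 - cap
    return p, c, q, d, evidence
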
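"""Exclusion criteria on hand-built boundary fixtures; directed belief change."""

import numpy as np
import pytest

from conftest import build_dataset, build_participant
from epirel.preprocessing import (
    apply_exclusions,
    attention_exclusion,
    directed_belief_change,
    reasoning_exclusion,
    task_sensitivity,
)
from epirel.simulate import generate_experiment

SENSITIVE = dict(p=0.2, c=3, q=0.8, d=6, r=0.9)  # clearly responsive trial
FLAT = dict(p=0.5, c=4, q=0.5, d=4, r=0.1)       # no probability or commitment change


def participant(pid, **kw):
    kw.setdefault("main_trials", [dict(SENSITIVE) for _ in range(10)])
    return build_participant(pid, **kw)


class TestAttention:
    def test_perfect_retained_one_miss_excluded(self):
        ds = build_dataset(
            participant("good"),
            participant("slip", attention_ok=(True, True, True, False)),
        )
        assert attention_exclusion(ds) == {"slip"}

    def test_empty_dataset(self):
        ds = build_dataset()
        assert attention_exclusion(ds) == set()


class TestReasoning:
    def test_half_rule_boundary(self):
        ds = build_dataset(
            participant("at50", reasoning_ok=(1, 1, 1, 1, 0, 0, 0, 0)),
            participant("below", reasoning_ok=(1, 1, 1, 0, 0, 0, 0, 0)),
        )
        flagged = reasoning_exclusion(ds, mode="half")
        assert flagged == {"below"}  # exactly 50% is not below 50%

    def test_both_wrong_relaxation(self):
        ds = build_dataset(
            participant("one_ok", reasoning_ok=(1, 1, 1, 1, 0, 0, 0, 0)),
            participant("none_ok", reasoning_ok=(0, 0, 0, 1, 0, 0, 1, 0)),
        )
        flagged = reasoning_exclusion(ds, mode="both_wrong")
        assert flagged == {"none_ok"}

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            reasoning_exclusion(build_dataset(participant("x")), mode="strictest")


class TestSensitivity:
    def test_fully_sensitive_retained(self):
        ds = build_dataset(participant("p"))
        assert task_sensitivity(ds, "p") == 1.0

    def test_fraction_and_boundary(self):
        # 9 informative trials (one slot is a non-answer filler): make
        # exactly 6 sensitive -> 2/3, and a second participant with
        # exactly 0.75 (6 of 8 informative trials sensitive).
        mains_a = [dict(SENSITIVE) for _ in range(6)] + [dict(FLAT) for _ in range(3)] + [
            dict(FLAT, answer_certainty="non-answer")
        ]
        mains_b = [dict(SENSITIVE) for _ in range(6)] + [dict(FLAT) for _ in range(2)] + [
            dict(FLAT, answer_certainty="non-answer"),
            dict(FLAT, answer_certainty="non-answer"),
        ]
        ds = build_dataset(
            build_participant("twothirds", mains_a),
            build_participant("exact75", mains_b),
        )
        assert task_sensitivity(ds, "twothirds") == pytest.approx(6 / 9)
        assert task_sensitivity(ds, "exact75") == pytest.approx(0.75)
        report = apply_exclusions(ds)
        # both at or below 0.75 are excluded ("0.75 or lower")
        assert set(report.low_sensitivity) == {"twothirds", "exact75"}

    def test_small_probability_move_is_insensitive(self):
        mains = [dict(p=0.50, c=4, q=0.55, d=4, r=0.2) for _ in range(10)]
        ds = build_dataset(build_participant("p", mains))
        assert task_sensitivity(ds, "p") == 0.0  # 0.05 change is "0.05 or less"

    def test_no_eligible_trials(self):
        mains = [dict(FLAT, answer_certainty="non-answer") for _ in range(10)]
        ds = build_dataset(build_participant("p", mains))
        with pytest.raises(ValueError):
            task_sensitivity(ds, "p")


class TestSequentialApplication:
    def test_no_double_counting(self):
        ds = build_dataset(
            participant("clean"),
            participant(
                "fails_everything",
                attention_ok=(False, False, False, False),
                reasoning_ok=(0,) * 8,
                main_trials=[dict(FLAT) for _ in range(10)],
            ),
            participant("reasoning_only", reasoning_ok=(1, 0, 0, 0, 0, 0, 0, 0)),
            build_participant("insensitive", [dict(FLAT) for _ in range(10)]),
        )
        report = apply_exclusions(ds)
        assert report.attention_failed == ["fails_everything"]
        assert report.reasoning_failed == ["reasoning_only"]
        assert report.low_sensitivity == ["insensitive"]
        assert report.n_excluded == 3
        assert report.n_retained == 1
        assert report.retained.participants == ["clean"]

    def test_compliant_synthetic_dataset_keeps_everyone(self):
        ds = generate_experiment(n_participants=15, seed=2)
        report = apply_exclusions(ds)
        assert report.attention_failed == [] and report.reasoning_failed == []


class TestDirectedBeliefChange:
    def test_sign_convention(self):
        t = dict(answer_certainty="high-certainty", answer_polarity="positive",
                 prior_prob=0.4, post_prob=0.7)
        assert directed_belief_change(t) == pytest.approx(0.3)
        t = dict(answer_certainty="high-certainty", answer_polarity="negative",
                 prior_prob=0.7, post_prob=0.4)
        assert directed_belief_change(t) == pytest.approx(0.3)
        t["post_prob"] = t["prior_prob"]
        assert directed_belief_change(t) == 0.0

    def test_non_answer_not_applicable(self):
        t = dict(answer_certainty="non-answer", answer_polarity="positive",
                 prior_prob=0.4, post_prob=0.4)
        with pytest.raises(ValueError):
            directed_belief_change(t)

    def test_antisymmetry_under_polarity_flip(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p, q = rng.uniform(0, 1, 2)
            pos = dict(answer_certainty="high-certainty", answer_polarity="positive",
                       prior_prob=p, post_prob=q)
            neg = dict(answer_certainty="high-certainty", answer_polarity="negative",
                       prior_prob=p, post_prob=q)
            assert directed_belief_change(pos) == pytest.approx(
                -directed_belief_change(neg)
            )
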
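"""Shared fixtures: hand-built trial tables and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epirel.io import ExperimentDataset
from epirel.simulate import ATTENTION_TARGETS, TRIAL_SEQUENCE, generate_experiment

CERTAINTIES = ("exhaustive", "high-certainty", "low-certainty", "non-answer")


def build_participant(
    pid: str,
    main_trials: list[dict],
    attention_ok=(True, True, True, True),
    reasoning_ok=(True,) * 8,
) -> list[dict]:
    """Rows for one participant in the fixed 14-trial sequence.

    ``main_trials`` supplies up to 10 dicts with p, c, q, d, r and
    optional condition labels; missing slots are filled with a bland
    non-answer trial.  ``attention_ok`` gives the four attention
    judgments (2 trials x prob, commit); ``reasoning_ok`` the eight
    reasoning judgments (2 trials x prior/posterior x prob/commit).
    """
    main_trials = list(main_trials)
    while len(main_trials) < 10:
        main_trials.append(
            dict(p=0.5, c=4, q=0.5, d=4, r=0.0, answer_certainty="non-answer")
        )
    att_iter = iter(range(2))
    reas_iter = iter(range(2))
    main_iter = iter(enumerate(main_trials))
    rows = []
    for t_idx, t_type in enumerate(TRIAL_SEQUENCE, start=1):
        row = {
            "participant_id": pid,
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
            "truth_correct_prior_prob": np.nan,
            "truth_correct_prior_commit": np.nan,
            "truth_correct_post_prob": np.nan,
            "truth_correct_post_commit": np.nan,
        }
        if t_type == "main":
            i, t = next(main_iter)
            row.update(
                vignette_id=t.get("vignette_id", i + 1),
                context_type=t.get("context_type", "neutral"),
                answer_certainty=t.get("answer_certainty", "high-certainty"),
                answer_polarity=t.get("answer_polarity", "positive"),
                prior_prob=t["p"],
                prior_commit=t["c"],
                post_prob=t["q"],
                post_commit=t["d"],
                relevance=t.get("r", np.nan),
            )
        elif t_type == "attention":
            k = next(att_iter)
            tp, tc = ATTENTION_TARGETS[k]
            ok_p, ok_c = attention_ok[2 * k], attention_ok[2 * k + 1]
            row.update(
                prior_prob=tp if ok_p else round(tp + 0.11, 2),
                prior_commit=tc if ok_c else (tc % 7) + 1,
            )
        else:
            k = next(reas_iter)
            flags = reasoning_ok[4 * k : 4 * k + 4]
            row.update(
                truth_correct_prior_prob=int(flags[0]),
                truth_correct_prior_commit=int(flags[1]),
                truth_correct_post_prob=int(flags[2]),
                truth_correct_post_commit=int(flags[3]),
            )
        rows.append(row)
    return rows


def build_dataset(*participants_rows) -> ExperimentDataset:
    rows = [r for rows in participants_rows for r in rows]
    if not rows:
        cols = ["participant_id", "trial_index", "trial_type"]
        return ExperimentDataset(pd.DataFrame(columns=cols))
    return ExperimentDataset(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_dataset() -> ExperimentDataset:
    """20 compliant participants, Bayes-factor-generated relevance."""
    return generate_experiment(n_participants=20, seed=5)


@pytest.fixture(scope="session")
def noiseless_dataset() -> ExperimentDataset:
    """Noiseless relevance from entropy change (known ground truth)."""
    return generate_experiment(
        n_participants=15, seed=9, generating_measure="entropy_change", noise_sd=0.0
    )
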
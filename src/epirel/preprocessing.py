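"""Participant exclusion filters and derived per-trial quantities.

The study excludes a participant's data entirely if any of three criteria
fires, applied in order so each participant is counted once:

(i)   less-than-perfect attention checks — all four instructed judgments
      (2 trials x probability, commitment) must match exactly;
(ii)  a reasoning-check score below 50% over the eight reasoning
      judgments (2 trials x prior/posterior x probability/commitment);
      the relevance-only follow-up relaxes this to excluding only
      participants with both reasoning trials wrong;
(iii) task sensitivity of 0.75 or lower, where a main trial (non-answers
      excluded) counts as sensitive if its probability moved by more than
      0.05 or its commitment changed at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExperimentDataset
from .simulate import ATTENTION_TARGETS

__all__ = [
    "ExclusionReport",
    "attention_exclusion",
    "reasoning_exclusion",
    "task_sensitivity",
    "directed_belief_change",
    "apply_exclusions",
]

SLIDER_DP = 2  # attention sliders compared at this granularity

_REASONING_COLS = (
    "truth_correct_prior_prob",
    "truth_correct_prior_commit",
    "truth_correct_post_prob",
    "truth_correct_post_commit",
)


@dataclass
class ExclusionReport:
    """Sequential exclusion flags and the retained dataset."""

    attention_failed: list = field(default_factory=list)
    reasoning_failed: list = field(default_factory=list)
    low_sensitivity: list = field(default_factory=list)
    n_total: int = 0
    retained: ExperimentDataset | None = None

    @property
    def n_excluded(self) -> int:
        return len(self.attention_failed) + len(self.reasoning_failed) + len(
            self.low_sensitivity
        )

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_excluded

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "attention_failed": sorted(self.attention_failed),
            "reasoning_failed": sorted(self.reasoning_failed),
            "low_sensitivity": sorted(self.low_sensitivity),
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def attention_exclusion(dataset: ExperimentDataset, targets=ATTENTION_TARGETS) -> set:
    """Participants whose attention-check judgments are not all exact.

    Slider probabilities are compared after rounding to the slider's
    granularity; commitments must match exactly.
    """
    df = dataset.trials
    att = df[df["trial_type"] == "attention"]
    if att.empty and not df.empty:
        raise ValueError("dataset has no attention-check trials")
    flagged = set()
    for pid, grp in att.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial_index")
        if len(grp) != len(targets):
            flagged.add(pid)
            continue
        for (tp, tc), (_, row) in zip(targets, grp.iterrows()):
            ok_p = round(float(row["prior_prob"]), SLIDER_DP) == round(tp, SLIDER_DP)
            ok_c = int(row["prior_commit"]) == tc
            if not (ok_p and ok_c):
                flagged.add(pid)
                break
    return flagged


def reasoning_exclusion(dataset: ExperimentDataset, mode: str = "half") -> set:
    """Participants failing the reasoning checks.

    ``mode="half"``: flag a score strictly below 50% over all recorded
    reasoning judgments.  ``mode="both_wrong"``: flag only participants
    with no fully correct reasoning trial (the relevance-only relaxation).
    """
    if mode not in ("half", "both_wrong"):
        raise ValueError(f"unknown reasoning mode {mode!r}")
    df = dataset.trials
    reas = df[df["trial_type"] == "reasoning"]
    if reas.empty and not df.empty:
        raise ValueError("dataset has no reasoning-check trials")
    flagged = set()
    for pid, grp in reas.groupby("participant_id", sort=False):
        scores = grp[list(_REASONING_COLS)].to_numpy(dtype=float)
        if mode == "half":
            vals = scores[~np.isnan(scores)]
            if vals.size and vals.mean() < 0.5:
                flagged.add(pid)
        else:
            trial_ok = [np.nanmin(row) >= 1 for row in scores if not np.all(np.isnan(row))]
            if trial_ok and not any(trial_ok):
                flagged.add(pid)
    return flagged


def task_sensitivity(dataset: ExperimentDataset, participant) -> float:
    """Fraction of a participant's informative main trials that responded.

    A trial is sensitive if |p - q| > 0.05 or the commitment changed;
    non-answer trials are excluded from the computation.
    """
    df = dataset.trials
    main = df[
        (df["trial_type"] == "main")
        & (df["participant_id"] == participant)
        & (df["answer_certainty"] != "non-answer")
    ]
    if main.empty:
        raise ValueError(f"participant {participant!r} has no eligible main trials")
    # round away float representation error so a slider move of exactly
    # 0.05 counts as "0.05 or less" (insensitive)
    dp = (main["prior_prob"] - main["post_prob"]).abs().round(9)
    dc = (main["prior_commit"] - main["post_commit"]).abs()
    sensitive = (dp > 0.05) | (dc > 0)
    return float(sensitive.mean())


def directed_belief_change(trial) -> float:
    """a(q - p), with a = +1 for positive answers and -1 for negative.

    Positive when beliefs moved in the direction the answer pointed.
    Non-answers carry no direction and are not applicable.
    """
    get = trial.get if hasattr(trial, "get") else lambda k: getattr(trial, k)
    if get("answer_certainty") == "non-answer":
        raise ValueError("directed belief change is undefined for non-answers")
    a = 1.0 if get("answer_polarity") == "positive" else -1.0
    return float(a * (get("post_prob") - get("prior_prob")))


def add_directed_belief_change(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized a(q - p) column over informative main trials (NaN elsewhere)."""
    out = df.copy()
    a = np.where(out["answer_polarity"] == "positive", 1.0, -1.0)
    dbc = a * (out["post_prob"] - out["prior_prob"])
    informative = (out["trial_type"] == "main") & (
        out["answer_certainty"].isin(("exhaustive", "high-certainty", "low-certainty"))
    )
    out["directed_belief_change"] = np.where(informative, dbc, np.nan)
    return out


def apply_exclusions(
    dataset: ExperimentDataset,
    *,
    reasoning_mode: str = "half",
    sensitivity_threshold: float = 0.75,
    attention_targets=ATTENTION_TARGETS,
) -> ExclusionReport:
    """Run criteria (i)-(iii) in order; earlier exclusions are not recounted."""
    participants = dataset.participants
    report = ExclusionReport(n_total=len(participants))

    att = attention_exclusion(dataset, attention_targets) if participants else set()
    report.attention_failed = [p for p in participants if p in att]
    remaining = [p for p in participants if p not in att]

    reas = reasoning_exclusion(dataset.subset(remaining), reasoning_mode) if remaining else set()
    report.reasoning_failed = [p for p in remaining if p in reas]
    remaining = [p for p in remaining if p not in reas]

    low = set()
    if sensitivity_threshold is not None:  # None skips (iii): relevance-only data
        for pid in remaining:
            if task_sensitivity(dataset, pid) <= sensitivity_threshold:
                low.add(pid)
    report.low_sensitivity = [p for p in remaining if p in low]
    remaining = [p for p in remaining if p not in low]

    report.retained = dataset.subset(remaining)
    return report
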
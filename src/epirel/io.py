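"""Trial-table schema, dataset container, and CSV/JSON round-tripping.

The canonical on-disk format is a UTF-8 comma-separated table with one row
per trial and the columns in :data:`SCHEMA_COLUMNS`.  Probabilities are
serialized at 6 decimals (lossless for the pipeline; the experiment's
sliders are coarser).  Generator provenance travels in a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_COLUMNS",
    "CONTEXT_TYPES",
    "ANSWER_CERTAINTIES",
    "ANSWER_POLARITIES",
    "TRIAL_TYPES",
    "SchemaError",
    "ExperimentDataset",
    "read_trials",
    "write_trials",
    "read_osf_deposit",
    "config_hash",
]

CONTEXT_TYPES = ("negative", "neutral", "positive")
ANSWER_CERTAINTIES = ("exhaustive", "high-certainty", "low-certainty", "non-answer")
ANSWER_POLARITIES = ("positive", "negative")
TRIAL_TYPES = ("main", "attention", "reasoning")

#: Required columns, in canonical order.  truth_* columns are optional
#: generator provenance and pass through unvalidated.
SCHEMA_COLUMNS = (
    "participant_id",
    "trial_index",
    "trial_type",
    "vignette_id",
    "context_type",
    "answer_certainty",
    "answer_polarity",
    "prior_prob",
    "prior_commit",
    "post_prob",
    "post_commit",
    "relevance",
)

_FLOAT_COLS = ("prior_prob", "post_prob", "relevance")
_COMMIT_COLS = ("prior_commit", "post_commit")


class SchemaError(ValueError):
    """Raised when a trial table violates the schema; carries row details."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        msg = "; ".join(problems[:20])
        if len(problems) > 20:
            msg += f"; ... ({len(problems) - 20} more)"
        super().__init__(f"trial table violates schema: {msg}")


@dataclass
class ExperimentDataset:
    """A collection of trials plus generation/provenance metadata."""

    trials: pd.DataFrame
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def main_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["trial_type"] == "main"]

    @property
    def participants(self) -> list:
        return list(dict.fromkeys(self.trials["participant_id"]))

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def subset(self, participant_ids) -> "ExperimentDataset":
        keep = self.trials["participant_id"].isin(set(participant_ids))
        return ExperimentDataset(
            self.trials[keep].reset_index(drop=True), seed=self.seed, config=self.config
        )


def _validate(df: pd.DataFrame, relevance_only: bool) -> None:
    problems: list[str] = []
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"missing columns: {missing}"])
    main = df["trial_type"] == "main"
    for i, row in df.iterrows():
        if row["trial_type"] not in TRIAL_TYPES:
            problems.append(f"row {i}: bad trial_type {row['trial_type']!r}")
            continue
        if row["trial_type"] == "main":
            if row["context_type"] not in CONTEXT_TYPES:
                problems.append(f"row {i}: bad context_type {row['context_type']!r}")
            if row["answer_certainty"] not in ANSWER_CERTAINTIES:
                problems.append(f"row {i}: bad answer_certainty {row['answer_certainty']!r}")
            if row["answer_polarity"] not in ANSWER_POLARITIES:
                problems.append(f"row {i}: bad answer_polarity {row['answer_polarity']!r}")
    belief_required = not relevance_only
    for col in _FLOAT_COLS:
        vals = pd.to_numeric(df.loc[main, col], errors="coerce")
        required = (col == "relevance") or belief_required
        bad = vals.notna() & ((vals < 0) | (vals > 1))
        for i in df.loc[main].index[bad]:
            problems.append(f"row {i}: {col} outside [0, 1]")
        if required and vals.isna().any() and col != "relevance":
            for i in df.loc[main].index[vals.isna()]:
                problems.append(f"row {i}: missing {col}")
    if belief_required:
        for col in _COMMIT_COLS:
            vals = pd.to_numeric(df.loc[main, col], errors="coerce")
            bad = vals.notna() & (~vals.isin(range(1, 8)))
            for i in df.loc[main].index[bad]:
                problems.append(f"row {i}: {col} not an integer 1..7")
    if problems:
        raise SchemaError(problems)


def read_trials(path, *, relevance_only: bool = False) -> ExperimentDataset:
    """Load and validate a trial CSV; row-level problems raise a single
    :class:`SchemaError` naming the offending rows."""
    path = Path(path)
    df = pd.read_csv(path)
    _validate(df, relevance_only)
    seed = None
    config: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        seed = meta.get("seed")
        config = meta.get("config", {})
    return ExperimentDataset(df, seed=seed, config=config)


def write_trials(dataset: ExperimentDataset, path) -> Path:
    """Write the dataset CSV plus a JSON sidecar with seed and config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.trials.to_csv(path, index=False, float_format="%.6f")
    sidecar = path.with_suffix(".json")
    meta = {
        "seed": dataset.seed,
        "config": dataset.config,
        "config_hash": config_hash(dataset.config),
        "n_trials": int(len(dataset.trials)),
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=_jsonable))
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def config_hash(config: dict) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


#: Column mapping from the public study deposit to the canonical schema.
#: Untested against the remote data; provided as a documented stub only.
_OSF_COLUMN_MAP = {
    "submission_id": "participant_id",
    "trial_number": "trial_index",
    "trial_name": "trial_type",
    "vignette": "vignette_id",
    "ContextType": "context_type",
    "AnswerCertainty": "answer_certainty",
    "AnswerPolarity": "answer_polarity",
    "prior": "prior_prob",
    "prior_confidence": "prior_commit",
    "posterior": "post_prob",
    "posterior_confidence": "post_commit",
    "relevance": "relevance",
}


def read_osf_deposit(path, *, relevance_only: bool = False) -> ExperimentDataset:
    """Best-effort loader for the deposited study data (column-name stub).

    Renames deposit columns to the canonical schema and validates.  Ships
    untested against the remote deposit; expect to adjust the mapping.
    """
    df = pd.read_csv(path).rename(columns=_OSF_COLUMN_MAP)
    for col in SCHEMA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    _validate(df, relevance_only)
    return ExperimentDataset(df)
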
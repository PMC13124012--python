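"""Comparing fitted measures against relevance judgments.

Two scale-free comparison criteria are computed for every measure:
per-trial mean squared error (on which the parameters were fitted) and an
item-level Pearson correlation, where an "item" is one answer-in-context
cell (vignette x certainty x polarity x context) and judgments are
averaged over the participants who saw it.  Measures are then ranked by
each criterion, rankings compared by Spearman correlation, and per-trial
rank differences (predicted rank minus observed-relevance rank) expose
where a measure systematically under- or over-predicts relevance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .beliefs import MeasureParams
from .fitting import measure_predictions
from .measures import MEASURE_NAMES

__all__ = [
    "ITEM_KEYS",
    "item_means",
    "item_level_correlation",
    "rank_measures",
    "rank_difference_table",
    "ordinal_condition_checks",
]

ITEM_KEYS = ["vignette_id", "context_type", "answer_certainty", "answer_polarity"]


def _main(df_like) -> pd.DataFrame:
    df = df_like.trials if hasattr(df_like, "trials") else df_like
    if "trial_type" in df.columns:
        df = df[df["trial_type"] == "main"]
    return df


def item_means(data, *, require_beliefs: bool = True) -> pd.DataFrame:
    """Per-item means of the quintuple components.

    Commitment means stay real-valued; the linking function accepts real
    exponents, so no rounding back to Likert levels is needed.
    """
    df = _main(data)
    cols = ["prior_prob", "prior_commit", "post_prob", "post_commit", "relevance"]
    if not require_beliefs:
        cols = ["relevance"]
    grouped = df.groupby(ITEM_KEYS, dropna=False)[cols].mean().reset_index()
    return grouped


def item_level_correlation(
    data,
    measure_name: str,
    params: MeasureParams | None = None,
    scale_coef: float | None = None,
    relevance_data=None,
) -> float:
    """Pearson correlation between item-mean relevance and the measure
    computed from item-mean beliefs.

    ``relevance_data`` supports the two-dataset mode: beliefs averaged
    from ``data``, relevance averaged from a second dataset sharing the
    same items (e.g. a relevance-only run).
    """
    beliefs = item_means(data)
    if relevance_data is not None:
        rel = item_means(relevance_data, require_beliefs=False)
        merged = beliefs.drop(columns="relevance").merge(rel, on=ITEM_KEYS, how="inner")
    else:
        merged = beliefs
    merged = merged.dropna(
        subset=["prior_prob", "prior_commit", "post_prob", "post_commit", "relevance"]
    )
    if len(merged) < 3:
        raise ValueError("item-level correlation needs at least 3 items")
    pred = measure_predictions(
        measure_name,
        merged["prior_prob"].to_numpy(),
        merged["prior_commit"].to_numpy(),
        merged["post_prob"].to_numpy(),
        merged["post_commit"].to_numpy(),
        params,
        scale_coef,
    )
    r_obs = merged["relevance"].to_numpy()
    if np.std(pred) == 0 or np.std(r_obs) == 0:
        raise ValueError("item-level correlation undefined: zero variance")
    return float(stats.pearsonr(pred, r_obs)[0])


def rank_measures(score_lists: dict, higher_is_better: dict | bool = True) -> dict:
    """Rank the registry by each score list and compare rankings.

    ``score_lists`` maps a label (e.g. "mse", "correlation") to a
    ``{measure: score}`` mapping over the full registry.
    ``higher_is_better`` may be a single flag or a per-label mapping.
    Ties are broken by registry order (documented, deterministic).

    Returns ``{"rankings": {label: [measures best-first]},
    "spearman": {(label_a, label_b): rho}}``.
    """
    if len(score_lists) < 1:
        raise ValueError("need at least one score list")
    for label, scores in score_lists.items():
        if set(scores) != set(MEASURE_NAMES):
            raise ValueError(f"score list {label!r} does not cover the registry")

    def better_flag(label):
        if isinstance(higher_is_better, dict):
            return higher_is_better[label]
        return higher_is_better

    rankings = {}
    rank_vectors = {}
    for label, scores in score_lists.items():
        sign = -1.0 if better_flag(label) else 1.0
        keyed = sorted(
            MEASURE_NAMES, key=lambda m: (sign * scores[m], MEASURE_NAMES.index(m))
        )
        rankings[label] = list(keyed)
        rank_vectors[label] = np.array([keyed.index(m) for m in MEASURE_NAMES])

    spearman = {}
    labels = list(score_lists)
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            rho = stats.spearmanr(rank_vectors[la], rank_vectors[lb]).statistic
            spearman[(la, lb)] = float(rho)
    return {"rankings": rankings, "spearman": spearman}


def rank_difference_table(
    data,
    measure_name: str,
    params: MeasureParams | None = None,
    scale_coef: float | None = None,
) -> pd.DataFrame:
    """Per-trial (rank by measure) - (rank by observed relevance).

    Ranks use average ties, so the differences sum to zero over a
    complete dataset.  Negative differences mark trials where the
    measure under-predicts relevance.
    """
    df = _main(data).dropna(
        subset=["prior_prob", "prior_commit", "post_prob", "post_commit", "relevance"]
    )
    if len(df) < 2:
        raise ValueError("rank differences need at least 2 trials")
    pred = measure_predictions(
        measure_name,
        df["prior_prob"].to_numpy(),
        df["prior_commit"].to_numpy(),
        df["post_prob"].to_numpy(),
        df["post_commit"].to_numpy(),
        params,
        scale_coef,
    )
    out = df[["participant_id", "trial_index", "prior_prob", "post_prob", "relevance"]].copy()
    out["measure_value"] = pred
    out["rank_measure"] = stats.rankdata(pred, method="average")
    out["rank_relevance"] = stats.rankdata(df["relevance"].to_numpy(), method="average")
    out["rank_difference"] = out["rank_measure"] - out["rank_relevance"]
    return out.reset_index(drop=True)


def ordinal_condition_checks(
    data, n_boot: int = 1000, seed: int = 0, ci: float = 0.95
) -> pd.DataFrame:
    """Design-manipulation sanity checks with bootstrap intervals.

    Verifies the expected orderings by group means: relevance increasing
    in answer information (non-answer < low-certainty < high-certainty <
    exhaustive) and prior probability increasing with context bias
    (negative < neutral < positive).  Each row reports one adjacent
    comparison, its mean difference, a seeded bootstrap percentile
    interval, and whether the direction holds.
    """
    df = _main(data)
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2

    def compare(col, group_col, lower, upper):
        a = df.loc[df[group_col] == lower, col].dropna().to_numpy()
        b = df.loc[df[group_col] == upper, col].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            raise ValueError(f"missing condition {lower!r} or {upper!r}")
        diff = b.mean() - a.mean()
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = (
                rng.choice(b, b.size).mean() - rng.choice(a, a.size).mean()
            )
        lo, hi = np.quantile(boots, [lo_q, hi_q])
        return {
            "comparison": f"{lower} < {upper}",
            "measure": col,
            "mean_difference": float(diff),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "passes": bool(diff > 0),
        }

    rows = [
        compare("relevance", "answer_certainty", "non-answer", "low-certainty"),
        compare("relevance", "answer_certainty", "low-certainty", "high-certainty"),
        compare("relevance", "answer_certainty", "high-certainty", "exhaustive"),
        compare("prior_prob", "context_type", "negative", "neutral"),
        compare("prior_prob", "context_type", "neutral", "positive"),
    ]
    return pd.DataFrame(rows)
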
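"""Model/Results front door for the relevance-measure comparison.

``RelevanceModel`` wraps a trial table (the per-trial quintuples
<p, c, q, d, r> with condition labels), applies the study's exclusion
filters, and on ``fit()`` estimates every registry measure's free
parameters by mean squared error.  The returned ``RelevanceResults``
carries the fitted parameters, per-measure MSE, and the comparison
machinery: item-level correlations, measure rankings with Spearman rank
agreement, per-trial rank-difference diagnostics, and a ``summary()``
table.

Typical use::

    from epirel import RelevanceModel, generate_experiment

    data = generate_experiment(n_participants=50, seed=7)
    res = RelevanceModel.from_dataset(data).fit()
    print(res.summary())
    res.item_correlations()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation, fitting, preprocessing
from .fitting import FitResult, SearchConfig, fits_table
from .io import ExperimentDataset, read_trials
from .measures import MEASURE_NAMES

__all__ = ["RelevanceModel", "RelevanceResults"]


class RelevanceModel:
    """Comparison of epistemic-relevance measures on one trial table.

    Parameters
    ----------
    data : ExperimentDataset or DataFrame
        Trials in the canonical schema.
    apply_exclusions : bool
        Run the attention / reasoning / sensitivity filters before
        fitting (default True when check trials are present).
    exp2_mode : bool
        Relevance-only protocol: relaxes the reasoning criterion to
        both-trials-wrong and skips the sensitivity criterion.
    """

    def __init__(self, data, *, apply_exclusions: bool | None = None,
                 exp2_mode: bool = False):
        if isinstance(data, pd.DataFrame):
            data = ExperimentDataset(data)
        self.dataset = data
        self.exp2_mode = exp2_mode
        has_checks = (data.trials["trial_type"] != "main").any()
        if apply_exclusions is None:
            apply_exclusions = bool(has_checks)
        self.exclusion_report = None
        if apply_exclusions:
            self.exclusion_report = preprocessing.apply_exclusions(
                data,
                reasoning_mode="both_wrong" if exp2_mode else "half",
                sensitivity_threshold=None if exp2_mode else 0.75,
            )
            self.data = self.exclusion_report.retained
        else:
            self.data = data

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RelevanceModel":
        return cls(read_trials(path, relevance_only=kwargs.get("exp2_mode", False)),
                   **kwargs)

    @classmethod
    def from_dataset(cls, dataset: ExperimentDataset, **kwargs) -> "RelevanceModel":
        return cls(dataset, **kwargs)

    @property
    def n_participants(self) -> int:
        return self.data.n_participants

    def fit(self, measures=None, search: SearchConfig | None = None) -> "RelevanceResults":
        """Fit free parameters of every (requested) measure independently."""
        names = list(measures) if measures is not None else list(MEASURE_NAMES)
        fits: dict[str, FitResult] = {}
        for name in names:
            fits[name] = fitting.fit_measure(self.data, name, search)
        return RelevanceResults(self, fits)


class RelevanceResults:
    """Fitted measure parameters, fit quality, and comparison diagnostics."""

    def __init__(self, model: RelevanceModel, fits: dict[str, FitResult]):
        self.model = model
        self.fits = fits

    @property
    def params(self) -> pd.DataFrame:
        """Best-fit parameter table (measure, a, b, r, mse)."""
        full = {n: self.fits.get(n) for n in MEASURE_NAMES}
        rows = {n: f for n, f in full.items() if f is not None}
        return fits_table(rows) if len(rows) == len(MEASURE_NAMES) else pd.DataFrame(
            [f.to_dict() for f in self.fits.values()]
        )

    @property
    def mse(self) -> pd.Series:
        return pd.Series({n: f.mse for n, f in self.fits.items()}, name="mse")

    def predict(self, measure_name: str) -> np.ndarray:
        """Per-trial predicted relevance under a fitted measure."""
        f = self.fits[measure_name]
        p, c, q, d, _ = fitting._arrays(self.model.data)
        return fitting.measure_predictions(
            measure_name, p, c, q, d, f.params, f.scale_coef
        )

    def item_correlations(self, relevance_data=None) -> pd.Series:
        """Item-level Pearson correlation per fitted measure."""
        out = {}
        for name, f in self.fits.items():
            out[name] = evaluation.item_level_correlation(
                self.model.data, name, f.params, f.scale_coef, relevance_data
            )
        return pd.Series(out, name="pearson_r")

    def rank_measures(self, relevance_data=None) -> dict:
        """Rank the registry by MSE and by item correlation; Spearman agreement."""
        scores = {
            "mse": self.mse.to_dict(),
            "correlation": self.item_correlations(relevance_data).to_dict(),
        }
        return evaluation.rank_measures(
            scores, higher_is_better={"mse": False, "correlation": True}
        )

    def rank_difference_table(self, measure_name: str) -> pd.DataFrame:
        f = self.fits[measure_name]
        return evaluation.rank_difference_table(
            self.model.data, measure_name, f.params, f.scale_coef
        )

    def ordinal_checks(self, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
        return evaluation.ordinal_condition_checks(self.model.data, n_boot, seed)

    def comparison_report(self, relevance_data=None) -> dict:
        """JSON-ready per-measure scores, rankings and rank agreement."""
        corr = self.item_correlations(relevance_data)
        ranks = self.rank_measures(relevance_data)
        return {
            "per_measure": {
                n: {"mse": float(self.fits[n].mse), "pearson_r": float(corr[n])}
                for n in self.fits
            },
            "rankings": ranks["rankings"],
            "spearman": {f"{a}|{b}": v for (a, b), v in ranks["spearman"].items()},
            "n_participants": self.model.n_participants,
        }

    def plot_rank_differences(self, measure_name: str, ax=None):
        """Rank-difference scatter over the prior/posterior plane."""
        import matplotlib.pyplot as plt

        table = self.rank_difference_table(measure_name)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        lim = np.abs(table["rank_difference"]).max() or 1.0
        sc = ax.scatter(
            table["prior_prob"], table["post_prob"],
            c=table["rank_difference"], cmap="RdBu", vmin=-lim, vmax=lim, s=12,
        )
        ax.set_xlabel("prior probability of 'yes'")
        ax.set_ylabel("posterior probability of 'yes'")
        ax.set_title(measure_name)
        plt.colorbar(sc, ax=ax, label="rank difference")
        return ax

    def summary(self):
        """Text summary table in the statsmodels style."""
        from statsmodels.iolib.table import SimpleTable

        corr = None
        try:
            corr = self.item_correlations()
        except ValueError:
            pass
        headers = ["measure", "a", "b", "r", "coef", "MSE", "item r"]
        rows = []
        for name, f in self.fits.items():
            rows.append(
                [
                    name,
                    _fmt(f.params.a_link),
                    _fmt(f.params.b_link),
                    _fmt(f.params.r_scale),
                    _fmt(f.scale_coef),
                    _fmt(f.mse, 5),
                    _fmt(None if corr is None else corr[name], 3),
                ]
            )
        title = (
            f"Epistemic relevance measure comparison "
            f"(n={self.model.n_participants} participants)"
        )
        return SimpleTable(rows, headers, title=title)


def _fmt(x, nd: int = 3) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "--"
    if isinstance(x, float) and (abs(x) >= 1e4 or (x != 0 and abs(x) < 1e-3)):
        return f"{x:.3g}"
    return f"{x:.{nd}f}"
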
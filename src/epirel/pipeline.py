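"""Config-driven pipeline: simulate -> preprocess -> fit -> evaluate -> report.

The config is a plain mapping (typically loaded from YAML) with a
``stages`` list and per-stage parameter blocks.  Every artifact written
embeds the seed and a hash of the config it was produced from, so reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import simulate
from .fitting import SearchConfig, fit_all, fits_table
from .io import ExperimentDataset, config_hash, read_trials, write_trials
from .measures import MEASURE_NAMES, evaluate_measure
from .model import RelevanceModel, RelevanceResults
from .preprocessing import apply_exclusions

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG", "measures_table"]

log = logging.getLogger("epirel")

STAGES = ("simulate", "preprocess", "measures", "fit", "evaluate", "report")

DEFAULT_CONFIG: dict = {
    "stages": ["simulate", "preprocess", "measures", "fit", "evaluate", "report"],
    "seed": 0,
    "simulate": {"n_participants": 50, "generating_measure": "bayes_factor_utility",
                 "noise_sd": 0.05},
    "preprocess": {"exp2_mode": False},
    "fit": {},
    "evaluate": {"n_boot": 1000},
}


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    unknown = [s for s in cfg.get("stages", []) if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    return cfg


def measures_table(dataset: ExperimentDataset) -> pd.DataFrame:
    """Tidy table: one row per main trial x registry measure."""
    rows = []
    main = dataset.main_trials.dropna(
        subset=["prior_prob", "prior_commit", "post_prob", "post_commit"]
    )
    for name in MEASURE_NAMES:
        vals = evaluate_measure(
            name,
            main["prior_prob"].to_numpy(),
            main["prior_commit"].to_numpy(),
            main["post_prob"].to_numpy(),
            main["post_commit"].to_numpy(),
        )
        block = main[["participant_id", "trial_index", "relevance"]].copy()
        block["measure"] = name
        block["value"] = vals
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: dict, out_dir, *, input_csv=None) -> dict:
    """Execute the requested stages in order; returns paths of artifacts.

    ``input_csv`` supplies the dataset when "simulate" is not among the
    stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
    seed = int(config.get("seed", 0))
    chash = config_hash(config)
    artifacts: dict[str, str] = {}
    results: RelevanceResults | None = None
    dataset: ExperimentDataset | None = None

    def _stamp(payload: dict) -> dict:
        return {"seed": seed, "config_hash": chash, **payload}

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            sim_cfg = dict(config.get("simulate", {}))
            dataset = simulate.generate_experiment(seed=seed, **sim_cfg)
            artifacts["dataset"] = str(write_trials(dataset, out / "trials.csv"))
        elif stage == "preprocess":
            dataset = dataset or _load_input(input_csv, config)
            pre = config.get("preprocess", {})
            exp2 = bool(pre.get("exp2_mode", False))
            report = apply_exclusions(
                dataset,
                reasoning_mode="both_wrong" if exp2 else "half",
                sensitivity_threshold=None if exp2 else pre.get("sensitivity_threshold", 0.75),
            )
            artifacts["exclusions"] = str(report.to_json(out / "exclusions.json"))
            artifacts["filtered"] = str(
                write_trials(report.retained, out / "trials_filtered.csv")
            )
            dataset = report.retained
        elif stage == "measures":
            dataset = dataset or _load_input(input_csv, config)
            table = measures_table(dataset)
            path = out / "measures.csv"
            table.to_csv(path, index=False, float_format="%.6f")
            artifacts["measures"] = str(path)
        elif stage == "fit":
            dataset = dataset or _load_input(input_csv, config)
            search = SearchConfig(**config.get("fit", {}).get("search", {}))
            model = RelevanceModel(dataset, apply_exclusions=False)
            results = model.fit(search=search)
            (out / "fits.json").write_text(
                json.dumps(
                    _stamp({"fits": [f.to_dict() for f in results.fits.values()]}),
                    indent=2,
                )
            )
            fits_table(results.fits).to_csv(out / "fits.csv", index=False)
            artifacts["fits"] = str(out / "fits.json")
        elif stage == "evaluate":
            if results is None:
                raise ValueError('stage "evaluate" requires a prior "fit" stage')
            report = results.comparison_report()
            (out / "comparison.json").write_text(json.dumps(_stamp(report), indent=2))
            pd.DataFrame(report["per_measure"]).T.to_csv(out / "comparison.csv")
            artifacts["comparison"] = str(out / "comparison.json")
        elif stage == "report":
            if results is None:
                raise ValueError('stage "report" requires a prior "fit" stage')
            checks = results.ordinal_checks(
                n_boot=int(config.get("evaluate", {}).get("n_boot", 1000)), seed=seed
            )
            checks.to_csv(out / "ordinal_checks.csv", index=False)
            (out / "summary.txt").write_text(str(results.summary()) + "\n")
            artifacts["report"] = str(out / "summary.txt")
        log.info("stage %s finished in %.2fs (seed=%d)", stage, time.perf_counter() - t0, seed)
    return artifacts


def _load_input(input_csv, config) -> ExperimentDataset:
    if input_csv is None:
        raise ValueError("no dataset: include the simulate stage or pass an input CSV")
    exp2 = bool(config.get("preprocess", {}).get("exp2_mode", False))
    return read_trials(input_csv, relevance_only=exp2)
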
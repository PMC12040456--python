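"""End-to-end pipeline: simulate, screen, select, rank, report.

``run_pipeline`` chains the stages — OFAT table generation, per-genus
and pooled MANOVA of the treatment-series effect, composite-score model
selection, factor-importance ranking, optimum location and summary
reporting — writing every table of the report bundle as CSV under the
output directory.  All randomness flows from the seed block of the
configuration, so two runs with the same configuration produce
byte-identical bundles (for deterministic roster families).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio, importance, manova_stats, model_eval, synthetic_data
from .dataio import (FACTOR_COLUMNS, NUMERIC_FACTORS, RESPONSE_COLUMNS,
                     encode_features)
from .model_eval import DEFAULT_GRIDS, DEFAULT_ROSTER, FAMILIES

log = logging.getLogger("algaeopt")

STAGES = ("generate", "manova", "select", "importance", "report")


class ConfigError(ValueError):
    """Invalid pipeline configuration (raised before any computation)."""


@dataclass
class PipelineConfig:
    """Everything a run needs; seeds are mandatory, never wall-clock."""

    replicates: int = 3
    seeds: dict = field(default_factory=lambda: {
        "generate": 0, "split": 1, "cv": 2, "model": 3})
    design_overrides: dict = field(default_factory=dict)
    roster: tuple = DEFAULT_ROSTER
    grids: dict = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    k_folds: int = 5
    branches: tuple = ("none",)
    #: responses used for the model-selection leaderboard stage
    selection_targets: tuple = ("biomass",)
    #: 'auto': use the selected family when it supports impurity
    #: importances, otherwise fall back to the tuned forest
    importance_family: str = "auto"
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.roster = tuple(self.roster)
        self.branches = tuple(
            b if isinstance(b, str) else (b[0], int(b[1])) for b in self.branches)
        self.selection_targets = tuple(self.selection_targets)
        for fam in self.roster:
            if fam not in FAMILIES:
                raise ConfigError(f"unknown roster family {fam!r}")
        for key in ("generate", "split", "cv", "model"):
            if key not in self.seeds:
                raise ConfigError(f"missing seed {key!r}")
            if not isinstance(self.seeds[key], (int, np.integer)):
                raise ConfigError(f"seed {key!r} must be an integer")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        for t in self.selection_targets:
            if t not in RESPONSE_COLUMNS:
                raise ConfigError(f"unknown selection target {t!r}")
        if self.importance_family != "auto" \
                and self.importance_family not in FAMILIES:
            raise ConfigError(
                f"unknown importance family {self.importance_family!r}")
        for b in self.branches:
            if b == "none":
                continue
            kind, k = b
            if kind not in ("pca", "select"):
                raise ConfigError(f"unknown reduction branch {kind!r}")

    def with_master_seed(self, seed: int) -> "PipelineConfig":
        """Derive the four stage seeds from one master seed (kept < 2^31)."""
        derived = {name: int((seed * 4 + i) % (2**31 - 1))
                   for i, name in enumerate(("generate", "split", "cv", "model"))}
        cfg = PipelineConfig(**{**self.__dict__, "seeds": derived})
        cfg.validate()
        return cfg


@dataclass
class ReportBundle:
    table: pd.DataFrame
    manova: pd.DataFrame
    leaderboards: dict  # response -> metric-by-family frame
    selection: pd.DataFrame
    importance: pd.DataFrame
    top_factors: pd.DataFrame
    optimal_conditions: pd.DataFrame
    series_summary: pd.DataFrame
    correlations: pd.DataFrame


def summarize_by_series(table: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary per (genus, response, treatment series).

    Quartiles use linear interpolation, matching the convention of the
    box plots such summaries feed.
    """
    if table.empty:
        raise ValueError("table must be non-empty")
    rows = []
    for (genus, varied), sub in table.groupby(["genus", "varied_factor"],
                                              sort=True):
        for response in RESPONSE_COLUMNS:
            vals = sub[response].to_numpy(dtype=float)
            q = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0])
            rows.append({"genus": genus, "response": response,
                         "varied_factor": varied, "min": q[0], "q1": q[1],
                         "median": q[2], "q3": q[3], "max": q[4]})
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations over numeric factors and responses.

    Zero-variance columns yield NaN entries (undefined correlation);
    the diagonal is 1 wherever defined.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlations")
    cols = list(NUMERIC_FACTORS) + list(RESPONSE_COLUMNS)
    corr = table[cols].corr(method="pearson")
    return corr


def run_pipeline(config: PipelineConfig, outdir=None) -> ReportBundle:
    """Execute all stages in order and write the report bundle as CSVs."""
    config.validate()
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings = []

    def stage(name):
        log.info("stage %s", name)
        timings.append((name, time.perf_counter()))

    try:
        stage("generate")
        design = synthetic_data.build_design(config.design_overrides)
        surfaces = synthetic_data.default_surfaces(design)
        table = synthetic_data.generate_experiment(
            design, surfaces, config.replicates, config.seeds["generate"])
        dataio.write_experiment_csv(table, out / "experiment.csv")

        stage("manova")
        manova = manova_stats.manova_table(
            table, RESPONSE_COLUMNS, grouping="varied_factor", by="genus")
        manova.to_csv(out / "manova.csv", index=False)

        stage("select")
        leaderboards = {}
        selection_rows = []
        selected_family = None
        for target in config.selection_targets:
            enc = encode_features(table, design)
            y = table[target].to_numpy(dtype=float)
            res = model_eval.grid_search(
                config.roster, config.grids, enc.X, y, k=config.k_folds,
                seed=config.seeds["cv"], branches=config.branches)
            lb = model_eval.leaderboard_frame(res.leaderboard)
            lb.to_csv(out / f"leaderboard_{target}.csv")
            leaderboards[target] = lb
            selection_rows.append({
                "response": target, "family": res.best.family,
                "candidate": res.best.label(),
                **{f"holdout_{k}": v
                   for k, v in res.holdout_metrics.as_dict().items()},
            })
            if selected_family is None:
                selected_family = res.best.family
        selection = pd.DataFrame(selection_rows)
        selection.to_csv(out / "selection.csv", index=False)

        stage("importance")
        fam = config.importance_family
        if fam == "auto":
            fam = selected_family or "random_forest"
            probe = model_eval.make_estimator(
                model_eval.ModelCandidate(fam), seed=0)
            # impurity importances need a tree ensemble; otherwise fall
            # back to the tuned forest
            if not hasattr(probe, "feature_importances_") and fam not in (
                    "random_forest", "gradient_boosting", "decision_tree",
                    "ada_boost", "xgboost"):
                fam = "random_forest"
        profiles = importance.importance_table(
            table, family=fam, seed=config.seeds["model"], design=design)
        prof_frame = importance.profiles_frame(profiles)
        prof_frame.to_csv(out / "importance.csv", index=False)
        top = importance.rank_factors(profiles)
        top.to_csv(out / "top_factors.csv", index=False)

        opt_rows = []
        for genus in sorted(table["genus"].unique()):
            for response in RESPONSE_COLUMNS:
                oc = importance.find_optimal_conditions(table, response,
                                                        genus, design)
                opt_rows.append({"genus": genus, "response": response,
                                 **oc.condition,
                                 "mean_response": oc.mean_response,
                                 "n": oc.n_observations})
        optimal = pd.DataFrame(opt_rows)
        optimal.to_csv(out / "optimal_conditions.csv", index=False)

        stage("report")
        summary = summarize_by_series(table)
        summary.to_csv(out / "series_summary.csv", index=False)
        corr = correlation_matrix(table)
        corr.to_csv(out / "correlations.csv")

        with open(out / "run.log", "w", encoding="utf-8") as fh:
            fh.write(f"seeds: {config.seeds}\n")
            for (name, t0), (nxt, t1) in zip(timings, timings[1:]):
                fh.write(f"{name}: {t1 - t0:.2f}s\n")
            fh.write(f"{timings[-1][0]}: "
                     f"{time.perf_counter() - timings[-1][1]:.2f}s\n")
    except Exception as exc:
        failed = timings[-1][0] if timings else "init"
        raise RuntimeError(
            f"pipeline failed in stage {failed!r}: {exc}") from exc

    return ReportBundle(table, manova, leaderboards, selection, prof_frame,
                        top, optimal, summary, corr)
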
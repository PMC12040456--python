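"""Factor importance from tree ensembles, ranking and optimum location.

Tree ensembles attribute to every encoded feature the mean decrease in
impurity its splits achieve, averaged over trees.  Indicator columns of
the colour factor are pooled back into a single 'light_colour' score
before normalization, so the five environmental factors are compared on
one scale; each profile sums to 1.  The importance stage always works
on the unreduced encoded features (importances in component space would
not map back to factors), refitting the selected ensemble family per
(genus, response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import FACTOR_COLUMNS, RESPONSE_COLUMNS, encode_features
from .model_eval import ModelCandidate, make_estimator
from .synthetic_data import FactorDesign, build_design

__all__ = ["ImportanceProfile", "OptimalCondition", "impurity_importance",
           "rank_factors", "average_profiles", "find_optimal_conditions",
           "importance_table", "fit_importance_model"]


@dataclass(frozen=True)
class ImportanceProfile:
    """Normalized per-factor importance for one (genus, response).

    ``no_signal`` marks the degenerate case of a constant target, where
    all scores are zero and no ranking should be read off.
    """

    genus: str
    response: str
    scores: dict  # factor name -> score, design order
    no_signal: bool = False

    def top_factor(self, design_order=FACTOR_COLUMNS) -> tuple[str, float]:
        best, best_score = None, -np.inf
        for name in design_order:
            if name in self.scores and self.scores[name] > best_score:
                best, best_score = name, self.scores[name]
        return best, best_score


@dataclass(frozen=True)
class OptimalCondition:
    genus: str
    response: str
    condition: dict  # factor name -> level
    mean_response: float
    n_observations: int


def impurity_importance(fitted_model, column_map: dict, genus: str = "",
                        response: str = "") -> ImportanceProfile:
    """Pool encoded-column impurity importances into per-factor scores.

    Raw importances are summed within each source factor (one-hot
    indicator columns pool into their categorical factor), then the
    pooled scores are normalized to sum to 1.
    """
    if not hasattr(fitted_model, "feature_importances_"):
        raise TypeError("model does not expose impurity-based "
                        "feature_importances_")
    raw = np.asarray(fitted_model.feature_importances_, dtype=float)
    cols = list(column_map)
    if len(raw) != len(cols):
        raise ValueError("column_map does not cover the model's features")
    pooled: dict = {}
    for col, imp in zip(cols, raw):
        factor = column_map[col]
        pooled[factor] = pooled.get(factor, 0.0) + float(imp)
    total = sum(pooled.values())
    if total <= 0:
        return ImportanceProfile(genus, response,
                                 {f: 0.0 for f in pooled}, no_signal=True)
    return ImportanceProfile(genus, response,
                             {f: v / total for f, v in pooled.items()})


def rank_factors(profiles, design_order=FACTOR_COLUMNS) -> pd.DataFrame:
    """Top factor per (genus, response); ties break in design order."""
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rows = []
    for prof in profiles:
        top, score = prof.top_factor(design_order)
        rows.append({"genus": prof.genus, "response": prof.response,
                     "top_factor": top, "score": score,
                     "no_signal": prof.no_signal})
    return pd.DataFrame(rows)


def average_profiles(profiles) -> ImportanceProfile:
    """Mean profile over genera for one response, re-normalized."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("profiles must be non-empty")
    responses = {p.response for p in profiles}
    if len(responses) != 1:
        raise ValueError(f"profiles mix responses: {sorted(responses)}")
    factors = list(profiles[0].scores)
    if any(list(p.scores) != factors for p in profiles):
        raise ValueError("profiles have mismatched factor sets")
    mean = {f: float(np.mean([p.scores[f] for p in profiles])) for f in factors}
    total = sum(mean.values())
    if total <= 0:
        return ImportanceProfile("average", profiles[0].response, mean,
                                 no_signal=True)
    return ImportanceProfile("average", profiles[0].response,
                             {f: v / total for f, v in mean.items()})


def find_optimal_conditions(table: pd.DataFrame, response: str, genus: str,
                            design: FactorDesign | None = None) -> OptimalCondition:
    """Factor combination with the highest mean response for one genus.

    Observations are grouped by the full factor combination; ties between
    combinations break toward the design-order lexicographically smallest
    one (by level index).
    """
    design = design or build_design()
    if response not in RESPONSE_COLUMNS:
        raise KeyError(f"unknown response {response!r}")
    sub = table[table["genus"] == genus]
    if sub.empty:
        raise KeyError(f"no observations for genus {genus!r}")
    grouped = sub.groupby(list(FACTOR_COLUMNS), sort=False)[response] \
        .agg(["mean", "count"]).reset_index()
    keys = [design.condition_key(dict(r)) for _, r in
            grouped[list(FACTOR_COLUMNS)].iterrows()]
    grouped = grouped.iloc[sorted(range(len(keys)), key=keys.__getitem__)]
    best = None
    for _, row in grouped.iterrows():
        if best is None or row["mean"] > best["mean"]:  # strict >: first wins
            best = row
    cond = {f: best[f] for f in FACTOR_COLUMNS}
    return OptimalCondition(genus, response, cond, float(best["mean"]),
                            int(best["count"]))


#: split controls for the importance refit.  Attribution needs leaves fine
#: enough to isolate single conditions: in a triplicate OFAT layout a
#: factor's sharpest contrast involves only `replicates` rows, and a
#: prediction-tuned leaf size above that makes the contrast unsplittable,
#: silently shifting impurity credit onto factors with many-row contrasts
#: (notably the one-hot colour indicators).
_ATTRIBUTION_PARAMS = {"min_samples_leaf": 1, "min_samples_split": 2}


def fit_importance_model(table: pd.DataFrame, response: str,
                         family: str = "random_forest", seed: int = 0,
                         design: FactorDesign | None = None):
    """Fit the importance ensemble on the full unreduced encoded features."""
    design = design or build_design()
    enc = encode_features(table, design)
    model = make_estimator(ModelCandidate(family), seed=seed)
    if hasattr(model, "get_params"):
        valid = model.get_params()
        model.set_params(**{k: v for k, v in _ATTRIBUTION_PARAMS.items()
                            if k in valid})
    model.fit(enc.X, table[response].to_numpy(dtype=float))
    return model, enc


def importance_table(table: pd.DataFrame, family: str = "random_forest",
                     seed: int = 0, design: FactorDesign | None = None,
                     responses=RESPONSE_COLUMNS) -> list[ImportanceProfile]:
    """Per-(genus, response) profiles plus the cross-genus averages."""
    design = design or build_design()
    profiles = []
    genera = sorted(table["genus"].unique())
    for response in responses:
        per_genus = []
        for genus in genera:
            sub = table[table["genus"] == genus]
            model, enc = fit_importance_model(sub, response, family, seed,
                                              design)
            per_genus.append(impurity_importance(model, enc.column_map,
                                                 genus, response))
        profiles.extend(per_genus)
        profiles.append(average_profiles(per_genus))
    return profiles


def profiles_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for factor, score in p.scores.items():
            rows.append({"genus": p.genus, "response": p.response,
                         "factor": factor, "score": score,
                         "no_signal": p.no_signal})
    return pd.DataFrame(rows)
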
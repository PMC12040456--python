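"""Synthetic one-factor-at-a-time (OFAT) cultivation experiments.

The generator emulates a five-factor screening study on freshwater
microalgae: each treatment series varies a single environmental factor
across its four levels while every other factor is held at a baseline,
each condition run in triplicate, for five genera.  Nine biochemical
responses (biomass, lipid, protein, fibre, ash, moisture, NFE, Na, K)
are drawn from additive response surfaces with planted optima and a
declared factor-dominance ordering, so that downstream recovery of the
dominant factor and of the optimal condition can be tested against a
known ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "FactorDesign",
    "QuadraticEffect",
    "CategoricalEffect",
    "ResponseSurface",
    "GenusSurface",
    "PlantedTruth",
    "build_design",
    "default_surfaces",
    "generate_experiment",
    "planted_truth",
    "GENERA",
    "RESPONSES",
]

GENERA = ("Chlorella", "Botryococcus", "Chlamydomonas", "Tetraselmis", "Closterium")

#: canonical response order: biomass in g/l, six proximate fractions in
#: percent of dry weight, and two minerals in mg per 100 g.
RESPONSES = (
    "biomass", "lipid", "protein", "fibre", "ash", "moisture", "nfe", "na", "k",
)


@dataclass(frozen=True)
class Factor:
    """One environmental factor: its admissible levels and holding value."""

    name: str
    kind: str  # "numeric" | "categorical"
    levels: tuple
    baseline: object
    unit: str = ""

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        if len(self.levels) == 0:
            raise ValueError(f"factor {self.name!r} has an empty level set")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"factor {self.name!r} has duplicate levels")
        if self.baseline not in self.levels:
            raise ValueError(
                f"baseline {self.baseline!r} of factor {self.name!r} "
                "is not one of its levels"
            )

    def level_index(self, level) -> int:
        return self.levels.index(level)


@dataclass(frozen=True)
class FactorDesign:
    """Ordered collection of factors; order fixes all tie-breaking."""

    factors: tuple[Factor, ...]

    def __post_init__(self):
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names in design")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def n_conditions(self) -> int:
        """Number of OFAT conditions (one per factor level, per series)."""
        return sum(len(f.levels) for f in self.factors)

    def baseline_condition(self) -> dict:
        return {f.name: f.baseline for f in self.factors}

    def ofat_conditions(self):
        """Yield (varied_factor, condition dict) for every series level."""
        for f in self.factors:
            for level in f.levels:
                cond = self.baseline_condition()
                cond[f.name] = level
                yield f.name, cond

    def condition_key(self, condition: dict) -> tuple:
        """Level-index tuple in design order; the canonical sort key for
        deterministic lexicographic tie-breaking between conditions."""
        return tuple(f.level_index(condition[f.name]) for f in self.factors)

    def distinct_ofat_conditions(self) -> list[dict]:
        """Distinct OFAT conditions sorted by :meth:`condition_key`."""
        seen = {}
        for _, cond in self.ofat_conditions():
            seen[self.condition_key(cond)] = cond
        return [seen[k] for k in sorted(seen)]


_DEFAULT_FACTORS = (
    ("co2_pct", "numeric", (5.0, 7.0, 9.0, 11.0), 9.0, "%"),
    ("pH", "numeric", (5.0, 7.0, 9.0, 11.0), 7.0, ""),
    ("temperature_C", "numeric", (10.0, 20.0, 30.0, 40.0), 30.0, "degC"),
    ("light_intensity_lux", "numeric", (2000.0, 2500.0, 3000.0, 3500.0), 3000.0, "lux"),
    ("light_colour", "categorical", ("white", "red", "green", "blue"), "white", ""),
)


def build_design(overrides: dict | None = None) -> FactorDesign:
    """Build the five-factor, four-level screening design.

    ``overrides`` maps a factor name to either an iterable of levels or a
    ``{"levels": ..., "baseline": ...}`` mapping.  When the old baseline
    drops out of an overridden level set, the first remaining level
    becomes the baseline.
    """
    overrides = dict(overrides or {})
    factors = []
    for name, kind, levels, baseline, unit in _DEFAULT_FACTORS:
        if name in overrides:
            ov = overrides.pop(name)
            if isinstance(ov, dict):
                levels = tuple(ov.get("levels", levels))
                baseline = ov.get("baseline", baseline)
            else:
                levels = tuple(ov)
            if len(levels) == 0:
                raise ValueError(f"override leaves factor {name!r} with no levels")
            if baseline not in levels:
                baseline = levels[0]
        factors.append(Factor(name, kind, levels, baseline, unit))
    if overrides:
        raise KeyError(f"unknown factors in overrides: {sorted(overrides)}")
    return FactorDesign(tuple(factors))


# ---------------------------------------------------------------------------
# response surfaces


@dataclass(frozen=True)
class QuadraticEffect:
    """Peaked effect of a numeric factor: amplitude at the optimum level,
    falling quadratically to zero at the level farthest from it."""

    amplitude: float
    optimum: float

    def value(self, x: float, levels: tuple) -> float:
        w = max(abs(l - self.optimum) for l in levels)
        if w == 0:
            return self.amplitude
        return self.amplitude * (1.0 - ((x - self.optimum) / w) ** 2)

    def amplitude_over(self, levels: tuple) -> float:
        vals = [self.value(l, levels) for l in levels]
        return max(vals) - min(vals)

    def optimum_level(self, levels: tuple):
        return self.optimum


@dataclass(frozen=True)
class CategoricalEffect:
    """Additive per-level offsets for a categorical factor."""

    offsets: dict

    def value(self, x, levels: tuple) -> float:
        return self.offsets[x]

    def amplitude_over(self, levels: tuple) -> float:
        vals = [self.offsets[l] for l in levels]
        return max(vals) - min(vals)

    def optimum_level(self, levels: tuple):
        # design-order tie-break: first level attaining the max offset
        best = max(self.offsets[l] for l in levels)
        for l in levels:
            if self.offsets[l] == best:
                return l


@dataclass(frozen=True)
class ResponseSurface:
    """Additive surface for one response: base + sum of factor effects,
    Gaussian noise truncated (clipped) at the physical bounds."""

    base: float
    effects: dict  # factor name -> effect
    noise_sd: float
    bounds: tuple[float, float]

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must satisfy min < max")

    def value(self, condition: dict, design: FactorDesign) -> float:
        v = self.base
        for name, eff in self.effects.items():
            v += eff.value(condition[name], design.factor(name).levels)
        return float(np.clip(v, *self.bounds))


@dataclass(frozen=True)
class GenusSurface:
    """All nine response surfaces for one genus."""

    genus: str
    responses: dict  # response name -> ResponseSurface

    def validate(self, design: FactorDesign) -> None:
        for rname, surf in self.responses.items():
            for fname, eff in surf.effects.items():
                fac = design.factor(fname)  # raises on unknown factor
                if isinstance(eff, QuadraticEffect):
                    if eff.optimum not in fac.levels:
                        raise ValueError(
                            f"{self.genus}/{rname}: optimum {eff.optimum!r} "
                            f"is not a level of {fname!r}"
                        )
                elif isinstance(eff, CategoricalEffect):
                    missing = set(fac.levels) - set(eff.offsets)
                    if missing:
                        raise ValueError(
                            f"{self.genus}/{rname}: missing offsets for {missing}"
                        )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth per (genus, response): the dominant factor, the best
    OFAT condition, and the noiseless response there."""

    dominant_factor: dict  # (genus, response) -> factor name
    optimum: dict  # (genus, response) -> condition dict
    optimum_value: dict  # (genus, response) -> float


# Per-genus peak (at the planted optimum) and base (worst-case) response
# levels, loosely following the magnitudes reported for these genera:
# biomass peaks 1.5-1.8 g/l, proteins up to ~50 %, lipids ~10-22 %.
# Each entry: response -> (base, peak, noise_sd).
_GENUS_LEVELS = {
    "Chlorella": {
        "biomass": (0.30, 1.78, 0.05), "lipid": (7.4, 10.2, 0.30),
        "protein": (22.0, 42.9, 1.2), "fibre": (7.0, 10.23, 0.25),
        "ash": (7.0, 9.5, 0.20), "moisture": (3.0, 4.0, 0.10),
        "nfe": (35.0, 50.0, 1.2), "na": (12.0, 13.5, 0.12),
        "k": (0.40, 0.48, 0.006),
    },
    "Botryococcus": {
        "biomass": (0.28, 1.66, 0.05), "lipid": (8.8, 10.78, 0.25),
        "protein": (8.0, 18.7, 0.9), "fibre": (5.6, 7.59, 0.18),
        "ash": (0.50, 0.85, 0.03), "moisture": (9.8, 10.6, 0.08),
        "nfe": (61.0, 67.0, 0.8), "na": (7.3, 7.9, 0.05),
        "k": (9.0, 9.6, 0.06),
    },
    "Chlamydomonas": {
        "biomass": (0.45, 1.95, 0.05), "lipid": (16.8, 21.67, 0.40),
        "protein": (19.8, 49.5, 1.5), "fibre": (5.2, 7.92, 0.22),
        "ash": (13.0, 17.3, 0.30), "moisture": (6.4, 11.6, 0.35),
        "nfe": (12.6, 24.2, 1.0), "na": (10.0, 13.3, 0.25),
        "k": (16.9, 21.7, 0.35),
    },
    "Tetraselmis": {
        "biomass": (0.27, 1.52, 0.05), "lipid": (9.2, 13.09, 0.30),
        "protein": (19.8, 41.8, 1.3), "fibre": (1.3, 2.53, 0.10),
        "ash": (5.8, 7.15, 0.12), "moisture": (2.6, 7.86, 0.30),
        "nfe": (36.0, 49.5, 1.1), "na": (7.4, 10.89, 0.25),
        "k": (8.8, 11.77, 0.22),
    },
    "Closterium": {
        "biomass": (0.45, 1.49, 0.05), "lipid": (10.8, 12.87, 0.20),
        "protein": (19.8, 41.8, 1.3), "fibre": (7.2, 8.91, 0.15),
        "ash": (12.4, 13.8, 0.12), "moisture": (6.1, 8.2, 0.15),
        "nfe": (12.6, 35.0, 1.4), "na": (8.2, 10.7, 0.18),
        "k": (10.1, 11.2, 0.10),
    },
}

# Relative factor-effect weights per response (fractions of peak - base).
# They fix the dominance ordering: CO2 leads biomass, lipid, ash, Na and K;
# pH leads protein, fibre, moisture and NFE, matching the qualitative
# pattern the screening design is meant to expose.
_RESPONSE_WEIGHTS = {
    "biomass": {"co2_pct": 0.60, "pH": 0.17, "temperature_C": 0.13,
                "light_intensity_lux": 0.07, "light_colour": 0.03},
    "lipid": {"co2_pct": 0.35, "pH": 0.25, "light_intensity_lux": 0.20,
              "temperature_C": 0.15, "light_colour": 0.05},
    "protein": {"pH": 0.40, "co2_pct": 0.30, "temperature_C": 0.15,
                "light_intensity_lux": 0.10, "light_colour": 0.05},
    "fibre": {"pH": 0.35, "temperature_C": 0.25, "co2_pct": 0.20,
              "light_intensity_lux": 0.12, "light_colour": 0.08},
    "ash": {"co2_pct": 0.35, "light_intensity_lux": 0.25, "temperature_C": 0.20,
            "pH": 0.15, "light_colour": 0.05},
    "moisture": {"pH": 0.40, "light_intensity_lux": 0.25, "temperature_C": 0.20,
                 "co2_pct": 0.10, "light_colour": 0.05},
    "nfe": {"pH": 0.55, "co2_pct": 0.20, "temperature_C": 0.12,
            "light_intensity_lux": 0.08, "light_colour": 0.05},
    "na": {"co2_pct": 0.30, "light_colour": 0.25, "pH": 0.20,
           "light_intensity_lux": 0.15, "temperature_C": 0.10},
    "k": {"co2_pct": 0.30, "light_intensity_lux": 0.25, "pH": 0.20,
          "temperature_C": 0.15, "light_colour": 0.10},
}

# Responses whose colour optimum is red rather than the white baseline
# (red light favours protein and lipid accumulation in these genera).
_RED_OPTIMAL = frozenset({"protein", "lipid"})

_RESPONSE_BOUNDS = {
    "biomass": (0.2, 2.1),  # g/l
    "na": (0.0, 50.0), "k": (0.0, 50.0),  # mg/100 g
}
_PCT_BOUNDS = (0.0, 100.0)

#: colour offsets as fractions of the colour amplitude, per optimum colour
_COLOUR_SHAPES = {
    "white": {"white": 1.0, "red": 0.6, "green": 0.2, "blue": 0.0},
    "red": {"red": 1.0, "white": 0.6, "green": 0.2, "blue": 0.0},
}


def default_surfaces(design: FactorDesign | None = None) -> list[GenusSurface]:
    """Default response surfaces for the five genera.

    Planted optima sit at the design baselines (CO2 9 %, pH 7, 30 degC,
    3000 lux, white light) except that red light is optimal for protein
    and lipid.
    """
    design = design or build_design()
    surfaces = []
    for genus in GENERA:
        resp = {}
        for rname in RESPONSES:
            base, peak, sd = _GENUS_LEVELS[genus][rname]
            span = peak - base
            weights = _RESPONSE_WEIGHTS[rname]
            effects = {}
            for fac in design.factors:
                amp = span * weights[fac.name]
                if fac.kind == "numeric":
                    effects[fac.name] = QuadraticEffect(amp, fac.baseline)
                else:
                    opt = "red" if rname in _RED_OPTIMAL else "white"
                    shape = _COLOUR_SHAPES[opt]
                    effects[fac.name] = CategoricalEffect(
                        {l: amp * shape[l] for l in fac.levels}
                    )
            bounds = _RESPONSE_BOUNDS.get(rname, _PCT_BOUNDS)
            resp[rname] = ResponseSurface(base, effects, sd, bounds)
        surfaces.append(GenusSurface(genus, resp))
    return surfaces


# ---------------------------------------------------------------------------
# generation


def generate_experiment(
    design: FactorDesign,
    surfaces: list[GenusSurface],
    replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the full OFAT experiment table.

    One row per (genus, treatment series, level, replicate); responses are
    the noiseless surface value plus truncated Gaussian noise.  The same
    seed always yields a byte-identical table.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible generation")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for s in surfaces:
        s.validate(design)

    rng = np.random.default_rng(seed)
    rows = []
    for gsurf in surfaces:
        for varied, cond in design.ofat_conditions():
            for rep in range(1, replicates + 1):
                row = {"genus": gsurf.genus, "varied_factor": varied,
                       "replicate": rep}
                row.update(cond)
                for rname in RESPONSES:
                    surf = gsurf.responses[rname]
                    noiseless = surf.value(cond, design)
                    val = noiseless + rng.normal(0.0, surf.noise_sd) \
                        if surf.noise_sd > 0 else noiseless
                    row[rname] = float(np.clip(val, *surf.bounds))
                rows.append(row)
    from .dataio import COLUMN_ORDER  # canonical schema lives in dataio

    return pd.DataFrame(rows, columns=COLUMN_ORDER)


def planted_truth(
    surfaces: list[GenusSurface], design: FactorDesign | None = None
) -> PlantedTruth:
    """Ground truth implied by a set of surfaces.

    The dominant factor maximises the effect amplitude over the design
    levels; the optimum is the best OFAT condition of the noiseless
    surface.  Ties break in design factor (and level) order.
    """
    if not surfaces:
        raise ValueError("surfaces must be non-empty")
    design = design or build_design()
    dominant, optimum, opt_value = {}, {}, {}
    for gsurf in surfaces:
        gsurf.validate(design)
        for rname, surf in gsurf.responses.items():
            key = (gsurf.genus, rname)
            best_name, best_amp = None, -np.inf
            for fac in design.factors:
                if fac.name not in surf.effects:
                    continue
                amp = surf.effects[fac.name].amplitude_over(fac.levels)
                if amp > best_amp:  # strict > keeps the earliest factor on ties
                    best_name, best_amp = fac.name, amp
            dominant[key] = best_name

            best_cond, best_val = None, -np.inf
            for cond in design.distinct_ofat_conditions():
                val = surf.value(cond, design)
                if val > best_val:  # strict >: lexicographic-smallest wins ties
                    best_cond, best_val = cond, val
            optimum[key] = best_cond
            opt_value[key] = best_val
    return PlantedTruth(dominant, optimum, opt_value)
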
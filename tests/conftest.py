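import numpy as np
import pytest

from algaeopt.synthetic_data import (RESPONSES, CategoricalEffect,
                                     GenusSurface, QuadraticEffect,
                                     ResponseSurface, build_design,
                                     default_surfaces, generate_experiment)


@pytest.fixture(scope="session")
def design():
    return build_design()


@pytest.fixture(scope="session")
def surfaces(design):
    return default_surfaces(design)


@pytest.fixture(scope="session")
def table(design, surfaces):
    """Default five-genus triplicate OFAT table (300 rows), seed 7."""
    return generate_experiment(design, surfaces, replicates=3, seed=7)


def make_recovery_surfaces(dominant_amp=0.75, other_amp=0.25, noise_sd=0.05,
                           co2_optimum=7.0):
    """Single-genus surfaces with one dominant factor (CO2) at a 3:1
    amplitude ratio and its optimum planted off the baseline, so both
    dominant-factor and optimum recovery are non-trivial."""
    effects = {
        "co2_pct": QuadraticEffect(dominant_amp, co2_optimum),
        "pH": QuadraticEffect(other_amp, 7.0),
        "temperature_C": QuadraticEffect(other_amp, 30.0),
        "light_intensity_lux": QuadraticEffect(other_amp, 3000.0),
        "light_colour": CategoricalEffect(
            {"white": other_amp, "red": 0.6 * other_amp,
             "green": 0.2 * other_amp, "blue": 0.0}),
    }
    responses = {r: ResponseSurface(1.0, {}, 0.0, (0.0, 100.0))
                 for r in RESPONSES}
    responses["biomass"] = ResponseSurface(0.3, effects, noise_sd, (0.2, 2.1))
    return [GenusSurface("Chlorella", responses)]


def zero_noise_surfaces(design):
    """Default surfaces with all noise switched off."""
    out = []
    for gs in default_surfaces(design):
        resp = {name: ResponseSurface(s.base, s.effects, 0.0, s.bounds)
                for name, s in gs.responses.items()}
        out.append(GenusSurface(gs.genus, resp))
    return out
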
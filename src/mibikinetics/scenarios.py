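"""Named simulation scenarios and seeded synthetic observations.

The registry ships the published parameter combinations for the
three-compartment sestamibi model as ready-made presets (named after the
figures of the source simulation study, ``fig2_no_elim`` … ``fig7``), so the
solver, washout statistics and fitting code are all exercisable without
external data.  :func:`generate_noisy_observations` samples a preset's
closed-form trajectory and adds seeded measurement noise, emulating
scintigraphy counting statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimation import ObservationSet
from .model import KineticParameters, simulate_closed_form

__all__ = [
    "Scenario",
    "SCENARIOS",
    "get_scenario",
    "list_scenarios",
    "generate_noisy_observations",
]

_LAMBDA_6H = math.log(2.0) / 6.0  # sestamibi isotope: 6 h half-life


@dataclass(frozen=True)
class Scenario:
    """A named, validated parameter preset."""

    name: str
    params: KineticParameters
    description: str


def _registry() -> dict[str, Scenario]:
    entries = [
        Scenario(
            "fig2_no_elim",
            KineticParameters(lambda_decay=0.0, elim=0.0, beta_zx=1.0, beta_zy=0.5),
            "Nonradioactive tracer, fully retentive cells, no elimination: "
            "pure uptake with mass conservation (beta_zy = beta_zx/2 = 1/2).",
        ),
        Scenario(
            "fig3_retentive",
            KineticParameters(
                lambda_decay=0.0, elim=0.1, beta_zx=1.0, beta_zy=0.5, beta_xz=0.0, beta_yz=0.5
            ),
            "Nonradioactive tracer with elimination; tumor cells fully retentive "
            "(beta_xz = 0), normal cells leak back to blood.",
        ),
        Scenario(
            "fig3_leaky",
            KineticParameters(
                lambda_decay=0.0, elim=0.1, beta_zx=1.0, beta_zy=0.5, beta_xz=0.1, beta_yz=0.5
            ),
            "Nonradioactive tracer with elimination and a weak tumor return flux "
            "(beta_xz = 0.1): elimination plus secondary redistribution.",
        ),
        Scenario(
            "fig4_decay_no_elim",
            KineticParameters(lambda_decay=_LAMBDA_6H, elim=0.0, beta_zx=1.0, beta_zy=0.5),
            "Radioactive tracer (6 h half-life), fully retentive cells, no "
            "elimination: total activity follows n0*exp(-lambda*t).",
        ),
        Scenario(
            "fig5_full",
            KineticParameters(
                lambda_decay=_LAMBDA_6H,
                elim=0.1,
                beta_zx=0.5,
                beta_zy=0.25,
                beta_xz=0.1,
                beta_yz=0.5,
            ),
            "Radioactive tracer with decay, weak elimination (E = 0.1) and "
            "redistribution (beta_zy = beta_zx/2 = 1/4).",
        ),
        Scenario(
            "fig6a",
            KineticParameters(
                lambda_decay=_LAMBDA_6H,
                elim=0.1,
                beta_zx=0.5,
                beta_zy=0.25,
                beta_xz=0.1,
                beta_yz=0.5,
            ),
            "Weak-elimination washout scenario (E = 0.1); the low-efflux arm of "
            "the elimination comparison.",
        ),
        Scenario(
            "fig6b",
            KineticParameters(
                lambda_decay=_LAMBDA_6H,
                elim=1.0,
                beta_zx=0.5,
                beta_zy=0.25,
                beta_xz=0.1,
                beta_yz=0.5,
            ),
            "Strong-elimination washout scenario (E = 1); the high-efflux arm of "
            "the elimination comparison.",
        ),
        Scenario(
            "fig7",
            KineticParameters(
                lambda_decay=_LAMBDA_6H,
                elim=0.1,
                beta_zx=0.5,
                beta_zy=0.25,
                beta_xz=0.1,
                beta_yz=0.5,
            ),
            "Summary tumor+normal concentration-time scenario (same parameters "
            "as the weak-elimination arm).",
        ),
    ]
    registry: dict[str, Scenario] = {}
    for scenario in entries:
        if scenario.name in registry:
            raise RuntimeError(f"duplicate scenario name {scenario.name!r}")
        scenario.params.validate_regime()
        registry[scenario.name] = scenario
    return registry


SCENARIOS: dict[str, Scenario] = _registry()


def get_scenario(name: str) -> Scenario:
    """Look up a preset by name; unknown names list the valid ones."""
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {', '.join(sorted(SCENARIOS))}"
        ) from None


def list_scenarios() -> list[Scenario]:
    return list(SCENARIOS.values())


def generate_noisy_observations(
    scenario: Scenario | KineticParameters,
    times: np.ndarray,
    compartment: str = "blood",
    noise_model: str = "gaussian",
    noise_scale: float = 0.01,
    seed: int = 0,
) -> ObservationSet:
    """Sample a scenario's closed-form trajectory with seeded noise.

    ``gaussian`` adds zero-mean noise with standard deviation ``noise_scale``
    (in concentration units) and truncates at zero, emulating background-
    subtracted count rates; ``poisson`` draws counts with mean
    ``value * noise_scale`` (``noise_scale`` = expected counts per unit
    concentration) and rescales back, emulating raw counting statistics.
    ``noise_scale = 0`` returns the noise-free trajectory samples under
    either model.
    """
    if noise_scale < 0:
        raise ValueError(f"noise_scale must be nonnegative, got {noise_scale!r}")
    params = scenario.params if isinstance(scenario, Scenario) else scenario
    times = np.asarray(times, dtype=float)
    truth = simulate_closed_form(params, times).series(compartment)
    rng = np.random.default_rng(seed)
    if noise_scale == 0:
        values = truth.copy()
    elif noise_model == "gaussian":
        values = np.maximum(truth + rng.normal(0.0, noise_scale, size=truth.shape), 0.0)
    elif noise_model == "poisson":
        values = rng.poisson(truth * noise_scale).astype(float) / noise_scale
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}; expected gaussian or poisson")
    return ObservationSet(
        times=times,
        values=values,
        compartment=compartment,
        noise_model=noise_model,
        noise_scale=noise_scale,
        seed=seed,
    )
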
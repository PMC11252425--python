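"""Preset designs for the three synthetic experiments.

Sample sizes, condition structure, endowments and punishment ranges
follow the three published experiments (time pressure; deliberation
pause; deliberation content).  The generating parameter values are
illustrative: they reproduce the direction and rough size of the
reported condition effects (moral punishment reduced under time
pressure and self-interest deliberation, increased by unguided
deliberation; cooperation near one half) but are not estimates read off
any dataset — the published estimates require the original deposited
data.
"""

from __future__ import annotations

from .model import ParameterSet
from .simulate import SimulationDesign

__all__ = ["STUDY_DESIGNS", "study_design", "study_conditions"]

STUDY_DESIGNS = {
    # time pressure on the punishment decision
    "exp1": dict(
        conditions=("no_pressure", "pressure"),
        parameters={
            "no_pressure": ParameterSet(0.50, 0.60, 0.25, 0.08, 0.04),
            "pressure": ParameterSet(0.50, 0.45, 0.25, 0.13, 0.09),
        },
        n_participants={"no_pressure": 102, "pressure": 104},
        starting_endowment=400,
        max_invest=5,
    ),
    # forced 30-s deliberation pause before the punishment decision
    "exp2": dict(
        conditions=("no_deliberation", "deliberation"),
        parameters={
            "no_deliberation": ParameterSet(0.52, 0.50, 0.22, 0.10, 0.06),
            "deliberation": ParameterSet(0.46, 0.62, 0.29, 0.10, 0.06),
        },
        n_participants={"no_deliberation": 258, "deliberation": 250},
        starting_endowment=80,
        max_invest=3,
    ),
    # content of deliberation: self-interest vs fairness
    "exp3": dict(
        conditions=("self_interest", "fairness"),
        parameters={
            "self_interest": ParameterSet(0.42, 0.50, 0.25, 0.15, 0.08),
            "fairness": ParameterSet(0.52, 0.60, 0.25, 0.08, 0.05),
        },
        n_participants={"self_interest": 255, "fairness": 272},
        starting_endowment=100,
        max_invest=3,
    ),
}


def study_design(name: str, seed: int) -> SimulationDesign:
    """Build the synthetic design for one of the three experiments."""
    preset = STUDY_DESIGNS[name]
    return SimulationDesign(
        parameters=preset["parameters"],
        n_participants=preset["n_participants"],
        starting_endowment=preset["starting_endowment"],
        max_invest=preset["max_invest"],
        seed=seed,
    )


def study_conditions(name: str) -> tuple:
    return STUDY_DESIGNS[name]["conditions"]
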
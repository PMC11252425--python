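"""Synthetic Prisoner's-Dilemma-with-punishment experiments.

Generates trial-level tables with the statistical structure the MPT
analysis assumes: each participant plays 20 one-shot rounds against 20
programmed partners (10 cooperating, 10 defecting, in a seeded random
order per participant), makes a binary cooperate/defect choice, and may
then invest 1..max_invest cents to deduct ten times that amount from
the partner.  Programmed partners morally punish unilateral defection
with a random magnitude.  Payoffs per round: mutual cooperation +10
each; mutual defection 0 each; unilateral cooperation −10 for the
cooperator and +20 for the defector.

Choices and punishment events are drawn from the generative reading of
the cooperation-and-punishment model: own cooperation with probability
C, punishment with the cell's total punishment probability (the
outcome-contingent process plus the bias route).  The model concerns the
punish/no-punish dichotomy only, so invested amounts for model-driven
punishers are drawn uniformly on the allowed range — a stand-in, since
no magnitude distribution is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CATEGORY_INDEX,
    CategoryCounts,
    ParameterSet,
    category_probabilities,
)

__all__ = [
    "TRIAL_COLUMNS",
    "SimulationDesign",
    "apply_payoffs",
    "simulate_experiment",
    "simulate_counts",
    "aggregate_counts",
]

#: Trial-table schema; serialized column order is part of the file contract.
TRIAL_COLUMNS = (
    "participant_id",
    "condition",
    "round_index",
    "is_practice",
    "partner_type",
    "own_choice",
    "punish_invested",
    "punish_deducted",
    "own_payoff",
    "partner_payoff",
    "partner_punished_me",
    "balance_after",
)

PAYOFFS = {
    ("cooperate", "cooperate"): (10, 10),
    ("defect", "defect"): (0, 0),
    ("cooperate", "defect"): (-10, 20),
    ("defect", "cooperate"): (20, -10),
}

#: magnitudes (cents) programmed partners deduct when punishing
PARTNER_PUNISH_MAGNITUDES = (10, 20, 30, 40, 50)


def apply_payoffs(own_choice: str, partner_choice: str) -> tuple[int, int]:
    """Round payoffs (own, partner) of the Prisoner's Dilemma stage."""
    try:
        return PAYOFFS[(own_choice, partner_choice)]
    except KeyError:
        raise ValueError(
            f"choices must be 'cooperate' or 'defect', got "
            f"({own_choice!r}, {partner_choice!r})"
        ) from None


@dataclass(frozen=True)
class SimulationDesign:
    """Design of one synthetic experiment.

    ``parameters`` maps condition label to the generating
    :class:`ParameterSet`; ``n_participants`` maps condition label to
    the per-condition sample size.  ``round_drift`` optionally adds a
    linear per-round drift to a parameter (name, total change over the
    20 rounds), clipped to [0, 1] — a hook for exercising the
    across-rounds stability analysis under violation.
    """

    parameters: Mapping[str, ParameterSet]
    n_participants: Mapping[str, int]
    seed: int = 0
    n_rounds: int = 20
    n_cooperating_partners: int = 10
    n_practice_rounds: int = 4
    starting_endowment: int = 400
    max_invest: int = 5
    round_drift: tuple | None = None

    def __post_init__(self) -> None:
        if set(self.parameters) != set(self.n_participants):
            raise ValueError("parameters and n_participants must share conditions")
        for label, n in self.n_participants.items():
            if n < 1:
                raise ValueError(f"n_participants[{label!r}] must be positive")
        if not (0 <= self.n_cooperating_partners <= self.n_rounds):
            raise ValueError("n_cooperating_partners must lie in [0, n_rounds]")
        if self.max_invest < 1:
            raise ValueError("max_invest must be >= 1")


def _round_params(design: SimulationDesign, base: ParameterSet,
                  round_index: int) -> ParameterSet:
    if design.round_drift is None:
        return base
    name, total = design.round_drift
    frac = (round_index - 1) / max(1, design.n_rounds - 1)
    value = float(np.clip(getattr(base, name) + total * frac, 0.0, 1.0))
    return replace(base, **{name: value})


def simulate_experiment(design: SimulationDesign) -> pd.DataFrame:
    """Simulate the full experiment; fully reproducible from the seed."""
    rng = np.random.default_rng(design.seed)
    rows = []
    pid = 0
    prob_cache: dict = {}
    for condition in design.parameters:
        params = design.parameters[condition]
        for _ in range(design.n_participants[condition]):
            pid += 1
            partner_types = np.array(
                ["cooperator"] * design.n_cooperating_partners
                + ["defector"] * (design.n_rounds - design.n_cooperating_partners)
            )
            rng.shuffle(partner_types)
            balance = design.starting_endowment
            for round_index in range(1, design.n_rounds + 1):
                cache_key = (condition, round_index if design.round_drift else 0)
                if cache_key not in prob_cache:
                    p = _round_params(design, params, round_index)
                    prob_cache[cache_key] = (p.C, category_probabilities(p))
                c_prob, probs = prob_cache[cache_key]
                partner_type = partner_types[round_index - 1]
                partner_choice = (
                    "cooperate" if partner_type == "cooperator" else "defect"
                )
                own_choice = "cooperate" if rng.random() < c_prob else "defect"
                cell_pp = probs[(partner_type, own_choice, "yes")]
                cell_np = probs[(partner_type, own_choice, "no")]
                punish_prob = cell_pp / (cell_pp + cell_np)
                punishes = rng.random() < punish_prob
                invested = int(rng.integers(1, design.max_invest + 1)) if punishes else 0
                own_payoff, partner_payoff = apply_payoffs(own_choice, partner_choice)
                # programmed partners morally punish unilateral defection
                if own_choice == "defect" and partner_choice == "cooperate":
                    partner_punished_me = int(rng.choice(PARTNER_PUNISH_MAGNITUDES))
                else:
                    partner_punished_me = 0
                balance += own_payoff - invested - partner_punished_me
                if balance < 0:
                    balance = 0  # floor-at-zero rule; logged via balance_after
                rows.append(
                    (
                        f"P{pid:04d}",
                        condition,
                        round_index,
                        round_index <= design.n_practice_rounds,
                        partner_type,
                        own_choice,
                        invested,
                        10 * invested,
                        own_payoff,
                        partner_payoff,
                        partner_punished_me,
                        balance,
                    )
                )
    frame = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    return frame


def simulate_counts(
    params: ParameterSet,
    n_cooperator: int,
    n_defector: int,
    rng: np.random.Generator,
) -> CategoryCounts:
    """Draw aggregated category counts directly from the two tree multinomials.

    Statistically equivalent to simulating trials and aggregating (the
    model is i.i.d. across trials within a tree); used by Monte-Carlo
    calibration loops where trial-level detail is not needed.
    """
    probs = category_probabilities(params).values
    defector = rng.multinomial(n_defector, probs[:4] / probs[:4].sum())
    cooperator = rng.multinomial(n_cooperator, probs[4:] / probs[4:].sum())
    return CategoryCounts(np.concatenate([defector, cooperator]))


def aggregate_counts(
    trials: pd.DataFrame,
    stratify_by: str = "condition",
    include_practice: bool = True,
    condition_order: Sequence[str] | None = None,
) -> dict:
    """Tabulate trials into per-stratum 8-cell category counts.

    ``stratify_by`` is ``"condition"`` or ``"condition_round"`` (the
    latter yields one stratum per (condition, round_index) pair, the
    stratification of the across-rounds stability analysis).
    Punishment is dichotomized as ``punish_invested > 0``.
    """
    required = {"condition", "round_index", "is_practice", "partner_type",
                "own_choice", "punish_invested"}
    missing = sorted(required - set(trials.columns))
    if missing:
        raise ValueError(f"trial table lacks required columns: {missing}")
    bad_partner = ~trials["partner_type"].isin(["cooperator", "defector"])
    if bad_partner.any():
        raise ValueError(
            "unknown partner_type labels at rows "
            f"{trials.index[bad_partner][:5].tolist()}"
        )
    bad_choice = ~trials["own_choice"].isin(["cooperate", "defect"])
    if bad_choice.any():
        raise ValueError(
            "unknown own_choice labels at rows "
            f"{trials.index[bad_choice][:5].tolist()}"
        )

    retained = trials if include_practice else trials.loc[~trials["is_practice"].astype(bool)]

    if stratify_by == "condition":
        strata_keys = retained["condition"].tolist()
    elif stratify_by == "condition_round":
        strata_keys = list(zip(retained["condition"], retained["round_index"]))
    else:
        raise ValueError("stratify_by must be 'condition' or 'condition_round'")

    punished = np.where(retained["punish_invested"].to_numpy() > 0, "yes", "no")
    cell_pos = {key: i for i, key in enumerate(CATEGORY_INDEX)}
    tallies: dict = {}
    for stratum, cell in zip(
        strata_keys,
        zip(retained["partner_type"], retained["own_choice"], punished),
    ):
        if stratum not in tallies:
            tallies[stratum] = np.zeros(8, dtype=np.int64)
        tallies[stratum][cell_pos[cell]] += 1

    out = {stratum: CategoryCounts(values) for stratum, values in
           sorted(tallies.items(), key=lambda kv: str(kv[0]))}
    if condition_order is not None and stratify_by == "condition":
        unknown = [c for c in out if c not in condition_order]
        if unknown:
            raise ValueError(f"conditions not in declared order: {unknown}")
        out = {c: out[c] for c in condition_order if c in out}
    return out
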
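"""Synthetic experiment generator: game mechanics and aggregation."""

import numpy as np
import pandas as pd
import pytest

from coop_punish import (
    CATEGORY_INDEX,
    ParameterSet,
    SimulationDesign,
    aggregate_counts,
    apply_payoffs,
    category_probabilities,
    simulate_experiment,
)


@pytest.mark.parametrize(
    "own, partner, expected",
    [
        ("cooperate", "cooperate", (10, 10)),
        ("defect", "defect", (0, 0)),
        ("cooperate", "defect", (-10, 20)),
        ("defect", "cooperate", (20, -10)),
    ],
)
def test_payoff_matrix(own, partner, expected):
    assert apply_payoffs(own, partner) == expected


def test_unknown_choice_rejected():
    with pytest.raises(ValueError):
        apply_payoffs("cooperate", "waffle")


def _design(**overrides):
    kwargs = dict(
        parameters={
            "x": ParameterSet(0.5, 0.6, 0.25, 0.1, 0.05),
            "y": ParameterSet(0.5, 0.45, 0.25, 0.15, 0.10),
        },
        n_participants={"x": 30, "y": 30},
        seed=123,
    )
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)


class TestSimulateExperiment:
    def test_partner_composition_and_schema(self):
        trials = simulate_experiment(_design())
        per_participant = trials.groupby("participant_id")["partner_type"]
        assert (per_participant.apply(lambda s: (s == "cooperator").sum()) == 10).all()
        assert (per_participant.size() == 20).all()
        # bookkeeping invariants
        assert (trials["punish_deducted"] == 10 * trials["punish_invested"]).all()
        payoff_pairs = set(zip(trials["own_payoff"], trials["partner_payoff"]))
        assert payoff_pairs <= {(10, 10), (0, 0), (-10, 20), (20, -10)}
        # programmed partners punish only unilateral defection
        punished_back = trials["partner_punished_me"] > 0
        unilateral = (trials["own_choice"] == "defect") & (
            trials["partner_type"] == "cooperator"
        )
        assert (punished_back <= unilateral).all()
        assert trials.loc[unilateral, "partner_punished_me"].isin(
            [10, 20, 30, 40, 50]
        ).all()
        assert trials.loc[punished_back, "partner_punished_me"].gt(0).all()
        assert (trials["balance_after"] >= 0).all()
        assert set(trials.loc[trials["is_practice"], "round_index"]) <= {1, 2, 3, 4}

    def test_seed_reproducibility(self):
        a = simulate_experiment(_design())
        b = simulate_experiment(_design())
        pd.testing.assert_frame_equal(a, b)
        c = simulate_experiment(_design(seed=124))
        assert not a.equals(c)
        # different seeds keep the marginal structure
        assert len(c) == len(a)
        assert (c.groupby("participant_id").size() == 20).all()

    def test_no_punishment_when_all_processes_zero(self):
        design = _design(
            parameters={"x": ParameterSet(1, 0, 0, 0, 0)},
            n_participants={"x": 20},
        )
        trials = simulate_experiment(design)
        assert (trials["punish_invested"] == 0).all()
        assert (trials["own_choice"] == "cooperate").all()

    def test_certain_antisocial_punishment(self):
        design = _design(
            parameters={"x": ParameterSet(0, 0, 0, 1, 0)},
            n_participants={"x": 10},
            n_cooperating_partners=20,
        )
        trials = simulate_experiment(design)
        assert (trials["own_choice"] == "defect").all()
        assert (trials["punish_invested"] > 0).all()
        assert (trials["partner_payoff"] == -10).all()

    def test_aggregate_proportions_match_model(self):
        """Law of large numbers: cell proportions approach the category
        probabilities within 99% binomial bounds."""
        params = ParameterSet(0.55, 0.6, 0.3, 0.15, 0.08)
        design = _design(
            parameters={"x": params}, n_participants={"x": 500}, seed=42
        )
        counts = aggregate_counts(simulate_experiment(design))["x"]
        probs = category_probabilities(params).values
        for tree, n in ((slice(0, 4), counts.n_defector),
                        (slice(4, 8), counts.n_cooperator)):
            p = probs[tree] / probs[tree].sum()
            observed = counts.values[tree]
            bound = 2.576 * np.sqrt(n * p * (1 - p))
            assert np.all(np.abs(observed - n * p) <= bound + 1e-9)

    def test_round_drift_hook(self):
        drifting = _design(
            parameters={"x": ParameterSet(0.5, 0.2, 0.2, 0.1, 0.05)},
            n_participants={"x": 400},
            round_drift=("P_Moral", 0.6),
            seed=9,
        )
        trials = simulate_experiment(drifting)
        moral = trials[
            (trials["partner_type"] == "defector")
            & (trials["own_choice"] == "cooperate")
        ]
        early = moral[moral["round_index"] <= 5]["punish_invested"].gt(0).mean()
        late = moral[moral["round_index"] > 15]["punish_invested"].gt(0).mean()
        assert late > early + 0.2


class TestAggregateCounts:
    def test_practice_flag_changes_totals(self):
        design = _design(n_participants={"x": 1, "y": 1})
        trials = simulate_experiment(design)
        with_practice = aggregate_counts(trials, include_practice=True)
        without = aggregate_counts(trials, include_practice=False)
        assert sum(c.n_total for c in with_practice.values()) == 40
        assert sum(c.n_total for c in without.values()) == 32
        assert with_practice["x"].n_total == 20
        assert without["x"].n_total == 16

    def test_hand_tallied_toy_table(self):
        toy = pd.DataFrame(
            {
                "participant_id": ["p1"] * 6,
                "condition": ["c"] * 6,
                "round_index": [1, 2, 3, 4, 5, 6],
                "is_practice": [False] * 6,
                "partner_type": ["defector", "defector", "defector",
                                 "cooperator", "cooperator", "cooperator"],
                "own_choice": ["cooperate", "cooperate", "defect",
                               "cooperate", "defect", "defect"],
                "punish_invested": [3, 0, 1, 0, 5, 0],
            }
        )
        counts = aggregate_counts(toy)["c"]
        expected = {
            ("defector", "cooperate", "yes"): 1,
            ("defector", "cooperate", "no"): 1,
            ("defector", "defect", "yes"): 1,
            ("cooperator", "cooperate", "no"): 1,
            ("cooperator", "defect", "yes"): 1,
            ("cooperator", "defect", "no"): 1,
        }
        for key in CATEGORY_INDEX:
            assert counts[key] == expected.get(key, 0)

    def test_condition_round_stratification(self):
        design = _design(n_participants={"x": 5, "y": 5})
        trials = simulate_experiment(design)
        counts = aggregate_counts(trials, stratify_by="condition_round")
        assert len(counts) == 40
        assert sum(c.n_total for c in counts.values()) == len(trials)
        assert counts[("x", 1)].n_total == 5

    def test_unknown_labels_rejected(self):
        toy = pd.DataFrame(
            {
                "participant_id": ["p1"],
                "condition": ["c"],
                "round_index": [1],
                "is_practice": [False],
                "partner_type": ["stranger"],
                "own_choice": ["cooperate"],
                "punish_invested": [0],
            }
        )
        with pytest.raises(ValueError, match="partner_type"):
            aggregate_counts(toy)

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="punish_invested"):
            aggregate_counts(pd.DataFrame({"condition": ["c"]}))
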
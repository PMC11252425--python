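"""Cooperation-and-punishment multinomial processing tree (MPT) model.

The model describes one stratum (experimental group) of a Prisoner's
Dilemma game with a costly punishment option.  Each trial is classified
into one of eight observable categories indexed by

    (partner_type, own_choice, punished)

with ``partner_type`` in {defector, cooperator}, ``own_choice`` in
{cooperate, defect} and ``punished`` in {yes, no}.  Five latent
probabilities generate these categories:

``C``
    probability that the participant cooperates (shared between the two
    partner-type trees of a stratum — there is no per-tree C),
``P_Moral``
    conditional probability of punishing a defecting partner after
    having cooperated oneself (moral punishment),
``P_Hypocritical``
    conditional probability of punishing a defecting partner after
    having defected oneself,
``P_Antisocial``
    conditional probability of punishing a cooperating partner after
    having defected oneself,
``b``
    unspecific punishment bias: the probability of punishing
    irrespective of the game outcome, and the only route to punishment
    after mutual cooperation.

The outcome-contingent punishment processes act first; if they do not
fire, the bias ``b`` may still produce punishment, so the total
punishment probability in a cell with process ``P`` is ``P + (1-P)*b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PARAMETER_NAMES",
    "CATEGORY_INDEX",
    "ParameterSet",
    "CategoryProbabilities",
    "CategoryCounts",
    "ModelSpec",
    "category_probabilities",
    "category_probability_jacobian",
    "expected_counts",
    "degrees_of_freedom",
]

PARAMETER_NAMES = ("C", "P_Moral", "P_Hypocritical", "P_Antisocial", "b")

#: Canonical serialization order of the eight response categories.
#: Defector-partner tree first, within a tree cooperate before defect,
#: punished before not punished.
CATEGORY_INDEX = (
    ("defector", "cooperate", "yes"),
    ("defector", "cooperate", "no"),
    ("defector", "defect", "yes"),
    ("defector", "defect", "no"),
    ("cooperator", "cooperate", "yes"),
    ("cooperator", "cooperate", "no"),
    ("cooperator", "defect", "yes"),
    ("cooperator", "defect", "no"),
)

# slices of the two partner-type trees in the canonical order
DEFECTOR_TREE = slice(0, 4)
COOPERATOR_TREE = slice(4, 8)


def _check_unit_interval(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ValueError(f"parameter {name}={value!r} outside the unit interval [0, 1]")


@dataclass(frozen=True)
class ParameterSet:
    """The five model probabilities of one stratum."""

    C: float
    P_Moral: float
    P_Hypocritical: float
    P_Antisocial: float
    b: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            _check_unit_interval(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ParameterSet":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise ValueError(f"expected 5 parameters, got shape {values.shape}")
        return cls(*values.tolist())


@dataclass(frozen=True)
class CategoryProbabilities:
    """Eight category probabilities in the canonical order.

    Probabilities within each partner-type tree sum to one.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (8,):
            raise ValueError("CategoryProbabilities requires exactly 8 entries")
        object.__setattr__(self, "values", values)

    def tree(self, partner_type: str) -> np.ndarray:
        return self.values[DEFECTOR_TREE if partner_type == "defector" else COOPERATOR_TREE]

    def __getitem__(self, key: tuple[str, str, str]) -> float:
        return float(self.values[CATEGORY_INDEX.index(key)])


@dataclass(frozen=True)
class CategoryCounts:
    """Eight observed category frequencies with per-tree totals."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != (8,):
            raise ValueError("CategoryCounts requires exactly 8 entries")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        object.__setattr__(self, "values", np.asarray(np.round(values), dtype=np.int64))

    @property
    def n_defector(self) -> int:
        return int(self.values[DEFECTOR_TREE].sum())

    @property
    def n_cooperator(self) -> int:
        return int(self.values[COOPERATOR_TREE].sum())

    @property
    def n_total(self) -> int:
        return int(self.values.sum())

    def __getitem__(self, key: tuple[str, str, str]) -> int:
        return int(self.values[CATEGORY_INDEX.index(key)])


def category_probabilities(params: ParameterSet) -> CategoryProbabilities:
    """Map the five model parameters to the eight category probabilities.

    Defector-partner tree::

        P(cooperate, punished)   = C * (P_Moral + (1-P_Moral) * b)
        P(cooperate, unpunished) = C * (1-P_Moral) * (1-b)
        P(defect, punished)      = (1-C) * (P_Hypocritical + (1-P_Hypocritical) * b)
        P(defect, unpunished)    = (1-C) * (1-P_Hypocritical) * (1-b)

    Cooperator-partner tree::

        P(cooperate, punished)   = C * b
        P(cooperate, unpunished) = C * (1-b)
        P(defect, punished)      = (1-C) * (P_Antisocial + (1-P_Antisocial) * b)
        P(defect, unpunished)    = (1-C) * (1-P_Antisocial) * (1-b)
    """
    return CategoryProbabilities(_probabilities_array(params.as_array()))


def _probabilities_array(theta: np.ndarray) -> np.ndarray:
    """Vectorized core: theta has shape (..., 5); returns shape (..., 8)."""
    theta = np.asarray(theta, dtype=float)
    c, pm, ph, pa, b = (theta[..., i] for i in range(5))
    out = np.empty(theta.shape[:-1] + (8,), dtype=float)
    out[..., 0] = c * (pm + (1 - pm) * b)
    out[..., 1] = c * (1 - pm) * (1 - b)
    out[..., 2] = (1 - c) * (ph + (1 - ph) * b)
    out[..., 3] = (1 - c) * (1 - ph) * (1 - b)
    out[..., 4] = c * b
    out[..., 5] = c * (1 - b)
    out[..., 6] = (1 - c) * (pa + (1 - pa) * b)
    out[..., 7] = (1 - c) * (1 - pa) * (1 - b)
    return out


def category_probability_jacobian(theta: np.ndarray) -> np.ndarray:
    """d p_cell / d parameter for theta of shape (..., 5); returns (..., 8, 5).

    Parameter order follows :data:`PARAMETER_NAMES`.
    """
    theta = np.asarray(theta, dtype=float)
    c, pm, ph, pa, b = (theta[..., i] for i in range(5))
    jac = np.zeros(theta.shape[:-1] + (8, 5), dtype=float)
    # column 0: d/dC
    jac[..., 0, 0] = pm + (1 - pm) * b
    jac[..., 1, 0] = (1 - pm) * (1 - b)
    jac[..., 2, 0] = -(ph + (1 - ph) * b)
    jac[..., 3, 0] = -((1 - ph) * (1 - b))
    jac[..., 4, 0] = b
    jac[..., 5, 0] = 1 - b
    jac[..., 6, 0] = -(pa + (1 - pa) * b)
    jac[..., 7, 0] = -((1 - pa) * (1 - b))
    # column 1: d/dP_Moral
    jac[..., 0, 1] = c * (1 - b)
    jac[..., 1, 1] = -c * (1 - b)
    # column 2: d/dP_Hypocritical
    jac[..., 2, 2] = (1 - c) * (1 - b)
    jac[..., 3, 2] = -(1 - c) * (1 - b)
    # column 3: d/dP_Antisocial
    jac[..., 6, 3] = (1 - c) * (1 - b)
    jac[..., 7, 3] = -(1 - c) * (1 - b)
    # column 4: d/db
    jac[..., 0, 4] = c * (1 - pm)
    jac[..., 1, 4] = -c * (1 - pm)
    jac[..., 2, 4] = (1 - c) * (1 - ph)
    jac[..., 3, 4] = -(1 - c) * (1 - ph)
    jac[..., 4, 4] = c
    jac[..., 5, 4] = -c
    jac[..., 6, 4] = (1 - c) * (1 - pa)
    jac[..., 7, 4] = -(1 - c) * (1 - pa)
    return jac


def expected_counts(
    params: ParameterSet, n_cooperator: float, n_defector: float
) -> np.ndarray:
    """Expected category frequencies (real-valued) for given tree totals.

    The defector-partner tree probabilities are scaled by ``n_defector``
    and the cooperator-partner tree by ``n_cooperator``; per-tree sums
    equal the totals exactly.
    """
    if n_cooperator < 0 or n_defector < 0:
        raise ValueError("tree totals must be non-negative")
    probs = category_probabilities(params).values
    scale = np.array([n_defector] * 4 + [n_cooperator] * 4, dtype=float)
    return probs * scale


@dataclass(frozen=True)
class ModelSpec:
    """A multi-stratum model defined by parameter tying.

    ``strata`` is the ordered list of stratum labels.  ``assignments``
    maps each (stratum, parameter-name) slot to either a shared free
    parameter identifier (str) or a fixed constant (float).  Slots that
    share an identifier are constrained equal; distinct identifiers are
    free to differ.
    """

    strata: tuple
    assignments: Mapping[tuple, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        strata = tuple(self.strata)
        if len(set(strata)) != len(strata):
            raise ValueError("stratum labels must be unique")
        assignments = dict(self.assignments)
        for stratum in strata:
            for name in PARAMETER_NAMES:
                slot = (stratum, name)
                if slot not in assignments:
                    raise ValueError(f"missing assignment for slot {slot}")
                value = assignments[slot]
                if isinstance(value, str):
                    continue
                if isinstance(value, (int, float)):
                    _check_unit_interval(f"constant at {slot}", float(value))
                    assignments[slot] = float(value)
                else:
                    raise TypeError(
                        f"slot {slot} must map to an identifier or a constant"
                    )
        extra = set(assignments) - {
            (s, n) for s in strata for n in PARAMETER_NAMES
        }
        if extra:
            raise ValueError(f"assignments reference unknown slots: {sorted(extra)}")
        object.__setattr__(self, "strata", strata)
        object.__setattr__(self, "assignments", assignments)
        if degrees_of_freedom(self) < 0:
            raise ValueError(
                "over-parameterized model: more free parameters than data cells"
            )

    @classmethod
    def saturated(cls, strata: Iterable) -> "ModelSpec":
        """One free parameter per slot (the base model)."""
        strata = tuple(strata)
        assignments = {
            (stratum, name): f"{name}[{stratum}]"
            for stratum in strata
            for name in PARAMETER_NAMES
        }
        return cls(strata, assignments)

    @property
    def free_parameters(self) -> tuple:
        """Free identifiers in order of first appearance."""
        seen: dict = {}
        for stratum in self.strata:
            for name in PARAMETER_NAMES:
                value = self.assignments[(stratum, name)]
                if isinstance(value, str) and value not in seen:
                    seen[value] = None
        return tuple(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    def tie(self, parameter: str, strata: Sequence | None = None,
            identifier: str | None = None) -> "ModelSpec":
        """Return a copy with ``parameter`` constrained equal across strata.

        By default the parameter is equated across all strata; passing a
        subset ties it within that subset only.
        """
        if parameter not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter {parameter!r}")
        target = tuple(self.strata if strata is None else strata)
        for stratum in target:
            if stratum not in self.strata:
                raise ValueError(f"unknown stratum {stratum!r}")
        label = identifier or f"{parameter}[{'='.join(str(s) for s in target)}]"
        assignments = dict(self.assignments)
        for stratum in target:
            assignments[(stratum, parameter)] = label
        return ModelSpec(self.strata, assignments)

    def fix(self, stratum, parameter: str, value: float) -> "ModelSpec":
        """Return a copy with one slot fixed to a constant."""
        assignments = dict(self.assignments)
        assignments[(stratum, parameter)] = float(value)
        return ModelSpec(self.strata, assignments)

    def is_nested_in(self, base: "ModelSpec") -> bool:
        """True if this spec's tying map refines ``base``'s.

        Every equality (or constant) constraint of ``base`` must be
        preserved here: slots sharing a base identifier must share an
        identifier (or constant) in this spec, and base constants must
        be identical here.
        """
        if tuple(self.strata) != tuple(base.strata):
            return False
        groups: dict = {}
        for slot, value in base.assignments.items():
            if isinstance(value, str):
                groups.setdefault(value, []).append(slot)
            else:
                mine = self.assignments[slot]
                if isinstance(mine, str) or mine != value:
                    return False
        for slots in groups.values():
            values = {self.assignments[s] if isinstance(self.assignments[s], str)
                      else ("__const__", self.assignments[s]) for s in slots}
            if len(values) > 1:
                return False
        return True


def degrees_of_freedom(spec: ModelSpec) -> int:
    """Data degrees of freedom minus free parameters.

    Each stratum contributes two multinomial trees with four cells each,
    i.e. 6 independent data cells, so ``df = 6 * n_strata - n_free``.
    """
    n_free = len(
        {v for v in spec.assignments.values() if isinstance(v, str)}
    )
    return 6 * len(spec.strata) - n_free
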
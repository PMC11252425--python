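"""End-to-end analysis driver: trial table in, structured report out.

Reads a trial-level table, aggregates it into per-stratum category
counts, fits the two-condition base model, runs the battery of
parameter-equality ΔG² tests, optionally runs the across-rounds
stability test of the moral-punishment parameter, and serializes the
whole thing as a JSON report plus a human-readable summary.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .estimation import FitResult, TestResult, delta_g2_test, fit
from .model import PARAMETER_NAMES, ModelSpec
from .simulate import TRIAL_COLUMNS, aggregate_counts

__all__ = [
    "AnalysisConfig",
    "ExperimentReport",
    "read_trials",
    "write_trials",
    "run_experiment_analysis",
    "write_report",
    "report_to_dict",
    "format_report",
]

REQUIRED_COLUMNS = (
    "participant_id",
    "condition",
    "round_index",
    "is_practice",
    "partner_type",
    "own_choice",
    "punish_invested",
)

BATTERY_PARAMETERS = PARAMETER_NAMES  # C, P_Moral, P_Hypocritical, P_Antisocial, b


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one experiment analysis.

    ``conditions`` names the exactly-two condition labels in display
    order.  ``column_aliases`` maps canonical column names to the names
    used in the input file (for externally produced exports whose
    layout differs from the canonical schema); ``value_aliases``
    optionally recodes cell values per canonical column, e.g.
    ``{"own_choice": {"1": "cooperate", "0": "defect"}}``.
    """

    conditions: tuple
    include_practice: bool = True
    n_restarts: int = 20
    seed: int = 0
    battery: tuple = BATTERY_PARAMETERS
    stability_test: bool = True
    stability_free_all: bool = True
    column_aliases: Mapping[str, str] = field(default_factory=dict)
    value_aliases: Mapping[str, Mapping] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError("an experiment analysis needs exactly two conditions")
        unknown = [p for p in self.battery if p not in PARAMETER_NAMES]
        if unknown:
            raise ValueError(f"unknown battery parameters: {unknown}")
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "battery", tuple(self.battery))

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class ExperimentReport:
    """Base fit, test battery, optional stability test, and provenance."""

    base_fit: FitResult
    battery: Mapping[str, TestResult]
    stability: TestResult | None
    n_total: int
    n_participants: int
    provenance: Mapping


def read_trials(
    path,
    column_aliases: Mapping[str, str] | None = None,
    value_aliases: Mapping[str, Mapping] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a trial table from delimited text.

    Tolerates extra columns.  ``column_aliases`` maps canonical names to
    the file's column names.  Raises a validation error naming missing
    columns, and rejects non-binary choice codes with the first
    offending line.
    """
    frame = pd.read_csv(path, sep=sep)
    if column_aliases:
        rename = {src: canonical for canonical, src in column_aliases.items()}
        missing_src = [s for s in rename if s not in frame.columns]
        if missing_src:
            raise ValueError(f"aliased columns absent from file: {missing_src}")
        frame = frame.rename(columns=rename)
    if value_aliases:
        for column, mapping in value_aliases.items():
            if column in frame.columns:
                frame[column] = (
                    frame[column].astype(str).map(lambda v: mapping.get(v, v))
                )
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    bad = ~frame["own_choice"].isin(["cooperate", "defect"])
    if bad.any():
        first = int(frame.index[bad][0])
        raise ValueError(
            f"non-binary own_choice code {frame.loc[first, 'own_choice']!r} "
            f"at data line {first + 2}"
        )
    frame["is_practice"] = frame["is_practice"].astype(bool)
    frame["round_index"] = frame["round_index"].astype(int)
    frame["punish_invested"] = frame["punish_invested"].astype(int)
    return frame


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical column order."""
    ordered = [c for c in TRIAL_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in ordered]
    trials[ordered + extra].to_csv(path, index=False)


def _battery_specs(base: ModelSpec, parameter: str) -> ModelSpec:
    return base.tie(parameter)


def _stability_specs(
    conditions: Sequence, rounds: Sequence, free_all: bool = True
) -> tuple:
    """Base and restricted specs of the across-rounds stability test.

    Base: one stratum per (condition, round), all five parameters free
    per stratum.  Restricted: identical except that the moral-punishment
    parameter is equated across rounds within each condition, which
    removes (n_rounds − 1) free parameters per condition — 38 df for
    two conditions × 20 rounds.  With ``free_all=False`` the other four
    parameters are pre-tied across rounds within condition in both
    models (an alternative reading of the same 38-df restriction).
    """
    strata = [(c, r) for c in conditions for r in rounds]
    base = ModelSpec.saturated(strata)
    if not free_all:
        for condition in conditions:
            cond_strata = [(condition, r) for r in rounds]
            for name in ("C", "P_Hypocritical", "P_Antisocial", "b"):
                base = base.tie(name, strata=cond_strata,
                                identifier=f"{name}[{condition}]")
    restricted = base
    for condition in conditions:
        restricted = restricted.tie(
            "P_Moral",
            strata=[(condition, r) for r in rounds],
            identifier=f"P_Moral[{condition}]",
        )
    return base, restricted


def run_experiment_analysis(
    trials: pd.DataFrame, config: AnalysisConfig
) -> ExperimentReport:
    """Run the full model-based analysis of one two-condition experiment."""
    observed_conditions = set(trials["condition"].unique())
    unknown = observed_conditions - set(config.conditions)
    if unknown:
        raise ValueError(f"unknown condition labels in data: {sorted(unknown)}")
    absent = set(config.conditions) - observed_conditions
    if absent:
        raise ValueError(f"configured conditions absent from data: {sorted(absent)}")

    counts = aggregate_counts(
        trials,
        stratify_by="condition",
        include_practice=config.include_practice,
        condition_order=config.conditions,
    )
    n_total = sum(c.n_total for c in counts.values())
    n_participants = trials["participant_id"].nunique()

    base_spec = ModelSpec.saturated(config.conditions)
    base_fit = fit(counts, base_spec, seed=config.seed, n_restarts=config.n_restarts)

    battery: dict = {}
    for parameter in config.battery:
        battery[parameter] = delta_g2_test(
            counts,
            base_spec,
            _battery_specs(base_spec, parameter),
            n_total=n_total,
            seed=config.seed,
            n_restarts=config.n_restarts,
            base_fit=base_fit,
        )

    stability = None
    if config.stability_test:
        retained = (
            trials
            if config.include_practice
            else trials.loc[~trials["is_practice"]]
        )
        rounds = sorted(retained["round_index"].unique())
        round_counts = aggregate_counts(
            trials,
            stratify_by="condition_round",
            include_practice=config.include_practice,
        )
        stab_base, stab_restricted = _stability_specs(
            config.conditions, rounds, free_all=config.stability_free_all
        )
        stability = delta_g2_test(
            round_counts,
            stab_base,
            stab_restricted,
            n_total=n_total,
            seed=config.seed,
            n_restarts=min(config.n_restarts, 5),
        )

    provenance = {
        "software": f"coop-punish {__version__}",
        "seed": config.seed,
        "n_restarts": config.n_restarts,
        "include_practice": config.include_practice,
        "conditions": list(config.conditions),
        "n_total": n_total,
        "n_participants": int(n_participants),
    }
    return ExperimentReport(
        base_fit=base_fit,
        battery=battery,
        stability=stability,
        n_total=n_total,
        n_participants=int(n_participants),
        provenance=provenance,
    )


def _fit_to_dict(fr: FitResult) -> dict:
    return {
        "estimates": dict(fr.estimates),
        "standard_errors": dict(fr.standard_errors),
        "g_squared": fr.g_squared,
        "df": fr.df,
        "p_value": fr.p_value,
        "log_likelihood": fr.log_likelihood,
        "converged": fr.converged,
        "n_restarts_used": fr.n_restarts_used,
        "unidentified": list(fr.unidentified),
    }


def _test_to_dict(tr: TestResult) -> dict:
    return {
        "delta_g_squared": tr.delta_g_squared,
        "df": tr.df,
        "p_value": tr.p_value,
        "w": tr.w,
        "restricted_g_squared": tr.restricted_fit.g_squared,
        "base_g_squared": tr.base_fit.g_squared,
    }


def report_to_dict(report: ExperimentReport) -> dict:
    data = {
        "provenance": dict(report.provenance),
        "base_fit": _fit_to_dict(report.base_fit),
        "battery": {p: _test_to_dict(t) for p, t in report.battery.items()},
    }
    if report.stability is not None:
        data["stability"] = _test_to_dict(report.stability)
    return data


def write_report(report: ExperimentReport, path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True))


def format_report(report: ExperimentReport) -> str:
    """Human-readable summary table of an experiment analysis."""
    buf = io.StringIO()
    prov = report.provenance
    print(f"Analysis of {prov['conditions'][0]} vs {prov['conditions'][1]} "
          f"(N = {report.n_participants} participants, "
          f"{report.n_total} trials)", file=buf)
    bf = report.base_fit
    print(f"Base model: G²({bf.df}) = {bf.g_squared:.2f}, p = {bf.p_value:.3f}",
          file=buf)
    print("\nParameter estimates (SE):", file=buf)
    for condition in prov["conditions"]:
        parts = []
        for name in PARAMETER_NAMES:
            key = f"{name}[{condition}]"
            est = bf.estimates.get(key)
            se = bf.standard_errors.get(key, float("nan"))
            if est is not None:
                parts.append(f"{name}={est:.3f} ({se:.3f})")
        print(f"  {condition}: " + ", ".join(parts), file=buf)
    print("\nEquality tests across conditions:", file=buf)
    for parameter, tr in report.battery.items():
        print(f"  {parameter:15s} ΔG²({tr.df}) = {tr.delta_g_squared:6.2f}, "
              f"p = {tr.p_value:.3f}, w = {tr.w:.2f}", file=buf)
    if report.stability is not None:
        st = report.stability
        print(f"\nAcross-rounds stability of P_Moral: ΔG²({st.df}) = "
              f"{st.delta_g_squared:.2f}, p = {st.p_value:.3f}", file=buf)
    return buf.getvalue()
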
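"""Across-rounds stability of the moral-punishment parameter.

Stratifies each simulated experiment by condition × round (40 strata),
fits a base model with all five parameters free per stratum, and tests
the restriction that the moral-punishment parameter is constant across
the 20 rounds within each condition (19 restrictions per condition,
38 df in total).  Under the simulated conditions the parameter is
constant by construction, so the test should be non-significant.
Writes results/stability.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from coop_punish.pipeline import AnalysisConfig, read_trials, run_experiment_analysis
from coop_punish.studies import STUDY_DESIGNS, study_conditions

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()

    rows = []
    for name in STUDY_DESIGNS:
        trials = read_trials(args.data_dir / f"{name}_trials.csv")
        config = AnalysisConfig(conditions=study_conditions(name),
                                seed=args.seed, n_restarts=5,
                                battery=(), stability_test=True)
        report = run_experiment_analysis(trials, config)
        test = report.stability
        verdict = "stable" if test.p_value >= 0.05 else "changes across rounds"
        print(f"{name}: ΔG²({test.df}) = {test.delta_g_squared:.2f}, "
              f"p = {test.p_value:.3f}  [{verdict}]")
        rows.append(dict(experiment=name, delta_g_squared=test.delta_g_squared,
                         df=test.df, p_value=test.p_value))

    (ROOT / "results").mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(ROOT / "results" / "stability.csv", index=False)
    print("wrote results/stability.csv")


if __name__ == "__main__":
    main()
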
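"""Run the parameter-equality test battery on each simulated experiment.

For each of the five model parameters the battery equates the parameter
across the two conditions and tests the restriction with a 1-df ΔG²
statistic; the effect size is Cohen's w = sqrt(ΔG²/N_total) with
N_total the total number of game trials.  Writes results/test_battery.csv.
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
    parser.add_argument("--n-restarts", type=int, default=10)
    args = parser.parse_args()

    rows = []
    for name in STUDY_DESIGNS:
        trials = read_trials(args.data_dir / f"{name}_trials.csv")
        config = AnalysisConfig(conditions=study_conditions(name),
                                seed=args.seed, n_restarts=args.n_restarts,
                                stability_test=False)
        report = run_experiment_analysis(trials, config)
        print(f"\n{name} (N_total = {report.n_total}):")
        for parameter, test in report.battery.items():
            verdict = "differs" if test.p_value < 0.05 else "equal"
            print(f"  {parameter:15s} ΔG²({test.df}) = {test.delta_g_squared:6.2f}, "
                  f"p = {test.p_value:.3f}, w = {test.w:.2f}  [{verdict}]")
            rows.append(dict(experiment=name, parameter=parameter,
                             delta_g_squared=test.delta_g_squared, df=test.df,
                             p_value=test.p_value, w=test.w,
                             n_total=report.n_total))

    (ROOT / "results").mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(ROOT / "results" / "test_battery.csv", index=False)
    print("\nwrote results/test_battery.csv")


if __name__ == "__main__":
    main()
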
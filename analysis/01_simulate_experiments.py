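"""Simulate the three experiments and write their trial tables.

Generates synthetic trial-level data for the time-pressure experiment
(206 participants), the deliberation-pause experiment (508) and the
deliberation-content experiment (527), each with 20 Prisoner's Dilemma
rounds per participant against 10 cooperating and 10 defecting
programmed partners.  Tables go to results/data/.
"""

import argparse
from pathlib import Path

from coop_punish.pipeline import write_trials
from coop_punish.simulate import simulate_experiment
from coop_punish.studies import STUDY_DESIGNS, study_design

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20260101)
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for offset, name in enumerate(STUDY_DESIGNS):
        design = study_design(name, seed=args.seed + offset)
        trials = simulate_experiment(design)
        path = args.out_dir / f"{name}_trials.csv"
        write_trials(trials, path)
        n = trials["participant_id"].nunique()
        print(f"{name}: {n} participants, {len(trials)} trials -> {path.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
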
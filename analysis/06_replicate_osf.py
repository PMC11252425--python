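"""Replicate the published statistics from the original deposited data.

The published G², ΔG² and w values can only be reproduced from the
original trial-level data deposited at https://osf.io/a23gy/ — the
synthetic experiments elsewhere in this repository share the design but
not the participants' actual choices.  This driver runs the full
analysis (base fit, five equality tests, 38-df stability test) on that
deposit once it has been downloaded.

Usage: place the per-experiment trial tables as CSV under data/osf/
(exp1.csv, exp2.csv, exp3.csv) and, because the deposit's column layout
is not described in the publication, provide a YAML alias file mapping
the canonical column names (participant_id, condition, round_index,
is_practice, partner_type, own_choice, punish_invested) and choice
codes onto the deposit's, e.g.

    column_aliases: {own_choice: decision, punish_invested: punish}
    value_aliases:
      own_choice: {"1": cooperate, "0": defect}
    conditions: {exp1: [no_pressure, pressure], ...}

Without the deposit the script reports what is missing and exits
cleanly; it is not part of the synthetic analysis chain.
"""

import argparse
import json
import sys
from pathlib import Path

import yaml

from coop_punish.pipeline import (
    AnalysisConfig,
    format_report,
    read_trials,
    report_to_dict,
    run_experiment_analysis,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data-dir", type=Path, default=ROOT / "data" / "osf")
    parser.add_argument("--aliases", type=Path, default=None,
                        help="YAML file with column/value aliases per the docstring")
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    if not args.data_dir.is_dir():
        print(f"original deposit not found under {args.data_dir}; download it "
              "from https://osf.io/a23gy/ to run the replication", file=sys.stderr)
        return

    aliases = {}
    if args.aliases is not None:
        aliases = yaml.safe_load(args.aliases.read_text())

    out_dir = ROOT / "results" / "osf_replication"
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("exp1", "exp2", "exp3"):
        path = args.data_dir / f"{name}.csv"
        if not path.is_file():
            print(f"{name}: {path} missing, skipped", file=sys.stderr)
            continue
        trials = read_trials(
            path,
            column_aliases=aliases.get("column_aliases", {}),
            value_aliases=aliases.get("value_aliases", {}),
        )
        conditions = aliases.get("conditions", {}).get(
            name, sorted(trials["condition"].unique())
        )
        config = AnalysisConfig(conditions=tuple(conditions), seed=args.seed,
                                n_restarts=20)
        report = run_experiment_analysis(trials, config)
        (out_dir / f"{name}_report.json").write_text(
            json.dumps(report_to_dict(report), indent=2, sort_keys=True)
        )
        print(f"=== {name} ===")
        print(format_report(report))


if __name__ == "__main__":
    main()
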
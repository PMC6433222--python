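#!/usr/bin/env python
"""Adjudicate practice effects: per-group change over the 6-month period
against the half-SD criterion, the Bland-Altman measurement-error check,
and the overall first-vs-last paired test.

Reads results/equated_totals.csv and gbta artifacts from 05; writes
practice_effect_report.json and practice_effect_report.md.  Pass --plot to
drop a Bland-Altman figure under scratch/.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

import raschtraj as rt
from raschtraj.gbta import fit_gbta
from raschtraj.practice_effect import (
    adjudicate,
    bland_altman,
    bland_altman_plot,
    half_sd_criterion,
    overall_first_last_test,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--in-dir", type=Path, default=Path("results"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args()

    totals = pd.read_csv(args.in_dir / "equated_totals.csv")
    model_cfg = json.loads((args.in_dir / "gbta_model.json").read_text())
    model = fit_gbta(
        totals, K=model_cfg["K"], order=model_cfg["order"],
        n_starts=10, seed=args.seed,
    )

    wide = totals.pivot_table(index="person_id", columns="session", values="score")
    first_s, last_s = wide.columns.min(), wide.columns.max()
    criterion = half_sd_criterion(wide[first_s].dropna().to_numpy())
    paired = wide[[first_s, last_s]].dropna()
    ba = bland_altman(
        paired[first_s].to_numpy(), paired[last_s].to_numpy(),
        person_ids=list(paired.index),
    )
    overall = overall_first_last_test(
        paired[first_s].to_numpy(), paired[last_s].to_numpy()
    )
    months = totals["month"].max() - totals["month"].min()
    report = adjudicate(model, criterion, ba, period_months=months,
                        overall=overall)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "criterion_value": report.criterion_value,
        "period_months": report.period_months,
        "groups": [asdict(g) for g in report.groups],
        "bland_altman": {
            "mean_diff": ba.mean_diff, "loa_low": ba.loa_low,
            "loa_high": ba.loa_high, "n": ba.n, "n_outside": ba.n_outside,
        },
        "overall_statistic": report.overall_statistic,
        "overall_p_one_tailed": report.overall_p_one_tailed,
    }
    (args.out_dir / "practice_effect_report.json").write_text(
        json.dumps(payload, indent=2)
    )
    (args.out_dir / "practice_effect_report.md").write_text(
        report.to_markdown() + "\n"
    )
    if args.plot:
        Path("scratch").mkdir(exist_ok=True)
        bland_altman_plot(
            ba, paired[first_s].to_numpy(), paired[last_s].to_numpy(),
            Path("scratch") / "bland_altman.png",
        )

    print(report.to_markdown())


if __name__ == "__main__":
    main()
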
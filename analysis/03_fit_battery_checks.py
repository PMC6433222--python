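#!/usr/bin/env python
"""Quality-control battery for the calibrated scale: threshold order,
item/person fit, unidimensionality, response dependency, targeting and
person separation.

Reads results/cohort_responses.csv; writes fit_report.json and prints the
human-readable diagnostic table.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import raschtraj as rt
from raschtraj.dif_split import calibrate_with_collapse
from raschtraj.fit_battery import full_fit_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--n-intervals", type=int, default=5)
    args = ap.parse_args()

    responses = pd.read_csv(args.in_dir / "cohort_responses.csv")
    calib, _ = calibrate_with_collapse(responses, rt.calibrate)
    report = full_fit_report(calib, n_intervals=args.n_intervals)

    u = report.unidimensionality
    payload = {
        "threshold_order": report.threshold_order.to_dict("records"),
        "item_fit": report.item_fit.to_dict("records"),
        "unidimensionality": {
            "verdict": u.verdict,
            "proportion_outside": None if np.isnan(u.proportion) else u.proportion,
            "ci": [u.ci_low, u.ci_high],
            "positive_items": u.positive_items,
            "negative_items": u.negative_items,
        },
        "dependency": report.dependency.to_dict("records"),
        "targeting": report.targeting.__dict__,
        "psi": report.psi,
        "psi_note": report.psi_note,
    }
    args.out_dir.mkdir(parents=True, exist_ok=True)
    (args.out_dir / "fit_report.json").write_text(
        json.dumps(payload, indent=2, default=float)
    )
    print(report.to_text())


if __name__ == "__main__":
    main()
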
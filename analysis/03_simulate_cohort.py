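#!/usr/bin/env python
"""Generate the default synthetic cohort: 100 nurses (8-hour rotations),
100 support staff (12-24h) and 100 security staff (24-48h), each judging
every comparison context of the shift-work network.

Judgments are log-normal perturbations (sigma = 0.15) of the consistent
ratio matrices implied by each group's published weights, snapped to the
17-value judgment scale.  The full questionnaire CSV (~60k judgment rows)
goes to scratch/ (it is regenerable from the seed); a per-group summary of
respondent counts and consistency screening lands in
results/cohort_summary.csv.
"""

from pathlib import Path

import pandas as pd

from shiftanp.network import GROUPS, load_shiftwork_network
from shiftanp.survey import screen_by_cr, write_responses_csv
from shiftanp.synthetic import (CohortDesign, NoiseModel, generate_cohort,
                                ground_truth_from_fixtures)

ROOT = Path(__file__).resolve().parent.parent
SEED = 0
SIGMA = 0.15


def main():
    (ROOT / "scratch").mkdir(exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)
    net = load_shiftwork_network()
    design = CohortDesign(seed=SEED)
    records = generate_cohort(design, ground_truth_from_fixtures(net),
                              NoiseModel(sigma=SIGMA), net)
    csv_path = ROOT / "scratch" / "synthetic_responses.csv"
    write_responses_csv(records, net, csv_path)
    print(f"wrote {len(records)} respondents to {csv_path}")

    rows = []
    for g in GROUPS:
        members = [r for r in records if r.group == g]
        screening = screen_by_cr(members, threshold=0.1)
        rows.append({
            "group": g, "n_respondents": len(members),
            "n_excluded_cr": len(screening.excluded),
            "n_married": sum(r.demographics["married"] for r in members),
            "n_obligatory": sum(r.demographics["obligatory_selection"]
                                for r in members),
            "n_satisfied": sum(r.demographics["satisfied"] for r in members),
        })
        print(f"{g}: {len(members)} respondents, "
              f"{len(screening.excluded)} excluded by CR >= 0.1")
    out = ROOT / "results" / "cohort_summary.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
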
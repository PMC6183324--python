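#!/usr/bin/env python
"""Load and validate the shift-work decision network, and enumerate the
pairwise-comparison workload it implies.

The bundled network groups 30 decision elements: 7 disorder criteria, 20
specific complaints (sub-criteria), and the 3 shift types (alternatives),
under a single prioritization goal.  With inner dependence among the
criteria switched on (the bundled default) a respondent faces 35
comparison contexts; the pure hierarchy needs 28.

Writes results/network_contexts.csv (one row per context) and prints a
summary.
"""

from pathlib import Path

import pandas as pd

from shiftanp.network import comparison_contexts, load_shiftwork_network

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for feedback, tag in ((True, "with_criteria_feedback"), (False, "hierarchy_only")):
        net = load_shiftwork_network(criteria_feedback=feedback)
        ctxs = comparison_contexts(net)
        judgments = sum(c.n * (c.n - 1) // 2 for c in ctxs)
        print(f"{tag}: {len(net.nodes)} nodes, {len(net.edges)} edges, "
              f"{len(ctxs)} contexts, {judgments} judgments per respondent")
        for c in ctxs:
            rows.append({"variant": tag, "context": c.id, "wrt": c.target,
                         "cluster": c.cluster_id, "n_compared": c.n,
                         "n_judgments": c.n * (c.n - 1) // 2})
    out = RESULTS / "network_contexts.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
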
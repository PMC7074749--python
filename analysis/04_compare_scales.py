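#!/usr/bin/env python
"""Contrast the bulk and single-particle analyses.

Reads the per-scale outputs of the previous steps and writes a side-by-side
panel (co-occurrence topology, rule-type composition) to
results/comparison.tsv, highlighting how sample resolution changes the
inferred interaction structure.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for scale in ("bulk", "particle"):
        out = ROOT / "results" / scale
        summary = json.loads((out / "summary.json").read_text())
        topo = json.loads((out / "topology_cooccurrence.json").read_text())
        rules = json.loads((out / "rule_breakdown.json").read_text())
        rows.append(
            {
                "scale": scale,
                "fragments": summary["n_fragments"],
                "correlated_pairs": summary["n_correlated"],
                "positive": summary["n_positive"],
                "negative": summary["n_negative"],
                "estimated_fdr": summary["estimated_fdr"],
                "nodes": topo["n_nodes"],
                "edges": topo["n_edges"],
                "density": round(topo["density"], 3),
                "cpl": round(topo["characteristic_path_length"], 2),
                "clustering": round(topo["clustering_coefficient"], 2),
                "rules_total": rules["total"],
                "archaeum_to_bacterium": rules["archaeum_to_bacterium"],
                "bacterium_to_bacterium": rules["bacterium_to_bacterium"],
            }
        )
    panel = pd.DataFrame(rows).set_index("scale").T
    panel.to_csv(ROOT / "results" / "comparison.tsv", sep="\t")
    print(panel.to_string())
    ab_bulk = rows[0]["archaeum_to_bacterium"] / rows[0]["rules_total"]
    ab_part = rows[1]["archaeum_to_bacterium"] / rows[1]["rules_total"]
    print(
        f"\narchaeum -> bacterium rule share: bulk {ab_bulk:.0%} vs particle {ab_part:.0%} — "
        "the finer sample resolution concentrates dependencies on archaeal origins."
    )


if __name__ == "__main__":
    main()
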
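"""Simulate every screened network and score it against the E/M references.

For each condition's screened topologies, runs a randomized-parameter
ensemble (RACIPE-style), binarizes the steady-state profiles by per-gene
two-means, matches them to the role-derived E/M reference vectors under the
Hamming cutoff with random-match probability < 0.05, and writes the ranked
accuracy table (the machine analog of the accuracy-vs-network-property
sweep) under results/evaluation/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from emtcircuits import evaluate, racipe
from emtcircuits.netbuild import SignedNetwork
from emtcircuits.racipe import read_topology

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "evaluation"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-models", type=int, default=500)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    roles_table = pd.read_csv(BASE / "datf" / "roles.tsv", sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)
    all_rows = []
    for cond_dir in sorted((BASE / "networks").iterdir()):
        if not cond_dir.is_dir():
            continue
        label = cond_dir.name
        roles = (roles_table[roles_table["condition"] == label]
                 .set_index("tf")["role"].to_dict())
        manifest = json.loads((cond_dir / "manifest.json").read_text())
        for entry in manifest:
            topology = read_topology(cond_dir / f"{entry['name']}.topo")
            network = SignedNetwork(
                nodes=topology.genes,
                edges=[(s, t, 1 if y == 1 else -1) for s, t, y in topology.interactions],
                pos_cutoff=entry["pos_cutoff"], neg_cutoff=entry["neg_cutoff"],
                condition=label)
            ensemble = racipe.simulate_ensemble(topology, n_models=args.n_models,
                                                seed=args.seed)
            try:
                _, report = evaluate.evaluate_network(ensemble, roles, network)
            except (evaluate.UnevaluableNetworkError, ValueError):
                continue
            all_rows.append({
                "condition": label, "network": entry["name"],
                "pos_cutoff": entry["pos_cutoff"], "neg_cutoff": entry["neg_cutoff"],
                "n_nodes": network.n_nodes, "n_edges": network.n_edges,
                "k_common": report.k_common, "hamming_cutoff": report.hamming_cutoff,
                "n_e": report.n_e, "n_m": report.n_m,
                "accuracy": report.accuracy,
            })
    table = (pd.DataFrame(all_rows)
             .sort_values(["condition", "accuracy"], ascending=[True, False]))
    table.to_csv(OUT / "accuracy.tsv", sep="\t", index=False)
    best = table.groupby("condition").head(1)
    print(best.to_string(index=False))
    print(f"\nbest accuracy over the study: {table['accuracy'].max():.3f} "
          f"({len(table)} evaluable networks)")


if __name__ == "__main__":
    main()
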
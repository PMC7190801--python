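"""Construct context-specific signed networks for every condition.

Loads activities, regulons and the per-condition role annotations, scores
the regulon-derived candidate edges with Miller-Madow mutual information and
Spearman signs in each direction, sweeps the 20 x 10 MI cutoff grid, removes
sign conflicts, prunes signaling-only nodes once and screens for >= 5 E/M
TFs.  Writes each screened topology plus a manifest per condition under
results/networks/, and reports recovery against the known true circuit.
"""

import json
from pathlib import Path

import pandas as pd

from emtcircuits import datf, netbuild
from emtcircuits.datasets import ActivityDataset, RegulonSet
from emtcircuits.racipe import read_topology, write_topology

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "networks"


def main() -> None:
    roles_table = pd.read_csv(BASE / "datf" / "roles.tsv", sep="\t")
    true_topo = read_topology(BASE / "study" / "true_circuit.topo")
    true_set = {(s, t) for s, t, _ in true_topo.interactions}
    true_signs = {(s, t): (1 if y == 1 else -1) for s, t, y in true_topo.interactions}

    OUT.mkdir(parents=True, exist_ok=True)
    for path in sorted(BASE.glob("study/activities_*.tsv")):
        label = path.stem.removeprefix("activities_")
        dataset = ActivityDataset.from_tsv(path)
        regulons = RegulonSet.from_tsv(BASE / "study" / f"regulons_{label}_forward.tsv",
                                       BASE / "study" / f"regulons_{label}_backward.tsv")
        roles = (roles_table[roles_table["condition"] == label]
                 .set_index("tf")["role"].to_dict())
        common = [tf for tf, role in roles.items() if role in ("E", "M")]
        forward, backward = datf.split_forward_backward(dataset)
        backward = datf.scale_backward(forward, backward)
        candidates = netbuild.candidate_edges(regulons, common, dataset.tf_names)
        scored = netbuild.score_edges(candidates, forward, backward)
        networks = netbuild.sweep_grid(scored, condition=label)
        screened = [n for n in networks
                    if netbuild.screen_network(n, roles) and n.n_edges > 0]
        manifest = []
        cond_dir = OUT / label
        cond_dir.mkdir(parents=True, exist_ok=True)
        best_prec = 0.0
        for i, net in enumerate(screened):
            name = f"network_{i:03d}"
            write_topology(net.to_topology(), cond_dir / f"{name}.topo")
            prec = netbuild.edge_precision(net, true_set)
            sacc = netbuild.sign_accuracy(net, true_signs)
            best_prec = max(best_prec, prec if prec == prec else 0.0)
            manifest.append({
                "name": name, "pos_cutoff": net.pos_cutoff,
                "neg_cutoff": net.neg_cutoff, "n_nodes": net.n_nodes,
                "n_edges": net.n_edges, "cutoff_pairs": net.cutoff_pairs,
                "edge_precision_vs_truth": prec,
                "sign_accuracy_vs_truth": sacc,
            })
        (cond_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        print(f"{label}: {len(networks)} distinct topologies, "
              f"{len(screened)} screened, best edge precision {best_prec:.2f}")


if __name__ == "__main__":
    main()
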
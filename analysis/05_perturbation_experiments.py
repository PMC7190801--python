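"""Stochastic signal induction, removal and inhibition on the best network.

Takes the highest-accuracy network of the study, selects its E-state models,
and runs the three-phase protocol: induction (production of the M-team
signal genes x10,000), removal (rates restored) and inhibition (x0.0001),
with noise.  Reports the hysteresis asymmetry (fewer models revert after
removal than after inhibition), the calibrated signal+noise transition
comparison, and the per-timepoint PCA trajectory of the experimental
activities projected on the simulation's principal components.  Outputs
under results/perturbation/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from emtcircuits import datf, evaluate, racipe
from emtcircuits.datasets import ActivityDataset
from emtcircuits.netbuild import SignedNetwork
from emtcircuits.racipe import PerturbationProtocol, read_topology

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "perturbation"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-models", type=int, default=500)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    accuracy = pd.read_csv(BASE / "evaluation" / "accuracy.tsv", sep="\t")
    best = accuracy.sort_values("accuracy", ascending=False).iloc[0]
    label = best["condition"]
    print(f"best network: {label}/{best['network']} accuracy={best['accuracy']:.3f}")

    topology = read_topology(BASE / "networks" / label / f"{best['network']}.topo")
    roles_table = pd.read_csv(BASE / "datf" / "roles.tsv", sep="\t")
    roles = (roles_table[roles_table["condition"] == label]
             .set_index("tf")["role"].to_dict())
    network = SignedNetwork(
        nodes=topology.genes,
        edges=[(s, t, 1 if y == 1 else -1) for s, t, y in topology.interactions],
        pos_cutoff=best["pos_cutoff"], neg_cutoff=best["neg_cutoff"], condition=label)

    ensemble = racipe.simulate_ensemble(topology, n_models=args.n_models,
                                        seed=args.seed)
    reference = evaluate.build_reference(roles, network)
    cutoff = evaluate.hamming_cutoff(reference.k)
    binarized = evaluate.binarize_ensemble(ensemble)
    labels, report = evaluate.classify_models(binarized, ensemble.genes,
                                              reference, cutoff)
    e_idx = np.where(labels == "E")[0]
    m_genes = [tf for tf in topology.genes if roles.get(tf) == "M"]
    print(f"ensemble: {report.n_e} E, {report.n_m} M models; signal genes {m_genes}")

    OUT.mkdir(parents=True, exist_ok=True)

    # -- three-phase protocol with the published factors -------------------
    proto = PerturbationProtocol(signal_genes=m_genes, sample_times=(50.0,))
    induced = racipe.simulate_perturbation(ensemble, e_idx, proto, "induction",
                                           seed=args.seed + 1, relax_time=25.0)
    ind_b = evaluate.binarize_with_ensemble(ensemble, induced.final_states, binarized)
    ind_labels, _ = evaluate.classify_models(ind_b, ensemble.genes, reference, cutoff)
    transited = ind_labels == "M"
    summary = {"n_e_models": int(e_idx.size),
               "induced_to_m": int(transited.sum())}
    for phase in ("removal", "inhibition"):
        rec = racipe.simulate_perturbation(ensemble, e_idx, proto, phase,
                                           seed=args.seed + 2,
                                           initial_states=induced.final_states,
                                           relax_time=25.0)
        b = evaluate.binarize_with_ensemble(ensemble, rec.final_states, binarized)
        lab, _ = evaluate.classify_models(b, ensemble.genes, reference, cutoff)
        summary[f"returned_to_e_after_{phase}"] = int(((lab == "E") & transited).sum())
    print(f"hysteresis: {summary['induced_to_m']} E->M under induction; "
          f"{summary['returned_to_e_after_removal']} revert after removal vs "
          f"{summary['returned_to_e_after_inhibition']} after inhibition")

    # -- calibrated signal+noise comparison --------------------------------
    sn = evaluate.signal_noise_experiment(ensemble, roles, network,
                                          signal_genes=m_genes, seed=args.seed + 3)
    summary["signal_noise"] = {
        "signal_plus_noise": sn.transitions_signal_noise,
        "signal_only": sn.transitions_signal_only,
        "noise_only": sn.transitions_noise_only,
        "p_vs_signal_only": sn.p_vs_signal_only,
        "p_vs_noise_only": sn.p_vs_noise_only,
    }
    print(f"transitions: signal+noise {sn.transitions_signal_noise}, "
          f"signal {sn.transitions_signal_only}, noise {sn.transitions_noise_only} "
          f"(p={sn.p_vs_signal_only:.3g} / {sn.p_vs_noise_only:.3g})")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))

    # -- experimental trajectory on simulation PCs --------------------------
    dataset = ActivityDataset.from_tsv(BASE / "study" / f"activities_{label}.tsv")
    combined = datf.combine_on_forward_scale(dataset)
    subset = ActivityDataset(activities=combined.activities[topology.genes],
                             cell_meta=combined.cell_meta)
    _, timepoint_summary = evaluate.pca_project(ensemble, subset,
                                                e_centroid_labels=labels)
    timepoint_summary.to_csv(OUT / "pca_trajectory.tsv", sep="\t")
    print("per-timepoint PC1 trajectory:")
    print(timepoint_summary["pc1_mean"].round(2).to_string())

    # -- k=3 state clustering of the ensemble -------------------------------
    clusters = evaluate.cluster_states(ensemble, k=3)
    sizes = pd.Series(clusters).value_counts().sort_index()
    summary["state_cluster_sizes"] = sizes.tolist()
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"k=3 state clusters: {sizes.tolist()}")


if __name__ == "__main__":
    main()
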
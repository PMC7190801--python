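"""End-to-end pipeline: study -> differential activity -> networks -> evaluation.

Convenience drivers that chain the module stages for one condition of a
study: run the seven comparisons, annotate roles, build the candidate edges
from the regulons, sweep the MI cutoff grid, screen the networks, simulate
each screened topology as a RACIPE-style ensemble and score it against the
E/M references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datf, evaluate, netbuild, racipe
from .synth import SyntheticStudy


@dataclass
class ConditionNetworks:
    """Differential results and candidate networks for one condition."""

    condition: str
    comparisons: dict[str, pd.DataFrame]
    roles: dict[str, str]
    scored_edges: list[netbuild.CandidateEdge]
    networks: list[netbuild.SignedNetwork]
    screened: list[netbuild.SignedNetwork]


def analyze_condition(study: SyntheticStudy, condition: str,
                      alpha: float = 0.05, min_em: int = 5) -> ConditionNetworks:
    """Differential analysis and grid sweep for one study condition."""
    dataset = study.datasets[condition]
    comparisons = datf.run_comparisons(dataset)
    annotation = datf.annotate_em(comparisons, condition=condition, alpha=alpha)
    roles = annotation["role"].to_dict()
    common = [tf for tf, role in roles.items() if role in ("E", "M")]
    forward, backward = datf.split_forward_backward(dataset)
    backward = datf.scale_backward(forward, backward)
    candidates = netbuild.candidate_edges(study.regulons[condition], common,
                                          dataset.tf_names)
    scored = netbuild.score_edges(candidates, forward, backward)
    networks = netbuild.sweep_grid(scored, condition=condition)
    screened = [n for n in networks
                if netbuild.screen_network(n, roles, min_em=min_em) and n.n_edges > 0]
    return ConditionNetworks(condition=condition, comparisons=comparisons,
                             roles=roles, scored_edges=scored,
                             networks=networks, screened=screened)


@dataclass
class NetworkScore:
    """Accuracy of one simulated network topology."""

    network: netbuild.SignedNetwork
    report: evaluate.AccuracyReport

    @property
    def accuracy(self) -> float:
        return self.report.accuracy


def score_networks(result: ConditionNetworks, n_models: int = 500,
                   seed: int = 0, dt: float = 0.05,
                   networks: list[netbuild.SignedNetwork] | None = None,
                   ) -> list[NetworkScore]:
    """Simulate each screened network and score it against the E/M references.

    Networks whose role-annotated node count is too small for a valid
    Hamming cutoff are skipped (unevaluable at alpha).
    """
    scores: list[NetworkScore] = []
    for network in (networks if networks is not None else result.screened):
        topology = network.to_topology()
        if not topology.interactions:
            continue
        ensemble = racipe.simulate_ensemble(topology, n_models=n_models,
                                            seed=seed, dt=dt)
        try:
            _, report = evaluate.evaluate_network(ensemble, result.roles, network)
        except (evaluate.UnevaluableNetworkError, ValueError):
            continue
        scores.append(NetworkScore(network=network, report=report))
    return scores


def ranked_accuracy_table(scores: list[NetworkScore]) -> pd.DataFrame:
    """Machine analog of the accuracy-vs-network-property sweep plots."""
    rows = [{
        "pos_cutoff": s.network.pos_cutoff,
        "neg_cutoff": s.network.neg_cutoff,
        "n_nodes": s.network.n_nodes,
        "n_edges": s.network.n_edges,
        "k_common": s.report.k_common,
        "hamming_cutoff": s.report.hamming_cutoff,
        "n_e": s.report.n_e,
        "n_m": s.report.n_m,
        "accuracy": s.report.accuracy,
    } for s in scores]
    return (pd.DataFrame(rows)
            .sort_values("accuracy", ascending=False)
            .reset_index(drop=True))


def scramble_signs(network: netbuild.SignedNetwork) -> netbuild.SignedNetwork:
    """Control topology with every interaction sign flipped."""
    return netbuild.SignedNetwork(
        nodes=list(network.nodes),
        edges=[(s, t, -sign) for s, t, sign in network.edges],
        pos_cutoff=network.pos_cutoff, neg_cutoff=network.neg_cutoff,
        condition=f"{network.condition}:sign-scrambled",
    )
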
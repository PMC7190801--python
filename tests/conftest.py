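"""Shared fixtures: one synthetic study and small simulation ensembles.

Session-scoped so the expensive objects (12-condition study, differential
results, ODE ensembles) are computed once for the whole suite.
"""

import numpy as np
import pytest

from emtcircuits import datf, racipe
from emtcircuits.synth import ConditionSpec, generate_circuit, generate_study

STUDY_SEED = 10


@pytest.fixture(scope="session")
def circuit():
    """12-TF ground-truth circuit with 4 cell-line x 3 signal role structure."""
    return generate_circuit(n_tfs=12, n_conditions=12, role_switch_rate=0.3,
                            seed=1, grid=(4, 3))


@pytest.fixture(scope="session")
def base_spec():
    return ConditionSpec(cell_line="CL1", signal="SIG1", cells_per_timepoint=100,
                         noise_sd=0.5, effect_size=2.0, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study(circuit, base_spec):
    """The full synthetic study: 12 activity datasets plus regulon sets."""
    return generate_study(circuit, base_spec)


@pytest.fixture(scope="session")
def study_comparisons(study):
    """All 84 differential comparisons of the synthetic study."""
    return datf.run_study_comparisons(study.datasets)


@pytest.fixture(scope="session")
def toggle_topology():
    return racipe.Topology(genes=["A", "B"],
                           interactions=[("A", "B", 2), ("B", "A", 2)])


@pytest.fixture(scope="session")
def toggle_ensemble(toggle_topology):
    return racipe.simulate_ensemble(toggle_topology, n_models=2000, seed=7)


def team_topology(n_per_team: int = 3) -> racipe.Topology:
    """Mutually inhibitory E/M teams with intra-team activation cycles."""
    e_genes = [f"E{i}" for i in range(n_per_team)]
    m_genes = [f"M{i}" for i in range(n_per_team)]
    interactions = []
    for group in (e_genes, m_genes):
        for i, g in enumerate(group):
            interactions.append((g, group[(i + 1) % n_per_team], 1))
    for i in range(n_per_team):
        interactions.append((e_genes[i], m_genes[i], 2))
        interactions.append((m_genes[i], e_genes[i], 2))
    return racipe.Topology(genes=e_genes + m_genes, interactions=interactions)


@pytest.fixture(scope="session")
def team_ensemble():
    """500-model ensemble of the 3+3 team circuit, for evaluation tests."""
    return racipe.simulate_ensemble(team_topology(3), n_models=500, seed=7)


@pytest.fixture(scope="session")
def team_roles():
    return {f"E{i}": "E" for i in range(3)} | {f"M{i}": "M" for i in range(3)}


@pytest.fixture(scope="session")
def condition_networks(study):
    """Full differential + network-construction pass for one condition."""
    from emtcircuits.pipeline import analyze_condition
    return analyze_condition(study, "CL1_SIG1")


@pytest.fixture(scope="session")
def network_scores(condition_networks):
    """Accuracy of every screened CL1_SIG1 network (500-model ensembles)."""
    from emtcircuits.pipeline import score_networks
    return score_networks(condition_networks, n_models=500, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
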
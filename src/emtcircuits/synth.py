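"""Synthetic ground-truth circuits, time-series TF-activity data and regulons.

The generator emulates the structure of a multi-condition EMT time-course
study: 4 cell lines x 3 signals, eight timepoints (five during signal
induction, three after removal), per-TF temporal roles (E: activity falls
during induction; M: rises; I: rises then falls; I2: falls then rises; flat),
condition-specific role switching, day-7 cells shared by the forward and
backward splits, and regulon files containing the circuit's true targets
plus decoys.

Activities are continuous regulon-activity scores: per-cell values are the
role's mean trajectory plus homoscedastic Gaussian noise.  A signed fraction
of each regulator's intrinsic fluctuation is propagated to its true targets
(``edge_coupling``), so that TF pairs connected in the ground-truth circuit
co-fluctuate within a timepoint — the statistical signature the downstream
mutual-information scoring relies on.  Backward-direction measurements live
on a deliberately different per-TF affine scale, emulating the two splits
being processed separately, so the rescaling stage has an exactly
recoverable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import TIMEPOINTS, ActivityDataset, RegulonSet

ROLES = ("E", "M", "I", "I2", "flat")

#: Mean activity at the eight design timepoints, in multiples of effect_size.
#: Forward and removal branches are deliberately asymmetric (hysteresis-like),
#: so forward/backward trajectories do not retrace each other.
ROLE_SHAPES: dict[str, tuple[float, ...]] = {
    "E": (0.0, -0.25, -0.5, -0.75, -1.0, -0.7, -0.4, -0.1),
    "M": (0.0, 0.25, 0.5, 0.75, 1.0, 0.7, 0.4, 0.1),
    "I": (0.0, 0.8, 1.0, 0.5, 0.0, 0.3, 0.15, 0.0),
    "I2": (0.0, -0.8, -1.0, -0.5, 0.0, -0.3, -0.15, 0.0),
    "flat": (0.0,) * 8,
}

MIN_EM_PER_CONDITION = 5


@dataclass
class GroundTruthCircuit:
    """A known regulatory circuit with per-condition TF roles.

    edges are (source, target, sign, strength) with sign in {+1, -1} and
    strength in (0, 1]; roles maps condition label -> {tf: role}.
    """

    tf_names: list[str]
    edges: list[tuple[str, str, int, float]]
    roles: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        tfs = set(self.tf_names)
        seen: set[tuple[str, str]] = set()
        for src, tgt, sign, strength in self.edges:
            if src not in tfs or tgt not in tfs:
                raise ValueError(f"edge {src}->{tgt} references unknown TF")
            if (src, tgt) in seen:
                raise ValueError(f"duplicate edge {src}->{tgt}")
            if sign not in (1, -1) or not (0.0 < strength <= 1.0):
                raise ValueError(f"bad sign/strength on edge {src}->{tgt}")
            seen.add((src, tgt))
        for cond, mapping in self.roles.items():
            n_em = sum(1 for r in mapping.values() if r in ("E", "M"))
            if n_em < MIN_EM_PER_CONDITION:
                raise ValueError(f"condition {cond} has only {n_em} E/M TFs")

    @property
    def conditions(self) -> list[str]:
        return list(self.roles)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, _, _ in self.edges}

    def edge_signs(self) -> dict[tuple[str, str], int]:
        return {(s, t): sign for s, t, sign, _ in self.edges}

    def true_targets(self, tf: str) -> set[str]:
        return {t for s, t, _, _ in self.edges if s == tf}


@dataclass
class ConditionSpec:
    """Study-condition settings for one cell line x signal combination."""

    cell_line: str
    signal: str
    cells_per_timepoint: int = 100
    noise_sd: float = 0.5
    effect_size: float = 2.0
    edge_coupling: float = 0.9
    seed: int = 0
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        if tuple(self.timepoints) != TIMEPOINTS:
            raise ValueError("timepoints are fixed to the 8-point design")
        if self.cells_per_timepoint < 20:
            raise ValueError("cells_per_timepoint must be >= 20")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def condition(self) -> str:
        return f"{self.cell_line}_{self.signal}"


def _base_roles(tf_names: list[str]) -> dict[str, str]:
    n = len(tf_names)
    n_em = max(3, (3 * n) // 10)
    rest = n - 2 * n_em
    n_i = n_i2 = max(1, rest // 3) if rest >= 2 else 0
    roles: dict[str, str] = {}
    for i, tf in enumerate(tf_names):
        if i < n_em:
            roles[tf] = "E"
        elif i < 2 * n_em:
            roles[tf] = "M"
        elif i < 2 * n_em + n_i:
            roles[tf] = "I"
        elif i < 2 * n_em + n_i + n_i2:
            roles[tf] = "I2"
        else:
            roles[tf] = "flat"
    return roles


def _switch_roles(base: dict[str, str], rate: float, rng: np.random.Generator) -> dict[str, str]:
    """Reassign a Bernoulli(rate) fraction of TFs to a different random role,
    then revert switches as needed to keep at least 5 E/M TFs."""
    roles = dict(base)
    switched: list[str] = []
    for tf in roles:
        if rng.uniform() < rate:
            options = [r for r in ROLES if r != roles[tf]]
            roles[tf] = options[rng.integers(len(options))]
            switched.append(tf)
    rng.shuffle(switched)
    while sum(1 for r in roles.values() if r in ("E", "M")) < MIN_EM_PER_CONDITION and switched:
        tf = switched.pop()
        roles[tf] = base[tf]
    return roles


def generate_circuit(n_tfs: int, n_conditions: int, role_switch_rate: float,
                     seed: int, grid: tuple[int, int] | None = None) -> GroundTruthCircuit:
    """Build a ground-truth circuit with mutually inhibitory E/M teams.

    E-group TFs activate each other and inhibit the M group (and vice versa);
    I/I2 TFs are wired between the two teams; flat TFs carry no edges.  Roles
    are re-drawn per condition: a fraction ``role_switch_rate`` of TFs change
    role relative to the first condition.  With ``grid=(n_cell_lines,
    n_signals)``, switching is hierarchical — cell-line level at the full
    rate, signal level within a cell line at a third of it — so conditions of
    the same cell line share more roles than conditions of the same signal.
    """
    if n_tfs < 8:
        raise ValueError("circuit too small for E/M screening")
    if not 0.0 <= role_switch_rate <= 1.0:
        raise ValueError("role_switch_rate must be in [0, 1]")
    if grid is not None and grid[0] * grid[1] != n_conditions:
        raise ValueError("grid dimensions must multiply to n_conditions")
    rng = np.random.default_rng(seed)
    tf_names = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    base = _base_roles(tf_names)
    e_group = [tf for tf in tf_names if base[tf] == "E"]
    m_group = [tf for tf in tf_names if base[tf] == "M"]
    i_group = [tf for tf in tf_names if base[tf] == "I"]
    i2_group = [tf for tf in tf_names if base[tf] == "I2"]

    def strength() -> float:
        return float(rng.uniform(0.5, 1.0))

    edges: list[tuple[str, str, int, float]] = []
    for group in (e_group, m_group):  # intra-team activation (cycle)
        for i, tf in enumerate(group):
            edges.append((tf, group[(i + 1) % len(group)], 1, strength()))
    for i, tf in enumerate(e_group):  # inter-team mutual inhibition
        edges.append((tf, m_group[i % len(m_group)], -1, strength()))
    for i, tf in enumerate(m_group):
        edges.append((tf, e_group[i % len(e_group)], -1, strength()))
    for i, tf in enumerate(i_group):  # intermediates bridge the teams
        edges.append((m_group[i % len(m_group)], tf, 1, strength()))
        edges.append((tf, e_group[i % len(e_group)], -1, strength()))
    for i, tf in enumerate(i2_group):
        edges.append((e_group[i % len(e_group)], tf, 1, strength()))
        edges.append((tf, m_group[i % len(m_group)], -1, strength()))

    if grid is None:
        labels = [f"cond{i + 1}" for i in range(n_conditions)]
        roles = {labels[0]: dict(base)}
        for label in labels[1:]:
            roles[label] = _switch_roles(base, role_switch_rate, rng)
    else:
        n_lines, n_signals = grid
        roles = {}
        for li in range(n_lines):
            line_roles = _switch_roles(base, role_switch_rate, rng) if li else dict(base)
            for si in range(n_signals):
                label = f"CL{li + 1}_SIG{si + 1}"
                if si == 0:
                    roles[label] = dict(line_roles)
                else:
                    roles[label] = _switch_roles(line_roles, role_switch_rate / 3.0, rng)
    return GroundTruthCircuit(tf_names=tf_names, edges=edges, roles=roles)


def simulate_timecourse(circuit: GroundTruthCircuit, spec: ConditionSpec) -> ActivityDataset:
    """Simulate one condition's cells x TFs activity matrix.

    Per-TF means follow the role's trajectory scaled by ``effect_size``;
    per-cell values add Gaussian noise (sd ``noise_sd``) plus the signed,
    strength-weighted coupling of each regulator's intrinsic noise to its
    true targets.  Day-7 cells are generated once and tagged
    direction="both"; the per-TF backward affine scale is recorded on the
    dataset for the split stage to apply.
    """
    condition = spec.condition
    if condition not in circuit.roles:
        raise ValueError(f"circuit has no roles for condition {condition!r}")
    roles = circuit.roles[condition]
    for tf in circuit.tf_names:
        if roles.get(tf) not in ROLES:
            raise ValueError(f"unknown role {roles.get(tf)!r} for TF {tf}")
    rng = np.random.default_rng(spec.seed)
    tfs = circuit.tf_names
    tf_pos = {tf: j for j, tf in enumerate(tfs)}
    n_tp = len(TIMEPOINTS)
    n_cells = n_tp * spec.cells_per_timepoint

    means = np.array([[ROLE_SHAPES[roles[tf]][ti] * spec.effect_size
                       for tf in tfs] for ti in range(n_tp)])
    tp_index = np.repeat(np.arange(n_tp), spec.cells_per_timepoint)
    intrinsic = rng.normal(0.0, spec.noise_sd, size=(n_cells, len(tfs)))
    acts = means[tp_index] + intrinsic
    for src, tgt, sign, strength in circuit.edges:
        acts[:, tf_pos[tgt]] += sign * strength * spec.edge_coupling * intrinsic[:, tf_pos[src]]

    cell_ids = [f"{condition}_{TIMEPOINTS[t]}_{i}"
                for t in range(n_tp) for i in range(spec.cells_per_timepoint)]
    timepoint_labels = [TIMEPOINTS[t] for t in tp_index]
    direction = ["both" if tp == "7d" else ("backward" if tp.endswith("_rm") else "forward")
                 for tp in timepoint_labels]
    meta = pd.DataFrame(
        {"condition": condition, "timepoint": timepoint_labels, "direction": direction},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    activities = pd.DataFrame(acts, index=meta.index, columns=tfs)
    backward_scale = pd.DataFrame(
        {"slope": rng.uniform(0.5, 2.0, size=len(tfs)),
         "intercept": rng.uniform(-1.0, 1.0, size=len(tfs))},
        index=pd.Index(tfs, name="tf"),
    )
    return ActivityDataset(activities=activities, cell_meta=meta,
                           backward_scale=backward_scale)


def generate_regulons(circuit: GroundTruthCircuit, decoy_rate: float,
                      seed: int, dropout: float = 0.0) -> RegulonSet:
    """Regulon files: true targets per TF plus uniformly drawn decoy targets.

    Decoys form fraction ``decoy_rate`` of each regulon's entries and are
    drawn from TFs the regulator has no true edge to.  Forward and backward
    regulons differ by independent per-entry dropout.
    """
    if not 0.0 <= decoy_rate < 1.0:
        raise ValueError("decoy_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    forward: dict[str, set[str]] = {}
    backward: dict[str, set[str]] = {}
    for tf in circuit.tf_names:
        true = sorted(circuit.true_targets(tf))
        if not true:
            continue
        n_decoy = int(round(len(true) * decoy_rate / (1.0 - decoy_rate)))
        pool = sorted(set(circuit.tf_names) - set(true) - {tf})
        n_decoy = min(n_decoy, len(pool))
        decoys = list(rng.choice(pool, size=n_decoy, replace=False)) if n_decoy else []
        entries = true + decoys
        for mapping in (forward, backward):
            kept = {t for t in entries if rng.uniform() >= dropout}
            if kept:
                mapping[tf] = kept
    return RegulonSet(forward=forward, backward=backward)


@dataclass
class SyntheticStudy:
    """A full 4 cell-line x 3 signal study: circuit, datasets, regulons."""

    circuit: GroundTruthCircuit
    datasets: dict[str, ActivityDataset]
    regulons: dict[str, RegulonSet]

    @property
    def conditions(self) -> list[str]:
        return list(self.datasets)


def generate_study(circuit: GroundTruthCircuit, base_spec: ConditionSpec,
                   n_cell_lines: int = 4, n_signals: int = 3,
                   decoy_rate: float = 0.3, dropout: float = 0.1) -> SyntheticStudy:
    """Generate the full multi-condition study from one ground-truth circuit.

    The circuit must carry roles for every ``CL{i}_SIG{j}`` condition (use
    ``generate_circuit(..., grid=(n_cell_lines, n_signals))``).  Each
    condition gets its own activity dataset and regulon set; per-condition
    seeds are derived deterministically from ``base_spec.seed``.
    """
    datasets: dict[str, ActivityDataset] = {}
    regulons: dict[str, RegulonSet] = {}
    idx = 0
    for li in range(n_cell_lines):
        for si in range(n_signals):
            cell_line, signal = f"CL{li + 1}", f"SIG{si + 1}"
            label = f"{cell_line}_{signal}"
            if label not in circuit.roles:
                raise ValueError(f"circuit has no roles for condition {label!r}")
            spec = replace(base_spec, cell_line=cell_line, signal=signal,
                           seed=base_spec.seed + 1000 * (idx + 1))
            datasets[label] = simulate_timecourse(circuit, spec)
            regulons[label] = generate_regulons(circuit, decoy_rate,
                                                seed=base_spec.seed + 77 * (idx + 1),
                                                dropout=dropout)
            idx += 1
    return SyntheticStudy(circuit=circuit, datasets=datasets, regulons=regulons)


def circuit_to_topology_rows(circuit: GroundTruthCircuit) -> list[tuple[str, str, int]]:
    """Ground-truth edges in the Source/Target/Type convention (1=act, 2=inh)."""
    return [(s, t, 1 if sign > 0 else 2) for s, t, sign, _ in circuit.edges]
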
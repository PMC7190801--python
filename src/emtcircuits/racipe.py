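"""Random-circuit-perturbation (RACIPE-style) ensemble simulator.

A network topology (regulator, target, interaction type) is simulated as an
ensemble of ODE models whose kinetic parameters are randomized within fixed
ranges.  Each gene obeys

    dx_i/dt = g_i * prod_j H(x_j; x0_ij, n_ij, lambda_ij) - k_i * x_i

where H is the shifted Hill function, equal to 1 at zero regulator and to
lambda at saturation (lambda > 1 for activation, lambda < 1 for inhibition).
The generic steady-state repertoire of the topology emerges across the
ensemble rather than within any single parameter set.

Parameter ranges: maximum production rate g in [1, 100], degradation rate k
in [0.1, 1], Hill coefficient n in {1..6}, fold change in [1, 100].  The
regulation threshold of each interaction is sampled uniformly on
[0.02*M, 1.98*M], where M is the median unregulated level g/k over the
parameter ranges, so that each link is functional in roughly half of the
ensemble (the half-functional rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

ACTIVATION = 1
INHIBITION = 2

G_RANGE = (1.0, 100.0)
K_RANGE = (0.1, 1.0)
N_CHOICES = (1, 2, 3, 4, 5, 6)
FOLD_RANGE = (1.0, 100.0)
THRESHOLD_SPAN = (0.02, 1.98)  # multiples of the unregulated median level


# ---------------------------------------------------------------------------
# Topology


@dataclass
class Topology:
    """Directed signed regulatory network in the Source/Target/Type convention."""

    genes: list[str]
    interactions: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        seen: set[tuple[str, str]] = set()
        for src, tgt, typ in self.interactions:
            if src not in gene_set or tgt not in gene_set:
                raise ValueError(f"interaction {src}->{tgt} references unknown gene")
            if typ not in (ACTIVATION, INHIBITION):
                raise ValueError(f"unknown interaction type {typ} for {src}->{tgt}")
            if (src, tgt) in seen:
                raise ValueError(f"duplicate interaction {src}->{tgt}")
            seen.add((src, tgt))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def read_topology(path: str | Path) -> Topology:
    """Parse a three-column 'Source Target Type' file (Type 1/2)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty topology file")
    header = lines[0].split()
    if [h.lower() for h in header] != ["source", "target", "type"]:
        raise ValueError(f"bad topology header at line 1: {lines[0]!r}")
    genes: list[str] = []
    seen: set[str] = set()
    interactions: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ValueError(f"expected 3 columns at line {lineno}: {line!r}")
        src, tgt, typ_s = fields
        try:
            typ = int(typ_s)
        except ValueError:
            raise ValueError(f"non-integer interaction type at line {lineno}") from None
        if typ not in (ACTIVATION, INHIBITION):
            raise ValueError(f"unknown interaction type at line {lineno}")
        for g in (src, tgt):  # gene order = order of first appearance
            if g not in seen:
                seen.add(g)
                genes.append(g)
        interactions.append((src, tgt, typ))
    return Topology(genes=genes, interactions=interactions)


def write_topology(topology: Topology, path: str | Path) -> None:
    lines = ["Source Target Type"]
    lines += [f"{s} {t} {y}" for s, t, y in topology.interactions]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Kinetics


def shifted_hill(x: np.ndarray | float, x0: np.ndarray | float,
                 n: np.ndarray | int, lam: np.ndarray | float) -> np.ndarray | float:
    """Regulation term: 1 at x = 0, lambda at saturation, (1+lambda)/2 at x0."""
    return lam + (1.0 - lam) / (1.0 + (np.asarray(x, dtype=float) / x0) ** n)


@lru_cache(maxsize=1)
def median_unregulated_level() -> float:
    """Median of g/k with g ~ U[1,100], k ~ U[0.1,1] (closed-form CDF, solved)."""
    g_lo, g_hi = G_RANGE
    k_lo, k_hi = K_RANGE

    def cdf(m: float) -> float:
        # P(g/k <= m) = E_k[ clip((m k - g_lo)/(g_hi - g_lo), 0, 1) ]
        ks = np.linspace(k_lo, k_hi, 20001)
        p = np.clip((m * ks - g_lo) / (g_hi - g_lo), 0.0, 1.0)
        return float(np.trapezoid(p, ks) / (k_hi - k_lo))

    return float(brentq(lambda m: cdf(m) - 0.5, g_lo / k_hi, g_hi / k_lo))


@dataclass
class KineticParameters:
    """Per-model kinetic parameters for one topology, stacked across models.

    Arrays are shaped (n_models, n_genes) for g and k and
    (n_models, n_interactions) for n, fold and threshold.  ``lam`` holds the
    effective Hill asymptote: the sampled fold change for activations and its
    reciprocal for inhibitions.
    """

    topology: Topology
    g: np.ndarray
    k: np.ndarray
    n: np.ndarray
    fold: np.ndarray
    threshold: np.ndarray
    src_idx: np.ndarray = field(repr=False, default=None)
    tgt_idx: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        idx = self.topology.gene_index()
        if self.src_idx is None:
            self.src_idx = np.array([idx[s] for s, _, _ in self.topology.interactions], dtype=int)
        if self.tgt_idx is None:
            self.tgt_idx = np.array([idx[t] for _, t, _ in self.topology.interactions], dtype=int)

    @property
    def n_models(self) -> int:
        return self.g.shape[0]

    @property
    def lam(self) -> np.ndarray:
        types = np.array([y for _, _, y in self.topology.interactions])
        lam = self.fold.copy()
        if lam.size:
            lam[:, types == INHIBITION] = 1.0 / lam[:, types == INHIBITION]
        return lam

    def subset(self, model_idx: np.ndarray) -> "KineticParameters":
        return KineticParameters(
            topology=self.topology,
            g=self.g[model_idx].copy(), k=self.k[model_idx].copy(),
            n=self.n[model_idx].copy(), fold=self.fold[model_idx].copy(),
            threshold=self.threshold[model_idx].copy(),
        )


def sample_parameters(topology: Topology, n_models: int, seed: int) -> KineticParameters:
    """Sample one ensemble of randomized kinetic parameter sets."""
    rng = np.random.default_rng(seed)
    n_genes = topology.n_genes
    n_int = len(topology.interactions)
    g = rng.uniform(*G_RANGE, size=(n_models, n_genes))
    k = rng.uniform(*K_RANGE, size=(n_models, n_genes))
    n = rng.integers(N_CHOICES[0], N_CHOICES[-1] + 1, size=(n_models, n_int)).astype(float)
    fold = rng.uniform(*FOLD_RANGE, size=(n_models, n_int))
    m = median_unregulated_level()
    threshold = rng.uniform(THRESHOLD_SPAN[0] * m, THRESHOLD_SPAN[1] * m, size=(n_models, n_int))
    return KineticParameters(topology=topology, g=g, k=k, n=n, fold=fold, threshold=threshold)


def initial_condition(params: KineticParameters, seed: int) -> np.ndarray:
    """Log-uniform initial state between each gene's min and max possible level.

    min = (g/k) * prod of incoming inhibitory lambdas (< 1);
    max = (g/k) * prod of incoming activating lambdas (> 1).
    An unregulated gene starts exactly at g/k.
    """
    rng = np.random.default_rng(seed)
    base = params.g / params.k  # (models, genes)
    lo = base.copy()
    hi = base.copy()
    lam = params.lam
    types = np.array([y for _, _, y in params.topology.interactions])
    for e, (src, tgt, typ) in enumerate(params.topology.interactions):
        j = params.tgt_idx[e]
        if typ == INHIBITION:
            lo[:, j] *= lam[:, e]
        else:
            hi[:, j] *= lam[:, e]
    u = rng.uniform(size=base.shape)
    return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


def _derivative(x: np.ndarray, params: KineticParameters) -> np.ndarray:
    """dx/dt for all models at once; x has shape (n_models, n_genes)."""
    prod = np.ones_like(x)
    lam = params.lam
    for e in range(len(params.topology.interactions)):
        h = shifted_hill(x[:, params.src_idx[e]], params.threshold[:, e],
                         params.n[:, e], lam[:, e])
        prod[:, params.tgt_idx[e]] *= h
    return params.g * prod - params.k * x


def integrate(params: KineticParameters, init: np.ndarray,
              t_end: float = 50.0, dt: float = 0.05) -> np.ndarray:
    """Classic fourth-order Runge-Kutta to t_end; negative excursions clipped at 0."""
    n_steps = int(round(t_end / dt))
    if not np.isclose(n_steps * dt, t_end):
        raise ValueError("dt must divide t_end")
    x = np.asarray(init, dtype=float).copy()
    for _ in range(n_steps):
        k1 = _derivative(x, params)
        k2 = _derivative(np.clip(x + 0.5 * dt * k1, 0.0, None), params)
        k3 = _derivative(np.clip(x + 0.5 * dt * k2, 0.0, None), params)
        k4 = _derivative(np.clip(x + dt * k3, 0.0, None), params)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.clip(x, 0.0, None, out=x)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("integration diverged")
    return x


LOG_EPS = 1e-6


def process_states(raw: np.ndarray) -> np.ndarray:
    """log2 transform (with a small floor) and per-gene standardization."""
    logged = np.log2(raw + LOG_EPS)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (logged - mu) / sd


@dataclass
class ModelEnsemble:
    """Steady-state profiles of n_models randomized models of one topology."""

    topology: Topology
    parameters: KineticParameters
    raw_states: np.ndarray        # (n_models, n_genes), >= 0
    processed_states: np.ndarray  # log2 + standardized per gene
    seed: int

    @property
    def n_models(self) -> int:
        return self.raw_states.shape[0]

    @property
    def genes(self) -> list[str]:
        return self.topology.genes


def simulate_ensemble(topology: Topology, n_models: int = 2000,
                      seed: int = 0, dt: float = 0.05) -> ModelEnsemble:
    """Simulate an ensemble: sample parameters, integrate each model for 50 time units."""
    params = sample_parameters(topology, n_models, seed=seed)
    init = initial_condition(params, seed=seed + 1)
    raw = integrate(params, init, t_end=50.0, dt=dt)
    return ModelEnsemble(topology=topology, parameters=params, raw_states=raw,
                         processed_states=process_states(raw), seed=seed)


# ---------------------------------------------------------------------------
# Stochastic perturbation protocols


@dataclass
class PerturbationProtocol:
    """Signal induction / removal / inhibition settings.

    The production rates of ``signal_genes`` are multiplied by the factor of
    the active phase (each factor is applied to the original rates, so
    removal restores them and inhibition drops them below baseline).
    ``noise_level`` sets the additive Gaussian noise of the Euler-Maruyama
    integration in units of each gene's unregulated expression scale g/k:
    the per-gene amplitude is noise_level * (g/k), always computed from the
    unperturbed production rates.
    """

    signal_genes: list[str]
    induction_factor: float = 10000.0
    removal_factor: float = 1.0
    inhibition_factor: float = 0.0001
    noise_level: float = 0.05
    sample_times: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0, 50.0)

    def factor_for(self, phase: str) -> float:
        try:
            return {"induction": self.induction_factor,
                    "removal": self.removal_factor,
                    "inhibition": self.inhibition_factor}[phase]
        except KeyError:
            raise ValueError(f"unknown phase {phase!r}") from None


@dataclass
class TrajectoryRecord:
    """Sampled stochastic trajectories of a perturbation phase."""

    phase: str
    times: np.ndarray              # (n_times,)
    states: np.ndarray             # (n_times, n_models, n_genes), raw scale
    final_states: np.ndarray       # (n_models, n_genes)
    model_idx: np.ndarray          # indices into the parent ensemble


def simulate_perturbation(ensemble: ModelEnsemble, model_idx: np.ndarray,
                          protocol: PerturbationProtocol, phase: str,
                          seed: int, dt: float = 0.05,
                          initial_states: np.ndarray | None = None,
                          signal_factor: float | None = None,
                          relax_time: float = 0.0) -> TrajectoryRecord:
    """Euler-Maruyama integration of one protocol phase with modified production.

    Initial states default to the selected models' steady states; chained
    phases pass the previous phase's final states.  Noise is additive with
    per-gene amplitude noise_level * (g/k) (from the unperturbed rates),
    scaled by sqrt(dt) per step and reflected at zero so concentrations stay
    nonnegative.  ``signal_factor`` overrides the phase's default factor
    (the paper's own procedure selects signal strength and noise so that
    noise-assisted transitions are demonstrable).  With ``relax_time`` > 0
    the final states are additionally relaxed deterministically under the
    phase's parameters, so they sit on an attractor before classification.
    """
    model_idx = np.asarray(model_idx, dtype=int)
    if model_idx.size == 0:
        raise ValueError("model subset is empty")
    factor = protocol.factor_for(phase) if signal_factor is None else signal_factor
    params = ensemble.parameters.subset(model_idx)
    amplitude = protocol.noise_level * params.g / params.k  # unperturbed scale
    gene_pos = ensemble.topology.gene_index()
    for gene in protocol.signal_genes:
        if gene not in gene_pos:
            raise ValueError(f"signal gene {gene!r} not in topology")
        params.g[:, gene_pos[gene]] *= factor

    if initial_states is None:
        x = ensemble.raw_states[model_idx].copy()
    else:
        x = np.asarray(initial_states, dtype=float).copy()
    rng = np.random.default_rng(seed)
    sample_times = np.asarray(protocol.sample_times, dtype=float)
    t_end = float(sample_times.max())
    n_steps = int(round(t_end / dt))
    sample_steps = {int(round(t / dt)): i for i, t in enumerate(sample_times)}
    sampled = np.empty((len(sample_times),) + x.shape)
    sqrt_dt = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        drift = _derivative(x, params)
        noise = amplitude * sqrt_dt * rng.standard_normal(x.shape)
        x = np.abs(x + dt * drift + noise)  # reflect at 0
        if step in sample_steps:
            sampled[sample_steps[step]] = x
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("integration diverged")
    if relax_time > 0.0:
        x = integrate(params, x, t_end=relax_time, dt=dt)
    return TrajectoryRecord(phase=phase, times=sample_times, states=sampled,
                            final_states=x, model_idx=model_idx)
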
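"""Scoring simulated ensembles against experimentally derived E/M states.

The role-annotated network TFs define two complementary binary reference
vectors: in the E reference, E TFs are high (1) and M TFs low (0), and vice
versa.  Each model's processed steady-state profile is binarized per gene by
1-D two-means clustering and matched to the references by Hamming distance
over the common TFs, with the distance cutoff chosen so the probability of a
random binary profile matching either reference stays below 0.05.  Accuracy
is the fraction of models classified as E or M.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import fisher_exact
from sklearn.decomposition import PCA

from .datasets import TIMEPOINTS, ActivityDataset
from .netbuild import SignedNetwork
from .racipe import (
    LOG_EPS,
    ModelEnsemble,
    PerturbationProtocol,
    simulate_perturbation,
)


class UnevaluableNetworkError(ValueError):
    """Raised when no Hamming cutoff keeps the random-match probability below alpha."""


@dataclass
class EMReference:
    """Complementary binary E- and M-state references over the common TFs."""

    common_tfs: list[str]
    e_vector: np.ndarray
    m_vector: np.ndarray

    def __post_init__(self) -> None:
        self.e_vector = np.asarray(self.e_vector, dtype=int)
        self.m_vector = np.asarray(self.m_vector, dtype=int)
        if len(self.common_tfs) < 1:
            raise ValueError("network unevaluable: no role-annotated TFs")
        if not np.array_equal(self.e_vector, 1 - self.m_vector):
            raise ValueError("E and M references must be complementary")

    @property
    def k(self) -> int:
        return len(self.common_tfs)


@dataclass
class AccuracyReport:
    """Counts of E/M/unclassified models and the resulting accuracy."""

    n_e: int
    n_m: int
    n_unclassified: int
    accuracy: float
    hamming_cutoff: int
    k_common: int

    @property
    def n_models(self) -> int:
        return self.n_e + self.n_m + self.n_unclassified


def build_reference(roles: dict[str, str], network: SignedNetwork) -> EMReference:
    """E/M reference vectors over the network's role-annotated nodes."""
    common = [n for n in network.nodes if roles.get(n) in ("E", "M")]
    if not common:
        raise ValueError("network unevaluable: zero E/M TFs")
    e_vec = np.array([1 if roles[n] == "E" else 0 for n in common])
    return EMReference(common_tfs=common, e_vector=e_vec, m_vector=1 - e_vec)


def _two_means_1d(values: np.ndarray) -> np.ndarray:
    """1-D k-means (k=2), deterministically initialized at the two extremes."""
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("constant gene column cannot be binarized")
    centers = np.array([lo, hi])
    assign = np.zeros(values.shape[0], dtype=int)
    for _ in range(200):
        new_assign = (np.abs(values - centers[1]) < np.abs(values - centers[0])).astype(int)
        for c in (0, 1):
            if np.any(new_assign == c):
                centers[c] = values[new_assign == c].mean()
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    # 1 = higher-mean cluster
    return assign if centers[1] >= centers[0] else 1 - assign


def binarize_ensemble(ensemble: ModelEnsemble | np.ndarray) -> np.ndarray:
    """Binarize processed states gene-by-gene with two-means clustering."""
    states = ensemble.processed_states if isinstance(ensemble, ModelEnsemble) else np.asarray(ensemble)
    out = np.empty(states.shape, dtype=int)
    for j in range(states.shape[1]):
        try:
            out[:, j] = _two_means_1d(states[:, j])
        except ValueError as err:
            raise ValueError(f"gene column {j} is constant") from err
    return out


def random_match_probability(k: int, cutoff: int) -> float:
    """Exact probability a uniform random k-bit profile matches either reference.

    The references are complementary, so matches within distance d of one are
    at distance k - d of the other; for d < k/2 the two events are disjoint.
    """
    within = sum(comb(k, i) for i in range(min(cutoff, k) + 1))
    if 2 * (cutoff + 1) > k:  # events overlap: count the union exactly
        far = sum(comb(k, i) for i in range(k - cutoff, k + 1))
        overlap = sum(comb(k, i) for i in range(k - cutoff, cutoff + 1)) if k - cutoff <= cutoff else 0
        return (within + far - overlap) / 2.0 ** k
    return 2.0 * within / 2.0 ** k


def hamming_cutoff(k_common: int, alpha: float = 0.05) -> int:
    """Largest distance cutoff keeping the random-match probability below alpha."""
    if k_common < 1:
        raise ValueError("k_common must be >= 1")
    best = None
    for d in range(k_common + 1):
        if random_match_probability(k_common, d) < alpha:
            best = d
        else:
            break
    if best is None:
        raise UnevaluableNetworkError(
            f"no cutoff keeps the random-match probability below {alpha} for k={k_common}")
    return best


def classify_models(binarized: np.ndarray, genes: list[str], reference: EMReference,
                    cutoff: int) -> tuple[np.ndarray, AccuracyReport]:
    """Label each model E/M/none by Hamming distance over the common TFs."""
    pos = {g: i for i, g in enumerate(genes)}
    try:
        cols = [pos[tf] for tf in reference.common_tfs]
    except KeyError as err:
        raise ValueError(f"reference TF missing from ensemble: {err}") from None
    profiles = binarized[:, cols]
    d_e = (profiles != reference.e_vector).sum(axis=1)
    d_m = (profiles != reference.m_vector).sum(axis=1)
    is_e = d_e <= cutoff
    is_m = d_m <= cutoff
    labels = np.full(binarized.shape[0], "none", dtype=object)
    labels[is_e & ~is_m] = "E"
    labels[is_m & ~is_e] = "M"  # double matches stay 'none'
    n_e = int((labels == "E").sum())
    n_m = int((labels == "M").sum())
    n_models = binarized.shape[0]
    report = AccuracyReport(
        n_e=n_e, n_m=n_m, n_unclassified=n_models - n_e - n_m,
        accuracy=(n_e + n_m) / n_models, hamming_cutoff=cutoff,
        k_common=reference.k,
    )
    return labels, report


def evaluate_network(ensemble: ModelEnsemble, roles: dict[str, str],
                     network: SignedNetwork, alpha: float = 0.05,
                     ) -> tuple[np.ndarray, AccuracyReport]:
    """Full evaluation of one simulated network against the E/M references."""
    reference = build_reference(roles, network)
    cutoff = hamming_cutoff(reference.k, alpha=alpha)
    binarized = binarize_ensemble(ensemble)
    return classify_models(binarized, ensemble.genes, reference, cutoff)


def binarize_with_ensemble(ensemble: ModelEnsemble, raw_states: np.ndarray,
                           binarized: np.ndarray | None = None) -> np.ndarray:
    """Binarize new raw states on the parent ensemble's scale.

    The states are log2-transformed and standardized with the ensemble's
    per-gene statistics, then thresholded at the midpoint between the two
    cluster means of the ensemble's own binarization — so perturbed states
    are classified consistently with the steady-state ensemble.
    """
    if binarized is None:
        binarized = binarize_ensemble(ensemble)
    logged = np.log2(ensemble.raw_states + LOG_EPS)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    processed = (np.log2(np.asarray(raw_states) + LOG_EPS) - mu) / sd
    ref = (np.log2(ensemble.raw_states + LOG_EPS) - mu) / sd
    thresholds = np.empty(ref.shape[1])
    for j in range(ref.shape[1]):
        hi = ref[binarized[:, j] == 1, j]
        lo = ref[binarized[:, j] == 0, j]
        if hi.size == 0 or lo.size == 0:
            thresholds[j] = ref[:, j].mean()
        else:
            thresholds[j] = (hi.mean() + lo.mean()) / 2.0
    return (processed > thresholds).astype(int)


@dataclass
class SignalNoiseResult:
    """Transition counts of the three induction arms and their comparisons."""

    n_e_models: int
    transitions_signal_noise: int
    transitions_signal_only: int
    transitions_noise_only: int
    p_vs_signal_only: float
    p_vs_noise_only: float


def signal_noise_experiment(ensemble: ModelEnsemble, roles: dict[str, str],
                            network: SignedNetwork, signal_genes: list[str],
                            seed: int, signal_factor: float = 5.0,
                            noise_level: float = 0.5, t_end: float = 100.0,
                            relax_time: float = 25.0, alpha: float = 0.05,
                            ) -> SignalNoiseResult:
    """Compare E->M transition counts under signal+noise, signal-only, noise-only.

    Starting from the E-state models, the signal genes' production is scaled
    by ``signal_factor`` with and without stochastic noise, and noise is also
    applied without any signal.  Final states are relaxed to their attractors
    and classified against the E/M references; arms are compared by
    two-sided Fisher exact tests.  Signal strength and noise level are
    calibration knobs: they are chosen sub-saturating so that noise-assisted
    transitions are resolvable, mirroring the published selection procedure.
    """
    reference = build_reference(roles, network)
    cutoff = hamming_cutoff(reference.k, alpha=alpha)
    binarized = binarize_ensemble(ensemble)
    labels, _ = classify_models(binarized, ensemble.genes, reference, cutoff)
    e_idx = np.where(labels == "E")[0]
    if e_idx.size == 0:
        raise ValueError("no E-state models to perturb")
    protocol = PerturbationProtocol(signal_genes=signal_genes,
                                    noise_level=noise_level,
                                    sample_times=(t_end,))
    silent = PerturbationProtocol(signal_genes=signal_genes, noise_level=0.0,
                                  sample_times=(t_end,))

    def transitions(proto: PerturbationProtocol, phase: str, factor: float | None) -> int:
        record = simulate_perturbation(ensemble, e_idx, proto, phase, seed=seed,
                                       signal_factor=factor, relax_time=relax_time)
        after = binarize_with_ensemble(ensemble, record.final_states, binarized)
        after_labels, _ = classify_models(after, ensemble.genes, reference, cutoff)
        return count_transitions(labels[e_idx], after_labels).e_to_m

    n = int(e_idx.size)
    k_sn = transitions(protocol, "induction", signal_factor)
    k_s = transitions(silent, "induction", signal_factor)
    k_n = transitions(protocol, "removal", None)  # factors restored: noise only
    return SignalNoiseResult(
        n_e_models=n,
        transitions_signal_noise=k_sn,
        transitions_signal_only=k_s,
        transitions_noise_only=k_n,
        p_vs_signal_only=compare_transition_rates(k_sn, n, k_s, n),
        p_vs_noise_only=compare_transition_rates(k_sn, n, k_n, n),
    )


# ---------------------------------------------------------------------------
# Projections, clustering, transitions


def pca_project(ensemble: ModelEnsemble, experimental: ActivityDataset,
                e_centroid_labels: np.ndarray | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project experimental activities onto the simulation's first two PCs.

    The PCA is fitted on the processed simulated states; experimental
    activities are standardized per TF with their own mean/SD and projected
    onto the first two loadings.  If per-model E/M labels are given, PC1 is
    oriented to point from the E-state centroid toward the M-state centroid.
    Returns per-cell coordinates and a per-timepoint mean/SD summary.
    """
    missing = [g for g in ensemble.genes if g not in experimental.activities.columns]
    if missing:
        raise ValueError(f"experimental data lacks genes: {missing}")
    pca = PCA(n_components=2)
    sim_coords = pca.fit_transform(ensemble.processed_states)
    if e_centroid_labels is not None:
        labels = np.asarray(e_centroid_labels)
        if np.any(labels == "E") and np.any(labels == "M"):
            axis = sim_coords[labels == "M", 0].mean() - sim_coords[labels == "E", 0].mean()
            if axis < 0:
                pca.components_[0] *= -1.0
    acts = experimental.activities[ensemble.genes]
    sd = acts.std(axis=0, ddof=0).replace(0.0, 1.0)
    standardized = (acts - acts.mean(axis=0)) / sd
    coords = standardized.to_numpy() @ pca.components_.T
    coord_df = pd.DataFrame(coords, index=acts.index, columns=["PC1", "PC2"])
    coord_df["timepoint"] = experimental.cell_meta["timepoint"]
    summaries = []
    for tp in TIMEPOINTS:
        sub = coord_df[coord_df["timepoint"] == tp]
        if len(sub):
            summaries.append((tp, sub["PC1"].mean(), sub["PC1"].std(ddof=0),
                              sub["PC2"].mean(), sub["PC2"].std(ddof=0)))
    summary = pd.DataFrame(
        summaries, columns=["timepoint", "pc1_mean", "pc1_sd", "pc2_mean", "pc2_sd"]
    ).set_index("timepoint")
    return coord_df, summary


def cluster_states(ensemble: ModelEnsemble | np.ndarray, k: int) -> np.ndarray:
    """Ward hierarchical clustering of processed model states, cut at k.

    Labels are 0..k-1 ordered by decreasing cluster size (ties by first
    occurrence), so the labeling is deterministic.
    """
    states = ensemble.processed_states if isinstance(ensemble, ModelEnsemble) else np.asarray(ensemble)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > states.shape[0]:
        raise ValueError("k exceeds the number of models")
    tree = linkage(states, method="ward")
    raw = fcluster(tree, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = {label: rank for rank, label in enumerate(sizes.index)}
    return np.array([order[label] for label in raw])


@dataclass
class TransitionCounts:
    """E->M and M->E label changes between two phases of one model set."""

    e_to_m: int
    m_to_e: int
    n_e_before: int
    n_m_before: int
    n_models: int


def count_transitions(labels_before: np.ndarray, labels_after: np.ndarray) -> TransitionCounts:
    before = np.asarray(labels_before)
    after = np.asarray(labels_after)
    if before.shape != after.shape:
        raise ValueError("label vectors must be aligned by model index")
    return TransitionCounts(
        e_to_m=int(((before == "E") & (after == "M")).sum()),
        m_to_e=int(((before == "M") & (after == "E")).sum()),
        n_e_before=int((before == "E").sum()),
        n_m_before=int((before == "M").sum()),
        n_models=before.shape[0],
    )


def compare_transition_rates(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p-value comparing two transition proportions."""
    if min(n1, n2) <= 0 or k1 > n1 or k2 > n2:
        raise ValueError("invalid transition table")
    return float(fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")[1])
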
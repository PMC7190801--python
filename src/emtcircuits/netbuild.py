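"""Context-specific signed network construction from regulons and activities.

Candidate edges come from regulon neighborhoods of the common DATFs: TF1 ->
TF2 whenever TF2 sits in TF1's forward or backward regulon.  Each candidate
is scored per transition direction with Miller-Madow-corrected mutual
information (equal-frequency binning, natural log) and signed by the
Spearman correlation of the two activity profiles.  A cutoff grid (positive
MI cutoffs 0.05..1.00, negative 0.05..0.50, step 0.05) generates up to 200
networks per condition; edges with opposite forward/backward signs are
removed, the surviving directions are unioned, and nodes with only outgoing
interactions are pruned exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import ActivityDataset, RegulonSet
from .racipe import Topology

# ---------------------------------------------------------------------------
# Mutual information


def equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` equal-frequency bins.

    Ties are broken by stable rank so the binning is reproducible
    bit-for-bit for any input order.
    """
    n = x.shape[0]
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * bins) // n


def _entropy_ml(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def mutual_information_mm(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """Miller-Madow-corrected mutual information (nats) of two activity vectors.

    Vectors are discretized into B = ceil(N^(1/3)) equal-frequency bins
    (overridable via ``bins``); the plug-in MI from the joint histogram is
    corrected per entropy term by (m - 1)/(2N) with m the number of occupied
    bins, i.e. MI_mm = MI_ML + (m_X + m_Y - m_XY - 1)/(2N), floored at 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 observations")
    b = bins if bins is not None else int(np.ceil(n ** (1.0 / 3.0)))
    bx = equal_frequency_bins(x, b)
    by = equal_frequency_bins(y, b)
    joint = np.zeros((b, b), dtype=int)
    np.add.at(joint, (bx, by), 1)
    cx = joint.sum(axis=1)
    cy = joint.sum(axis=0)
    mi_ml = _entropy_ml(cx, n) + _entropy_ml(cy, n) - _entropy_ml(joint.ravel(), n)
    m_x = int((cx > 0).sum())
    m_y = int((cy > 0).sum())
    m_xy = int((joint > 0).sum())
    return max(0.0, mi_ml + (m_x + m_y - m_xy - 1) / (2.0 * n))


# ---------------------------------------------------------------------------
# Candidate edges and scoring


@dataclass
class CandidateEdge:
    """A regulon-derived candidate interaction with per-direction scores.

    ``sign_*`` is +1/-1 from the Spearman correlation's sign, or 0 when the
    direction is absent (TF missing from the split or rho exactly zero)."""

    source: str
    target: str
    mi_forward: float = np.nan
    mi_backward: float = np.nan
    rho_forward: float = np.nan
    rho_backward: float = np.nan
    sign_forward: int = 0
    sign_backward: int = 0


def candidate_edges(regulons: RegulonSet, common_tfs: list[str],
                    tf_universe: list[str]) -> list[CandidateEdge]:
    """Candidate interactions among the common DATFs and their regulon neighbors.

    The node set is the common TFs plus every TF directly upstream or
    downstream of them in the (forward-or-backward) regulons; non-TF regulon
    targets — anything outside ``tf_universe`` — are ignored.  An edge
    TF1 -> TF2 is created for every TF2 in TF1's regulon, both endpoints
    restricted to the node set.
    """
    universe = set(tf_universe)
    common = [tf for tf in common_tfs if tf in universe]
    nodes = set(common)
    for tf in common:
        nodes |= regulons.targets(tf) & universe          # downstream neighbors
    for tf in regulons.tfs:                               # upstream neighbors
        if tf in universe and regulons.targets(tf) & set(common):
            nodes.add(tf)
    edges = []
    for tf1 in sorted(nodes):
        for tf2 in sorted(regulons.targets(tf1) & nodes):
            edges.append(CandidateEdge(source=tf1, target=tf2))
    return edges


def _score_split(edge: CandidateEdge, split: ActivityDataset) -> tuple[float, float, int]:
    cols = split.activities.columns
    if edge.source not in cols or edge.target not in cols:
        return np.nan, np.nan, 0
    x = split.activities[edge.source].to_numpy()
    y = split.activities[edge.target].to_numpy()
    mi = mutual_information_mm(x, y)
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho) or rho == 0.0:
        return mi, rho, 0
    return mi, float(rho), (1 if rho > 0 else -1)


def score_edges(candidates: list[CandidateEdge], forward: ActivityDataset,
                backward: ActivityDataset) -> list[CandidateEdge]:
    """Fill MI, Spearman rho and sign of each candidate in each split."""
    for edge in candidates:
        edge.mi_forward, edge.rho_forward, edge.sign_forward = _score_split(edge, forward)
        edge.mi_backward, edge.rho_backward, edge.sign_backward = _score_split(edge, backward)
    return candidates


# ---------------------------------------------------------------------------
# Network assembly


@dataclass
class SignedNetwork:
    """A directed signed network with its construction provenance."""

    nodes: list[str]
    edges: list[tuple[str, str, int]]
    pos_cutoff: float
    neg_cutoff: float
    condition: str = ""
    cutoff_pairs: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def key(self) -> tuple:
        return (tuple(sorted(self.nodes)), tuple(sorted(self.edges)))

    def to_topology(self) -> Topology:
        interactions = [(s, t, 1 if sign > 0 else 2) for s, t, sign in self.edges]
        genes: list[str] = []
        seen: set[str] = set()
        for s, t, _ in interactions:
            for g in (s, t):
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
        for g in self.nodes:  # keep pruned-orphan nodes that lost all edges
            if g not in seen:
                seen.add(g)
                genes.append(g)
        return Topology(genes=genes, interactions=interactions)


@dataclass
class CutoffGrid:
    """The MI cutoff sweep: 20 positive x 10 negative values, step 0.05."""

    pos_values: tuple[float, ...] = tuple(np.round(np.arange(1, 21) * 0.05, 2))
    neg_values: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.05, 2))

    def pairs(self) -> list[tuple[float, float]]:
        return [(p, n) for p in self.pos_values for n in self.neg_values]

    def clipped(self, scored: list[CandidateEdge]) -> "CutoffGrid":
        """Restrict the grid to the observed MI range (optional per-condition clip)."""
        mis = [m for e in scored for m in (e.mi_forward, e.mi_backward) if np.isfinite(m)]
        mi_max = max(mis) if mis else 0.0
        pos = tuple(v for v in self.pos_values if v <= mi_max) or self.pos_values[:1]
        neg = tuple(v for v in self.neg_values if v <= mi_max) or self.neg_values[:1]
        return CutoffGrid(pos_values=pos, neg_values=neg)


def build_network(scored: list[CandidateEdge], pos_cutoff: float, neg_cutoff: float,
                  condition: str = "") -> SignedNetwork:
    """Assemble one signed network at a single cutoff pair.

    Per direction, excitatory edges need MI >= pos_cutoff and inhibitory
    edges MI >= neg_cutoff; candidates whose forward and backward signs
    conflict are removed outright; surviving directions are unioned.  Nodes
    with only outgoing interactions are then pruned in a single pass — nodes
    orphaned by that pass are kept.
    """
    if pos_cutoff <= 0 or neg_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    kept: dict[tuple[str, str], int] = {}
    for e in scored:
        if e.sign_forward and e.sign_backward and e.sign_forward != e.sign_backward:
            continue  # opposite sign in the two directions
        for sign, mi in ((e.sign_forward, e.mi_forward), (e.sign_backward, e.mi_backward)):
            if sign == 0 or not np.isfinite(mi):
                continue
            cutoff = pos_cutoff if sign > 0 else neg_cutoff
            if mi >= cutoff:
                kept[(e.source, e.target)] = sign
    nodes = sorted({n for pair in kept for n in pair})
    indeg = {n: 0 for n in nodes}
    for (_, tgt) in kept:
        indeg[tgt] += 1
    pruned = {n for n in nodes if indeg[n] == 0}  # only outgoing; removed once
    edges = sorted((s, t, sign) for (s, t), sign in kept.items()
                   if s not in pruned and t not in pruned)
    remaining = [n for n in nodes if n not in pruned]
    return SignedNetwork(nodes=remaining, edges=edges, pos_cutoff=pos_cutoff,
                         neg_cutoff=neg_cutoff, condition=condition,
                         cutoff_pairs=[(pos_cutoff, neg_cutoff)])


def sweep_grid(scored: list[CandidateEdge], grid: CutoffGrid | None = None,
               condition: str = "", clip_to_observed: bool = False) -> list[SignedNetwork]:
    """One network per cutoff pair, deduplicated by topology.

    Each distinct topology retains the full list of cutoff pairs that
    generated it.
    """
    grid = grid or CutoffGrid()
    if clip_to_observed:
        grid = grid.clipped(scored)
    networks: dict[tuple, SignedNetwork] = {}
    for pos, neg in grid.pairs():
        net = build_network(scored, pos, neg, condition=condition)
        key = net.key()
        if key in networks:
            networks[key].cutoff_pairs.append((pos, neg))
        else:
            networks[key] = net
    return list(networks.values())


def screen_network(network: SignedNetwork, roles: dict[str, str],
                   min_em: int = 5) -> bool:
    """True iff the network contains at least ``min_em`` E or M TFs."""
    return sum(1 for n in network.nodes if roles.get(n) in ("E", "M")) >= min_em


# ---------------------------------------------------------------------------
# Recovery metrics against a known circuit


def edge_precision(network: SignedNetwork, true_edges: set[tuple[str, str]]) -> float:
    """Fraction of network edges present in the ground-truth edge set."""
    if not network.edges:
        return np.nan
    hits = sum(1 for s, t, _ in network.edges if (s, t) in true_edges)
    return hits / network.n_edges


def sign_accuracy(network: SignedNetwork,
                  true_signs: dict[tuple[str, str], int]) -> float:
    """Among true-positive edges, the fraction with the correct sign."""
    tp = [(s, t, sign) for s, t, sign in network.edges if (s, t) in true_signs]
    if not tp:
        return np.nan
    return sum(1 for s, t, sign in tp if true_signs[(s, t)] == sign) / len(tp)
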
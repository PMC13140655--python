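"""Directed TE networks: adjacency matrices, centrality and similarity.

A participant's network is the 7x7 matrix of surrogate-thresholded TE
values (entry [i, j] is the significant TE from node i to node j, in
bits; the diagonal is zero).  Group networks are the element-wise median
across participants, zeros included, so edges that are non-significant in
a majority of participants vanish.  Networks are compared with the
Jaccard similarity on edge sets (JSI) and its weighted form
(WJSI = sum of entry-wise minima / sum of entry-wise maxima).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import CHANNELS, ParticipantRecording
from .surrogate import SurrogateResult, surrogate_test
from .te import TEConfig

__all__ = [
    "TEMatrix", "DegreeProfile", "SimilarityResult", "participant_network",
    "group_median_network", "weighted_degrees", "rank_nodes", "jsi", "wjsi",
    "total_te", "COMPARISON_SCHEMA",
]


@dataclass
class TEMatrix:
    """Directed, non-negative, zero-diagonal edge-weight matrix (bits)."""

    weights: np.ndarray
    nodes: tuple[str, ...] = CHANNELS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.nodes)
        if self.weights.shape != (k, k):
            raise ValueError(f"weights must be {k}x{k}, got {self.weights.shape}")
        if np.any(self.weights < 0):
            raise ValueError("TE weights must be non-negative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal (self-edges) must be zero")

    def edge_set(self) -> set[tuple[str, str]]:
        """Directed edges with strictly positive weight."""
        i, j = np.nonzero(self.weights > 0)
        return {(self.nodes[a], self.nodes[b]) for a, b in zip(i, j)}


@dataclass
class DegreeProfile:
    """Weighted in/out-degree per node; both sum to the network's total TE."""

    nodes: tuple[str, ...]
    indegree: np.ndarray   # column sums: the network's influence on a node
    outdegree: np.ndarray  # row sums: a node's influence on the network
    total_te: float


@dataclass
class SimilarityResult:
    jsi: float
    wjsi: float
    pair: tuple[str, str] = ("a", "b")


#: Table-style comparison schema: rest vs. exercise within each condition,
#: then condition pairs within each phase (nine similarity columns).
COMPARISON_SCHEMA: tuple[tuple[str, tuple, tuple], ...] = (
    ("rest_ex_CTR", ("CTR", "rest"), ("CTR", "exercise")),
    ("rest_ex_HY1", ("HY1", "rest"), ("HY1", "exercise")),
    ("rest_ex_HY2", ("HY2", "rest"), ("HY2", "exercise")),
    ("CTR_HY1_rest", ("CTR", "rest"), ("HY1", "rest")),
    ("CTR_HY1_ex", ("CTR", "exercise"), ("HY1", "exercise")),
    ("CTR_HY2_rest", ("CTR", "rest"), ("HY2", "rest")),
    ("CTR_HY2_ex", ("CTR", "exercise"), ("HY2", "exercise")),
    ("HY1_HY2_rest", ("HY1", "rest"), ("HY2", "rest")),
    ("HY1_HY2_ex", ("HY1", "exercise"), ("HY2", "exercise")),
)


def participant_network(recording: ParticipantRecording,
                        config: TEConfig = TEConfig(), *,
                        n_shuffles: int = 100, percentile: float = 95.0,
                        seed=0) -> TEMatrix:
    """Surrogate-thresholded TE matrix over all 42 ordered channel pairs.

    Each directed pair gets its own deterministic random substream derived
    from ``seed`` and the pair's position, so single entries can be
    reproduced in isolation.
    """
    k = len(CHANNELS)
    weights = np.zeros((k, k))
    for i, src in enumerate(CHANNELS):
        for j, dst in enumerate(CHANNELS):
            if i == j:
                continue
            pair_seed = np.random.SeedSequence((_seed_entropy(seed), i, j))
            try:
                res: SurrogateResult = surrogate_test(
                    recording[src], recording[dst], config,
                    n_shuffles=n_shuffles, percentile=percentile,
                    seed=pair_seed)
            except ValueError as exc:
                raise ValueError(f"TE estimation failed for pair "
                                 f"{src}->{dst}: {exc}") from exc
            weights[i, j] = res.final_te
    meta = {"participant_id": recording.participant_id,
            "condition": recording.condition, "phase": recording.phase}
    return TEMatrix(weights=weights, metadata=meta)


def _seed_entropy(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0])
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(2 ** 63))
    return int(seed)


def group_median_network(matrices: list[TEMatrix]) -> TEMatrix:
    """Element-wise median across participants, zeroed entries included.

    An even participant count uses the midpoint of the two central values.
    All matrices must share node order, condition and phase.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    nodes = matrices[0].nodes
    conds = {(m.metadata.get("condition"), m.metadata.get("phase"))
             for m in matrices}
    if any(m.nodes != nodes for m in matrices):
        raise ValueError("node order differs between matrices")
    if len(conds) != 1:
        raise ValueError(f"mixed condition/phase groups: {sorted(conds)}")
    stack = np.stack([m.weights for m in matrices])
    med = np.median(stack, axis=0)
    cond, phase = next(iter(conds))
    return TEMatrix(weights=med, nodes=nodes,
                    metadata={"participant_id": "group",
                              "condition": cond, "phase": phase})


def weighted_degrees(matrix: TEMatrix) -> DegreeProfile:
    """Weighted indegree (column sums) and outdegree (row sums)."""
    indeg = matrix.weights.sum(axis=0)
    outdeg = matrix.weights.sum(axis=1)
    return DegreeProfile(nodes=matrix.nodes, indegree=indeg,
                         outdegree=outdeg, total_te=float(matrix.weights.sum()))


def rank_nodes(profile: DegreeProfile, by: str = "ID") -> list[str]:
    """Nodes in descending degree order; ties keep the fixed channel order."""
    if by not in ("ID", "OD"):
        raise ValueError("by must be 'ID' or 'OD'")
    values = profile.indegree if by == "ID" else profile.outdegree
    order = np.argsort(-values, kind="stable")
    return [profile.nodes[i] for i in order]


def _check_comparable(a: TEMatrix, b: TEMatrix) -> None:
    if a.nodes != b.nodes:
        raise ValueError("matrices have different node orders")


def jsi(a: TEMatrix, b: TEMatrix) -> float:
    """Jaccard similarity of the binarised edge sets (shared / total)."""
    _check_comparable(a, b)
    ea, eb = a.edge_set(), b.edge_set()
    union = ea | eb
    if not union:
        return 1.0  # two empty networks are identical by convention
    return len(ea & eb) / len(union)


def wjsi(a: TEMatrix, b: TEMatrix) -> float:
    """Weighted Jaccard: sum of entry-wise minima over sum of maxima."""
    _check_comparable(a, b)
    lo = np.minimum(a.weights, b.weights).sum()
    hi = np.maximum(a.weights, b.weights).sum()
    if hi == 0.0:
        return 1.0
    return float(lo / hi)


def compare(a: TEMatrix, b: TEMatrix) -> SimilarityResult:
    """Both similarity indices for a pair of networks."""
    label = lambda m: "{}-{}".format(m.metadata.get("condition", "?"),
                                     m.metadata.get("phase", "?"))
    return SimilarityResult(jsi=jsi(a, b), wjsi=wjsi(a, b),
                            pair=(label(a), label(b)))


def total_te(matrix: TEMatrix) -> float:
    """Sum of all significant edge weights (bits)."""
    return float(matrix.weights.sum())
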
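"""Extrinsic and intrinsic social-influence attributes.

Two attributes decide how strongly a neighbour's communicated belief is
discounted before combination:

* the *weight* ``w_ij`` — neighbour ``j``'s share of degree within ``i``'s
  neighbourhood, a static structural measure of importance;
* the *reliability* ``r_ij`` — an affinity measure built from cosine
  similarity of beliefs, updated recursively within a round's learning group
  and then mapped onto a "fair" scale so that agreeing neighbours are trusted
  at least half-way but never fully.

Both feed the combined discounting coefficient ``c_ij = w / (1 + w - r)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np

from .belief import BeliefFunction, _cosine

__all__ = [
    "InfluenceParams",
    "degree_weight",
    "map_reliability",
    "recursive_reliability",
    "combined_coefficient",
    "influence_records",
]


@dataclass(frozen=True)
class InfluenceParams:
    """Parameters of the reliability mapping.

    ``r_fair`` is the floor assigned once similarity reaches the threshold
    ``r_eta``; ``r_max`` caps trust in any neighbour short of certainty.
    """

    r_fair: float = 0.5
    r_eta: float = 0.2
    r_max: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.r_eta < 1:
            raise ValueError(f"r_eta must lie in (0, 1), got {self.r_eta}")
        if not self.r_fair <= self.r_max <= 1:
            raise ValueError(
                f"need r_fair <= r_max <= 1, got r_fair={self.r_fair}, r_max={self.r_max}"
            )


def degree_weight(graph: nx.Graph, i, j) -> float:
    """Importance of neighbour ``j`` to ``i``: j's degree share in Gamma(i).

    Weights over ``i``'s neighbourhood sum to one; they are generally
    asymmetric (``w_ij != w_ji``) because the two neighbourhoods differ.
    """
    neighbours = list(graph.neighbors(i))
    if not neighbours:
        raise ValueError(f"node {i!r} is isolated")
    if j not in set(neighbours):
        raise ValueError(f"node {j!r} is not a neighbour of {i!r}")
    total = sum(graph.degree(v) for v in neighbours)
    return graph.degree(j) / total


def map_reliability(r_prime: float, params: InfluenceParams = InfluenceParams()) -> float:
    """Map a raw similarity onto the fair reliability scale.

    Below the threshold ``r_eta`` the similarity passes through unchanged;
    at and above it, it is rescaled affinely from [r_eta, 1] to
    [r_fair, r_max].
    """
    if not 0 <= r_prime <= 1:
        raise ValueError(f"raw reliability {r_prime} outside [0, 1]")
    if r_prime < params.r_eta:
        return float(r_prime)
    return params.r_fair + (params.r_max - params.r_fair) * (
        r_prime - params.r_eta
    ) / (1 - params.r_eta)


def recursive_reliability(
    m_i: BeliefFunction,
    neighbours_so_far: Sequence[BeliefFunction],
    k: int,
) -> float:
    """Raw reliability of the k-th information source in a learning round.

    For the first source this is just the ego-source cosine similarity.  From
    the second source on, the ego's own view counts only half, and the mutual
    agreement among all sources met so far contributes the rest, so a
    conflicting neighbour gains credibility once further sources back the same
    opposing view.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(neighbours_so_far) != k:
        raise ValueError(
            f"expected {k} neighbour beliefs, got {len(neighbours_so_far)}"
        )
    masses = [m.mass for m in neighbours_so_far]
    for m in neighbours_so_far:
        if m.frame != m_i.frame:
            raise ValueError("all beliefs must share the ego's frame")
    return _recursive_reliability_raw(m_i.mass, masses, k)


def _recursive_reliability_raw(ego: np.ndarray, masses: list, k: int) -> float:
    s_ego = _cosine(ego, masses[k - 1])
    if k == 1:
        return s_ego
    pair_sum = sum(_cosine(masses[a], masses[b]) for a, b in combinations(range(k), 2))
    return s_ego / 2 + pair_sum / (k * (k - 1))


def combined_coefficient(w: float, r: float) -> float:
    """Discounting coefficient ``c = w / (1 + w - r)``.

    Equals 1 only under full self-trust (w = r = 1); zero weight silences a
    source completely.  Weakly increasing in both arguments on [0, 1]^2.
    """
    if w == 0.0:
        return 0.0
    return min(w / (1.0 + w - r), 1.0)


def influence_records(
    graph: nx.Graph,
    beliefs,
    learning_sets: dict[int, list[int]],
    params: InfluenceParams = InfluenceParams(),
) -> list[dict]:
    """Inspectable dump of one round's influence attributes.

    ``beliefs`` maps node -> BeliefFunction (snapshot); one record per
    (ego, source) pair with the source's position in the weight-sorted
    sequence, its weight, raw and mapped reliability, and the combined
    coefficient.  Write with e.g. ``pandas.DataFrame(records).to_csv(...,
    sep="\\t")``.
    """
    records = []
    for ego in sorted(learning_sets):
        speakers = sorted(
            learning_sets[ego], key=lambda j: (-graph.degree(j), j)
        )
        for k, j in enumerate(speakers, start=1):
            r_raw = recursive_reliability(
                beliefs[ego], [beliefs[s] for s in speakers[:k]], k
            )
            r = map_reliability(min(r_raw, 1.0), params)
            w = degree_weight(graph, ego, j)
            records.append(
                {
                    "i": ego,
                    "j": j,
                    "k": k,
                    "w": w,
                    "r_raw": r_raw,
                    "r_mapped": r,
                    "c": combined_coefficient(w, r),
                }
            )
    return records
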
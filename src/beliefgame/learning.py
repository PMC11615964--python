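"""The three belief-update behaviours: social learning, self-learning, forgetting.

Social learning combines the ego's belief with its neighbours' beliefs using a
weighted evidential-reasoning (WER) rule: each source's masses are first
scaled by its discounting coefficient ``c`` (the remainder going to a separate
"unassigned" slot), the discounted functions are folded pairwise — cross terms
with the unassigned slot keep a source's own masses alive, intersection
products implement agreement, and conflicting products (empty intersection)
are dropped by renormalization — and finally the residual unassigned slot is
redistributed.  The fold is deliberately order-sensitive: sources are combined
in decreasing order of importance.

Self-learning moves an alpha-fraction of one randomly chosen verb's irregular
mass onto its regular form, modelling learners biased toward the regular rule.
Forgetting moves a beta-fraction of the strongest specific (non-Theta) mass to
total ignorance for agents that were left out of this round's learning.

Low-level kernels operate on raw mass vectors plus an unassigned scalar so the
simulator can keep all agent beliefs in one array; the public functions wrap
them in :class:`~beliefgame.belief.BeliefFunction` terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .belief import MASS_TOL, BeliefFunction, Frame

__all__ = [
    "DiscountedBelief",
    "TotalConflictError",
    "discount",
    "wer_combine_step",
    "social_learn",
    "self_learn",
    "forget",
]


class TotalConflictError(ValueError):
    """All joint mass fell on the empty set: the sources fully contradict."""


@dataclass
class DiscountedBelief:
    """A discounted mass vector plus the unassigned (uncommitted) slot.

    ``unassigned`` is bookkeeping for the support a source withholds, distinct
    from mass on the full frame (which is genuine ignorance); masses plus the
    slot sum to one.
    """

    frame: Frame
    mass: np.ndarray
    unassigned: float

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass[0] != 0.0:
            raise ValueError("mass on the empty set must be 0")
        total = float(self.mass.sum()) + self.unassigned
        if abs(total - 1.0) > MASS_TOL or self.unassigned < -MASS_TOL:
            raise ValueError(f"masses + unassigned must equal 1, got {total}")


@lru_cache(maxsize=8)
def _intersection_table(n_subsets: int) -> np.ndarray:
    """(S, S) table of pairwise subset intersections, by bitmask."""
    idx = np.arange(n_subsets)
    return idx[:, None] & idx[None, :]


# --- raw kernels (mass vector + unassigned scalar) --------------------------


def _wer_step_raw(
    m_a: np.ndarray, u_a: float, m_b: np.ndarray, u_b: float
) -> tuple[np.ndarray, float]:
    n = m_a.shape[0]
    inter = _intersection_table(n)
    outer = np.outer(m_a, m_b)
    tilde = np.bincount(inter.ravel(), weights=outer.ravel(), minlength=n)
    tilde += u_b * m_a + u_a * m_b
    tilde[0] = 0.0  # conflict products are discarded, not stored
    u_t = u_a * u_b
    z = tilde.sum() + u_t
    if z <= MASS_TOL:
        raise TotalConflictError(
            "combined sources assign all mass to the empty set"
        )
    return tilde / z, u_t / z


def _social_learn_raw(
    ego: np.ndarray, sources: Sequence[tuple[np.ndarray, float]]
) -> np.ndarray:
    """Fold ego (c=1) with discounted sources, then redistribute the slot."""
    acc = ego.astype(float, copy=True)
    u = 0.0
    for mass, c in sources:
        acc, u = _wer_step_raw(acc, u, c * mass, 1.0 - c)
    if u > 0.0:
        acc = acc / (1.0 - u)
    return acc


def _self_learn_raw(
    mass: np.ndarray, n_verbs: int, verb: int, alpha: float
) -> None:
    """In-place regular-form reinforcement for one verb; exempt if committed
    to that verb's irregular form."""
    reg = 1 << verb
    irr = 1 << (n_verbs + verb)
    m_irr = mass[irr]
    if m_irr >= 1.0 - MASS_TOL:
        return
    mass[reg] += alpha * m_irr
    mass[irr] = (1.0 - alpha) * m_irr


def _forget_raw(mass: np.ndarray, beta: float) -> None:
    """In-place transfer of a beta-fraction of the strongest non-Theta mass
    to Theta; ties break toward the lowest bitmask."""
    theta = mass.shape[0] - 1
    bf = int(np.argmax(mass[:theta]))
    if mass[bf] <= 0.0:
        return  # everything already on Theta
    moved = beta * mass[bf]
    mass[bf] -= moved
    mass[theta] += moved


# --- public operations -------------------------------------------------------


def discount(m: BeliefFunction, c: float) -> DiscountedBelief:
    """Scale every subset mass by ``c``; the remainder ``1 - c`` is left
    unassigned."""
    if not 0 <= c <= 1:
        raise ValueError(f"discount coefficient {c} outside [0, 1]")
    return DiscountedBelief(m.frame, c * m.mass, 1.0 - c)


def wer_combine_step(acc: DiscountedBelief, nxt: DiscountedBelief) -> DiscountedBelief:
    """One pairwise WER combination of two discounted belief functions.

    Raises :class:`TotalConflictError` when both operands are undiscounted and
    fully conflicting, which leaves nothing to renormalize.
    """
    if acc.frame != nxt.frame:
        raise ValueError("operands live on different frames")
    mass, u = _wer_step_raw(acc.mass, acc.unassigned, nxt.mass, nxt.unassigned)
    return DiscountedBelief(acc.frame, mass, u)


def social_learn(
    ego: BeliefFunction,
    sources: Sequence[tuple[BeliefFunction, float, float]],
) -> BeliefFunction:
    """Combine the ego's belief with ``(belief, w, r)`` sources, in order.

    The caller supplies sources sorted by decreasing weight; the ego enters
    the fold first with full self-trust (w = r = 1, hence c = 1).  After the
    fold, residual unassigned support is redistributed proportionally so the
    result is a proper belief function.
    """
    from .influence import combined_coefficient

    raw = []
    for m, w, r in sources:
        if m.frame != ego.frame:
            raise ValueError("source belief on a different frame")
        raw.append((m.mass, combined_coefficient(w, r)))
    return BeliefFunction(ego.frame, _social_learn_raw(ego.mass, raw))


def self_learn(
    m: BeliefFunction, verb: int, alpha: float
) -> BeliefFunction:
    """Reinforce the regular form of one verb at rate ``alpha``.

    An agent already committed to that verb's irregular form is exempt and
    returns unchanged.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha {alpha} outside [0, 1]")
    m.frame._check_verb(verb)
    mass = m.mass.copy()
    _self_learn_raw(mass, m.frame.n_verbs, verb, alpha)
    return BeliefFunction(m.frame, mass)


def forget(m: BeliefFunction, beta: float) -> BeliefFunction:
    """Move a ``beta``-fraction of the strongest non-Theta focal mass to Theta.

    Eligibility (not committed, under-engaged this round, Bernoulli success)
    is the simulator's responsibility; an all-ignorant belief is a no-op.
    """
    if not 0 <= beta <= 1:
        raise ValueError(f"beta {beta} outside [0, 1]")
    mass = m.mass.copy()
    _forget_raw(mass, beta)
    return BeliefFunction(m.frame, mass)
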
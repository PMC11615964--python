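"""Convergence, consensus and regularization observables.

An agent "adheres" to the singleton verb form carrying its largest singleton
mass (ties resolved toward the lowest bitmask, i.e. the earliest regular
form); adherence is weaker than commitment, which requires unit mass.  The
population's dominant proposition ``b1`` is the singleton most agents adhere
to.

* ``L1`` — fraction of agents *committed* (unit mass) to ``b1``; 1 means full
  linguistic consensus.
* ``R`` — belief index: mean over agents of mass on ``b1`` minus summed mass
  on every other singleton; 1 at consensus, 0 when the population splits in
  half, negative under fragmentation.
* ``r`` — local belief index: ``R`` computed inside each community against
  that community's own dominant singleton, averaged over communities.
* ``rho_R`` — regularization: summed per-verb fractions of agents adhering to
  that verb's regular form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .belief import MASS_TOL, BeliefFunction, Frame

__all__ = [
    "SweepRecord",
    "adhered_singletons",
    "dominant_element",
    "compute_L1",
    "compute_R",
    "compute_local_r",
    "compute_rho_R",
]


@dataclass(frozen=True)
class SweepRecord:
    """One time point of the observables."""

    t: int
    L1: float
    R: float
    r_local: float  # NaN when no community labels are available
    rho_R: float


def _as_array(states) -> tuple[Frame, np.ndarray]:
    """Accept a Population-like object or a sequence of BeliefFunction."""
    if hasattr(states, "beliefs") and hasattr(states, "frame"):
        return states.frame, states.beliefs
    states = list(states)
    if states and isinstance(states[0], BeliefFunction):
        return states[0].frame, np.stack([m.mass for m in states])
    raise TypeError("states must expose .frame/.beliefs or be BeliefFunctions")


def adhered_singletons(states) -> np.ndarray:
    """Bitmask of each agent's maximum-mass singleton (ties: lowest bitmask)."""
    frame, beliefs = _as_array(states)
    sing = frame.singletons
    return sing[np.argmax(beliefs[:, sing], axis=1)]


def dominant_element(states) -> int:
    """The singleton adhered to by the most agents (ties: lowest bitmask)."""
    frame, _ = _as_array(states)
    adhered = adhered_singletons(states)
    counts = np.bincount(adhered, minlength=frame.n_subsets)
    sing = frame.singletons
    return int(sing[np.argmax(counts[sing])])


def compute_L1(states, b1: int) -> float:
    """Fraction of agents with unit mass exactly on ``b1``."""
    _, beliefs = _as_array(states)
    return float(np.mean(beliefs[:, b1] >= 1.0 - MASS_TOL))


def compute_R(states, b1: int) -> float:
    """Belief index: mean of m(b1) minus the summed mass on other singletons.

    Mass on composite subsets counts toward neither side, so a fully ignorant
    population scores 0 while a fragmented one scores below 0.
    """
    frame, beliefs = _as_array(states)
    sing_total = beliefs[:, frame.singletons].sum(axis=1)
    on_b1 = beliefs[:, b1]
    return float(np.mean(on_b1 - (sing_total - on_b1)))


def compute_local_r(states, communities: dict[int, int]) -> float:
    """Community-local belief index against each community's own dominant
    singleton, averaged over communities with equal community weight."""
    if communities is None:
        raise ValueError("community labels are required for the local index")
    frame, beliefs = _as_array(states)
    sing = frame.singletons
    sing_total = beliefs[:, sing].sum(axis=1)
    labels = np.array([communities[i] for i in range(beliefs.shape[0])])
    total = 0.0
    comm_ids = np.unique(labels)
    for cid in comm_ids:
        members = np.flatnonzero(labels == cid)
        sub = beliefs[members][:, sing]
        adhered = np.argmax(sub, axis=1)
        b1k_col = int(np.argmax(np.bincount(adhered, minlength=len(sing))))
        on_b1 = beliefs[members, sing[b1k_col]]
        total += float(np.mean(on_b1 - (sing_total[members] - on_b1)))
    return total / len(comm_ids)


def compute_rho_R(states) -> float:
    """Summed per-verb fractions of agents adhering to the regular form."""
    frame, beliefs = _as_array(states)
    adhered = adhered_singletons(states)
    return float(
        sum(np.mean(adhered == frame.regular(v)) for v in range(frame.n_verbs))
    )
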
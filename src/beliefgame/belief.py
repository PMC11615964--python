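"""Frames of discernment and Dempster-Shafer belief functions over verb forms.

A frame collects the ``2n`` elementary outcomes for ``n`` verbs: the regular
past-tense form ``Ri`` and the irregular form ``Ii`` of each verb.  A belief
function (mass function) assigns non-negative mass to non-empty subsets of the
frame, summing to one; mass on a composite subset such as ``{R1, I1}``
expresses support for either form of the verb without committing to one, which
is how the model avoids a discrete "mixed" agent state.

Subsets are encoded as integer bitmasks over the element order
``R1..Rn, I1..In`` (bit ``i`` is ``Ri``, bit ``n+i`` is ``Ii``).  Mass vectors
are dense numpy arrays indexed by bitmask, so the empty set is index 0 and the
whole frame is the last index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "BeliefFunction",
    "make_frame",
    "cosine_similarity",
    "init_belief_dirichlet",
    "is_stable",
    "MASS_TOL",
]

#: tolerance for mass-conservation and commitment checks
MASS_TOL = 1e-9


@dataclass(frozen=True)
class Frame:
    """The set of all verb forms an agent may adopt, with a subset codec.

    Parameters
    ----------
    n_verbs:
        Number of verbs; the frame has ``2 * n_verbs`` elements and
        ``2 ** (2 * n_verbs)`` subsets including the empty set.
    """

    n_verbs: int
    elements: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not isinstance(self.n_verbs, (int, np.integer)) or self.n_verbs < 1:
            raise ValueError(f"n_verbs must be a positive integer, got {self.n_verbs!r}")
        labels = tuple(f"R{i + 1}" for i in range(self.n_verbs)) + tuple(
            f"I{i + 1}" for i in range(self.n_verbs)
        )
        object.__setattr__(self, "elements", labels)

    @property
    def n_elements(self) -> int:
        return 2 * self.n_verbs

    @property
    def n_subsets(self) -> int:
        """Size of the power set, empty set included."""
        return 1 << self.n_elements

    @property
    def theta(self) -> int:
        """Bitmask of the full frame."""
        return self.n_subsets - 1

    # --- singleton helpers -------------------------------------------------

    def regular(self, verb: int) -> int:
        """Bitmask of the singleton {R_verb} (verbs are 0-based)."""
        self._check_verb(verb)
        return 1 << verb

    def irregular(self, verb: int) -> int:
        """Bitmask of the singleton {I_verb} (verbs are 0-based)."""
        self._check_verb(verb)
        return 1 << (self.n_verbs + verb)

    @property
    def singletons(self) -> np.ndarray:
        """Bitmasks of all singletons in ascending order (R1..Rn, I1..In)."""
        return 1 << np.arange(self.n_elements)

    def _check_verb(self, verb: int) -> None:
        if not 0 <= verb < self.n_verbs:
            raise ValueError(f"verb index {verb} out of range for {self.n_verbs} verbs")

    # --- subset <-> label codec -------------------------------------------

    def subset_from_labels(self, labels) -> int:
        """Bitmask of the subset containing the given element labels."""
        mask = 0
        for lab in labels:
            try:
                mask |= 1 << self.elements.index(lab)
            except ValueError:
                raise ValueError(f"unknown element label {lab!r}") from None
        return mask

    def labels_of(self, mask: int) -> tuple[str, ...]:
        """Element labels of a subset bitmask, in frame order."""
        if not 0 <= mask < self.n_subsets:
            raise ValueError(f"bitmask {mask} out of range")
        return tuple(e for i, e in enumerate(self.elements) if mask >> i & 1)

    def subset_label(self, mask: int) -> str:
        """Serialized label of a subset, element names joined by '+'."""
        return "+".join(self.labels_of(mask))


def make_frame(n_verbs: int) -> Frame:
    """Build the frame of discernment for ``n_verbs`` verbs."""
    return Frame(n_verbs)


@dataclass
class BeliefFunction:
    """A mass assignment over the non-empty subsets of a frame.

    ``mass`` is indexed by subset bitmask; ``mass[0]`` (the empty set) is
    always zero and the total mass is one within :data:`MASS_TOL`.
    """

    frame: Frame
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.mass.shape != (self.frame.n_subsets,):
            raise ValueError(
                f"mass vector has shape {self.mass.shape}, "
                f"expected ({self.frame.n_subsets},)"
            )
        if self.mass[0] != 0.0:
            raise ValueError("mass on the empty set must be exactly 0")
        if np.any(self.mass < -MASS_TOL):
            raise ValueError("negative mass")
        total = float(self.mass.sum())
        if abs(total - 1.0) > MASS_TOL:
            raise ValueError(f"total mass {total} differs from 1 beyond tolerance")

    # --- constructors ------------------------------------------------------

    @classmethod
    def committed(cls, frame: Frame, subset: int) -> "BeliefFunction":
        """Unit mass on a single subset."""
        mass = np.zeros(frame.n_subsets)
        mass[subset] = 1.0
        return cls(frame, mass)

    @classmethod
    def vacuous(cls, frame: Frame) -> "BeliefFunction":
        """Total ignorance: unit mass on the whole frame."""
        return cls.committed(frame, frame.theta)

    @classmethod
    def from_dict(cls, frame: Frame, masses: dict) -> "BeliefFunction":
        """Build from a {subset label or bitmask -> mass} mapping."""
        mass = np.zeros(frame.n_subsets)
        for key, value in masses.items():
            if isinstance(key, str):
                key = frame.subset_from_labels(key.split("+"))
            mass[key] += value
        return cls(frame, mass)

    # --- views -------------------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        """Serialize as {subset label -> mass} over focal elements only."""
        return {
            self.frame.subset_label(int(b)): float(self.mass[b])
            for b in np.flatnonzero(self.mass)
        }

    def focal_elements(self) -> list[int]:
        """Bitmasks of subsets carrying strictly positive mass."""
        return [int(b) for b in np.flatnonzero(self.mass > 0)]

    def __getitem__(self, subset) -> float:
        if isinstance(subset, str):
            subset = self.frame.subset_from_labels(subset.split("+"))
        return float(self.mass[subset])


def cosine_similarity(m1: BeliefFunction, m2: BeliefFunction) -> float:
    """Normalized dot product between two belief functions on one frame.

    Lies in [0, 1] because masses are non-negative; equals 1 iff the mass
    vectors are proportional (hence, for unit-total masses, equal).
    """
    if m1.frame != m2.frame:
        raise ValueError("belief functions live on different frames")
    return _cosine(m1.mass, m2.mass)


def _cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    return float(np.dot(v1, v2) / denom)


def init_belief_dirichlet(
    frame: Frame, phi: float, rng: np.random.Generator
) -> BeliefFunction:
    """Draw an initial belief with masses on the singletons only.

    Singleton masses follow a Dirichlet with concentration 1 for every regular
    form and ``phi`` for every irregular form, so ``phi < 1`` makes agents
    initially lean regular and ``phi = 1`` is the symmetric, no-preference
    start.  Composite subsets start with zero mass; ignorance appears later
    through discounting and forgetting.
    """
    if not phi > 0:
        raise ValueError(f"phi must be positive, got {phi}")
    alpha = np.concatenate(
        [np.ones(frame.n_verbs), np.full(frame.n_verbs, float(phi))]
    )
    draw = rng.dirichlet(alpha)
    mass = np.zeros(frame.n_subsets)
    mass[frame.singletons] = draw
    return BeliefFunction(frame, mass)


def is_stable(m: BeliefFunction) -> bool:
    """Whether the agent is committed: some subset carries unit mass.

    The criterion is ``max_theta m(theta) = 1`` (within :data:`MASS_TOL`),
    taken literally: unit mass on the full frame also counts as stable.
    """
    return bool(m.mass.max() >= 1.0 - MASS_TOL)
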
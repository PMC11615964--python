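"""Round-based driver of the naming-game dynamics.

Each round: (1) every edge activates independently with probability ``f``;
(2) an activated edge hosts social learning with probability ``p_s`` or a
self-learning event otherwise; (3) on a social edge the two individuals
exchange information and *both* update: each endpoint adds the other to its
learning set and performs its own fold as ego (the two directions of the same
interaction generally disagree, since the combination is order-sensitive);
(4) every ego folds its sources — sorted by descending weight — through the
WER rule, with reliabilities computed recursively over the sorted prefix,
using *round-start* snapshots of all beliefs (asynchronous updating: the
order in which egos are processed cannot matter); (5) both endpoints of every
self-learning edge reinforce a random verb's regular form, after any social
learning they did; (6) agents that are not committed and learned fewer than
``eta`` times this round forget with probability ``p_f``.

A run terminates when every agent is committed (unit mass somewhere), when no
belief in the population has changed for ``stall_window`` consecutive rounds
(a genuine fixed point), or at ``t_max`` (with a warning); observables are
recorded every round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
import pandas as pd

from . import metrics
from .belief import MASS_TOL, BeliefFunction, Frame, make_frame
from .influence import InfluenceParams
from ._kernels import social_round
from .learning import _forget_raw, _self_learn_raw
from .networks import LabelledGraph

__all__ = [
    "SimulationConfig",
    "AgentState",
    "Population",
    "RunResult",
    "ReplicateResult",
    "step",
    "run",
    "replicate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of one simulation.

    Defaults are the model's reference conditions: two verbs, no initial
    preference (``phi = 1``), 10% edge activation, social learning only
    (``p_s = 1``, ``alpha = 0``) but forgetting on (``eta = 2``,
    ``p_f = 5%``, ``beta = 4%``).
    """

    f: float = 0.10
    p_s: float = 1.0
    alpha: float = 0.0
    p_f: float = 0.05
    beta: float = 0.04
    eta: int = 2
    phi: float = 1.0
    n_verbs: int = 2
    influence: InfluenceParams = field(default_factory=InfluenceParams)
    t_max: int = 5000
    stall_window: int = 200
    n_reps: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("f", "p_s", "alpha", "p_f", "beta"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.eta < 1 or self.t_max < 1 or self.n_reps < 1:
            raise ValueError("eta, t_max and n_reps must be positive")
        if self.phi <= 0:
            raise ValueError(f"phi must be positive, got {self.phi}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "influence" in d and isinstance(d["influence"], dict):
            d["influence"] = InfluenceParams(**d["influence"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class AgentState:
    """One agent's view: belief, learning count this round, stability flag."""

    belief: BeliefFunction
    learn_count: int
    stable: bool


class Population:
    """All agents' beliefs as one ``(N, n_subsets)`` mass array."""

    def __init__(self, frame: Frame, beliefs: np.ndarray):
        self.frame = frame
        self.beliefs = np.asarray(beliefs, dtype=float)
        self.learn_count = np.zeros(len(self.beliefs), dtype=int)

    @classmethod
    def initialize(
        cls, frame: Frame, n_agents: int, phi: float, rng: np.random.Generator
    ) -> "Population":
        """Dirichlet singleton start: concentration 1 for regular forms,
        ``phi`` for irregular forms."""
        alpha = np.concatenate(
            [np.ones(frame.n_verbs), np.full(frame.n_verbs, float(phi))]
        )
        beliefs = np.zeros((n_agents, frame.n_subsets))
        beliefs[:, frame.singletons] = rng.dirichlet(alpha, size=n_agents)
        return cls(frame, beliefs)

    @classmethod
    def from_beliefs(cls, beliefs: list[BeliefFunction]) -> "Population":
        return cls(beliefs[0].frame, np.stack([m.mass for m in beliefs]))

    def __len__(self) -> int:
        return len(self.beliefs)

    @property
    def stable(self) -> np.ndarray:
        return self.beliefs.max(axis=1) >= 1.0 - MASS_TOL

    def state(self, i: int) -> AgentState:
        return AgentState(
            belief=BeliefFunction(self.frame, self.beliefs[i].copy()),
            learn_count=int(self.learn_count[i]),
            stable=bool(self.stable[i]),
        )


class _Context:
    """Static per-graph precomputation: edge array and degree weights."""

    def __init__(self, graph, config: SimulationConfig):
        g = graph.graph if isinstance(graph, LabelledGraph) else graph
        self.nodes = sorted(g.nodes)
        if self.nodes != list(range(len(self.nodes))):
            raise ValueError("simulation graphs must use node ids 0..N-1")
        self.n = len(self.nodes)
        self.edges = np.array(sorted(tuple(sorted(e)) for e in g.edges), dtype=int)
        self.deg = np.array([g.degree(i) for i in range(self.n)], dtype=float)
        # sum of neighbour degrees: the weight denominator per ego
        self.denom = np.array(
            [sum(g.degree(j) for j in g.neighbors(i)) for i in range(self.n)],
            dtype=float,
        )

    def weight(self, i: int, j: int) -> float:
        return self.deg[j] / self.denom[i]


def _social_phase(
    ctx: _Context,
    snapshot: np.ndarray,
    learning_sets: dict[int, list[int]],
    params: InfluenceParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Fold every ego's learning set on the round-start snapshot."""
    egos = np.array(sorted(learning_sets), dtype=np.int64)
    offsets = np.zeros(len(egos) + 1, dtype=np.int64)
    flat: list[int] = []
    for i, ego in enumerate(egos):
        flat.extend(learning_sets[int(ego)])
        offsets[i + 1] = len(flat)
    updated = social_round(
        snapshot,
        egos,
        offsets,
        np.array(flat, dtype=np.int64),
        ctx.deg,
        ctx.denom,
        params.r_fair,
        params.r_eta,
        params.r_max,
    )
    return egos, updated


def step(
    graph,
    pop: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    ctx: _Context | None = None,
) -> dict:
    """Advance the population by one round in place; returns an event log."""
    if ctx is None:
        ctx = _Context(graph, config)
    n_edges = len(ctx.edges)
    pop.learn_count[:] = 0
    if n_edges == 0:
        return {"n_social": 0, "n_self": 0, "n_forget": 0}

    u_act = rng.random(n_edges)
    u_kind = rng.random(n_edges)

    learning_sets: dict[int, list[int]] = {}
    self_agents: list[int] = []
    for e in np.flatnonzero(u_act < config.f):
        a, b = int(ctx.edges[e, 0]), int(ctx.edges[e, 1])
        if u_kind[e] < config.p_s:
            learning_sets.setdefault(a, []).append(b)
            learning_sets.setdefault(b, []).append(a)
        else:
            self_agents.extend((a, b))

    # social learning on round-start snapshots (asynchronous updating)
    if learning_sets:
        snapshot = pop.beliefs.copy()
        egos, updated = _social_phase(ctx, snapshot, learning_sets, config.influence)
        pop.beliefs[egos] = updated
        pop.learn_count[egos] += 1

    # self-learning, after social learning, on current beliefs
    for agent in self_agents:
        verb = int(rng.integers(config.n_verbs))
        _self_learn_raw(pop.beliefs[agent], config.n_verbs, verb, config.alpha)
        pop.learn_count[agent] += 1

    # forgetting for uncommitted, under-engaged agents
    n_forget = 0
    if config.p_f > 0:
        u_forget = rng.random(ctx.n)
        eligible = (
            (~pop.stable)
            & (pop.learn_count < config.eta)
            & (u_forget < config.p_f)
        )
        for i in np.flatnonzero(eligible):
            _forget_raw(pop.beliefs[i], config.beta)
            n_forget += 1

    return {
        "n_social": len(learning_sets),
        "n_self": len(self_agents),
        "n_forget": n_forget,
    }


@dataclass
class RunResult:
    """Trajectory and final state of one simulation."""

    history: pd.DataFrame  # columns t, L1, R, r_local, rho_R
    population: Population
    graph: LabelledGraph
    termination: str  # "all_stable" | "fixed_point" | "t_max"
    t_final: int

    @property
    def final(self) -> pd.Series:
        return self.history.iloc[-1]


def _observe(pop: Population, t: int, communities) -> metrics.SweepRecord:
    b1 = metrics.dominant_element(pop)
    r_local = (
        metrics.compute_local_r(pop, communities)
        if communities is not None
        else float("nan")
    )
    return metrics.SweepRecord(
        t=t,
        L1=metrics.compute_L1(pop, b1),
        R=metrics.compute_R(pop, b1),
        r_local=r_local,
        rho_R=metrics.compute_rho_R(pop),
    )


def run(
    graph,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> RunResult:
    """Simulate one population on ``graph`` until stabilization.

    The trajectory is fully determined by (graph, config, seed/rng).
    Termination: every agent committed, or no belief changed for
    ``stall_window`` consecutive rounds, or ``t_max`` (warned).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not isinstance(graph, LabelledGraph):
        graph = LabelledGraph(graph)
    communities = graph.community
    ctx = _Context(graph, config)
    frame = make_frame(config.n_verbs)
    pop = Population.initialize(frame, ctx.n, config.phi, rng)

    records = [_observe(pop, 0, communities)]
    stall = 0
    termination = "t_max"
    t = 0
    prev = pop.beliefs.copy()
    for t in range(1, config.t_max + 1):
        step(graph, pop, config, rng, ctx=ctx)
        records.append(_observe(pop, t, communities))
        if np.array_equal(pop.beliefs, prev):
            stall += 1
        else:
            stall = 0
            prev = pop.beliefs.copy()
        if pop.stable.all():
            termination = "all_stable"
            break
        if stall >= config.stall_window:
            termination = "fixed_point"
            break
    if termination == "t_max":
        logger.warning("run hit t_max=%d before stabilizing", config.t_max)

    history = pd.DataFrame([vars(r) for r in records])
    return RunResult(history, pop, graph, termination, t)


@dataclass
class ReplicateResult:
    """Final observables of independent replicates, one row per run."""

    runs: pd.DataFrame  # rep, t_final, termination, L1, R, r_local, rho_R
    config: SimulationConfig

    def mean(self) -> pd.Series:
        return self.runs[["L1", "R", "r_local", "rho_R"]].mean()

    def sd(self) -> pd.Series:
        return self.runs[["L1", "R", "r_local", "rho_R"]].std()


GraphSpec = Union[LabelledGraph, Callable[[np.random.Generator], LabelledGraph]]


def replicate(
    graph_spec: GraphSpec,
    config: SimulationConfig,
    n_reps: int | None = None,
) -> ReplicateResult:
    """Average the observables over independent runs.

    ``graph_spec`` is either a fixed graph or a callable drawing a fresh
    realization per replicate; per-replicate RNGs are spawned from
    ``config.seed`` so replicates are independent and reproducible.
    """
    n_reps = config.n_reps if n_reps is None else n_reps
    children = np.random.SeedSequence(config.seed).spawn(n_reps)
    rows = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        graph = graph_spec(rng) if callable(graph_spec) else graph_spec
        result = run(graph, config, rng=rng)
        final = result.final
        rows.append(
            {
                "rep": rep,
                "t_final": result.t_final,
                "termination": result.termination,
                "L1": final.L1,
                "R": final.R,
                "r_local": final.r_local,
                "rho_R": final.rho_R,
            }
        )
    return ReplicateResult(pd.DataFrame(rows), config)
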
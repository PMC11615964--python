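"""Generators and loaders for the network families the simulations run on.

All generators return a :class:`LabelledGraph`: an undirected simple graph on
node ids ``0..N-1``, optionally with a node -> community partition.  Because
the dynamics need every agent reachable, disconnected realizations are
rejected and regenerated up to a bounded number of attempts.

Families: Watts-Strogatz small-world rings, Erdos-Renyi random graphs,
Barabasi-Albert preferential attachment, the Gomez-Gardenes/Moreno (GM)
one-parameter interpolation between them at fixed size, and the LFR community
benchmark.  Zachary's karate club (with its two factions) is available
offline as a fixture; the college-football network must be supplied by the
user as a GML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "LabelledGraph",
    "make_ws",
    "make_er",
    "make_ba",
    "make_gm",
    "make_lfr",
    "load_fixture",
    "read_graph",
    "write_graph",
]

_MAX_ATTEMPTS = 200


@dataclass
class LabelledGraph:
    """An undirected simple connected graph with optional community labels."""

    graph: nx.Graph
    community: dict[int, int] | None = None
    node_mapping: dict = field(default_factory=dict)  # original id -> 0..N-1

    def __post_init__(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges):
            raise ValueError("graph contains self-loops")
        if self.community is not None:
            if set(self.community) != set(g.nodes):
                raise ValueError("community labels must cover exactly the node set")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def communities(self) -> dict[int, list[int]]:
        """Community id -> sorted member list."""
        if self.community is None:
            raise ValueError("graph has no community labels")
        out: dict[int, list[int]] = {}
        for node in sorted(self.community):
            out.setdefault(self.community[node], []).append(node)
        return out


def _seeded(rng: np.random.Generator) -> int:
    """Draw a 31-bit seed for a networkx generator from our Generator."""
    return int(rng.integers(0, 2**31 - 1))


def _retry_connected(build, rng, what: str) -> nx.Graph:
    for _ in range(_MAX_ATTEMPTS):
        g = build(_seeded(rng))
        if g.number_of_nodes() and nx.is_connected(g):
            return g
    raise RuntimeError(
        f"could not generate a connected {what} graph in {_MAX_ATTEMPTS} attempts"
    )


def make_ws(n: int, k: int, p_rewire: float, rng: np.random.Generator) -> LabelledGraph:
    """Watts-Strogatz ring over ``n`` nodes, ``k`` nearest neighbours,
    rewiring probability ``p_rewire`` (0 gives the regular lattice)."""
    if k % 2 or not 0 < k < n:
        raise ValueError(f"k must be even and in (0, n), got k={k}, n={n}")
    g = _retry_connected(
        lambda s: nx.watts_strogatz_graph(n, k, p_rewire, seed=s), rng, "Watts-Strogatz"
    )
    return LabelledGraph(g)


def make_er(n: int, p_edge: float, rng: np.random.Generator) -> LabelledGraph:
    """Erdos-Renyi G(n, p) random graph (connected realization)."""
    if not 0 < p_edge <= 1:
        raise ValueError(f"p_edge must lie in (0, 1], got {p_edge}")
    g = _retry_connected(
        lambda s: nx.erdos_renyi_graph(n, p_edge, seed=s), rng, "Erdos-Renyi"
    )
    return LabelledGraph(g)


def make_ba(n: int, n_attach: int, rng: np.random.Generator) -> LabelledGraph:
    """Barabasi-Albert graph grown from a complete core of ``n_attach`` nodes,
    each new node attaching ``n_attach`` edges preferentially.

    The clique seed makes this the ``kappa = 0`` limit of :func:`make_gm`
    (which grows from a complete core by construction); the edge count is
    ``C(n_attach, 2) + (n - n_attach) * n_attach``.
    """
    if not 0 < n_attach < n:
        raise ValueError(f"n_attach must lie in (0, n), got {n_attach}")
    # a single-node "clique" has no degree mass to attach to; start from K2
    core = nx.complete_graph(max(n_attach, 2))
    g = _retry_connected(
        lambda s: nx.barabasi_albert_graph(n, n_attach, seed=s, initial_graph=core),
        rng,
        "Barabasi-Albert",
    )
    return LabelledGraph(g)


def _gm_once(n: int, m: int, kappa: float, rng: np.random.Generator) -> nx.Graph:
    """One GM-family realization.

    Start from a complete core of ``m`` nodes; each subsequent node brings
    ``m`` new links.  Each link is, independently, a uniformly random pair
    among all ``n`` nodes with probability ``kappa``, or a preferential
    attachment from the new node with probability ``1 - kappa``.  Node and
    edge counts are therefore identical for every ``kappa``.
    """
    g = nx.complete_graph(m)
    g.add_nodes_from(range(m, n))
    # repeated-nodes list for preferential attachment
    targets = [x for e in g.edges for x in e]
    for new in range(m, n):
        added: set[tuple[int, int]] = set()
        while len(added) < m:
            if rng.random() < kappa:
                u, v = rng.choice(n, size=2, replace=False)
                u, v = int(u), int(v)
            else:
                u, v = new, targets[int(rng.integers(len(targets)))]
            if u == v:
                continue
            e = (min(u, v), max(u, v))
            if e in added or g.has_edge(*e):
                continue
            added.add(e)
        for u, v in sorted(added):
            g.add_edge(u, v)
            targets.extend((u, v))
    return g


def make_gm(
    n: int, mean_degree: int, kappa: float, rng: np.random.Generator
) -> LabelledGraph:
    """GM one-parameter family at fixed mean degree.

    ``kappa = 0`` grows a pure preferential-attachment (BA-like) network,
    ``kappa = 1`` places every link uniformly at random (ER-like); every
    value of ``kappa`` yields the same node and edge counts.
    """
    if not 0 <= kappa <= 1:
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
    m = mean_degree // 2
    if not 0 < m < n:
        raise ValueError(f"mean_degree {mean_degree} incompatible with n={n}")
    for _ in range(_MAX_ATTEMPTS):
        g = _gm_once(n, m, kappa, rng)
        if nx.is_connected(g):
            return LabelledGraph(g)
    raise RuntimeError(
        f"could not generate a connected GM graph in {_MAX_ATTEMPTS} attempts"
    )


def make_lfr(
    n: int,
    tau1: float,
    tau2: float,
    mu: float,
    avg_deg: int,
    max_deg: int,
    min_comm: int,
    max_comm: int,
    rng: np.random.Generator,
    n_communities: int = 3,
    connected: bool = True,
) -> LabelledGraph:
    """LFR community benchmark, keeping only realizations with exactly
    ``n_communities`` communities (and, by default, a connected graph —
    note a vanishing ``mu`` forces disconnection between communities)."""
    for _ in range(_MAX_ATTEMPTS):
        try:
            g = nx.LFR_benchmark_graph(
                n,
                tau1,
                tau2,
                mu,
                average_degree=avg_deg,
                max_degree=max_deg,
                min_community=min_comm,
                max_community=max_comm,
                seed=_seeded(rng),
            )
        except nx.ExceededMaxIterations:
            continue
        g.remove_edges_from(nx.selfloop_edges(g))
        if connected and not nx.is_connected(g):
            continue
        comms = {frozenset(g.nodes[v]["community"]) for v in g}
        if len(comms) != n_communities:
            continue
        labels = {}
        for cid, members in enumerate(sorted(comms, key=min)):
            for v in members:
                labels[v] = cid
        plain = nx.Graph(g.edges)
        plain.add_nodes_from(g.nodes)
        return LabelledGraph(plain, community=labels)
    raise RuntimeError(
        f"no LFR realization with {n_communities} communities in "
        f"{_MAX_ATTEMPTS} attempts"
    )


def load_fixture(name: str, path: str | Path | None = None) -> LabelledGraph:
    """Load a bundled or user-supplied benchmark network.

    ``"karate"`` — Zachary's karate club (34 members, 78 friendships), with
    the two post-split factions as communities; available offline.
    ``"football"`` — the American college-football schedule network with its
    12 conferences; not redistributed here, pass the GML file via ``path``.
    """
    if name == "karate":
        g = nx.karate_club_graph()
        club = nx.get_node_attributes(g, "club")
        community = {v: (0 if club[v] == "Mr. Hi" else 1) for v in g}
        plain = nx.Graph(g.edges)
        plain.add_nodes_from(g.nodes)
        return LabelledGraph(plain, community=community)
    if name == "football":
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                "the college-football network is not bundled; download "
                "'football.gml' (M. Girvan & M. E. J. Newman's network "
                "collection) and pass its path"
            )
        lg = read_graph(path, fmt="gml")
        values = nx.get_node_attributes(nx.read_gml(str(path), label="id"), "value")
        if values:
            lg.community = {lg.node_mapping[k]: int(v) for k, v in values.items()}
        return lg
    raise ValueError(f"unknown fixture {name!r}; choose 'karate' or 'football'")


def _natural_key(node) -> tuple:
    """Sort numeric node labels numerically, everything else lexically."""
    s = str(node)
    try:
        return (0, float(s), "")
    except ValueError:
        return (1, 0.0, s)


def read_graph(
    path: str | Path,
    fmt: str = "edgelist",
    communities_path: str | Path | None = None,
) -> LabelledGraph:
    """Read a graph from an edge list or GML file, relabelled to ``0..N-1``.

    ``communities_path`` may point to a two-column TSV ``node_id<TAB>community``
    using the file's original node ids; ids absent from the graph are an
    error (reported with their line numbers).
    """
    path = Path(path)
    if fmt == "edgelist":
        g = nx.read_edgelist(str(path))
    elif fmt == "gml":
        g = nx.read_gml(str(path), label="id")
    else:
        raise ValueError(f"unsupported graph format {fmt!r}")
    g = nx.Graph(g)  # drop parallel edges / attributes
    g.remove_edges_from(nx.selfloop_edges(g))
    mapping = {orig: i for i, orig in enumerate(sorted(g.nodes, key=_natural_key))}
    g = nx.relabel_nodes(g, mapping)

    community = None
    if communities_path is not None:
        community = {}
        by_str = {str(orig): new for orig, new in mapping.items()}
        with open(communities_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 2:
                    raise ValueError(
                        f"{communities_path}:{lineno}: expected 2 columns, "
                        f"got {len(parts)}"
                    )
                node, comm = parts
                if node not in by_str:
                    raise ValueError(
                        f"{communities_path}:{lineno}: node {node!r} not in graph"
                    )
                community[by_str[node]] = int(comm)
        missing = set(g.nodes) - set(community)
        if missing:
            raise ValueError(
                f"community file lacks labels for {len(missing)} nodes"
            )
    return LabelledGraph(g, community=community, node_mapping=mapping)


def write_graph(lg: LabelledGraph, path: str | Path, fmt: str = "edgelist") -> None:
    """Write a graph as an edge list or GML; communities go to ``<path>.tsv``."""
    path = Path(path)
    if fmt == "edgelist":
        nx.write_edgelist(lg.graph, str(path), data=False)
    elif fmt == "gml":
        nx.write_gml(lg.graph, str(path))
    else:
        raise ValueError(f"unsupported graph format {fmt!r}")
    if lg.community is not None:
        with open(path.with_suffix(path.suffix + ".tsv"), "w") as fh:
            for node in sorted(lg.community):
                fh.write(f"{node}\t{lg.community[node]}\n")
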
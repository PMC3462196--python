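"""Ergodic sets: recurrent communicating classes of a PBCN.

The recurrent classes of the chain are determined by the semigroup generated
by the deterministic update maps alone — the numeric probabilities only
weight the edges, they never add or remove any (every configuration has
strictly positive probability in the open cube).  The classes are therefore
exactly the terminal strongly-connected components of the *union graph*,
the directed graph with an edge ``s -> s'`` whenever some configuration maps
``s`` to ``s'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd
from typing import Iterator

import numpy as np
import scipy.sparse as sparse
from scipy.sparse.csgraph import breadth_first_order, connected_components

from .network import NetworkSpec, StateIndex
from .transition import TransitionMatrix, UpdateMapFamily, build_update_maps, transition_matrix

__all__ = [
    "UnionGraph",
    "ErgodicSet",
    "union_graph",
    "recurrent_classes",
    "verify_probability_invariance",
    "InvarianceReport",
]


@dataclass(frozen=True)
class UnionGraph:
    """Union of the functional graphs of all update maps.

    Out-degree of every state is between 1 and the number of configurations;
    each edge can be annotated with the set of configurations realizing it.
    """

    family: UpdateMapFamily

    @property
    def n_states(self) -> int:
        return self.family.n_states

    def successors(self, state: int) -> tuple[int, ...]:
        return tuple(sorted(set(int(s) for s in self.family.maps[:, state])))

    def edges(self, *, annotate: bool = False) -> Iterator[tuple]:
        """Yield ``(s, s')`` or, annotated, ``(s, s', config_indices)``."""
        for s in range(self.n_states):
            if annotate:
                by_succ: dict[int, list[int]] = {}
                for c in range(self.family.maps.shape[0]):
                    by_succ.setdefault(int(self.family.maps[c, s]), []).append(c)
                for succ in sorted(by_succ):
                    yield s, succ, tuple(by_succ[succ])
            else:
                for succ in self.successors(s):
                    yield s, succ

    def to_scipy(self) -> sparse.csr_matrix:
        n = self.n_states
        rows = np.tile(np.arange(n, dtype=np.int64), self.family.maps.shape[0])
        cols = self.family.maps.reshape(-1)
        data = np.ones(rows.shape[0], dtype=np.int8)
        A = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        A.sum_duplicates()
        return A

    def to_networkx(self, *, annotate: bool = False):
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(range(self.n_states))
        if annotate:
            for s, succ, cfgs in self.edges(annotate=True):
                G.add_edge(s, succ, configs=cfgs)
        else:
            G.add_edges_from(self.edges())
        return G


@dataclass(frozen=True)
class ErgodicSet:
    """A recurrent communicating class: closed and strongly connected.

    ``period`` is the period of the chain restricted to the class (gcd of
    cycle lengths through any state); it is reported for information only —
    stationary distributions are computed by linear solve, which does not
    require aperiodicity.
    """

    id: str
    states: tuple[int, ...]  # sorted
    period: int

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, state: int) -> bool:
        return int(state) in self._state_set

    @property
    def _state_set(self) -> frozenset[int]:
        return frozenset(self.states)

    def labels(self) -> tuple[int, ...]:
        """Display labels (binary number + 1)."""
        return tuple(s + 1 for s in self.states)


def union_graph(maps: UpdateMapFamily) -> UnionGraph:
    return UnionGraph(maps)


def _class_period(graph: UnionGraph, states: tuple[int, ...]) -> int:
    """Period via BFS levels: gcd over internal edges of level(u)+1-level(v)."""
    state_set = set(states)
    root = states[0]
    level = {root: 0}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.successors(u):
                if v in state_set and v not in level:
                    level[v] = level[u] + 1
                    nxt.append(v)
        frontier = nxt
    g = 0
    for u in states:
        for v in graph.successors(u):
            if v in state_set:
                g = gcd(g, level[u] + 1 - level[v])
    return abs(g) if g else 1


def recurrent_classes(graph: UnionGraph) -> list[ErgodicSet]:
    """Terminal strongly-connected components of the union graph.

    Returned in canonical order (smallest contained state index first) with
    stable identifiers ES1, ES2, ...
    """
    A = graph.to_scipy()
    n_comp, labels = connected_components(A, directed=True, connection="strong")
    coo = A.tocoo()
    terminal = np.ones(n_comp, dtype=bool)
    src, dst = labels[coo.row], labels[coo.col]
    terminal[src[src != dst]] = False
    classes = []
    for comp in np.flatnonzero(terminal):
        states = tuple(int(s) for s in np.flatnonzero(labels == comp))
        classes.append(states)
    classes.sort(key=lambda st: st[0])
    return [
        ErgodicSet(f"ES{i + 1}", states, _class_period(graph, states))
        for i, states in enumerate(classes)
    ]


def reaches_some_class(graph: UnionGraph, classes: list[ErgodicSet]) -> bool:
    """True iff every state reaches at least one recurrent class (always holds
    on a finite chain; exposed as a sanity check for tests)."""
    A = graph.to_scipy()
    in_class = np.zeros(graph.n_states, dtype=bool)
    for cls in classes:
        in_class[list(cls.states)] = True
    # reverse-BFS from all class states
    AT = A.T.tocsr()
    seeds = np.flatnonzero(in_class)
    reached = np.zeros(graph.n_states, dtype=bool)
    reached[seeds] = True
    frontier = seeds
    while frontier.size:
        nxt = []
        for u in frontier:
            row = AT.indices[AT.indptr[u]:AT.indptr[u + 1]]
            new = row[~reached[row]]
            reached[new] = True
            nxt.append(new)
        frontier = np.concatenate(nxt) if nxt else np.empty(0, dtype=np.int64)
    return bool(reached.all())


@dataclass(frozen=True)
class InvarianceReport:
    """Result of checking probability-independence of the class structure."""

    samples: int
    discrepancies: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.discrepancies


def verify_probability_invariance(
    spec: NetworkSpec, samples: int, seed: int
) -> InvarianceReport:
    """Check that the recurrent classes of the numerically evaluated chain
    coincide with the probability-free union-graph classes.

    Evaluates the transition matrix at ``samples`` random interior
    probability vectors, recomputes closed communicating classes from each
    numeric support, and compares.  Any discrepancy signals an
    implementation bug, not a property of the model.
    """
    if samples < 1:
        raise ValueError("samples must be >= 1")
    rng = np.random.default_rng(seed)
    maps = build_update_maps(spec)
    reference = recurrent_classes(union_graph(maps))
    ref_sets = [cls.states for cls in reference]
    discrepancies: list[str] = []
    for k in range(samples):
        probs = {s: float(rng.uniform(0.05, 0.95)) for s in spec.symbols}
        numeric = transition_matrix(maps, probs)
        A = numeric.to_scipy()
        A.eliminate_zeros()
        n_comp, labels = connected_components(A, directed=True, connection="strong")
        coo = A.tocoo()
        terminal = np.ones(n_comp, dtype=bool)
        src, dst = labels[coo.row], labels[coo.col]
        terminal[src[src != dst]] = False
        numeric_sets = sorted(
            (
                tuple(int(s) for s in np.flatnonzero(labels == comp))
                for comp in np.flatnonzero(terminal)
            ),
            key=lambda st: st[0],
        )
        if numeric_sets != ref_sets:
            discrepancies.append(
                f"sample {k} at probs {probs}: classes {numeric_sets} != {ref_sets}"
            )
    return InvarianceReport(samples, tuple(discrepancies))
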
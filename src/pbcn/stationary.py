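"""Stationary distributions on ergodic sets and per-node activity functions.

Restricted to a recurrent class ``W`` the chain is irreducible but not
necessarily aperiodic, so the quantity of interest is the stationary
distribution — the unique solution of ``pi M_W = pi``, ``sum pi = 1`` —
rather than a limiting distribution.  It is computed by an exact linear
solve over the field of rational functions in the probability symbols
(sympy ``DomainMatrix`` over ``QQ(p_1, ..., p_m)``), never by power
iteration.  Each entry ``pi_s(p)`` is a rational function, positive and
continuous on the open unit cube.

The *activity function* of node ``X`` is the stationary expectation of its
bit, ``a_X(p) = sum_s pi_s(p) * bit_X(s)`` — the qualitative activation
level of the species the node represents.  Composing activity functions
with a time-dependent control schedule turns them into *activity profiles*,
functions of time over a modeled process such as a full cell cycle.

For classes larger than a configurable threshold the symbolic solve is
skipped and the restricted system is solved in floating point at each
requested probability vector instead (flagged ``numeric`` in metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from sympy.polys.matrices import DomainMatrix

from .control import ControlSchedule
from .errors import BoundaryProbabilityError, PBCNError
from .ergodic import ErgodicSet, recurrent_classes, union_graph
from .network import NetworkSpec, decode_state
from .transition import (
    TransitionMatrix,
    build_update_maps,
    transition_matrix,
    validate_probabilities,
)

__all__ = [
    "SymbolicDistribution",
    "SampledDistribution",
    "stationary_distribution",
    "ActivityTable",
    "activity_functions",
    "ActivityProfile",
    "compose_with_control",
    "monte_carlo_check",
    "MonteCarloReport",
    "DEFAULT_SYMBOLIC_THRESHOLD",
]

DEFAULT_SYMBOLIC_THRESHOLD = 64


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymbolicDistribution:
    """Stationary probabilities over an ergodic set, one rational function of
    the probability symbols per state (plain rationals when nothing varies).
    """

    ergodic_set: ErgodicSet
    pi: dict[int, sp.Expr]
    symbols: tuple[sp.Symbol, ...]

    numeric: bool = False  # exact symbolic result

    def evaluate(self, probs: Mapping[str, float]) -> dict[int, float]:
        subs = {sp.Symbol(k, positive=True): v for k, v in probs.items()}
        return {s: float(expr.subs(subs)) for s, expr in self.pi.items()}

    def total(self) -> sp.Expr:
        return sp.cancel(sum(self.pi.values()))


@dataclass(frozen=True)
class SampledDistribution:
    """Numeric fallback for large classes: exact dense solve of the restricted
    system at every requested probability vector (no symbolic expressions).
    """

    ergodic_set: ErgodicSet
    matrix: TransitionMatrix

    numeric: bool = True

    def evaluate(self, probs: Mapping[str, float]) -> dict[int, float]:
        numeric = self.matrix.evaluate(probs) if self.matrix.symbolic else self.matrix
        pi = _solve_numeric(numeric, self.ergodic_set.states)
        return dict(zip(self.ergodic_set.states, pi))


def _solve_numeric(matrix: TransitionMatrix, states: Sequence[int]) -> np.ndarray:
    _, M = matrix.restrict(states)
    k = len(states)
    A = (M - np.eye(k)).T
    A[-1, :] = 1.0
    b = np.zeros(k)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise PBCNError(
            "singular stationary system: the state set is not an irreducible "
            "class of this chain"
        ) from exc
    return pi


def _solve_symbolic(matrix: TransitionMatrix, states: Sequence[int],
                    symbols: tuple[sp.Symbol, ...]) -> list[sp.Expr]:
    """Exact solve of ``pi (M_W - I) = 0`` with one balance equation replaced
    by the normalization row, over ``QQ`` or ``QQ(p_1, ..., p_m)``."""
    _, M = matrix.restrict(states)
    k = len(states)
    A = (M - sp.eye(k)).T
    for j in range(k):
        A[k - 1, j] = sp.Integer(1)
    b = sp.zeros(k, 1)
    b[k - 1, 0] = sp.Integer(1)
    aug = DomainMatrix.from_Matrix(A.row_join(b))
    domain = sp.QQ.frac_field(*symbols) if symbols else sp.QQ
    aug = aug.convert_to(domain)
    try:
        x = aug[:, :k].lu_solve(aug[:, k:])
    except Exception as exc:  # DMNonInvertibleMatrixError and kin
        raise PBCNError(
            "singular stationary system: the state set is not an irreducible "
            "class of this chain"
        ) from exc
    xm = x.to_Matrix()
    return [sp.cancel(xm[i, 0]) for i in range(k)]


def stationary_distribution(
    matrix: TransitionMatrix,
    ergodic_set: ErgodicSet,
    *,
    symbolic_threshold: int = DEFAULT_SYMBOLIC_THRESHOLD,
):
    """Stationary distribution of the chain restricted to an ergodic set.

    Symbolic matrices yield a :class:`SymbolicDistribution` of exact
    rational functions when the class has at most ``symbolic_threshold``
    states, and a :class:`SampledDistribution` (per-point numeric solves)
    above it.  Numeric matrices always solve in floating point.

    Raises if the set is not closed under the matrix or the restricted
    system is singular (either signals inconsistent inputs).
    """
    states = ergodic_set.states
    if not matrix.symbolic:
        pi = _solve_numeric(matrix, states)
        return SymbolicDistribution(
            ergodic_set,
            {s: sp.Float(v) for s, v in zip(states, pi)},
            symbols=(),
            numeric=True,
        )
    symbols = tuple(
        sp.Symbol(name, positive=True) for name in matrix.spec.symbols
    )
    if len(states) > symbolic_threshold:
        # closure check up front so misuse fails fast
        matrix.restrict(states)
        return SampledDistribution(ergodic_set, matrix)
    pi = _solve_symbolic(matrix, states, symbols)
    return SymbolicDistribution(ergodic_set, dict(zip(states, pi)), symbols)


# ---------------------------------------------------------------------------
# activity functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityTable:
    """Per-node activity functions for one ergodic set.

    ``functions[node]`` is a sympy rational function of the probability
    symbols (a plain number when the dependence cancels).  For numeric
    fallback distributions the table holds no expressions and activities
    are obtained through :meth:`evaluate`.
    """

    spec: NetworkSpec
    ergodic_set: ErgodicSet
    functions: dict[str, sp.Expr] | None
    distribution: object = None  # backing distribution (for numeric mode)

    @property
    def numeric(self) -> bool:
        return self.functions is None

    def expr(self, node: str) -> sp.Expr:
        if self.functions is None:
            raise PBCNError(
                f"activity of {node!r} is numeric (class above the symbolic "
                f"threshold); use evaluate()"
            )
        return self.functions[node]

    def is_constant(self, node: str) -> bool:
        """Exact constancy: every partial derivative identically zero."""
        expr = self.expr(node)
        return all(
            sp.simplify(sp.diff(expr, s)) == 0 for s in expr.free_symbols
        ) if expr.free_symbols else True

    def evaluate(self, probs: Mapping[str, float] | None = None) -> dict[str, float]:
        if self.functions is not None:
            subs = (
                {sp.Symbol(k, positive=True): v for k, v in probs.items()}
                if probs
                else {}
            )
            return {
                node: float(expr.subs(subs)) for node, expr in self.functions.items()
            }
        pi = self.distribution.evaluate(probs or {})
        return _activities_from_pi(self.spec, self.ergodic_set, pi)

    def signature(self, *, tol: float = 0.0) -> dict[str, str]:
        """Mechanical qualitative signature: constant 1 -> 'active', constant
        0 -> 'inactive', anything else -> 'p-dependent'."""
        if self.functions is None:
            raise PBCNError("signatures require symbolic activity functions")
        out = {}
        for node, expr in self.functions.items():
            if expr.free_symbols or not self.is_constant(node):
                out[node] = "p-dependent"
            else:
                value = float(expr)
                if abs(value - 1.0) <= tol:
                    out[node] = "active"
                elif abs(value) <= tol:
                    out[node] = "inactive"
                else:
                    out[node] = "p-dependent"
        return out


def _activities_from_pi(spec: NetworkSpec, ergodic_set: ErgodicSet,
                        pi: Mapping[int, float]) -> dict[str, float]:
    out = {node: 0.0 for node in spec.internal}
    for s, weight in pi.items():
        bits = decode_state(s, spec)
        for node, bit in zip(spec.internal, bits):
            if bit:
                out[node] += weight
    return out


def activity_functions(dist, spec: NetworkSpec) -> ActivityTable:
    """Build the per-node activity table ``a_X = sum_s pi_s * bit_X(s)``."""
    if isinstance(dist, SampledDistribution):
        return ActivityTable(spec, dist.ergodic_set, None, distribution=dist)
    acc = {node: sp.Integer(0) for node in spec.internal}
    for s, expr in dist.pi.items():
        bits = decode_state(s, spec)
        for node, bit in zip(spec.internal, bits):
            if bit:
                acc[node] = acc[node] + expr
    functions = {node: sp.cancel(sp.together(e)) for node, e in acc.items()}
    return ActivityTable(spec, dist.ergodic_set, functions, distribution=dist)


# ---------------------------------------------------------------------------
# composition with control schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityProfile:
    """Per-node activities over a time grid, after composing activity
    functions with a control schedule.

    ``frame`` is a wide DataFrame indexed by time with one column per
    internal node; ``phase`` gives each grid point's phase index.  Phase
    boundaries are evaluated from within their own phase (right-continuous
    model switches), so discontinuities appear only at boundaries.
    """

    frame: pd.DataFrame
    phase: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def node(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def phase_slice(self, phase_index: int) -> pd.DataFrame:
        return self.frame.iloc[self.phase == phase_index]

    def to_long(self) -> pd.DataFrame:
        """Long form with columns time, node, activity, sorted by (time, node
        order); this is the TSV layout."""
        wide = self.frame
        long = wide.reset_index(names="time").melt(
            id_vars="time", var_name="node", value_name="activity"
        )
        node_order = {n: i for i, n in enumerate(wide.columns)}
        long["__order"] = long["node"].map(node_order)
        long = long.sort_values(["time", "__order"], kind="stable")
        return long.drop(columns="__order").reset_index(drop=True)


def compose_with_control(
    fns: ActivityTable | Sequence[ActivityTable],
    schedule: ControlSchedule,
    *,
    num_points: int = 1000,
) -> ActivityProfile:
    """Compose activity functions with a control schedule.

    ``fns`` is a single table (applied to every phase) or one table per
    schedule phase.  The time grid is uniform over the schedule domain;
    each grid point takes the control value and the activity table of the
    phase containing it.
    """
    phases = schedule.phases
    if isinstance(fns, ActivityTable):
        tables = [fns] * len(phases)
    else:
        tables = list(fns)
        if len(tables) != len(phases):
            raise PBCNError(
                f"{len(tables)} activity tables for {len(phases)} schedule phases"
            )
    t0, t1 = schedule.domain
    times = np.linspace(t0, t1, num_points)
    spec = tables[0].spec
    nodes = spec.internal
    values = np.empty((num_points, len(nodes)))
    phase_idx = np.empty(num_points, dtype=np.int64)

    # cache lambdified symbolic tables per phase
    evaluators = []
    for table in tables:
        if table.numeric:
            evaluators.append(None)
        else:
            syms = sorted(
                {s for e in table.functions.values() for s in e.free_symbols},
                key=str,
            )
            lam = {
                node: sp.lambdify(syms, expr, "numpy")
                for node, expr in table.functions.items()
            }
            evaluators.append((tuple(str(s) for s in syms), lam))

    for i, t in enumerate(times):
        k = schedule.phase_index(t)
        phase_idx[i] = k
        controls = schedule.control_values(t)
        for name, v in controls.items():
            if not 0.0 < v < 1.0:
                raise BoundaryProbabilityError(
                    f"control value {name}={v} at t={t} lies on the boundary"
                )
        table, ev = tables[k], evaluators[k]
        if ev is None:
            acts = table.evaluate(controls)
        else:
            sym_names, lam = ev
            args = [controls[s] for s in sym_names]
            acts = {node: float(f(*args)) for node, f in lam.items()}
        values[i] = [acts[node] for node in nodes]

    frame = pd.DataFrame(values, index=pd.Index(times, name="time"), columns=nodes)
    return ActivityProfile(frame, phase_idx)


# ---------------------------------------------------------------------------
# Monte-Carlo cross-check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonteCarloReport:
    """Empirical state frequencies over the absorbed class vs the analytic
    stationary distribution."""

    class_id: str
    steps: int
    burn_in: int
    empirical: dict[int, float]
    analytic: dict[int, float]
    l1_distance: float


def monte_carlo_check(
    spec: NetworkSpec,
    probs: Mapping[str, float],
    steps: int,
    burn_in: int,
    seed: int,
) -> MonteCarloReport:
    """Simulate the chain and compare post-burn-in state frequencies with the
    analytic stationary distribution of the visited class (L1 distance)."""
    from .simulate import walk  # local import to avoid a cycle

    if steps <= burn_in:
        raise ValueError("steps must exceed burn_in")
    validate_probabilities(spec, probs)
    maps = build_update_maps(spec)
    classes = recurrent_classes(union_graph(maps))
    traj = walk(spec, probs, steps, initial=0, seed=seed, _maps=maps)
    tail = traj.states[burn_in:]
    hit = None
    for cls in classes:
        if int(tail[-1]) in cls:
            hit = cls
            break
    if hit is None:  # impossible by absorption totality; defensive
        raise PBCNError("trajectory tail not inside any recurrent class")
    inside = np.isin(tail, np.asarray(hit.states))
    tail = tail[inside]
    counts = {s: 0 for s in hit.states}
    uniq, cnt = np.unique(tail, return_counts=True)
    for s, c in zip(uniq, cnt):
        counts[int(s)] = int(c)
    total = max(1, int(tail.shape[0]))
    empirical = {s: c / total for s, c in counts.items()}
    matrix = transition_matrix(maps, probs)
    dist = stationary_distribution(matrix, hit)
    analytic = dist.evaluate(dict(probs))
    l1 = sum(abs(empirical[s] - analytic[s]) for s in hit.states)
    return MonteCarloReport(hit.id, steps, burn_in, empirical, analytic, l1)
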
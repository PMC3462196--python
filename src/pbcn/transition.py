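"""Update maps and the PBCN transition matrix.

At each step one external configuration ``v`` is drawn (stochastic inputs
independent, ``P(v) = prod p_i^{v_i} (1-p_i)^{1-v_i}``) and the full
synchronous update ``f_v`` is applied to the internal state.  The transition
matrix is the probability-weighted sum of the deterministic maps,

    M[s, s'] = sum over v with f_v(s) = s' of P(v),

so each row has at most ``2**m_s`` nonzero entries and the sparsity pattern
depends only on the maps, never on the numeric probabilities.  Entries are
multivariate polynomials in the probability symbols, or floats after
evaluation at a numeric probability assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real
from typing import Mapping

import numpy as np
import scipy.sparse as sparse
import sympy as sp

from .errors import BoundaryProbabilityError, PBCNError
from .network import ExternalConfiguration, NetworkSpec, enumerate_external_configs

__all__ = [
    "UpdateMapFamily",
    "TransitionMatrix",
    "build_update_maps",
    "transition_matrix",
    "evaluate_matrix",
    "symbolic_probabilities",
    "validate_probabilities",
]


@dataclass(frozen=True)
class UpdateMapFamily:
    """One deterministic synchronous update map per external configuration.

    ``maps[c]`` is the successor array of configuration ``configs[c]``; these
    maps are the generators of the semigroup that fixes the recurrent class
    structure of the chain.
    """

    spec: NetworkSpec
    configs: tuple[ExternalConfiguration, ...]
    maps: np.ndarray  # shape (n_configs, 2**n), dtype int64

    @property
    def n_states(self) -> int:
        return self.maps.shape[1]

    def apply(self, config_index: int, state: int) -> int:
        return int(self.maps[config_index, state])


def build_update_maps(spec: NetworkSpec) -> UpdateMapFamily:
    """Compute ``f_v`` for every external configuration, vectorized over states."""
    n = spec.n
    n_states = spec.n_states
    configs = tuple(enumerate_external_configs(spec))
    states = np.arange(n_states, dtype=np.int64)
    # bit i (0 = MSB) of every state
    internal_bits = {
        node: (states >> (n - 1 - i)) & 1 for i, node in enumerate(spec.internal)
    }
    maps = np.zeros((len(configs), n_states), dtype=np.int64)
    for c, cfg in enumerate(configs):
        ext = cfg.assignment
        nxt = np.zeros(n_states, dtype=np.int64)
        for i, rule in enumerate(spec.rules):
            idx = np.zeros(n_states, dtype=np.int64)
            for reg in rule.regulators:
                bit = internal_bits[reg] if reg in internal_bits else ext[reg]
                idx = (idx << 1) | bit
            table = np.asarray(rule.table, dtype=np.int64)
            nxt |= table[idx] << (n - 1 - i)
        maps[c] = nxt
    return UpdateMapFamily(spec, configs, maps)


def symbolic_probabilities(spec: NetworkSpec) -> dict[str, sp.Symbol]:
    """Map each stochastic-input symbol name to a sympy symbol (symbolic mode)."""
    return {s: sp.Symbol(s, positive=True) for s in spec.symbols}


def validate_probabilities(spec: NetworkSpec, probs: Mapping[str, object]) -> None:
    """Check coverage of every stochastic symbol; numeric values must lie in (0,1)."""
    for name in spec.symbols:
        if name not in probs:
            raise PBCNError(f"missing probability for stochastic symbol {name!r}")
        val = probs[name]
        if isinstance(val, Real) and not isinstance(val, bool):
            if not 0.0 < float(val) < 1.0:
                raise BoundaryProbabilityError(
                    f"probability {name}={float(val)} must lie strictly inside (0, 1); "
                    f"boundary values change the chain's recurrent class structure"
                )


def _config_probability(cfg: ExternalConfiguration, spec: NetworkSpec,
                        probs: Mapping[str, object]):
    """``P(v)`` as a product over stochastic inputs (symbolic or float)."""
    assignment = cfg.assignment
    numeric = all(
        isinstance(probs[s], Real) and not isinstance(probs[s], bool)
        for s in spec.symbols
    )
    if numeric:
        out = 1.0
        for e in spec.stochastic_inputs:
            p = float(probs[e.symbol])
            out *= p if assignment[e.id] else (1.0 - p)
        return out
    out = sp.Integer(1)
    for e in spec.stochastic_inputs:
        p = sp.sympify(probs[e.symbol])
        out *= p if assignment[e.id] else (1 - p)
    return sp.expand(out)


@dataclass(frozen=True)
class TransitionMatrix:
    """Sparse row-stochastic transition matrix of a PBCN.

    Stored implicitly as the update-map family plus one probability weight
    per configuration; rows are materialized on demand.  ``symbolic`` is
    true when the weights are polynomials in the probability symbols.
    """

    family: UpdateMapFamily
    config_probs: tuple[object, ...]  # sympy Expr or float, one per config
    symbolic: bool

    @property
    def spec(self) -> NetworkSpec:
        return self.family.spec

    @property
    def n_states(self) -> int:
        return self.family.n_states

    def row(self, state: int) -> dict[int, object]:
        """Sparse row: successor state -> transition weight."""
        out: dict[int, object] = {}
        for c, w in enumerate(self.config_probs):
            succ = int(self.family.maps[c, state])
            if succ in out:
                out[succ] = out[succ] + w
            else:
                out[succ] = w
        if self.symbolic:
            out = {s: sp.expand(w) for s, w in out.items()}
        return out

    def support(self, state: int) -> frozenset[int]:
        return frozenset(int(s) for s in self.family.maps[:, state])

    def row_sum(self, state: int):
        total = sum(self.row(state).values())
        return sp.expand(total) if self.symbolic else total

    def restrict(self, states) -> tuple[dict[int, int], object]:
        """Restrict to a closed state set.

        Returns ``(index_of_state, M)`` where ``M`` is a dense
        ``sympy.Matrix`` (symbolic) or ``numpy.ndarray`` (numeric) over the
        given states in sorted order.  Raises if the set is not closed.
        """
        order = sorted(int(s) for s in states)
        index = {s: i for i, s in enumerate(order)}
        k = len(order)
        if self.symbolic:
            M = sp.zeros(k, k)
        else:
            M = np.zeros((k, k))
        for s in order:
            for succ, w in self.row(s).items():
                if succ not in index:
                    raise PBCNError(
                        f"state set is not closed: {s} -> {succ} leaves the set"
                    )
                M[index[s], index[succ]] += w
        return index, M

    def to_scipy(self) -> sparse.csr_matrix:
        """Numeric matrix as scipy CSR (requires numeric weights)."""
        if self.symbolic:
            raise PBCNError("evaluate the matrix at numeric probabilities first")
        n = self.n_states
        rows = np.tile(np.arange(n, dtype=np.int64), len(self.config_probs))
        cols = self.family.maps.reshape(-1)
        data = np.repeat(np.asarray(self.config_probs, dtype=float), n)
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def evaluate(self, probs: Mapping[str, float]) -> "TransitionMatrix":
        return evaluate_matrix(self, probs)


def transition_matrix(maps: UpdateMapFamily,
                      probs: Mapping[str, object] | None = None) -> TransitionMatrix:
    """Assemble the transition matrix, symbolically by default.

    ``probs`` maps each stochastic symbol to a number in (0, 1) or to a
    sympy expression; omitted, each symbol maps to itself (fully symbolic).
    """
    spec = maps.spec
    if probs is None:
        probs = symbolic_probabilities(spec)
    validate_probabilities(spec, probs)
    weights = tuple(_config_probability(cfg, spec, probs) for cfg in maps.configs)
    symbolic = any(isinstance(w, sp.Expr) and w.free_symbols for w in weights)
    if not symbolic:
        weights = tuple(float(w) for w in weights)
    return TransitionMatrix(maps, weights, symbolic)


def evaluate_matrix(matrix: TransitionMatrix,
                    probs: Mapping[str, float]) -> TransitionMatrix:
    """Evaluate a symbolic matrix at numeric probabilities in the open cube."""
    return transition_matrix(matrix.family, probs)
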
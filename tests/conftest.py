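"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive recurrence structure from first principles
(transitive closure of the one-step reachability relation) without touching
the package's SCC-based implementation, so the two routes stay independent.
"""

from pathlib import Path

import numpy as np
import pytest

import pbcn

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"

TOY_DOC = """{
  "name": "toy",
  "internal": [
    {"id": "A", "rule": "E"},
    {"id": "B", "rule": "A"}
  ],
  "external": [
    {"id": "E", "mode": "stochastic", "symbol": "p"}
  ]
}"""

CYCLE_DOC = """{
  "name": "negative_feedback_cycle",
  "internal": [
    {"id": "A", "rule": "NOT B"},
    {"id": "B", "rule": "A"}
  ],
  "external": []
}"""


@pytest.fixture(scope="session")
def toy_spec():
    """A' = E, B' = A with one stochastic input: the closed-form network
    (stationary law is two independent Bernoulli(p) bits)."""
    return pbcn.parse_network(TOY_DOC)


@pytest.fixture(scope="session")
def cycle_spec():
    """Deterministic negative-feedback two-node network: a single 4-cycle."""
    return pbcn.parse_network(CYCLE_DOC)


@pytest.fixture(scope="session")
def yeast_phase2():
    return pbcn.phase_pbcn(None, 2)


def reachability(maps: np.ndarray) -> np.ndarray:
    """Boolean reachability matrix R[s, t] = 'state t reachable from s in one
    or more steps', by iterated squaring of the one-step relation."""
    n = maps.shape[1]
    R = np.zeros((n, n), dtype=bool)
    for row in maps:
        R[np.arange(n), row] = True
    while True:
        R2 = R | (R @ R)
        if (R2 == R).all():
            return R
        R = R2


def brute_force_recurrent_classes(maps: np.ndarray) -> list[tuple[int, ...]]:
    """A state is recurrent iff it is reachable back from every state it
    reaches; recurrent states partition into classes of mutual reachability."""
    R = reachability(maps)
    n = maps.shape[1]
    recurrent = [s for s in range(n) if all(R[t, s] for t in np.flatnonzero(R[s]))]
    classes = []
    seen: set[int] = set()
    for s in recurrent:
        if s in seen:
            continue
        cls = {s} | {t for t in recurrent if R[s, t] and R[t, s]}
        seen |= cls
        classes.append(tuple(sorted(cls)))
    return sorted(classes, key=lambda c: c[0])
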
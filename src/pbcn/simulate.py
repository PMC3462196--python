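"""Monte-Carlo trajectory simulation — the brute-force oracle for the
analytic layer.

Each step draws every stochastic external input independently (probability
from a static assignment or from a control schedule evaluated at that
step's time) and applies the corresponding deterministic update map.  One
pseudorandom stream per walk is derived from ``(master seed, walk index)``
via ``numpy.random.SeedSequence`` spawning, a counter-based scheme, so
results are machine-independent and bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .control import ControlSchedule
from .errors import PBCNError
from .ergodic import ErgodicSet, recurrent_classes, union_graph
from .network import NetworkSpec
from .transition import UpdateMapFamily, build_update_maps, validate_probabilities

__all__ = ["Trajectory", "walk", "absorption_census"]


@dataclass(frozen=True)
class Trajectory:
    """A simulated walk: visited states (length steps+1, initial state first),
    the per-step external-configuration indices, and optional step times."""

    seed: int
    initial: int
    states: np.ndarray  # int64, length steps + 1
    configs: np.ndarray  # int64, length steps
    times: np.ndarray | None = None

    @property
    def steps(self) -> int:
        return len(self.configs)


def _config_indices(
    spec: NetworkSpec,
    steps: int,
    probs: Mapping[str, float] | ControlSchedule,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw the per-step external-configuration index (first stochastic input
    is the most significant bit, matching the enumeration order)."""
    m = len(spec.symbols)
    if m == 0:
        return np.zeros(steps, dtype=np.int64), None
    u = rng.random((steps, m))
    if isinstance(probs, ControlSchedule):
        t0, t1 = probs.domain
        # steps mapped uniformly onto the schedule domain
        times = t0 + (t1 - t0) * (np.arange(steps) / max(1, steps - 1))
        pmat = np.empty((steps, m))
        for i, t in enumerate(times):
            values = probs.control_values(t)
            pmat[i] = [values[s] for s in spec.symbols]
    else:
        validate_probabilities(spec, probs)
        times = None
        pmat = np.broadcast_to(
            np.array([float(probs[s]) for s in spec.symbols]), (steps, m)
        )
    draws = (u < pmat).astype(np.int64)
    weights = 1 << np.arange(m - 1, -1, -1, dtype=np.int64)
    return draws @ weights, times


def walk(
    spec: NetworkSpec,
    probs: Mapping[str, float] | ControlSchedule,
    steps: int,
    initial: int,
    seed: int,
    *,
    _maps: UpdateMapFamily | None = None,
) -> Trajectory:
    """Simulate ``steps`` synchronous updates from ``initial`` (a state index).

    Deterministic given ``(seed, initial, probs)``.  Under a schedule the
    per-step probability is the control value at that step's time.
    """
    if steps < 1:
        raise PBCNError("steps must be >= 1")
    if not 0 <= initial < spec.n_states:
        raise PBCNError(f"invalid initial state {initial}")
    maps = _maps if _maps is not None else build_update_maps(spec)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    configs, times = _config_indices(spec, steps, probs, rng)
    # tight loop over steps; the maps are plain arrays
    flat = maps.maps
    states = np.empty(steps + 1, dtype=np.int64)
    s = int(initial)
    states[0] = s
    clist = configs.tolist()
    rows = [row.tolist() for row in flat]
    for i, c in enumerate(clist):
        s = rows[c][s]
        states[i + 1] = s
    return Trajectory(seed, initial, states, configs, times)


def absorption_census(
    spec: NetworkSpec,
    probs: Mapping[str, float],
    walks: int,
    steps: int,
    seed: int,
    *,
    initial: np.ndarray | None = None,
) -> dict[str, float]:
    """Fraction of independent walks absorbed into each recurrent class.

    A walk counts as absorbed when its last ``4 * |largest class|`` states
    all lie in a single class.  Initial states default to a uniform draw
    over the state space.  Fractions sum to 1; a tail matching no class
    would be an implementation bug (absorption is total on a finite chain).
    """
    if walks < 1:
        raise PBCNError("walks must be >= 1")
    maps = build_update_maps(spec)
    classes = recurrent_classes(union_graph(maps))
    tail_len = 4 * max(len(cls) for cls in classes)
    if steps <= tail_len:
        raise PBCNError(
            f"steps={steps} too short for tail classification ({tail_len})"
        )
    master = np.random.SeedSequence(seed)
    init_rng = np.random.default_rng(master.spawn(1)[0])
    if initial is None:
        initial = init_rng.integers(0, spec.n_states, size=walks)
    walk_seeds = master.spawn(walks)
    counts = {cls.id: 0 for cls in classes}
    state_sets = {cls.id: frozenset(cls.states) for cls in classes}
    for w in range(walks):
        rng = np.random.default_rng(walk_seeds[w])
        configs, _ = _config_indices(spec, steps, probs, rng)
        rows = [row.tolist() for row in maps.maps]
        s = int(initial[w])
        trace = []
        for c in configs.tolist():
            s = rows[c][s]
            trace.append(s)
        tail = set(trace[-tail_len:])
        hit = [cid for cid, states in state_sets.items() if tail <= states]
        if len(hit) != 1:
            raise PBCNError(
                f"walk {w}: tail not confined to a single recurrent class"
            )
        counts[hit[0]] += 1
    return {cid: c / walks for cid, c in counts.items()}
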
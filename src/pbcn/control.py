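"""Control functions and phase schedules.

A *control function* assigns each stochastic external input a time-dependent
probability ``c(t)`` in the open interval (0, 1).  A :class:`ControlSchedule`
sequences several PBCNs into one modeled process: each phase fixes the
binary checkpoint inputs to one configuration and carries a control function
per stochastic input over its time interval.  Intervals must partition the
schedule domain contiguously.

The bundled yeast schedules put each cell-cycle phase on one quarter of the
unit interval.  The default cell-size signal (CSS) is a piecewise-linear ramp
rising over phases 1-3 and falling during phase 4, clamped to
``[eps, 1 - eps]``; the nitrogen-deprivation variant rises linearly during
G1 only and holds at 0.01 afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ScheduleError

__all__ = [
    "ControlPiece",
    "SchedulePhase",
    "ControlSchedule",
    "make_schedule",
    "yeast_default_css",
    "yeast_nitrogen_css",
    "parse_schedule",
    "serialize_schedule",
    "YEAST_CHECKPOINTS",
]

#: checkpoint configurations (Start, Bud, SAC) of the four yeast phase PBCNs
YEAST_CHECKPOINTS: tuple[dict[str, int], ...] = (
    {"Start": 0, "Bud": 0, "SAC": 0},
    {"Start": 1, "Bud": 0, "SAC": 0},
    {"Start": 1, "Bud": 1, "SAC": 0},
    {"Start": 1, "Bud": 1, "SAC": 1},
)

DEFAULT_EPS = 0.01


@dataclass(frozen=True)
class ControlPiece:
    """Linear segment of a control function on ``[t0, t1]`` (constant when
    ``v0 == v1``)."""

    t0: float
    t1: float
    v0: float
    v1: float

    def __post_init__(self):
        if not self.t1 > self.t0:
            raise ScheduleError(f"empty control piece interval [{self.t0}, {self.t1}]")
        for v in (self.v0, self.v1):
            if not 0.0 < v < 1.0:
                raise ScheduleError(
                    f"control value {v} outside the open interval (0, 1)"
                )

    def __call__(self, t: float) -> float:
        frac = (t - self.t0) / (self.t1 - self.t0)
        return self.v0 + (self.v1 - self.v0) * frac


@dataclass(frozen=True)
class SchedulePhase:
    """One phase: fixed checkpoint assignment, time interval, and one control
    function (a list of contiguous pieces) per stochastic input."""

    fixed: Mapping[str, int]
    interval: tuple[float, float]
    control: Mapping[str, tuple[ControlPiece, ...]]

    def __post_init__(self):
        a, b = self.interval
        if not b > a:
            raise ScheduleError(f"empty phase interval [{a}, {b}]")
        for name, pieces in self.control.items():
            if not pieces:
                raise ScheduleError(f"phase control for {name!r} has no pieces")
            if abs(pieces[0].t0 - a) > 1e-12 or abs(pieces[-1].t1 - b) > 1e-12:
                raise ScheduleError(
                    f"control pieces for {name!r} do not span the phase interval"
                )
            for left, right in zip(pieces, pieces[1:]):
                if abs(left.t1 - right.t0) > 1e-12:
                    raise ScheduleError(
                        f"gap or overlap between control pieces for {name!r}"
                    )

    def value(self, name: str, t: float) -> float:
        pieces = self.control[name]
        for piece in pieces:
            if piece.t0 <= t <= piece.t1:
                return piece(t)
        # numerical slack at the edges
        return pieces[0](t) if t < pieces[0].t0 else pieces[-1](t)


@dataclass(frozen=True)
class ControlSchedule:
    """Ordered phases partitioning the schedule domain."""

    domain: tuple[float, float]
    phases: tuple[SchedulePhase, ...]

    def __post_init__(self):
        t0, t1 = self.domain
        if not self.phases:
            raise ScheduleError("schedule needs at least one phase")
        if abs(self.phases[0].interval[0] - t0) > 1e-12:
            raise ScheduleError("first phase does not start at the domain start")
        if abs(self.phases[-1].interval[1] - t1) > 1e-12:
            raise ScheduleError("last phase does not end at the domain end")
        for left, right in zip(self.phases, self.phases[1:]):
            if abs(left.interval[1] - right.interval[0]) > 1e-12:
                raise ScheduleError(
                    f"gap or overlap between phase intervals {left.interval} "
                    f"and {right.interval}"
                )

    def phase_index(self, t: float) -> int:
        """Phase containing ``t``; boundaries belong to the *later* phase
        (right-continuity: a phase switch is a model switch, not a limit)."""
        t0, t1 = self.domain
        if not t0 <= t <= t1:
            raise ScheduleError(f"time {t} outside schedule domain [{t0}, {t1}]")
        for k, phase in enumerate(self.phases):
            a, b = phase.interval
            if a <= t < b:
                return k
        return len(self.phases) - 1

    def control_values(self, t: float) -> dict[str, float]:
        phase = self.phases[self.phase_index(t)]
        return {name: phase.value(name, t) for name in phase.control}

    def value(self, name: str, t: float) -> float:
        return self.control_values(t)[name]


def make_schedule(
    phases: Sequence[tuple[Mapping[str, int], tuple[float, float],
                           Mapping[str, Sequence[ControlPiece]]]]
) -> ControlSchedule:
    """Assemble and validate a schedule from (fixed, interval, control) triples."""
    built = tuple(
        SchedulePhase(dict(fixed), tuple(interval),
                      {k: tuple(v) for k, v in control.items()})
        for fixed, interval, control in phases
    )
    return ControlSchedule((built[0].interval[0], built[-1].interval[1]), built)


# ---------------------------------------------------------------------------
# bundled yeast schedules
# ---------------------------------------------------------------------------

def _ramp(t: float, eps: float) -> float:
    """Default CSS ramp: linear from eps at t=0 to 1-eps at t=3/4."""
    return eps + (1.0 - 2.0 * eps) * (t / 0.75)


def yeast_default_css(*, eps: float = DEFAULT_EPS) -> ControlSchedule:
    """Default cell-size-signal schedule over the unit interval.

    CSS rises linearly from ``eps`` at t=0 to ``1-eps`` at t=3/4 (phases
    1-3, mimicking cell growth with the Cln3 signal peaking at the onset of
    M/G1) and falls linearly back to ``eps`` on [3/4, 1] (division).  The
    checkpoint assignments are the four phase PBCN configurations.
    """
    phases = []
    quarters = [(0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0)]
    for k, (a, b) in enumerate(quarters):
        if k < 3:
            piece = ControlPiece(a, b, _ramp(a, eps), _ramp(b, eps))
        else:
            piece = ControlPiece(a, b, 1.0 - eps, eps)
        phases.append(
            SchedulePhase(YEAST_CHECKPOINTS[k], (a, b), {"p": (piece,)})
        )
    return ControlSchedule((0.0, 1.0), tuple(phases))


def yeast_nitrogen_css(*, eps: float = DEFAULT_EPS) -> ControlSchedule:
    """Nitrogen-deprivation schedule: CSS linear (rising) during the G1
    quarter, then held at 0.01 for the rest of the cycle — the cell-size
    signal is removed right after Start.  Checkpoints as in the default
    schedule."""
    quarters = [(0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0)]
    phases = [
        SchedulePhase(
            YEAST_CHECKPOINTS[0], quarters[0],
            {"p": (ControlPiece(0.0, 0.25, eps, _ramp(0.25, eps)),)},
        )
    ]
    for k in (1, 2, 3):
        a, b = quarters[k]
        phases.append(
            SchedulePhase(
                YEAST_CHECKPOINTS[k], (a, b),
                {"p": (ControlPiece(a, b, 0.01, 0.01),)},
            )
        )
    return ControlSchedule((0.0, 1.0), tuple(phases))


# ---------------------------------------------------------------------------
# JSON form
# ---------------------------------------------------------------------------

def _piece_to_json(piece: ControlPiece) -> dict:
    if piece.v0 == piece.v1:
        return {"type": "constant", "interval": [piece.t0, piece.t1],
                "value": piece.v0}
    return {"type": "linear", "interval": [piece.t0, piece.t1],
            "start": piece.v0, "end": piece.v1}


def _piece_from_json(doc: dict, interval: tuple[float, float]) -> ControlPiece:
    a, b = doc.get("interval", interval)
    kind = doc.get("type")
    if kind == "constant":
        return ControlPiece(a, b, doc["value"], doc["value"])
    if kind == "linear":
        return ControlPiece(a, b, doc["start"], doc["end"])
    raise ScheduleError(f"unknown control piece type {kind!r}")


def serialize_schedule(schedule: ControlSchedule, *, indent: int = 2) -> str:
    doc = {
        "domain": list(schedule.domain),
        "phases": [
            {
                "fixed": dict(phase.fixed),
                "interval": list(phase.interval),
                "control": {
                    name: (
                        _piece_to_json(pieces[0])
                        if len(pieces) == 1
                        else {"type": "pieces",
                              "pieces": [_piece_to_json(p) for p in pieces]}
                    )
                    for name, pieces in phase.control.items()
                },
            }
            for phase in schedule.phases
        ],
    }
    return json.dumps(doc, indent=indent)


def parse_schedule(document: str) -> ControlSchedule:
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ScheduleError(f"invalid schedule JSON: {exc.msg}") from None
    phases = []
    for ph in doc["phases"]:
        interval = tuple(ph["interval"])
        control = {}
        for name, cdoc in ph["control"].items():
            if cdoc.get("type") == "pieces":
                pieces = tuple(
                    _piece_from_json(p, interval) for p in cdoc["pieces"]
                )
            else:
                pieces = (_piece_from_json(cdoc, interval),)
            control[name] = pieces
        phases.append(SchedulePhase(ph.get("fixed", {}), interval, control))
    return ControlSchedule(tuple(doc["domain"]), tuple(phases))
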
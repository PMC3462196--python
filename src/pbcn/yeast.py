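"""The budding-yeast cell-cycle model and its three in-silico experiments.

The network has 13 internal nodes covering the core cell-cycle machinery of
*Saccharomyces cerevisiae* (each node may stand for several paralogous
species: Cln2 for Cln1,2; Clb5 for Clb5,6; Clb2 for Clb1,2; SMBF for the
SBF/MBF transcription factors; Yhp1 for YHP1/YOX1) and four external
inputs:

* ``CSS`` — the continuous cell-size signal, stochastic with probability
  symbol ``p``, driving Cln3;
* ``Start``, ``Bud``, ``SAC`` — binary checkpoints wired directly into the
  logic of the affected nodes: with Start unsatisfied Whi5 is forced active
  and Cln2 inactive; bud-neck formation (Bud=1) degrades Swe1; the spindle
  assembly checkpoint withholds Cdc20 until satisfied.

Phase switching never edits rule structure — only the fixed checkpoint
values change.  The four phase PBCNs are the sequential checkpoint
activations (0,0,0) -> (1,0,0) -> (1,1,0) -> (1,1,1) for G1, G1/S, G2/M and
M/G1.

Rule logic (transcribed from the qualitative interaction literature; the
full rationale is in docs/methods.md):

* Cln3 follows the cell-size signal.
* Whi5 is active pre-Start and reactivates when neither Cln3 nor Cln2
  phosphorylates it.
* SMBF activation needs an activating cyclin (Cln3 or Cln2) or persistence,
  and is repressed by Whi5, Clb2 and the mitotic-exit phosphatase Cdc14.
* Cln2 is SMBF-driven and Start-gated; Clb5 is SMBF-driven, opposed by Sic1
  and degraded via Cdc20.
* Clb2 needs its transcriptional drive (Clb5/Clb2/Mcm1), absence of the
  antagonists Sic1, Cdh1, Cdc20 and of the inhibitory kinase Swe1.
* Sic1 and Cdh1 recover when the cyclins are gone or Cdc14 resets them.
* Mcm1 follows Clb2; Cdc20 follows Clb2 once SAC is satisfied; Cdc14
  follows Cdc20; Yhp1 reports SMBF activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .control import (
    ControlSchedule,
    YEAST_CHECKPOINTS,
    yeast_default_css,
    yeast_nitrogen_css,
)
from .errors import PBCNError
from .ergodic import ErgodicSet, recurrent_classes, union_graph
from .network import NetworkSpec, parse_network, remove_regulator, serialize_network
from .stationary import (
    ActivityProfile,
    ActivityTable,
    activity_functions,
    compose_with_control,
    stationary_distribution,
    DEFAULT_SYMBOLIC_THRESHOLD,
)
from .transition import build_update_maps, transition_matrix

__all__ = [
    "YEAST_RULES",
    "YEAST_NODES",
    "KEY_CYCLINS",
    "yeast_network",
    "yeast_document",
    "phase_pbcn",
    "analyze_phase",
    "PhaseResult",
    "start_reversibility_experiment",
    "ReversibilityResult",
    "run_cycle",
    "CycleResult",
]

YEAST_NODES: tuple[str, ...] = (
    "Cln3", "Whi5", "SMBF", "Cln2", "Clb5", "Clb2",
    "Sic1", "Cdh1", "Swe1", "Mcm1", "Cdc20", "Cdc14", "Yhp1",
)

YEAST_RULES: dict[str, str] = {
    "Cln3": "CSS",
    "Whi5": "NOT Start OR NOT (Cln3 OR Cln2)",
    "SMBF": "(Cln3 OR Cln2 OR SMBF) AND NOT Whi5 AND NOT Clb2 AND NOT Cdc14",
    "Cln2": "Start AND SMBF",
    "Clb5": "SMBF AND NOT Sic1 AND NOT Cdc20",
    "Clb2": "(Clb5 OR Clb2 OR Mcm1) AND NOT Sic1 AND NOT Cdh1 "
            "AND NOT Cdc20 AND NOT Swe1",
    "Sic1": "(NOT Cln2 AND NOT Clb5 AND NOT Clb2) OR Cdc14",
    "Cdh1": "(NOT Cln2 AND NOT Clb5 AND NOT Clb2) OR Cdc14",
    "Swe1": "NOT Bud",
    "Mcm1": "Clb2",
    "Cdc20": "SAC AND Clb2",
    "Cdc14": "Cdc20",
    "Yhp1": "SMBF",
}

#: the cyclins and regulators tracked in the headline figures
KEY_CYCLINS: tuple[str, ...] = ("Cln2", "Clb5", "Clb2", "Sic1", "Cdc20")


def yeast_document(*, start: int = 0, bud: int = 0, sac: int = 0) -> str:
    """The fixture as a network-JSON document with the given checkpoints."""
    import json

    doc = {
        "name": "yeast_cell_cycle",
        "internal": [
            {"id": node, "rule": YEAST_RULES[node]} for node in YEAST_NODES
        ],
        "external": [
            {"id": "CSS", "mode": "stochastic", "symbol": "p"},
            {"id": "Start", "mode": "fixed", "value": start},
            {"id": "Bud", "mode": "fixed", "value": bud},
            {"id": "SAC", "mode": "fixed", "value": sac},
        ],
    }
    return json.dumps(doc, indent=2)


def yeast_network(*, start: int = 0, bud: int = 0, sac: int = 0) -> NetworkSpec:
    """The yeast fixture with checkpoints clamped to the given values."""
    return parse_network(yeast_document(start=start, bud=bud, sac=sac))


def phase_pbcn(fixture: NetworkSpec | None, phase: int) -> NetworkSpec:
    """The PBCN of cell-cycle phase 1..4 (G1, G1/S, G2/M, M/G1).

    ``fixture`` defaults to the bundled yeast network; a caller-modified
    fixture (e.g. after :func:`remove_regulator`) is re-clamped in place.
    """
    if phase not in (1, 2, 3, 4):
        raise PBCNError(f"invalid phase {phase!r}: must be 1..4")
    checkpoints = YEAST_CHECKPOINTS[phase - 1]
    if fixture is None:
        return yeast_network(
            start=checkpoints["Start"], bud=checkpoints["Bud"], sac=checkpoints["SAC"]
        )
    return fixture.with_fixed(**checkpoints)


@dataclass(frozen=True)
class PhaseResult:
    """Ergodic analysis of one phase PBCN."""

    phase: int
    spec: NetworkSpec
    ergodic_sets: tuple[ErgodicSet, ...]
    distributions: tuple[object, ...]  # one per ergodic set
    activity: ActivityTable  # of the first (for the yeast model: only) set
    signature: dict[str, str]

    @property
    def n_classes(self) -> int:
        return len(self.ergodic_sets)


def analyze_phase(
    fixture: NetworkSpec | None,
    phase: int,
    *,
    symbolic_threshold: int = DEFAULT_SYMBOLIC_THRESHOLD,
) -> PhaseResult:
    """Run the full pipeline on one phase PBCN: update maps, union graph,
    ergodic sets, symbolic stationary distributions, activity signatures."""
    spec = phase_pbcn(fixture, phase)
    maps = build_update_maps(spec)
    classes = recurrent_classes(union_graph(maps))
    matrix = transition_matrix(maps)
    dists = tuple(
        stationary_distribution(matrix, cls, symbolic_threshold=symbolic_threshold)
        for cls in classes
    )
    activity = activity_functions(dists[0], spec)
    signature = (
        activity.signature() if not activity.numeric
        else _sampled_signature(activity)
    )
    return PhaseResult(phase, spec, classes, dists, activity, signature)


def _sampled_signature(activity: ActivityTable, *, tol: float = 1e-9) -> dict[str, str]:
    """Signature for numeric-fallback tables: sampled constancy check."""
    grid = [0.1, 0.3, 0.5, 0.7, 0.9]
    samples = [activity.evaluate({"p": p}) for p in grid]
    out = {}
    for node in activity.spec.internal:
        vals = [s[node] for s in samples]
        if max(vals) - min(vals) > tol:
            out[node] = "p-dependent"
        elif abs(vals[0] - 1.0) <= tol:
            out[node] = "active"
        elif abs(vals[0]) <= tol:
            out[node] = "inactive"
        else:
            out[node] = "p-dependent"
    return out


@dataclass(frozen=True)
class ReversibilityResult:
    """Start-irreversibility experiment: PBCN2 with and without the Cln2 leg
    of the Whi5-SMBF-Cln2 positive feedback loop.

    With the loop intact the G1/S ergodic set pins Whi5 off and Cln2 on —
    constants, independent of the cell-size signal.  With Cln2 removed as a
    regulator of Whi5 the single ergodic set's Whi5 and Cln2 activities
    become genuine functions of p: lowering the size signal deactivates Cln2
    and reactivates Whi5, a return to G1 — Start is reversible.
    """

    baseline: PhaseResult
    modified: PhaseResult


def start_reversibility_experiment(
    *, symbolic_threshold: int = DEFAULT_SYMBOLIC_THRESHOLD
) -> ReversibilityResult:
    baseline = analyze_phase(None, 2, symbolic_threshold=symbolic_threshold)
    cut = remove_regulator(yeast_network(), "Whi5", "Cln2")
    modified = analyze_phase(cut, 2, symbolic_threshold=symbolic_threshold)
    return ReversibilityResult(baseline, modified)


@dataclass(frozen=True)
class CycleResult:
    """Whole-cycle composition: per-phase results plus the time profile."""

    phases: tuple[PhaseResult, ...]
    schedule: ControlSchedule
    profile: ActivityProfile


def run_cycle(
    fixture: NetworkSpec | None = None,
    schedule: ControlSchedule | None = None,
    *,
    nitrogen: bool = False,
    num_points: int = 1000,
    symbolic_threshold: int = DEFAULT_SYMBOLIC_THRESHOLD,
) -> CycleResult:
    """Concatenate the four phase analyses into a whole-cycle activity profile.

    Each node's profile is its phase activity function composed with the
    CSS control on that phase's quarter of the unit interval.
    """
    if schedule is None:
        schedule = yeast_nitrogen_css() if nitrogen else yeast_default_css()
    if len(schedule.phases) != 4:
        raise PBCNError("the yeast cycle schedule needs exactly four phases")
    results = tuple(
        analyze_phase(fixture, k, symbolic_threshold=symbolic_threshold)
        for k in (1, 2, 3, 4)
    )
    for res, phase in zip(results, schedule.phases):
        expected = YEAST_CHECKPOINTS[res.phase - 1]
        if dict(phase.fixed) != expected:
            raise PBCNError(
                f"schedule phase {res.phase} fixes {dict(phase.fixed)}, "
                f"expected the checkpoint configuration {expected}"
            )
    profile = compose_with_control(
        [res.activity for res in results], schedule, num_points=num_points
    )
    return CycleResult(results, schedule, profile)
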
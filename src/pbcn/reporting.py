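"""Report writers: TSV activity profiles, canonical rational-function JSON,
and machine-readable run reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import sympy as sp

from . import __version__
from .errors import PBCNError
from .stationary import ActivityProfile, ActivityTable

__all__ = [
    "write_profile_tsv",
    "read_profile_tsv",
    "rational_function_string",
    "functions_to_strings",
    "write_functions_json",
    "RunReport",
]


def write_profile_tsv(profile: ActivityProfile, path: str | Path) -> Path:
    """Write the long-form profile: ``time<TAB>node<TAB>activity``, activity
    with 6 significant digits, rows sorted by (time, node order)."""
    path = Path(path)
    long = profile.to_long()
    with path.open("w") as fh:
        fh.write("time\tnode\tactivity\n")
        for row in long.itertuples(index=False):
            fh.write(f"{row.time:.10g}\t{row.node}\t{row.activity:.6g}\n")
    return path


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    """Read a profile TSV back into a long DataFrame (time, node, activity)."""
    return pd.read_csv(path, sep="\t")


def rational_function_string(expr: sp.Expr) -> str:
    """Canonical string: expanded numerator/denominator with ordered
    monomials; constants as plain rationals."""
    expr = sp.cancel(sp.together(expr))
    if expr.is_number:
        return sp.sstr(sp.nsimplify(expr))
    num, den = sp.fraction(expr)
    num = sp.expand(num)
    den = sp.expand(den)
    if den == 1:
        return sp.sstr(num, order="lex")
    return f"({sp.sstr(num, order='lex')})/({sp.sstr(den, order='lex')})"


def functions_to_strings(table: ActivityTable) -> dict[str, str]:
    if table.numeric:
        raise PBCNError(
            "activity table is numeric (class above the symbolic threshold); "
            "no exact rational-function strings exist"
        )
    return {
        node: rational_function_string(expr)
        for node, expr in table.functions.items()
    }


def write_functions_json(table: ActivityTable, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "ergodic_set": table.ergodic_set.id,
        "states": list(table.ergodic_set.labels()),
        "activity_functions": functions_to_strings(table),
    }
    path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunReport:
    """Reproducibility record of a CLI run: inputs, seeds, outputs, warnings."""

    tool_version: str = __version__
    command: str = ""
    seed: int | None = None
    input_digests: dict[str, str] = field(default_factory=dict)
    class_summaries: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_input(self, path: str | Path) -> None:
        path = Path(path)
        self.input_digests[str(path)] = _digest(path)

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[str(path)] = _digest(path)

    def add_class(self, ergodic_set, *, signature: Mapping[str, str] | None = None,
                  numeric: bool = False) -> None:
        entry = {
            "id": ergodic_set.id,
            "size": len(ergodic_set),
            "period": ergodic_set.period,
            "states": list(ergodic_set.labels()),
        }
        if signature is not None:
            entry["signature"] = dict(signature)
        if numeric:
            entry["numeric_fallback"] = True
            self.warnings.append(
                f"{ergodic_set.id}: class above the symbolic threshold; "
                f"stationary distribution computed numerically per point"
            )
        self.class_summaries.append(entry)

    def to_json(self, *, indent: int = 2) -> str:
        return json.dumps(
            {
                "tool_version": self.tool_version,
                "command": self.command,
                "seed": self.seed,
                "inputs": self.input_digests,
                "classes": self.class_summaries,
                "outputs": self.outputs,
                "warnings": self.warnings,
            },
            indent=indent,
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n")
        return path
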
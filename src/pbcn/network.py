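"""Boolean networks with external control inputs.

A network consists of *internal* nodes, each governed by a Boolean update
rule, and *external* inputs that appear in rules but are never updated
themselves.  External inputs are either ``fixed`` (clamped to 0 or 1) or
``stochastic`` (drawn independently each step with a probability attached to
a named symbol).  The state of the chain is the internal-node vector only;
the externals select which deterministic update map acts at each step.

State encoding
--------------
Internal nodes are ordered; node 1 is the most significant bit of the state
index, so the all-zero state is index 0.  Display labels are the binary
number plus one (state ``0b00 -> label 1``).

Rules are written either as expressions over ``AND``/``OR``/``NOT`` (see
:func:`parse_expression`) or as explicit truth tables over a declared
regulator list.  Both forms are compiled eagerly to truth tables, which are
the single internal representation; the first declared/encountered
regulator is the most significant bit of the table index.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    NetworkSyntaxError,
    NetworkValidationError,
    StateSpaceCapError,
)

__all__ = [
    "BooleanRule",
    "ExternalInput",
    "ExternalConfiguration",
    "NetworkSpec",
    "StateIndex",
    "parse_expression",
    "compile_expression",
    "parse_network",
    "serialize_network",
    "encode_state",
    "decode_state",
    "enumerate_external_configs",
    "remove_regulator",
    "random_network",
]

DEFAULT_MAX_INTERNAL = 22

_IDENT_RE = re.compile(r"[A-Za-z][A-Za-z0-9_]*")
_KEYWORDS = frozenset({"AND", "OR", "NOT"})


# ---------------------------------------------------------------------------
# expression parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Token:
    kind: str  # 'ident' | 'kw' | 'lparen' | 'rparen' | 'const' | 'end'
    text: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line, col = 1, 1
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\n":
            line += 1
            col = 1
            i += 1
            continue
        if ch.isspace():
            col += 1
            i += 1
            continue
        if ch == "(":
            tokens.append(_Token("lparen", ch, line, col))
            i += 1
            col += 1
            continue
        if ch == ")":
            tokens.append(_Token("rparen", ch, line, col))
            i += 1
            col += 1
            continue
        if ch in "01":
            tokens.append(_Token("const", ch, line, col))
            i += 1
            col += 1
            continue
        m = _IDENT_RE.match(text, i)
        if m:
            word = m.group(0)
            kind = "kw" if word.upper() in _KEYWORDS else "ident"
            tokens.append(_Token(kind, word, line, col))
            col += len(word)
            i = m.end()
            continue
        raise NetworkSyntaxError(f"unexpected character {ch!r}", line, col)
    tokens.append(_Token("end", "", line, col))
    return tokens


class _Parser:
    """Recursive-descent parser for the Boolean expression grammar.

    expr := term ("OR" term)* ; term := factor ("AND" factor)* ;
    factor := "NOT" factor | "(" expr ")" | identifier | "0" | "1".
    Keywords are case-insensitive.
    """

    def __init__(self, tokens: list[_Token]):
        self._tokens = tokens
        self._pos = 0

    def _peek(self) -> _Token:
        return self._tokens[self._pos]

    def _next(self) -> _Token:
        tok = self._tokens[self._pos]
        self._pos += 1
        return tok

    def parse(self):
        node = self._expr()
        tok = self._peek()
        if tok.kind != "end":
            raise NetworkSyntaxError(
                f"unexpected token {tok.text!r}", tok.line, tok.column
            )
        return node

    def _expr(self):
        node = self._term()
        while self._peek().kind == "kw" and self._peek().text.upper() == "OR":
            self._next()
            node = ("or", node, self._term())
        return node

    def _term(self):
        node = self._factor()
        while self._peek().kind == "kw" and self._peek().text.upper() == "AND":
            self._next()
            node = ("and", node, self._factor())
        return node

    def _factor(self):
        tok = self._peek()
        if tok.kind == "kw" and tok.text.upper() == "NOT":
            self._next()
            return ("not", self._factor())
        if tok.kind == "lparen":
            self._next()
            node = self._expr()
            closing = self._next()
            if closing.kind != "rparen":
                raise NetworkSyntaxError(
                    "expected ')'", closing.line, closing.column
                )
            return node
        if tok.kind == "const":
            self._next()
            return ("const", int(tok.text))
        if tok.kind == "ident":
            self._next()
            return ("var", tok.text)
        raise NetworkSyntaxError(
            f"unexpected token {tok.text!r}" if tok.text else "unexpected end of expression",
            tok.line,
            tok.column,
        )


def parse_expression(text: str):
    """Parse a Boolean expression into an AST of nested tuples."""
    return _Parser(_tokenize(text)).parse()


def _ast_vars(node, out: list[str]) -> None:
    kind = node[0]
    if kind == "var":
        if node[1] not in out:
            out.append(node[1])
    elif kind == "not":
        _ast_vars(node[1], out)
    elif kind in ("and", "or"):
        _ast_vars(node[1], out)
        _ast_vars(node[2], out)


def _ast_eval(node, env: Mapping[str, int]) -> int:
    kind = node[0]
    if kind == "var":
        return env[node[1]]
    if kind == "const":
        return node[1]
    if kind == "not":
        return 1 - _ast_eval(node[1], env)
    if kind == "and":
        return _ast_eval(node[1], env) & _ast_eval(node[2], env)
    return _ast_eval(node[1], env) | _ast_eval(node[2], env)


def compile_expression(text: str) -> tuple[tuple[str, ...], tuple[int, ...]]:
    """Compile an expression to ``(regulators, truth_table)``.

    Regulator order is the order of first appearance in the expression; the
    first regulator is the most significant bit of the table index.
    """
    ast = parse_expression(text)
    regs: list[str] = []
    _ast_vars(ast, regs)
    k = len(regs)
    table = []
    for bits in itertools.product((0, 1), repeat=k):
        env = dict(zip(regs, bits))
        table.append(_ast_eval(ast, env))
    return tuple(regs), tuple(table)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanRule:
    """Compiled update rule for one internal node.

    ``table`` has ``2**len(regulators)`` entries indexed with the first
    regulator as the most significant bit.  ``expression`` preserves the
    source text when the rule was given as an expression.
    """

    target: str
    regulators: tuple[str, ...]
    table: tuple[int, ...]
    expression: str | None = None

    def __post_init__(self):
        if len(self.table) != 1 << len(self.regulators):
            raise NetworkValidationError(
                f"rule for {self.target!r}: truth table has {len(self.table)} rows, "
                f"expected {1 << len(self.regulators)} for {len(self.regulators)} regulators"
            )
        if any(v not in (0, 1) for v in self.table):
            raise NetworkValidationError(
                f"rule for {self.target!r}: truth table entries must be 0 or 1"
            )

    def evaluate(self, env: Mapping[str, int]) -> int:
        idx = 0
        for reg in self.regulators:
            idx = (idx << 1) | env[reg]
        return self.table[idx]


@dataclass(frozen=True)
class ExternalInput:
    """An external input: ``fixed`` at a value or ``stochastic`` with a symbol."""

    id: str
    mode: str
    value: int | None = None
    symbol: str | None = None

    def __post_init__(self):
        if self.mode not in ("fixed", "stochastic"):
            raise NetworkValidationError(
                f"external input {self.id!r}: mode must be 'fixed' or 'stochastic'"
            )
        if self.mode == "fixed" and self.value not in (0, 1):
            raise NetworkValidationError(
                f"fixed external input {self.id!r} needs a value of 0 or 1"
            )
        if self.mode == "stochastic" and not self.symbol:
            raise NetworkValidationError(
                f"stochastic external input {self.id!r} needs a probability symbol"
            )


@dataclass(frozen=True)
class StateIndex:
    """An internal state: integer index plus its display label (index + 1)."""

    value: int
    n: int

    @property
    def label(self) -> int:
        return self.value + 1


@dataclass(frozen=True)
class ExternalConfiguration:
    """A 0/1 assignment to every external input.

    Fixed inputs always carry their declared value; only stochastic inputs
    vary across the configurations of a network.
    """

    values: tuple[tuple[str, int], ...]

    @property
    def assignment(self) -> dict[str, int]:
        return dict(self.values)

    def __getitem__(self, name: str) -> int:
        return self.assignment[name]


@dataclass(frozen=True)
class NetworkSpec:
    """A validated Boolean network with external control inputs."""

    name: str
    internal: tuple[str, ...]
    external: tuple[ExternalInput, ...]
    rules: tuple[BooleanRule, ...]  # one per internal node, same order
    max_internal: int = DEFAULT_MAX_INTERNAL

    def __post_init__(self):
        _validate_spec(self)

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.internal)

    @property
    def n_states(self) -> int:
        return 1 << self.n

    @property
    def stochastic_inputs(self) -> tuple[ExternalInput, ...]:
        return tuple(e for e in self.external if e.mode == "stochastic")

    @property
    def fixed_inputs(self) -> tuple[ExternalInput, ...]:
        return tuple(e for e in self.external if e.mode == "fixed")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(e.symbol for e in self.stochastic_inputs)

    def rule_for(self, node: str) -> BooleanRule:
        try:
            return self.rules[self.internal.index(node)]
        except ValueError:
            raise NetworkValidationError(f"unknown internal node {node!r}") from None

    def node_bit(self, node: str) -> int:
        """Bit position of ``node`` (0 = most significant)."""
        return self.internal.index(node)

    def with_fixed(self, **values: int) -> "NetworkSpec":
        """Return a copy with the given fixed external inputs re-clamped."""
        ext = []
        names = {e.id for e in self.external}
        for name in values:
            if name not in names:
                raise NetworkValidationError(f"unknown external input {name!r}")
        for e in self.external:
            if e.id in values:
                if e.mode != "fixed":
                    raise NetworkValidationError(
                        f"external input {e.id!r} is stochastic; cannot clamp"
                    )
                v = values[e.id]
                if v not in (0, 1):
                    raise NetworkValidationError(
                        f"fixed value for {e.id!r} must be 0 or 1"
                    )
                ext.append(ExternalInput(e.id, "fixed", value=v))
            else:
                ext.append(e)
        return NetworkSpec(self.name, self.internal, tuple(ext), self.rules,
                           self.max_internal)


def _validate_spec(spec: NetworkSpec) -> None:
    if not spec.internal:
        raise NetworkValidationError("network needs at least one internal node")
    if len(spec.internal) > spec.max_internal:
        raise StateSpaceCapError(
            f"{len(spec.internal)} internal nodes exceeds the cap of "
            f"{spec.max_internal} (state space 2^{len(spec.internal)}); raise "
            f"max_internal explicitly if this is intended"
        )
    seen: set[str] = set()
    for name in spec.internal:
        if name in seen:
            raise NetworkValidationError(f"duplicate node {name!r}")
        seen.add(name)
    for e in spec.external:
        if e.id in seen:
            raise NetworkValidationError(f"duplicate node {e.id!r}")
        seen.add(e.id)
    if len(spec.rules) != len(spec.internal):
        raise NetworkValidationError(
            f"{len(spec.rules)} rules for {len(spec.internal)} internal nodes"
        )
    known = set(spec.internal) | {e.id for e in spec.external}
    for node, rule in zip(spec.internal, spec.rules):
        if rule.target != node:
            raise NetworkValidationError(
                f"rule order mismatch: expected rule for {node!r}, got {rule.target!r}"
            )
        for reg in rule.regulators:
            if reg not in known:
                raise NetworkValidationError(f"unknown identifier {reg!r}")


# ---------------------------------------------------------------------------
# state encoding
# ---------------------------------------------------------------------------

def encode_state(values: Sequence[int], spec: NetworkSpec) -> StateIndex:
    """Encode per-node bits (internal-node order, node 1 = MSB) as a state index."""
    if len(values) != spec.n:
        raise NetworkValidationError(
            f"expected {spec.n} bits, got {len(values)}"
        )
    idx = 0
    for v in values:
        if v not in (0, 1):
            raise NetworkValidationError("state bits must be 0 or 1")
        idx = (idx << 1) | v
    return StateIndex(idx, spec.n)


def decode_state(index: int | StateIndex, spec: NetworkSpec) -> tuple[int, ...]:
    """Decode a state index to per-node bits in internal-node order."""
    value = index.value if isinstance(index, StateIndex) else int(index)
    if not 0 <= value < spec.n_states:
        raise NetworkValidationError(
            f"state index {value} outside [0, {spec.n_states - 1}]"
        )
    return tuple((value >> (spec.n - 1 - i)) & 1 for i in range(spec.n))


def enumerate_external_configs(spec: NetworkSpec) -> list[ExternalConfiguration]:
    """All ``2**m_s`` external configurations, fixed inputs held at their values.

    The first stochastic input is the most significant bit of the enumeration
    order, so the list is stable across runs.
    """
    stoch = spec.stochastic_inputs
    fixed = {e.id: e.value for e in spec.fixed_inputs}
    configs = []
    for bits in itertools.product((0, 1), repeat=len(stoch)):
        assignment = dict(fixed)
        assignment.update({e.id: b for e, b in zip(stoch, bits)})
        configs.append(
            ExternalConfiguration(tuple((e.id, assignment[e.id]) for e in spec.external))
        )
    return configs


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def parse_network(document: str, *, max_internal: int = DEFAULT_MAX_INTERNAL) -> NetworkSpec:
    """Parse the network JSON dialect into a validated :class:`NetworkSpec`.

    See the package README for the dialect; rules may be given as expression
    strings or as ``{"regulators": [...], "table": [...]}``.
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise NetworkSyntaxError(
            f"invalid JSON: {exc.msg}", exc.lineno, exc.colno
        ) from None
    if not isinstance(doc, dict):
        raise NetworkSyntaxError("network document must be a JSON object")
    name = doc.get("name", "network")
    internal_docs = doc.get("internal")
    if not isinstance(internal_docs, list) or not internal_docs:
        raise NetworkValidationError("'internal' must be a non-empty list")
    external_docs = doc.get("external", [])

    externals = []
    for e in external_docs:
        mode = e.get("mode")
        if mode == "fixed":
            externals.append(ExternalInput(e["id"], "fixed", value=e.get("value")))
        elif mode == "stochastic":
            externals.append(ExternalInput(e["id"], "stochastic", symbol=e.get("symbol")))
        else:
            raise NetworkValidationError(
                f"external input {e.get('id')!r}: unknown mode {mode!r}"
            )

    internal = []
    rules = []
    for nd in internal_docs:
        node = nd.get("id")
        if not isinstance(node, str) or not _IDENT_RE.fullmatch(node):
            raise NetworkValidationError(f"invalid node identifier {node!r}")
        internal.append(node)
        if "rule" in nd:
            regs, table = compile_expression(nd["rule"])
            rules.append(BooleanRule(node, regs, table, expression=nd["rule"]))
        elif "table" in nd:
            regs = tuple(nd.get("regulators", ()))
            rules.append(BooleanRule(node, regs, tuple(nd["table"])))
        else:
            raise NetworkValidationError(f"node {node!r} has neither 'rule' nor 'table'")

    return NetworkSpec(name, tuple(internal), tuple(externals), tuple(rules),
                       max_internal=max_internal)


def serialize_network(spec: NetworkSpec, *, indent: int = 2) -> str:
    """Serialize to the network JSON dialect (round-trips through parse)."""
    doc = {
        "name": spec.name,
        "internal": [
            (
                {"id": r.target, "rule": r.expression}
                if r.expression is not None
                else {
                    "id": r.target,
                    "regulators": list(r.regulators),
                    "table": list(r.table),
                }
            )
            for r in spec.rules
        ],
        "external": [
            (
                {"id": e.id, "mode": "fixed", "value": e.value}
                if e.mode == "fixed"
                else {"id": e.id, "mode": "stochastic", "symbol": e.symbol}
            )
            for e in spec.external
        ],
    }
    return json.dumps(doc, indent=indent)


# ---------------------------------------------------------------------------
# structural edits
# ---------------------------------------------------------------------------

def remove_regulator(spec: NetworkSpec, target: str, regulator: str) -> NetworkSpec:
    """Remove ``regulator`` from ``target``'s rule by clamping it to 0 (inactive).

    The target's truth table is rebuilt with the regulator column fixed at 0
    and dropped from the regulator list; every other rule is untouched.
    """
    rule = spec.rule_for(target)
    if regulator not in rule.regulators:
        raise NetworkValidationError(
            f"{regulator!r} is not an upstream regulator of {target!r}"
        )
    pos = rule.regulators.index(regulator)
    new_regs = rule.regulators[:pos] + rule.regulators[pos + 1:]
    k = len(rule.regulators)
    new_table = []
    for bits in itertools.product((0, 1), repeat=k - 1):
        full = bits[:pos] + (0,) + bits[pos:]
        idx = 0
        for b in full:
            idx = (idx << 1) | b
        new_table.append(rule.table[idx])
    new_rule = BooleanRule(target, new_regs, tuple(new_table))
    rules = tuple(new_rule if r.target == target else r for r in spec.rules)
    return NetworkSpec(spec.name, spec.internal, spec.external, rules,
                       spec.max_internal)


# ---------------------------------------------------------------------------
# synthetic networks (test and benchmark material)
# ---------------------------------------------------------------------------

def random_network(
    n: int,
    m_s: int,
    rng: np.random.Generator,
    *,
    max_regulators: int = 3,
    name: str = "random",
) -> NetworkSpec:
    """Generate a random Boolean network with ``n`` internal nodes and ``m_s``
    stochastic external inputs.

    Each node draws 1..max_regulators distinct regulators uniformly from the
    internal nodes plus externals and a uniformly random truth table over
    them.  Used by the property-test suite as a source of small PBCNs.
    """
    internal = tuple(f"X{i + 1}" for i in range(n))
    externals = tuple(
        ExternalInput(f"E{j + 1}", "stochastic", symbol=f"p{j + 1}")
        for j in range(m_s)
    )
    pool = list(internal) + [e.id for e in externals]
    rules = []
    for node in internal:
        k = int(rng.integers(1, max_regulators + 1))
        k = min(k, len(pool))
        regs = tuple(rng.choice(pool, size=k, replace=False))
        table = tuple(int(b) for b in rng.integers(0, 2, size=1 << k))
        rules.append(BooleanRule(node, regs, table))
    return NetworkSpec(name, internal, externals, tuple(rules))
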
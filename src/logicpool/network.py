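"""Sign-labeled interaction graphs, Boolean update functions, and models.

A prior-knowledge network (PKN) is a directed graph whose nodes are signaling
components and whose edges carry one of four labels: an interaction can be
*essential* (it must be functional, with a known sign, in every model) or
*optional* (it may be present with the stated sign, or absent).  A Boolean
model assigns one update function per component; the set of all assignments
compatible with the labels is the model pool (see :mod:`logicpool.pools`).

The file dialect uses ASCII label tokens::

    +    essential activation
    -    essential inhibition
    +?   optional activation ("not inhibiting")
    -?   optional inhibition ("not activating")

States of an ``n``-component network are packed into integers: bit ``i`` of
the state holds the activity of component ``i`` in PKN order (order of first
mention in the file).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy
from sympy.logic import SOPform

__all__ = [
    "EdgeLabel",
    "BooleanFunction",
    "PKN",
    "Model",
    "PKNError",
    "parse_pkn",
    "write_pkn",
    "validate_pkn",
    "export_model",
    "pack_state",
    "unpack_state",
]


class PKNError(ValueError):
    """Raised for malformed PKN files or invalid network structure."""


class EdgeLabel(enum.Enum):
    """Edge label: sign (activation/inhibition) x necessity (essential/optional)."""

    ESS_POS = "+"
    ESS_NEG = "-"
    OPT_POS = "+?"
    OPT_NEG = "-?"

    @property
    def essential(self) -> bool:
        return self in (EdgeLabel.ESS_POS, EdgeLabel.ESS_NEG)

    @property
    def sign(self) -> int:
        """+1 for activating labels, -1 for inhibiting labels."""
        return 1 if self in (EdgeLabel.ESS_POS, EdgeLabel.OPT_POS) else -1

    @property
    def relaxed(self) -> "EdgeLabel":
        """The optional label with the same sign (identity on optional labels)."""
        return EdgeLabel.OPT_POS if self.sign > 0 else EdgeLabel.OPT_NEG


@dataclass(frozen=True, eq=False)
class BooleanFunction:
    """A Boolean update rule over an ordered tuple of regulators.

    The truth table is stored as an integer: bit ``j`` is the output for the
    input whose regulator values, read with the *first regulator as the most
    significant bit*, spell ``j`` in binary.  Two functions are considered
    equal when their projections onto their observable regulators coincide,
    so padding a function with variables it ignores does not create a new
    function.
    """

    regulators: tuple[str, ...]
    table: int

    def __post_init__(self):
        k = len(self.regulators)
        if len(set(self.regulators)) != k:
            raise ValueError(f"duplicate regulators: {self.regulators}")
        if not 0 <= self.table < (1 << (1 << k)):
            raise ValueError(f"table {self.table} out of range for {k} regulators")

    @property
    def k(self) -> int:
        return len(self.regulators)

    # -- evaluation ---------------------------------------------------------

    def input_index(self, values: Mapping[str, int]) -> int:
        j = 0
        for reg in self.regulators:
            j = (j << 1) | (values[reg] & 1)
        return j

    def __call__(self, values: Mapping[str, int]) -> int:
        return (self.table >> self.input_index(values)) & 1

    def output(self, j: int) -> int:
        return (self.table >> j) & 1

    # -- structural queries -------------------------------------------------

    def restrict(self, regulator: str, value: int) -> "BooleanFunction":
        """Cofactor: fix one regulator to a constant, dropping it."""
        pos = self.regulators.index(regulator)
        k = self.k
        shift = k - 1 - pos  # bit position of `regulator` within an input index
        table = 0
        for j2 in range(1 << (k - 1)):
            low = j2 & ((1 << shift) - 1)
            high = j2 >> shift
            j = (high << (shift + 1)) | (value << shift) | low
            table |= self.output(j) << j2
        regs = self.regulators[:pos] + self.regulators[pos + 1 :]
        return BooleanFunction(regs, table)

    def depends_on(self, regulator: str) -> bool:
        """True iff some context exists where flipping `regulator` flips the output."""
        if regulator not in self.regulators:
            return False
        return self.restrict(regulator, 0).table != self.restrict(regulator, 1).table

    def is_monotone(self, regulator: str, sign: int) -> bool:
        """Non-decreasing (sign=+1) or non-increasing (sign=-1) in `regulator`."""
        f0 = self.restrict(regulator, 0).table
        f1 = self.restrict(regulator, 1).table
        lo, hi = (f0, f1) if sign > 0 else (f1, f0)
        return lo & ~hi == 0

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(r for r in self.regulators if self.depends_on(r))

    def project(self, regulators: Sequence[str]) -> "BooleanFunction":
        """Restrict to a regulator subset that must contain the support."""
        f = self
        for r in self.regulators:
            if r not in regulators:
                if f.depends_on(r):
                    raise ValueError(f"cannot drop observable regulator {r!r}")
                f = f.restrict(r, 0)
        # reorder to match requested order
        order = [r for r in regulators if r in f.regulators]
        return f._reorder(tuple(order))

    def _reorder(self, regulators: tuple[str, ...]) -> "BooleanFunction":
        if regulators == self.regulators:
            return self
        assert set(regulators) == set(self.regulators)
        k = self.k
        table = 0
        for j in range(1 << k):
            vals = {
                r: (j >> (k - 1 - p)) & 1 for p, r in enumerate(regulators)
            }
            table |= self(vals) << j
        return BooleanFunction(regulators, table)

    def pad(self, regulators: Sequence[str]) -> "BooleanFunction":
        """Extend to a regulator superset (new variables are ignored)."""
        extra = [r for r in regulators if r not in self.regulators]
        regs = tuple(regulators)
        if set(regs) != set(self.regulators) | set(extra):
            raise ValueError("pad target must be a superset of current regulators")
        k = len(regs)
        table = 0
        for j in range(1 << k):
            vals = {r: (j >> (k - 1 - p)) & 1 for p, r in enumerate(regs)}
            table |= self(vals) << j
        return BooleanFunction(regs, table)

    def canonical(self) -> "BooleanFunction":
        """Projection onto the support — the representative used for equality."""
        return self.project(self.support)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanFunction):
            return NotImplemented
        a, b = self.canonical(), other.canonical()
        return a.regulators == b.regulators and a.table == b.table

    def __hash__(self) -> int:
        c = self.canonical()
        return hash((c.regulators, c.table))

    # -- construction & rendering -------------------------------------------

    @classmethod
    def constant(cls, value: int) -> "BooleanFunction":
        return cls((), 1 if value else 0)

    @classmethod
    def identity(cls, regulator: str) -> "BooleanFunction":
        return cls((regulator,), 0b10)

    @classmethod
    def from_expr(cls, expr: str, regulators: Sequence[str]) -> "BooleanFunction":
        """Parse a formula over ``& | ! ( ) 0 1`` and regulator names."""
        ast = _parse_bool_expr(expr)
        names = _expr_names(ast)
        unknown = names - set(regulators)
        if unknown:
            raise PKNError(f"unknown regulator(s) in expression: {sorted(unknown)}")
        regs = tuple(regulators)
        k = len(regs)
        table = 0
        for j in range(1 << k):
            vals = {r: (j >> (k - 1 - p)) & 1 for p, r in enumerate(regs)}
            table |= _eval_bool_expr(ast, vals) << j
        return cls(regs, table)

    def to_expr(self) -> str:
        """Minimal-DNF rendering over the support, e.g. ``EGFR & !Sora``."""
        f = self.canonical()
        if f.k == 0:
            return str(f.table & 1)
        syms = sympy.symbols(" ".join(f.regulators)) if f.k > 1 else (
            sympy.Symbol(f.regulators[0]),
        )
        if not isinstance(syms, (list, tuple)):
            syms = (syms,)
        minterms = [
            [(j >> (f.k - 1 - p)) & 1 for p in range(f.k)]
            for j in range(1 << f.k)
            if f.output(j)
        ]
        expr = SOPform(list(syms), minterms)
        return str(expr).replace("~", "!")

    def literal_count(self) -> int:
        """Number of literals in the minimal-DNF rendering (0 for constants)."""
        f = self.canonical()
        if f.k == 0:
            return 0
        expr = self.to_expr()
        return len(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", expr))

    def __repr__(self) -> str:
        return f"BooleanFunction({self.to_expr()!r} over {list(self.regulators)})"


# -- tiny recursive-descent parser for function/PKN expressions -------------

_TOKEN_RE = re.compile(r"\s*(?:([A-Za-z_][A-Za-z0-9_]*)|([01])|([&|!()]))")


def _tokenize(expr: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m or m.end() == pos:
            if expr[pos:].strip():
                raise PKNError(f"bad token near {expr[pos:pos+10]!r}")
            break
        tokens.append(m.group(1) or m.group(2) or m.group(3))
        pos = m.end()
    return tokens


def _parse_bool_expr(expr: str):
    tokens = _tokenize(expr)
    if not tokens:
        raise PKNError("empty expression")
    pos = [0]

    def peek():
        return tokens[pos[0]] if pos[0] < len(tokens) else None

    def take():
        t = peek()
        pos[0] += 1
        return t

    def parse_or():
        node = parse_and()
        while peek() == "|":
            take()
            node = ("or", node, parse_and())
        return node

    def parse_and():
        node = parse_not()
        while peek() == "&":
            take()
            node = ("and", node, parse_not())
        return node

    def parse_not():
        if peek() == "!":
            take()
            return ("not", parse_not())
        return parse_atom()

    def parse_atom():
        t = take()
        if t == "(":
            node = parse_or()
            if take() != ")":
                raise PKNError("unbalanced parentheses")
            return node
        if t in ("0", "1"):
            return ("const", int(t))
        if t is None or t in "&|!)":
            raise PKNError(f"unexpected token {t!r}")
        return ("var", t)

    node = parse_or()
    if pos[0] != len(tokens):
        raise PKNError(f"trailing tokens: {tokens[pos[0]:]}")
    return node


def _expr_names(node) -> set[str]:
    op = node[0]
    if op == "var":
        return {node[1]}
    if op == "const":
        return set()
    return set().union(*(_expr_names(c) for c in node[1:]))


def _eval_bool_expr(node, values: Mapping[str, int]) -> int:
    op = node[0]
    if op == "var":
        return values[node[1]]
    if op == "const":
        return node[1]
    if op == "not":
        return 1 - _eval_bool_expr(node[1], values)
    a = _eval_bool_expr(node[1], values)
    b = _eval_bool_expr(node[2], values)
    return a & b if op == "and" else a | b


# -- PKN ---------------------------------------------------------------------


@dataclass
class PKN:
    """Prior-knowledge network: components, labeled edges, optional pinned rules.

    ``components`` fixes the bit order of states; ``edges`` maps an ordered
    (source, target) pair to its label; ``fixed_functions`` pins the update
    rule of a component whose regulation is fully known.
    """

    components: list[str]
    edges: dict[tuple[str, str], EdgeLabel] = field(default_factory=dict)
    fixed_functions: dict[str, "BooleanFunction"] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.components)

    def index(self, component: str) -> int:
        return self.components.index(component)

    @property
    def component_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.components)}

    def regulators_of(self, component: str) -> tuple[str, ...]:
        """Candidate regulators of a component, in PKN component order."""
        srcs = {u for (u, v) in self.edges if v == component}
        return tuple(c for c in self.components if c in srcs)

    def in_labels(self, component: str) -> dict[str, EdgeLabel]:
        return {
            u: lab for (u, v), lab in self.edges.items() if v == component
        }

    def optional_edges(self) -> list[tuple[str, str]]:
        order = self.component_index
        return sorted(
            (e for e, lab in self.edges.items() if not lab.essential),
            key=lambda e: (order[e[1]], order[e[0]]),
        )

    def copy(self) -> "PKN":
        return PKN(list(self.components), dict(self.edges), dict(self.fixed_functions))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PKN):
            return NotImplemented
        return (
            self.components == other.components
            and self.edges == other.edges
            and self.fixed_functions == other.fixed_functions
        )


def pack_state(bits: Mapping[str, int] | Sequence[int], pkn: PKN) -> int:
    """Pack per-component activities into the integer state representation."""
    if isinstance(bits, Mapping):
        values = [bits[c] for c in pkn.components]
    else:
        values = list(bits)
    if len(values) != pkn.n:
        raise ValueError("state length does not match component count")
    s = 0
    for i, b in enumerate(values):
        s |= (b & 1) << i
    return s


def unpack_state(s: int, pkn: PKN) -> dict[str, int]:
    if not 0 <= s < (1 << pkn.n):
        raise ValueError(f"state {s} out of range")
    return {c: (s >> i) & 1 for i, c in enumerate(pkn.components)}


# -- Model -------------------------------------------------------------------


@dataclass(frozen=True)
class Model:
    """One Boolean network: a complete assignment component -> update function."""

    assignment: Mapping[str, BooleanFunction]

    def __getitem__(self, component: str) -> BooleanFunction:
        return self.assignment[component]

    def components(self) -> tuple[str, ...]:
        return tuple(self.assignment)


# -- PKN file I/O ------------------------------------------------------------

_LABEL_TOKENS = {lab.value: lab for lab in EdgeLabel}
_EDGE_RE = re.compile(
    r"^(?P<src>\S+)\s*->\s*(?P<tgt>\S+)\s+(?P<label>\S+)$"
)
_FUNC_RE = re.compile(r"^function\s+(?P<tgt>\S+)\s*=\s*(?P<expr>.+)$")
_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def parse_pkn(text: str) -> PKN:
    """Parse the edge-list PKN dialect; component order = order of first mention."""
    components: list[str] = []
    edges: dict[tuple[str, str], EdgeLabel] = {}
    func_lines: list[tuple[int, str, str]] = []

    def declare(name: str, lineno: int) -> None:
        if not _NAME_RE.match(name):
            raise PKNError(f"line {lineno}: invalid component name {name!r}")
        if name not in components:
            components.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _FUNC_RE.match(line)
        if m:
            func_lines.append((lineno, m.group("tgt"), m.group("expr")))
            continue
        m = _EDGE_RE.match(line)
        if not m:
            raise PKNError(f"line {lineno}: cannot parse {line!r}")
        src, tgt, token = m.group("src"), m.group("tgt"), m.group("label")
        if token not in _LABEL_TOKENS:
            raise PKNError(
                f"line {lineno}: malformed label {token!r} (expected +, -, +?, -?)"
            )
        declare(src, lineno)
        declare(tgt, lineno)
        if (src, tgt) in edges:
            raise PKNError(f"line {lineno}: duplicate edge {src} -> {tgt}")
        edges[(src, tgt)] = _LABEL_TOKENS[token]

    pkn = PKN(components, edges)
    for lineno, tgt, expr in func_lines:
        if tgt not in components:
            raise PKNError(f"line {lineno}: function for unknown component {tgt!r}")
        regs = pkn.regulators_of(tgt)
        try:
            f = BooleanFunction.from_expr(expr, regs)
        except PKNError as exc:
            raise PKNError(f"line {lineno}: {exc}") from exc
        pkn.fixed_functions[tgt] = f

    diagnostics = validate_pkn(pkn)
    if diagnostics:
        raise PKNError("; ".join(diagnostics))
    return pkn


def write_pkn(pkn: PKN) -> str:
    """Render a PKN in the file dialect (inverse of :func:`parse_pkn`).

    Edges are emitted so that the order of first mention reproduces
    ``pkn.components``.
    """
    order = pkn.component_index
    lines = []
    # Ensure first mention order: emit, for each component in order, one edge
    # that mentions it as early as possible, then the rest.
    edges = sorted(pkn.edges, key=lambda e: (max(order[e[0]], order[e[1]]),
                                             order[e[1]], order[e[0]]))
    for (u, v) in edges:
        lines.append(f"{u} -> {v} {pkn.edges[(u, v)].value}")
    for tgt in pkn.components:
        if tgt in pkn.fixed_functions:
            lines.append(f"function {tgt} = {pkn.fixed_functions[tgt].to_expr()}")
    return "\n".join(lines) + "\n"


def validate_pkn(pkn: PKN) -> list[str]:
    """Structural diagnostics; empty list iff the PKN is well-formed."""
    from .pools import label_admits  # local import to avoid a cycle

    diags: list[str] = []
    seen = set()
    for c in pkn.components:
        if not _NAME_RE.match(c):
            diags.append(f"invalid component name {c!r}")
        if c in seen:
            diags.append(f"duplicate component {c!r}")
        seen.add(c)
    for (u, v), lab in pkn.edges.items():
        for endpoint in (u, v):
            if endpoint not in pkn.components:
                diags.append(f"edge ({u},{v}): unknown component {endpoint!r}")
    for c in pkn.components:
        if not pkn.regulators_of(c) and c not in pkn.fixed_functions:
            diags.append(
                f"component {c!r} has no regulators and no fixed function"
            )
    for c, f in pkn.fixed_functions.items():
        regs = pkn.regulators_of(c)
        if set(f.regulators) - set(regs):
            diags.append(
                f"fixed function of {c!r} uses non-regulators "
                f"{sorted(set(f.regulators) - set(regs))}"
            )
            continue
        g = f.pad(regs) if set(f.regulators) != set(regs) else f._reorder(regs)
        for u, lab in pkn.in_labels(c).items():
            if not label_admits(g, u, lab):
                diags.append(
                    f"fixed function of {c!r} violates label "
                    f"{lab.value!r} of edge ({u},{c})"
                )
    return diags


def export_model(model: Model, pkn: PKN | None = None) -> str:
    """Render one model as bnet text: ``target, minimal-DNF factors`` per line."""
    names = list(pkn.components) if pkn is not None else list(model.assignment)
    lines = []
    for c in names:
        lines.append(f"{c}, {model[c].to_expr()}")
    return "\n".join(lines) + "\n"
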
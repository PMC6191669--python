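"""CTL queries over asynchronous Boolean dynamics, and pool filtering.

The query dialect is one named formula per logical line::

    WB.DMSO: EF(AG(mTORC1=1)) IS:Sora=0

Atoms are ``component=0|1``; ``Delta=0`` is the reserved steady-state atom
(the conjoined state must be a fixed point).  Connectives are ``& | !`` and
the temporal operators ``EF`` (exists finally) and ``AG`` (always globally).
The ``IS:`` clause pins components in the initial state; a model satisfies a
query when some state consistent with the clause satisfies the formula
(existential semantics, the default) or when all such states do (universal).

Satisfaction sets are computed by backward fixpoints over the bit-parallel
transition system: EF is the least fixpoint of S -> Sat(phi) | pre(S) and
AG phi = !EF(!phi).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    StateSet,
    TransitionSystem,
    _component_pattern,
    function_state_mask,
)
from .network import PKN, Model
from .pools import ModelPool

__all__ = [
    "Atom",
    "Fix",
    "Not",
    "And",
    "Or",
    "EF",
    "AG",
    "Query",
    "QueryError",
    "parse_queries",
    "format_query",
    "satisfying_states",
    "steady_as_fixed_point",
    "check_model",
    "filter_pool",
    "AnnotatedPool",
    "SubPool",
    "intersect_pools",
]


class QueryError(ValueError):
    """Raised for malformed query text or atoms unknown to the network."""


# -- AST ----------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    component: str
    value: int


@dataclass(frozen=True)
class Fix:
    """Reserved steady-state atom: holds exactly at fixed points."""


@dataclass(frozen=True)
class Not:
    child: object


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


@dataclass(frozen=True)
class EF:
    child: object


@dataclass(frozen=True)
class AG:
    child: object


@dataclass(frozen=True)
class Query:
    name: str
    formula: object
    init: Mapping[str, int] = field(default_factory=dict)


_RESERVED_TEMPORAL = {"AF", "EG", "AX", "EX", "EU", "AU"}
_FIX_ATOM = "Delta"


# -- parsing ------------------------------------------------------------------

_QTOKEN_RE = re.compile(r"\s*(?:([A-Za-z_][A-Za-z0-9_.]*)|([01])|([=&|!()]))")
_NAME_LINE_RE = re.compile(r"^\s*(?!IS\s*:)([A-Za-z_][A-Za-z0-9_.]*)\s*:")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _QTOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise QueryError(f"bad token near {text[pos:pos+12]!r}")
            break
        tokens.append(m.group(1) or m.group(2) or m.group(3))
        pos = m.end()
    return tokens


def _parse_formula(text: str, aliases: Mapping[str, str] | None = None):
    aliases = aliases or {}
    tokens = _tokenize(text)
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
            rhs = parse_and()
            node = Or((node, rhs))
        return node

    def parse_and():
        node = parse_unary()
        while peek() == "&":
            take()
            rhs = parse_unary()
            node = And((node, rhs))
        return node

    def parse_unary():
        t = peek()
        if t == "!":
            take()
            return Not(parse_unary())
        if t in ("EF", "AG"):
            take()
            if take() != "(":
                raise QueryError(f"{t} must be followed by '('")
            node = parse_or()
            if take() != ")":
                raise QueryError("unbalanced parentheses")
            return EF(node) if t == "EF" else AG(node)
        if t in _RESERVED_TEMPORAL:
            raise QueryError(f"temporal operator {t} is reserved but not supported")
        return parse_atom()

    def parse_atom():
        t = take()
        if t == "(":
            node = parse_or()
            if take() != ")":
                raise QueryError("unbalanced parentheses")
            return node
        if t is None or t in "=&|!()01":
            raise QueryError(f"unexpected token {t!r}")
        name = t
        if take() != "=":
            raise QueryError(f"expected '=' after atom name {name!r}")
        v = take()
        if v not in ("0", "1"):
            raise QueryError(f"atom value must be 0 or 1, got {v!r}")
        if name == _FIX_ATOM:
            if v != "0":
                raise QueryError("Delta=1 is not a valid atom (only Delta=0)")
            return Fix()
        return Atom(aliases.get(name, name), int(v))

    node = parse_or()
    if pos[0] != len(tokens):
        raise QueryError(f"trailing tokens: {tokens[pos[0]:]}")
    return node


def _parse_init(text: str, aliases: Mapping[str, str] | None = None) -> dict[str, int]:
    aliases = aliases or {}
    init: dict[str, int] = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        m = re.match(r"^([A-Za-z_][A-Za-z0-9_.]*)\s*=\s*([01])$", part)
        if not m:
            raise QueryError(f"malformed IS assignment {part!r}")
        init[aliases.get(m.group(1), m.group(1))] = int(m.group(2))
    return init


def parse_queries(
    text: str, aliases: Mapping[str, str] | None = None
) -> list[Query]:
    """Parse a query file; whitespace-insensitive, continuation lines allowed.

    A new query starts at a line of the form ``NAME:`` (the token ``IS:`` does
    not start a query); all other lines continue the current one.
    """
    blocks: list[list[str]] = []
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.strip().startswith("#"):
            continue
        if _NAME_LINE_RE.match(line):
            blocks.append([line])
        else:
            if not blocks:
                raise QueryError("query text must start with 'NAME: formula'")
            blocks[-1].append(line)

    queries = []
    for block in blocks:
        joined = " ".join(block)
        m = _NAME_LINE_RE.match(joined)
        name = m.group(1)
        body = joined[m.end():]
        is_match = re.search(r"\bIS\s*:", body)
        if is_match:
            formula_text = body[: is_match.start()]
            init = _parse_init(body[is_match.end():], aliases)
        else:
            formula_text, init = body, {}
        queries.append(Query(name, _parse_formula(formula_text, aliases), init))
    names = [q.name for q in queries]
    if len(set(names)) != len(names):
        raise QueryError("duplicate query names")
    return queries


def format_formula(node) -> str:
    if isinstance(node, Atom):
        return f"{node.component}={node.value}"
    if isinstance(node, Fix):
        return "Delta=0"
    if isinstance(node, Not):
        return f"!({format_formula(node.child)})"
    if isinstance(node, And):
        return "&".join(format_formula(c) for c in node.children)
    if isinstance(node, Or):
        return "|".join(
            f"({format_formula(c)})" if isinstance(c, And) else format_formula(c)
            for c in node.children
        )
    if isinstance(node, EF):
        return f"EF({format_formula(node.child)})"
    if isinstance(node, AG):
        return f"AG({format_formula(node.child)})"
    raise TypeError(f"not a formula node: {node!r}")


def format_query(q: Query) -> str:
    txt = f"{q.name}: {format_formula(q.formula)}"
    if q.init:
        txt += " IS:" + ",".join(f"{c}={b}" for c, b in q.init.items())
    return txt


def steady_as_fixed_point(obj):
    """Rewrite steady-state encodings EF(AG(X)) into EF(Delta=0 & X).

    ``EF(AG(X))`` accepts any reachable region (including cycling attractors)
    on which X stays true; the fixed-point form additionally requires the
    region to be a single steady state.  Model checkers that encode
    persistence through a steady-state flag decide the latter, so the two
    encodings can give different pool counts; this rewrite converts a parsed
    query (or bare formula) to the fixed-point reading.  Only ``AG`` nodes
    whose body is purely propositional are rewritten.
    """
    if isinstance(obj, Query):
        return Query(obj.name, steady_as_fixed_point(obj.formula), obj.init)
    node = obj
    if isinstance(node, AG) and _propositional(node.child):
        return And((Fix(), node.child))
    if isinstance(node, (Atom, Fix)):
        return node
    if isinstance(node, Not):
        return Not(steady_as_fixed_point(node.child))
    if isinstance(node, And):
        return And(tuple(steady_as_fixed_point(c) for c in node.children))
    if isinstance(node, Or):
        return Or(tuple(steady_as_fixed_point(c) for c in node.children))
    if isinstance(node, EF):
        return EF(steady_as_fixed_point(node.child))
    if isinstance(node, AG):
        return AG(steady_as_fixed_point(node.child))
    raise TypeError(f"not a formula node: {node!r}")


def _propositional(node) -> bool:
    if isinstance(node, (Atom, Fix)):
        return True
    if isinstance(node, Not):
        return _propositional(node.child)
    if isinstance(node, (And, Or)):
        return all(_propositional(c) for c in node.children)
    return False


def formula_atoms(node) -> set[str]:
    if isinstance(node, Atom):
        return {node.component}
    if isinstance(node, Fix):
        return set()
    if isinstance(node, Not):
        return formula_atoms(node.child)
    if isinstance(node, (EF, AG)):
        return formula_atoms(node.child)
    if isinstance(node, (And, Or)):
        return set().union(*(formula_atoms(c) for c in node.children))
    raise TypeError(f"not a formula node: {node!r}")


def validate_query(q: Query, pkn: PKN) -> None:
    unknown = (formula_atoms(q.formula) | set(q.init)) - set(pkn.components)
    if unknown:
        raise QueryError(
            f"query {q.name!r} uses unknown component(s) {sorted(unknown)}"
        )


# -- model checking -----------------------------------------------------------


def _sat_mask(ts: TransitionSystem, node, comp_index: Mapping[str, int]) -> int:
    if isinstance(node, Atom):
        p = _component_pattern(ts.n, comp_index[node.component])
        return p if node.value else ~p & ts.full
    if isinstance(node, Fix):
        return ts.fixed_mask
    if isinstance(node, Not):
        return ~_sat_mask(ts, node.child, comp_index) & ts.full
    if isinstance(node, And):
        m = ts.full
        for c in node.children:
            m &= _sat_mask(ts, c, comp_index)
        return m
    if isinstance(node, Or):
        m = 0
        for c in node.children:
            m |= _sat_mask(ts, c, comp_index)
        return m
    if isinstance(node, EF):
        sat = _sat_mask(ts, node.child, comp_index)
        while True:
            grown = sat | ts.pre_exists_mask(sat)
            if grown == sat:
                return sat
            sat = grown
    if isinstance(node, AG):
        inner = _sat_mask(ts, Not(node.child), comp_index)
        sat = inner
        while True:
            grown = sat | ts.pre_exists_mask(sat)
            if grown == sat:
                break
            sat = grown
        return ~sat & ts.full  # AG phi = !EF(!phi)
    raise TypeError(f"not a formula node: {node!r}")


def satisfying_states(pkn: PKN, model: Model, formula) -> StateSet:
    """States of the model's totalized STG that satisfy a CTL formula."""
    ts = TransitionSystem(pkn, model)
    return StateSet(pkn.n, _sat_mask(ts, formula, pkn.component_index))


def _init_mask(ts: TransitionSystem, init: Mapping[str, int],
               comp_index: Mapping[str, int]) -> int:
    m = ts.full
    for comp, bit in init.items():
        p = _component_pattern(ts.n, comp_index[comp])
        m &= p if bit else ~p & ts.full
    return m


def check_model(
    pkn: PKN, model: Model, query: Query, universal: bool = False
) -> bool:
    """Decide a query for one model (existential initial states by default)."""
    validate_query(query, pkn)
    ts = TransitionSystem(pkn, model)
    return _check_ts(ts, query, pkn.component_index, universal)


def _check_ts(ts, query, comp_index, universal):
    sat = _sat_mask(ts, query.formula, comp_index)
    init = _init_mask(ts, query.init, comp_index)
    if universal:
        return init & ~sat == 0
    return sat & init != 0


# -- pool filtering -----------------------------------------------------------


@dataclass
class AnnotatedPool:
    """Model pool plus per-model annotation bits.

    ``table`` has one row per model: ``id``, one ``q_<name>`` validity column
    per checked query, and (once edge annotation ran) one ``edge_<src>__<tgt>``
    presence column per optional edge plus ``n_opt_edges``.
    """

    pool: ModelPool
    table: pd.DataFrame
    queries: list[Query] = field(default_factory=list)

    def query_counts(self) -> dict[str, int]:
        return {
            q.name: int(self.table[f"q_{q.name}"].sum()) for q in self.queries
        }

    def subpool(self, query_names: Sequence[str] | None = None) -> "SubPool":
        """Models whose validity bit is 1 for every named query."""
        mask = np.ones(len(self.table), dtype=bool)
        for name in query_names if query_names is not None else [
            q.name for q in self.queries
        ]:
            col = f"q_{name}"
            if col not in self.table.columns:
                raise KeyError(f"no validity bits for query {name!r}")
            mask &= self.table[col].to_numpy(dtype=bool)
        ids = self.table.loc[mask, "id"].to_numpy()
        return SubPool(self.pool, np.sort(ids))


@dataclass
class SubPool:
    """A subset of a pool, by sorted model id."""

    pool: ModelPool
    ids: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def __and__(self, other: "SubPool") -> "SubPool":
        return intersect_pools(self, other)


def intersect_pools(a: SubPool, b: SubPool) -> SubPool:
    if a.pool.pkn != b.pool.pkn:
        raise ValueError("subpools over different networks cannot be intersected")
    return SubPool(a.pool, np.intersect1d(a.ids, b.ids))


def filter_pool(
    pool: ModelPool,
    queries: Sequence[Query],
    universal: bool = False,
    progress: bool = False,
) -> AnnotatedPool:
    """Model-check every model of the pool against every query.

    Per-component transition masks are precomputed once per admissible
    function choice, so building a model's transition system is a table
    lookup; the CTL fixpoints run on packed integer state sets.
    """
    pkn = pool.pkn
    for q in queries:
        validate_query(q, pkn)
    comp_index = pkn.component_index
    n = pkn.n
    # one state mask per (component, function choice)
    choice_masks = {
        c: [function_state_mask(pkn, f) for f in pool.choices[c]]
        for c in pkn.components
    }
    size = len(pool)
    bits = {q.name: np.zeros(size, dtype=np.uint8) for q in queries}
    for model_id in range(size):
        digs = pool.digits(model_id)
        fmasks = [
            choice_masks[c][d] for c, d in zip(pkn.components, digs)
        ]
        ts = TransitionSystem.from_masks(n, fmasks)
        for q in queries:
            if _check_ts(ts, q, comp_index, universal):
                bits[q.name][model_id] = 1
        if progress and model_id % 2000 == 1999:
            print(f"  checked {model_id + 1}/{size} models", flush=True)
    columns = {"id": np.arange(size, dtype=np.int64)}
    columns.update({f"q_{q.name}": bits[q.name] for q in queries})
    table = pd.DataFrame(columns)
    return AnnotatedPool(pool, table, list(queries))
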
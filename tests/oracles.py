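"""Independent brute-force oracles used to cross-check the engine.

These deliberately avoid the package's bit-parallel machinery: the CTL oracle
builds an explicit state transition graph edge by edge and decides EF/AG by
graph reachability over it; the admissibility oracle filters every one of the
2^(2^k) truth tables by checking the monotonicity/observability definitions
pointwise over all regulator contexts.
"""

from __future__ import annotations

import networkx as nx

from logicpool.network import PKN, BooleanFunction, EdgeLabel, Model
from logicpool.queries import AG, And, Atom, EF, Fix, Not, Or, Query


def explicit_stg(pkn: PKN, model: Model) -> nx.DiGraph:
    """Totalized asynchronous STG built by direct per-state evaluation."""
    g = nx.DiGraph()
    n = pkn.n
    for s in range(1 << n):
        g.add_node(s)
        values = {c: (s >> i) & 1 for i, c in enumerate(pkn.components)}
        moved = False
        for i, c in enumerate(pkn.components):
            if model[c](values) != values[c]:
                g.add_edge(s, s ^ (1 << i))
                moved = True
        if not moved:
            g.add_edge(s, s)  # fixed point self-loop
    return g


def oracle_sat(pkn: PKN, model: Model, formula) -> set[int]:
    """States satisfying a CTL formula, by explicit-graph reachability."""
    g = explicit_stg(pkn, model)
    n = pkn.n
    all_states = set(range(1 << n))

    def sat(node) -> set[int]:
        if isinstance(node, Atom):
            i = pkn.index(node.component)
            return {s for s in all_states if (s >> i) & 1 == node.value}
        if isinstance(node, Fix):
            return {s for s in all_states if list(g.successors(s)) == [s]}
        if isinstance(node, Not):
            return all_states - sat(node.child)
        if isinstance(node, And):
            out = all_states
            for c in node.children:
                out = out & sat(c)
            return out
        if isinstance(node, Or):
            out = set()
            for c in node.children:
                out |= sat(c)
            return out
        if isinstance(node, EF):
            target = sat(node.child)
            return {
                s
                for s in all_states
                if s in target or target & nx.descendants(g, s)
            }
        if isinstance(node, AG):
            good = sat(node.child)
            return {
                s
                for s in all_states
                if s in good and nx.descendants(g, s) <= good
            }
        raise TypeError(f"unknown node {node!r}")

    return sat(formula)


def oracle_check(pkn: PKN, model: Model, query: Query, universal=False) -> bool:
    sat = oracle_sat(pkn, model, query.formula)
    init = set(range(1 << pkn.n))
    for comp, bit in query.init.items():
        i = pkn.index(comp)
        init = {s for s in init if (s >> i) & 1 == bit}
    if universal:
        return init <= sat
    return bool(init & sat)


def oracle_admits(table: int, k: int, pos: int, label: EdgeLabel) -> bool:
    """Definition-level admissibility check for regulator at position ``pos``.

    Loops over every context of the other regulators; input indices read the
    first regulator as the most significant bit.
    """
    shift = k - 1 - pos
    increases = decreases = False
    for j in range(1 << k):
        if (j >> shift) & 1:
            continue  # enumerate contexts via the regulator=0 input
        j1 = j | (1 << shift)
        lo = (table >> j) & 1
        hi = (table >> j1) & 1
        if lo < hi:
            increases = True
        if lo > hi:
            decreases = True
    if label.sign > 0 and decreases:
        return False
    if label.sign < 0 and increases:
        return False
    if label.essential and not (increases or decreases):
        return False
    return True


def oracle_admissible_tables(labels: list[EdgeLabel]) -> list[int]:
    """All 2^(2^k) tables filtered by the definition-level check."""
    k = len(labels)
    return [
        t
        for t in range(1 << (1 << k))
        if all(oracle_admits(t, k, pos, lab) for pos, lab in enumerate(labels))
    ]
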
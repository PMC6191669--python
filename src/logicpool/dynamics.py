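"""Asynchronous dynamics: successors, fixed points, bit-parallel state sets.

The asynchronous state transition graph (STG) of an ``n``-component model has
2^n states; a transition flips exactly one component whose update function
disagrees with its current value.  Fixed points receive a self-loop so the
transition relation is total (a Kripke structure), which is what makes
``EF(AG(...))`` steady-state queries satisfiable.

Subsets of the state space are manipulated as Python integers with one
membership bit per state (bit s <=> state s in the set); the existential
predecessor operator needed by CTL fixpoints is then a per-component bit
shuffle of the membership mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .network import PKN, BooleanFunction, Model

__all__ = [
    "StateSet",
    "TransitionSystem",
    "async_successors",
    "is_fixed_point",
    "stg_edges",
    "write_stg",
]

_MAX_COMPONENTS = 24


def _component_pattern(n: int, i: int) -> int:
    """Bitmask over state indices s in [0, 2^n) with bit i of s set."""
    b = 1 << i
    pat = ((1 << b) - 1) << b  # one period: low half 0, high half 1
    size = 2 * b
    total = 1 << n
    while size < total:
        pat |= pat << size
        size *= 2
    return pat


def function_state_mask(pkn: PKN, f: BooleanFunction) -> int:
    """Bitmask over all states s where f evaluates to 1."""
    n = pkn.n
    idx = pkn.component_index
    states = np.arange(1 << n, dtype=np.uint32)
    k = len(f.regulators)
    j = np.zeros_like(states)
    for pos, reg in enumerate(f.regulators):
        bit = (states >> np.uint32(idx[reg])) & 1
        j |= bit << np.uint32(k - 1 - pos)
    bits = np.array([(f.table >> t) & 1 for t in range(1 << k)], dtype=np.uint8)
    out = bits[j]
    return int.from_bytes(np.packbits(out, bitorder="little").tobytes(), "little")


@dataclass(frozen=True)
class StateSet:
    """An immutable subset of the 2^n state space with bit-parallel set algebra."""

    n: int
    mask: int

    def __post_init__(self):
        if not 0 <= self.mask < (1 << (1 << self.n)):
            raise ValueError("mask out of range for state-space size")

    @classmethod
    def empty(cls, n: int) -> "StateSet":
        return cls(n, 0)

    @classmethod
    def full(cls, n: int) -> "StateSet":
        return cls(n, (1 << (1 << n)) - 1)

    @classmethod
    def from_states(cls, n: int, states: Iterable[int]) -> "StateSet":
        mask = 0
        for s in states:
            mask |= 1 << s
        return cls(n, mask)

    def _check(self, other: "StateSet") -> None:
        if self.n != other.n:
            raise ValueError("state sets over different state spaces")

    def __or__(self, other: "StateSet") -> "StateSet":
        self._check(other)
        return StateSet(self.n, self.mask | other.mask)

    def __and__(self, other: "StateSet") -> "StateSet":
        self._check(other)
        return StateSet(self.n, self.mask & other.mask)

    def __sub__(self, other: "StateSet") -> "StateSet":
        self._check(other)
        return StateSet(self.n, self.mask & ~other.mask)

    def __invert__(self) -> "StateSet":
        return StateSet(self.n, ~self.mask & ((1 << (1 << self.n)) - 1))

    def __contains__(self, state: int) -> bool:
        return bool((self.mask >> state) & 1)

    def __len__(self) -> int:
        return self.mask.bit_count()

    def __bool__(self) -> bool:
        return self.mask != 0

    def __iter__(self) -> Iterator[int]:
        m, s = self.mask, 0
        while m:
            if m & 1:
                yield s
            m >>= 1
            s += 1

    def issubset(self, other: "StateSet") -> bool:
        self._check(other)
        return self.mask & ~other.mask == 0


class TransitionSystem:
    """Totalized asynchronous STG of one model, in bit-parallel form.

    Precomputes, per component i, the mask of states where component i is
    enabled to flip; predecessor computation then reduces to shifting the
    target-set mask by 2^i within the half-spaces where bit i is 0/1.
    """

    def __init__(self, pkn: PKN, model: Model):
        fmasks = [function_state_mask(pkn, model[c]) for c in pkn.components]
        self._init_from_masks(pkn.n, fmasks)
        self.pkn = pkn

    @classmethod
    def from_masks(cls, n: int, fmasks: list[int]) -> "TransitionSystem":
        obj = cls.__new__(cls)
        obj._init_from_masks(n, fmasks)
        obj.pkn = None
        return obj

    def _init_from_masks(self, n: int, fmasks: list[int]) -> None:
        if n > _MAX_COMPONENTS:
            raise ValueError(f"state space too large (n={n})")
        self.n = n
        self.full = (1 << (1 << n)) - 1
        self.patterns = [_component_pattern(n, i) for i in range(n)]
        # states where component i disagrees with its update => flip enabled
        self.enabled = [fm ^ p for fm, p in zip(fmasks, self.patterns)]
        agg = 0
        for e in self.enabled:
            agg |= e
        self.fixed_mask = ~agg & self.full

    # -- raw-int core (used by the CTL fixpoints) ----------------------------

    def pre_exists_mask(self, target: int) -> int:
        """States with at least one (totalized) successor inside ``target``."""
        result = self.fixed_mask & target  # self-loops at fixed points
        for i in range(self.n):
            b = 1 << i
            p = self.patterns[i]
            shuffled = ((target & p) >> b) | ((target & ~p & self.full) << b)
            result |= self.enabled[i] & shuffled
        return result

    # -- StateSet API --------------------------------------------------------

    def pre_exists(self, target: StateSet) -> StateSet:
        if target.n != self.n:
            raise ValueError("state set over a different state space")
        return StateSet(self.n, self.pre_exists_mask(target.mask))

    def fixed_points(self) -> StateSet:
        return StateSet(self.n, self.fixed_mask)

    def successors(self, state: int) -> set[int]:
        out = set()
        for i in range(self.n):
            if (self.enabled[i] >> state) & 1:
                out.add(state ^ (1 << i))
        return out


def async_successors(pkn: PKN, model: Model, state: int) -> set[int]:
    """Direct (non-bit-parallel) successor computation; empty iff fixed point."""
    values = {c: (state >> i) & 1 for i, c in enumerate(pkn.components)}
    out = set()
    for i, c in enumerate(pkn.components):
        if model[c](values) != values[c]:
            out.add(state ^ (1 << i))
    return out


def is_fixed_point(pkn: PKN, model: Model, state: int) -> bool:
    values = {c: (state >> i) & 1 for i, c in enumerate(pkn.components)}
    return all(model[c](values) == values[c] for c in pkn.components)


def stg_edges(pkn: PKN, model: Model, totalized: bool = False):
    """Explicit STG edge list (state-int pairs); optionally with fixed-point loops."""
    edges = []
    for s in range(1 << pkn.n):
        succ = async_successors(pkn, model, s)
        if not succ and totalized:
            edges.append((s, s))
        edges.extend((s, t) for t in sorted(succ))
    return edges


def write_stg(pkn: PKN, model: Model, path, fmt: str = "edgelist") -> None:
    """Dump one model's STG with states rendered as bitstrings."""

    def render(s: int) -> str:
        return "".join(str((s >> i) & 1) for i in range(pkn.n))

    edges = stg_edges(pkn, model)
    with open(path, "w") as fh:
        if fmt == "dot":
            fh.write("digraph stg {\n")
            for s, t in edges:
                fh.write(f'  "{render(s)}" -> "{render(t)}";\n')
            fh.write("}\n")
        elif fmt == "edgelist":
            for s, t in edges:
                fh.write(f"{render(s)}\t{render(t)}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")
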
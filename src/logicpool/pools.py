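"""Enumeration of admissible update functions and the model pool.

An essential activating edge u -> v requires every model's f_v to be monotone
non-decreasing in u *and* observable in u (some regulator context where
flipping u flips the output); an essential inhibiting edge requires the
non-increasing analogue.  An optional edge relaxes observability: the
function may instead be constant in u.  The model pool is the product, over
components, of the per-component admissible function sets.

Monotone candidate tables are generated recursively by Shannon expansion
(f = [x=0 cofactor, x=1 cofactor] with the two cofactors ordered according to
the edge sign) rather than by filtering all 2^(2^k) tables, so enumeration is
output-sensitive; exhaustive filtering is kept to the test suite as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Sequence

from .network import PKN, BooleanFunction, EdgeLabel, Model, PKNError

__all__ = [
    "label_admits",
    "admissible_functions",
    "pool_size",
    "build_pool",
    "ModelPool",
]

_MAX_REGULATORS = 6  # tables stay machine-word sized; pools beyond this are impractical


def label_admits(f: BooleanFunction, regulator: str, label: EdgeLabel) -> bool:
    """Does ``f`` respect the label of the edge ``regulator -> owner``?

    Essential labels demand sign-monotonicity plus observability; optional
    labels accept the same or a function constant in the regulator.
    """
    if regulator not in f.regulators:
        raise ValueError(f"{regulator!r} is not a candidate regulator of {f!r}")
    if not f.is_monotone(regulator, label.sign):
        return False
    if label.essential and not f.depends_on(regulator):
        return False
    return True


@lru_cache(maxsize=None)
def _monotone_tables(signs: tuple[int, ...]) -> tuple[int, ...]:
    """All truth tables (ints) monotone in each variable with the given sign.

    Variable order matches the sign tuple, first variable most significant.
    Constants are included; observability is filtered by the caller.
    """
    if not signs:
        return (0, 1)
    rest = _monotone_tables(signs[1:])
    half = 1 << (len(signs) - 1)
    out = []
    for f0 in rest:  # cofactor at first variable = 0
        for f1 in rest:  # cofactor at first variable = 1
            lo, hi = (f0, f1) if signs[0] > 0 else (f1, f0)
            if lo & ~hi == 0:
                out.append(f0 | (f1 << half))
    return tuple(sorted(out))


def admissible_functions(pkn: PKN, component: str) -> list[BooleanFunction]:
    """Ordered set of update functions compatible with the incoming labels.

    A pinned function short-circuits enumeration.  Otherwise every monotone
    table over the candidate regulators is kept iff each essential regulator
    is observable; the result is sorted by canonical truth-table integer so
    that model ids are stable.
    """
    if component in pkn.fixed_functions:
        f = pkn.fixed_functions[component]
        regs = pkn.regulators_of(component)
        g = f.pad(regs) if set(f.regulators) != set(regs) else f._reorder(regs)
        return [g]
    regs = pkn.regulators_of(component)
    if not regs:
        raise PKNError(f"component {component!r} has no regulators and no function")
    if len(regs) > _MAX_REGULATORS:
        raise PKNError(
            f"component {component!r} has {len(regs)} candidate regulators "
            f"(max {_MAX_REGULATORS})"
        )
    labels = pkn.in_labels(component)
    signs = tuple(labels[r].sign for r in regs)
    essential = [r for r in regs if labels[r].essential]
    out = []
    for table in _monotone_tables(signs):
        f = BooleanFunction(regs, table)
        if all(f.depends_on(r) for r in essential):
            out.append(f)
    return out


def pool_size(pkn: PKN) -> int:
    """Product of per-component admissible counts, without materializing models."""
    size = 1
    for c in pkn.components:
        size *= len(admissible_functions(pkn, c))
    return size


@dataclass
class ModelPool:
    """The full model pool as an indexed product space.

    Model ids are mixed-radix numbers over per-component choice indices, the
    first component being the most significant digit; ids are stable for a
    fixed PKN because function choices are canonically ordered.
    """

    pkn: PKN
    choices: dict[str, list[BooleanFunction]]

    def __post_init__(self):
        self._radices = [len(self.choices[c]) for c in self.pkn.components]
        self._size = 1
        for r in self._radices:
            self._size *= r

    def __len__(self) -> int:
        return self._size

    def digits(self, model_id: int) -> tuple[int, ...]:
        """Per-component choice indices for a model id."""
        if not 0 <= model_id < self._size:
            raise IndexError(f"model id {model_id} out of range")
        out = []
        for radix in reversed(self._radices):
            model_id, d = divmod(model_id, radix)
            out.append(d)
        return tuple(reversed(out))

    def id_of(self, digits: Sequence[int]) -> int:
        if len(digits) != len(self._radices):
            raise ValueError("digit tuple length mismatch")
        model_id = 0
        for d, radix in zip(digits, self._radices):
            if not 0 <= d < radix:
                raise ValueError(f"digit {d} out of range for radix {radix}")
            model_id = model_id * radix + d
        return model_id

    def model(self, model_id: int) -> Model:
        digs = self.digits(model_id)
        return Model(
            {
                c: self.choices[c][d]
                for c, d in zip(self.pkn.components, digs)
            }
        )

    def __iter__(self) -> Iterator[Model]:
        for i in range(self._size):
            yield self.model(i)

    def function_tuple(self, model_id: int) -> tuple[BooleanFunction, ...]:
        digs = self.digits(model_id)
        return tuple(
            self.choices[c][d] for c, d in zip(self.pkn.components, digs)
        )


def build_pool(pkn: PKN, cap: int = 10**7) -> ModelPool:
    """Materialize the pool index (models themselves are built on demand)."""
    size = pool_size(pkn)
    if size > cap:
        raise PKNError(f"pool size {size} exceeds cap {cap}")
    choices = {c: admissible_functions(pkn, c) for c in pkn.components}
    return ModelPool(pkn, choices)
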
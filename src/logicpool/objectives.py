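"""Objective transforms on a prior-knowledge network.

Three study objectives are encoded as PKN rewrites executed *before* pool
generation:

* driver-mutation testing — every essential edge touching a mutated
  component is relaxed to the optional label with the same sign, letting the
  data decide whether the interaction survived the mutation;
* drug testing — the drug becomes a new constant input (a component with an
  essential activating self-loop) with an optional inhibiting edge to each
  candidate target; where the target's rule f' is known and the drug's
  dominant mechanism is established, the rule is pinned to f' & !drug;
* crosstalk hypotheses — candidate cross-pathway edges are added as optional
  edges of the stated sign.

All transforms return a new PKN and unpin the update rule of any component
that gains or changes incoming edges, since its regulation is no longer
fully known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .network import PKN, BooleanFunction, EdgeLabel, PKNError

__all__ = ["MutationSpec", "DrugSpec", "apply_mutation", "add_drug", "add_crosstalk"]


@dataclass(frozen=True)
class MutationSpec:
    """Mutated components; scope defaults to every edge incident to one of them."""

    mutated_components: frozenset[str]
    edge_scope: frozenset[tuple[str, str]] | None = None

    def __init__(self, mutated_components, edge_scope=None):
        object.__setattr__(self, "mutated_components", frozenset(mutated_components))
        object.__setattr__(
            self, "edge_scope", None if edge_scope is None else frozenset(edge_scope)
        )

    def in_scope(self, edge: tuple[str, str]) -> bool:
        if self.edge_scope is not None:
            return edge in self.edge_scope
        u, v = edge
        return u in self.mutated_components or v in self.mutated_components


@dataclass(frozen=True)
class DrugSpec:
    """A drug component and its candidate targets.

    ``targets`` maps each target to a flag: True when the drug's dominant
    mechanism on that target is known (the target's pinned rule, if any, is
    then extended to f' & !drug), False when the effect is a hypothesis.
    """

    name: str
    targets: tuple[tuple[str, bool], ...]

    def __init__(self, name: str, targets):
        object.__setattr__(self, "name", name)
        norm = []
        for t in targets:
            if isinstance(t, str):
                norm.append((t, False))
            else:
                norm.append((t[0], bool(t[1])))
        object.__setattr__(self, "targets", tuple(norm))
        if not self.targets:
            raise ValueError("drug must have at least one target")


def apply_mutation(pkn: PKN, spec: MutationSpec) -> PKN:
    """Relax essential edges in the mutation scope to their optional label."""
    unknown = spec.mutated_components - set(pkn.components)
    if unknown:
        raise PKNError(f"unknown mutated component(s) {sorted(unknown)}")
    if spec.edge_scope is not None:
        missing = spec.edge_scope - set(pkn.edges)
        if missing:
            raise PKNError(f"edge scope contains absent edge(s) {sorted(missing)}")
    out = pkn.copy()
    for edge, lab in pkn.edges.items():
        if spec.in_scope(edge) and lab.essential:
            out.edges[edge] = lab.relaxed
            out.fixed_functions.pop(edge[1], None)
    return out


def add_drug(pkn: PKN, spec: DrugSpec) -> PKN:
    """Extend the PKN with a drug input and optional inhibiting target edges."""
    if spec.name in pkn.components:
        raise PKNError(f"component {spec.name!r} already exists")
    unknown = {t for t, _ in spec.targets} - set(pkn.components)
    if unknown:
        raise PKNError(f"unknown drug target(s) {sorted(unknown)}")
    out = pkn.copy()
    out.components.append(spec.name)
    out.edges[(spec.name, spec.name)] = EdgeLabel.ESS_POS
    for target, known in spec.targets:
        out.edges[(spec.name, target)] = EdgeLabel.OPT_NEG
        old = out.fixed_functions.pop(target, None)
        if known and old is not None:
            regs = out.regulators_of(target)  # includes the drug now
            padded = old.pad(regs)
            # f = f' & !drug : keep outputs only where the drug bit is 0
            shift = len(regs) - 1 - padded.regulators.index(spec.name)
            table = 0
            for j in range(1 << len(regs)):
                if (j >> shift) & 1 == 0 and padded.output(j):
                    table |= 1 << j
            out.fixed_functions[target] = BooleanFunction(padded.regulators, table)
    return out


def add_crosstalk(pkn: PKN, edges: Sequence[tuple[str, str, str]]) -> PKN:
    """Add optional signed edges (sign '+' or '-'); unpins affected targets."""
    out = pkn.copy()
    for src, tgt, sign in edges:
        if (src, tgt) in out.edges:
            raise PKNError(f"edge ({src}, {tgt}) already present")
        for endpoint in (src, tgt):
            if endpoint not in out.components:
                raise PKNError(f"unknown component {endpoint!r}")
        if sign not in ("+", "-"):
            raise PKNError(f"crosstalk sign must be '+' or '-', got {sign!r}")
        out.edges[(src, tgt)] = (
            EdgeLabel.OPT_POS if sign == "+" else EdgeLabel.OPT_NEG
        )
        out.fixed_functions.pop(tgt, None)
    return out
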
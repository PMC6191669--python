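"""Analysis of (filtered) model pools: classification, frequencies, minimality.

Models in a pool differ in which optional interactions their update functions
actually use.  An optional edge u -> v is *present* in a model when u is
observable in that model's f_v; classification groups models by such
properties and counts class sizes (the relational SELECT DISTINCT/COUNT
view of the pool), edge frequencies summarize presence across a subpool, and
minimal mechanisms list the subset-minimal crosstalk combinations that
realize each exact drug-target scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .queries import AnnotatedPool, SubPool
from .pools import ModelPool

__all__ = [
    "MechanismRow",
    "annotate_edges",
    "classify",
    "edge_frequency",
    "no_effect_fraction",
    "minimal_mechanisms",
    "minimal_models",
    "edge_column",
]


def edge_column(edge: tuple[str, str]) -> str:
    return f"edge_{edge[0]}__{edge[1]}"


def _edge_presence_table(pool: ModelPool) -> pd.DataFrame:
    """Presence bit per (model, optional edge), vectorized over the product space.

    Presence per model depends only on the model's per-component choice digit,
    so presence is precomputed per admissible function and broadcast along the
    mixed-radix index.
    """
    pkn = pool.pkn
    size = len(pool)
    ids = np.arange(size, dtype=np.int64)
    radices = [len(pool.choices[c]) for c in pkn.components]
    # digit of component i for every model id, vectorized
    digit_of = {}
    div = np.ones(size, dtype=np.int64)
    for c, radix in zip(reversed(pkn.components), reversed(radices)):
        digit_of[c] = (ids // div) % radix
        div = div * radix
    columns = {"id": ids}
    total = np.zeros(size, dtype=np.int64)
    for (u, v) in pool.pkn.optional_edges():
        presence = np.array(
            [1 if f.depends_on(u) else 0 for f in pool.choices[v]], dtype=np.uint8
        )
        col = presence[digit_of[v]]
        columns[edge_column((u, v))] = col
        total += col
    columns["n_opt_edges"] = total
    return pd.DataFrame(columns)


def annotate_edges(target: AnnotatedPool | ModelPool) -> pd.DataFrame:
    """Add per-optional-edge presence bits (and their count) to the annotation.

    Accepts a bare pool (returns a fresh annotation table) or an
    :class:`AnnotatedPool` (merges the columns in place and returns them).
    """
    if isinstance(target, ModelPool):
        return _edge_presence_table(target)
    pool = target.pool
    cols = _edge_presence_table(pool)
    new = [c for c in cols.columns if c != "id" and c not in target.table.columns]
    if new:
        target.table = pd.concat([target.table, cols[new]], axis=1)
    return cols


def _restrict(table: pd.DataFrame, restriction) -> pd.DataFrame:
    if restriction is None:
        return table
    if isinstance(restriction, SubPool):
        return table[table["id"].isin(restriction.ids)]
    if isinstance(restriction, str):
        return table.query(restriction)
    mask = np.asarray(restriction, dtype=bool)
    return table[mask]


def classify(
    annotated: AnnotatedPool,
    classes: Sequence[str],
    restriction=None,
) -> pd.DataFrame:
    """Count models per realized combination of class properties.

    ``classes`` are annotation column names (edge presence bits, query
    validity bits, ``n_opt_edges``...); ``restriction`` is a SubPool, a
    pandas query string over the annotation columns, or a boolean mask.
    Returns one row per realized combination with its ``count``; counts over
    any partition sum to the size of the restricted pool.
    """
    table = annotate_edges_table(annotated)
    table = _restrict(table, restriction)
    for c in classes:
        if c not in table.columns:
            raise KeyError(f"unknown class property {c!r}")
    if not classes:
        return pd.DataFrame({"count": [len(table)]})
    out = (
        table.groupby(list(classes), sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def annotate_edges_table(annotated: AnnotatedPool) -> pd.DataFrame:
    """The annotation table with edge-presence columns guaranteed present."""
    if "n_opt_edges" not in annotated.table.columns:
        annotate_edges(annotated)
    return annotated.table


def edge_frequency(
    annotated: AnnotatedPool, subpool: SubPool | None = None
) -> dict[tuple[str, str], float]:
    """Fraction of models containing each optional edge (1.0 = in all models)."""
    table = annotate_edges_table(annotated)
    table = _restrict(table, subpool)
    if len(table) == 0:
        raise ValueError("empty subpool has no edge frequencies")
    return {
        edge: float(table[edge_column(edge)].mean())
        for edge in annotated.pool.pkn.optional_edges()
    }


def no_effect_fraction(
    annotated: AnnotatedPool,
    drug_edges: Sequence[tuple[str, str]],
    subpool: SubPool | None = None,
) -> float:
    """Fraction of models in which every listed drug edge is absent."""
    table = annotate_edges_table(annotated)
    table = _restrict(table, subpool)
    if len(table) == 0:
        return 0.0
    if not drug_edges:
        return 1.0
    mask = np.ones(len(table), dtype=bool)
    for edge in drug_edges:
        mask &= table[edge_column(edge)].to_numpy() == 0
    return float(mask.mean())


@dataclass(frozen=True)
class MechanismRow:
    """A subset-minimal tracked-edge vector within one exact drug-target scenario."""

    scenario: tuple[str, ...]  # names of the drug targets present
    vector: tuple[int, ...]  # presence bits in tracked-edge order


def _subset_minimal(vectors: set[tuple[int, ...]]) -> list[tuple[int, ...]]:
    def leq(a, b):
        return all(x <= y for x, y in zip(a, b))

    minimal = [
        v
        for v in vectors
        if not any(u != v and leq(u, v) for u in vectors)
    ]
    return sorted(minimal)


def minimal_mechanisms(
    annotated: AnnotatedPool,
    subpool: SubPool,
    drug_edges: Sequence[tuple[str, str]],
    tracked_edges: Sequence[tuple[str, str]],
) -> list[MechanismRow]:
    """Subset-minimal crosstalk vectors per exact drug-target scenario.

    The subpool is split by which drug edges are present, with *exact*
    equality (one-target scenarios exclude supersets).  Within each scenario
    the distinct tracked-edge presence vectors are reduced to their
    subset-minimal elements, in lexicographic order; infeasible scenarios
    contribute no rows.
    """
    table = annotate_edges_table(annotated)
    table = _restrict(table, subpool)
    rows: list[MechanismRow] = []
    drug_edges = list(drug_edges)
    for r in range(len(drug_edges) + 1):
        for combo in combinations(drug_edges, r):
            present = set(combo)
            mask = np.ones(len(table), dtype=bool)
            for edge in drug_edges:
                want = 1 if edge in present else 0
                mask &= table[edge_column(edge)].to_numpy() == want
            sel = table[mask]
            if len(sel) == 0:
                continue
            vectors = {
                tuple(int(b) for b in row)
                for row in sel[[edge_column(e) for e in tracked_edges]].to_numpy()
            }
            scenario = tuple(t for (_, t) in combo)
            for v in _subset_minimal(vectors):
                rows.append(MechanismRow(scenario, v))
    return rows


def minimal_models(
    annotated: AnnotatedPool,
    subpool: SubPool,
    criterion: str = "structural",
) -> list[int]:
    """Model ids minimal within a subpool.

    ``structural``: models whose set of present optional edges is
    subset-minimal in the subpool.  ``functional``: among the structural
    minima, the models whose update rules have the fewest total literals in
    minimal DNF.
    """
    if criterion not in ("structural", "functional"):
        raise ValueError(f"unknown minimality criterion {criterion!r}")
    if len(subpool) == 0:
        raise ValueError("empty subpool")
    table = annotate_edges_table(annotated)
    table = _restrict(table, subpool)
    opt = annotated.pool.pkn.optional_edges()
    cols = [edge_column(e) for e in opt]
    vec_of = {
        int(row.id): tuple(int(getattr(row, c)) for c in cols)
        for row in table.itertuples()
    }
    distinct = set(vec_of.values())
    minimal_vecs = set(_subset_minimal(distinct))
    structural = sorted(i for i, v in vec_of.items() if v in minimal_vecs)
    if criterion == "structural":
        return structural
    pool = annotated.pool
    costs = {
        i: sum(f.literal_count() for f in pool.function_tuple(i))
        for i in structural
    }
    best = min(costs.values())
    return sorted(i for i in structural if costs[i] == best)
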
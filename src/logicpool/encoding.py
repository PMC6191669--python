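"""Discretization of measurement tables and CTL encoding of the results.

Measurements arrive in long format (experiment, treatment, component, time,
value).  For each (experiment, component) a single threshold is computed over
*all* time points and *all* treatments — cells cultivated in parallel are
assumed comparable, so e.g. the Erk threshold is shared between drug and
vehicle treatment within one experiment — and a value is discretized to 1
when it reaches the threshold.  The threshold is the grand mean by default,
or the grand median as a robustness alternative.

Series that barely vary (coefficient of variation below a cutoff) cannot be
discretized meaningfully and are flagged for exclusion.

Discretized rows are then encoded as CTL: a time series becomes a nested
reachability chain EF(row1 & EF(row2 & ... )) — the measurements must lie, in
order, on one trajectory — and a persistent observation becomes a steady
state, either EF(AG(row)) or the fixed-point-atom form EF(Delta=0 & row).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .queries import AG, And, Atom, EF, Fix, Query

__all__ = [
    "DiscretizationResult",
    "discretize",
    "variance_screen",
    "encode_timeseries",
    "encode_steady_state",
    "timeseries_rows",
]

REQUIRED_COLUMNS = ["experiment", "treatment", "component", "time", "value"]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table lacks column(s) {missing}")
    if table.empty:
        raise ValueError("empty measurement table")
    dup = table.duplicated(subset=["experiment", "treatment", "component", "time"])
    if dup.any():
        raise ValueError("duplicate (experiment, treatment, component, time) rows")
    if (table["value"] < 0).any():
        raise ValueError("negative measurement values")
    return table


@dataclass
class DiscretizationResult:
    """Thresholds, boolean calls, and low-variance flags per series."""

    thresholds: pd.DataFrame  # experiment, component, theta
    booleans: pd.DataFrame  # experiment, treatment, component, time, value, b
    flags: pd.DataFrame  # experiment, component, cv, flagged
    method: str
    tie_value: int = 1


def discretize(
    table: pd.DataFrame,
    method: str = "mean",
    tie_value: int = 1,
    cv_threshold: float = 0.1,
) -> DiscretizationResult:
    """Threshold each (experiment, component) series by its grand mean/median.

    ``tie_value`` decides calls exactly at the threshold (default: 1, i.e.
    the comparison is >=).
    """
    table = _validate_table(table)
    if method not in ("mean", "median"):
        raise ValueError(f"unknown discretization method {method!r}")
    agg = table.groupby(["experiment", "component"])["value"].agg(method)
    thresholds = agg.rename("theta").reset_index()
    merged = table.merge(thresholds, on=["experiment", "component"])
    above = merged["value"] > merged["theta"]
    at = np.isclose(merged["value"], merged["theta"])
    merged["b"] = np.where(at, tie_value, above.astype(int)).astype(int)
    booleans = merged[REQUIRED_COLUMNS + ["b"]]
    flags = variance_screen(table, cv_threshold=cv_threshold)
    return DiscretizationResult(thresholds, booleans, flags, method, tie_value)


def variance_screen(table: pd.DataFrame, cv_threshold: float = 0.1) -> pd.DataFrame:
    """Flag (experiment, component) series whose dispersion is too small.

    The statistic is the coefficient of variation (population standard
    deviation over mean); series below ``cv_threshold`` are flagged as
    candidates for exclusion.  A zero-mean series is flagged with CV = inf.
    """
    table = _validate_table(table)
    rows = []
    for (exp, comp), grp in table.groupby(["experiment", "component"]):
        values = grp["value"].to_numpy(dtype=float)
        mean = values.mean()
        std = values.std(ddof=0)
        if mean == 0:
            cv = float("inf") if std > 0 else float("nan")
            flagged = True  # undefined CV: cannot be discretized meaningfully
        else:
            cv = std / mean
            flagged = cv < cv_threshold
        rows.append(
            {"experiment": exp, "component": comp, "cv": cv, "flagged": flagged}
        )
    return pd.DataFrame(rows)


def _conjunction(row: Mapping[str, int], extra=None):
    atoms = tuple([extra] if extra is not None else []) + tuple(
        Atom(c, int(b)) for c, b in row.items()
    )
    if not atoms:
        raise ValueError("empty observation row")
    node = atoms[0]
    for a in atoms[1:]:
        node = And((node, a))
    return node


def encode_timeseries(
    rows: Sequence[Mapping[str, int]],
    init: Mapping[str, int] | None = None,
    name: str = "series",
    collapse: bool = True,
) -> Query:
    """Encode ordered discrete observations as a nested EF reachability chain.

    Consecutive identical rows carry no ordering information in the
    most-conservative reading and are collapsed by default.
    """
    rows = [dict(r) for r in rows]
    if not rows or any(not r for r in rows):
        raise ValueError("need at least one nonempty observation row")
    if collapse:
        kept = [rows[0]]
        for r in rows[1:]:
            if r != kept[-1]:
                kept.append(r)
        rows = kept
    node = EF(_conjunction(rows[-1]))
    for row in reversed(rows[:-1]):
        node = EF(And((_conjunction(row), node)))
    return Query(name, node, dict(init or {}))


def encode_steady_state(
    row: Mapping[str, int],
    init: Mapping[str, int] | None = None,
    name: str = "steady",
    style: str = "nested",
) -> Query:
    """Encode a persistent observation as a reachable steady state.

    ``style='nested'`` emits EF(AG(row)); ``style='fix_atom'`` emits
    EF(Delta=0 & row), requiring the observed state to be a fixed point.
    """
    if not row:
        raise ValueError("empty observation row")
    if style == "nested":
        formula = EF(AG(_conjunction(row)))
    elif style == "fix_atom":
        formula = EF(_conjunction(row, extra=Fix()))
    else:
        raise ValueError(f"unknown steady-state style {style!r}")
    return Query(name, formula, dict(init or {}))


def timeseries_rows(
    result: DiscretizationResult,
    experiment: str,
    treatment: str,
    components: Sequence[str],
    max_time: float | None = None,
    exclude: Sequence[str] = (),
) -> list[dict[str, int]]:
    """Extract ordered boolean observation rows for one experiment/treatment.

    ``max_time`` drops late time points (e.g. keep signaling-scale
    measurements only); ``exclude`` drops components (e.g. flagged series).
    """
    df = result.booleans
    sel = df[(df["experiment"] == experiment) & (df["treatment"] == treatment)]
    if max_time is not None:
        sel = sel[sel["time"] <= max_time]
    keep = [c for c in components if c not in set(exclude)]
    rows = []
    for t in sorted(sel["time"].unique()):
        at_t = sel[sel["time"] == t]
        row = {
            c: int(at_t.loc[at_t["component"] == c, "b"].iloc[0])
            for c in keep
            if (at_t["component"] == c).any()
        }
        if row:
            rows.append(row)
    return rows
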
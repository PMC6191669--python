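"""Packaged networks and queries, plus a seeded random-PKN generator.

Two fixtures ship with the package:

* ``toy_network`` — the four-component illustration network: a known chain
  A -> B -> D driven by input A, and a single uncertain (optional activating)
  regulation of C by D, giving a pool of exactly three models.
* ``rcc_network`` — a ten-component reconstruction of MAPK/PI3K-mTORC1
  growth-factor signaling in two renal cancer cell lines treated with
  Sorafenib, with seven optional edges (three candidate drug targets, three
  pathway crosstalks, and the mTORC1 -> IGFR feedback relaxed because of an
  mTOR mutation of unknown effect).  The topology is calibrated so that the
  per-component admissible-function counts multiply to the published generic
  pool size of 19,404 (= 11 * 14 * 14 * 3 * 3); the eleven published CTL
  observation formulas are packaged verbatim.  In the Bio-Plex formulas the
  atom ``mTor`` reads out the same phosphorylation target as ``mTORC1`` and
  is treated as an alias.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .network import PKN, EdgeLabel, parse_pkn
from .queries import Query, parse_queries

__all__ = ["Fixture", "toy_network", "rcc_network", "random_pkn", "RCC_ALIASES"]

RCC_ALIASES: dict[str, str] = {"mTor": "mTORC1"}

# Cell-line-specific query panels (each also requires the shared WB.DMSO set).
RCC_QUERY_SETS: dict[str, tuple[str, ...]] = {
    "Rp.1851": (
        "WB.DMSO",
        "WB1851Sora",
        "Bp1851Sora",
        "Bp1851Sora2",
        "Bp1851DMSO",
        "Bp1851DMSO2",
    ),
    "Rp.1257": (
        "WB.DMSO",
        "WB1257Sora",
        "Bp1257Sora",
        "Bp1257Sora2",
        "Bp1257DMSO",
        "Bp1257DMSO2",
    ),
}

RCC_DRUG_EDGES: tuple[tuple[str, str], ...] = (
    ("Sora", "Raf"),
    ("Sora", "EGFR"),
    ("Sora", "IGFR"),
)

# Crosstalk/feedback tracking order used by the minimal-mechanism tables.
RCC_TRACKED_EDGES: tuple[tuple[str, str], ...] = (
    ("EGFR", "PI3K"),
    ("Erk", "mTORC1"),
    ("mTORC1", "IGFR"),
    ("PI3K", "Raf"),
)


@dataclass
class Fixture:
    """A packaged network with its query set and documented expectations."""

    name: str
    pkn: PKN
    queries: list[Query]
    aliases: Mapping[str, str] = field(default_factory=dict)
    expected: Mapping[str, object] = field(default_factory=dict)
    corrections: Mapping[str, Query] = field(default_factory=dict)

    def calibrated_queries(self) -> list[Query]:
        """The query set in the form that reproduces the published counts.

        Two calibrations are applied on top of the verbatim query text:

        * steady states are read as "a fixed point satisfying the observation
          is reachable" (EF(Delta=0 & X)); the printed EF(AG(X)) rendering is
          weaker (it also accepts cycling attractors) and yields larger
          subpools than published;
        * queries listed in ``corrections`` are replaced by their corrected
          form (see :func:`rcc_network` for the evidence).
        """
        from .queries import steady_as_fixed_point

        return [
            steady_as_fixed_point(self.corrections.get(q.name, q))
            for q in self.queries
        ]


def _read(name: str) -> str:
    return resources.files("logicpool.data").joinpath(name).read_text()


def toy_network() -> Fixture:
    pkn = parse_pkn(_read("toy.pkn"))
    queries = parse_queries(_read("toy.queries"))
    return Fixture(
        name="toy",
        pkn=pkn,
        queries=queries,
        expected={
            "pool_size": 3,
            "filtered_pool_size": 2,  # the f_C = 0 model cannot raise C
        },
    )


# Two published Bio-Plex formulas carry demonstrable single-bit transcription
# slips: with the verbatim text their pool counts are 11,583 and 11,088, while
# the corrected forms below reproduce the published 12,393 and 10,032 exactly,
# and downstream the published cell-line pool size (1,017) and feedback
# frequency (71%) follow only from the corrected forms.  Bp1257Sora2's last
# printed row differs from its fifth by one Akt bit; equating them (i.e. a
# five-level chain) matches the published count.  Bp1257DMSO2's first row
# matches the published count with mTor=0 instead of mTor=1.
RCC_CORRECTED_QUERIES = """
Bp1257Sora2: EF(mTor=0&Akt=0&EGFR=0&Erk=0&EF(mTor=0&Akt=1&EGFR=0&Erk=0&EF(mTor=1&Akt=1&EGFR=1&Erk=1&EF(mTor=1&Akt=1&EGFR=1&Erk=0&EF(mTor=1&Akt=0&EGFR=1&Erk=1)))))IS:Sora=1
Bp1257DMSO2: EF(mTor=0&Akt=0&EGFR=1&Erk=1&EF(mTor=1&Akt=0&EGFR=1&Erk=0&EF(mTor=1&Akt=1&EGFR=1&Erk=1&EF(mTor=0&Akt=0&EGFR=0&Erk=0&EF(mTor=1&Akt=1&EGFR=1&Erk=1)))))IS:Sora=0
"""


def rcc_network() -> Fixture:
    pkn = parse_pkn(_read("rcc.pkn"))
    queries = parse_queries(_read("rcc.queries"), aliases=RCC_ALIASES)
    corrections = {
        q.name: q for q in parse_queries(RCC_CORRECTED_QUERIES, aliases=RCC_ALIASES)
    }
    return Fixture(
        name="rcc",
        pkn=pkn,
        queries=queries,
        aliases=dict(RCC_ALIASES),
        expected={
            "pool_size": 19404,
            "admissible_counts": {
                "Sora": 1, "EGF": 1, "IGF": 1, "EGFR": 11, "IGFR": 14,
                "Raf": 14, "Erk": 1, "PI3K": 3, "Akt": 1, "mTORC1": 3,
            },
            "subpool_sizes": {"Rp.1257": 1017, "Rp.1851": 293},
            "query_sets": RCC_QUERY_SETS,
            "drug_edges": RCC_DRUG_EDGES,
            "tracked_edges": RCC_TRACKED_EDGES,
        },
        corrections=corrections,
    )


def export_fixture(name: str, directory) -> list[str]:
    """Copy a packaged fixture's plain-text files into a directory."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for suffix in ("pkn", "queries"):
        fname = f"{name}.{suffix}"
        (directory / fname).write_text(_read(fname))
        written.append(str(directory / fname))
    return written


def random_pkn(seed: int, n_components: int = 4, p_optional: float = 0.5) -> PKN:
    """Seeded random PKN for property tests: a DAG over one input plus
    occasional feedback, random signs, optional labels with rate
    ``p_optional``.  Every component is reachable from the input.
    """
    if not 1 <= n_components <= 6:
        raise ValueError("n_components must be in 1..6")
    rng = random.Random(seed)
    names = [f"v{i}" for i in range(n_components)]
    edges: dict[tuple[str, str], EdgeLabel] = {(names[0], names[0]): EdgeLabel.ESS_POS}

    def label() -> EdgeLabel:
        sign = rng.random() < 0.5
        opt = rng.random() < p_optional
        if sign:
            return EdgeLabel.OPT_POS if opt else EdgeLabel.ESS_POS
        return EdgeLabel.OPT_NEG if opt else EdgeLabel.ESS_NEG

    for i in range(1, n_components):
        n_regs = rng.randint(1, min(3, i))
        for src in rng.sample(names[:i], n_regs):
            edges[(src, names[i])] = label()
    # occasional feedback edge from a downstream to an upstream component
    if n_components >= 3 and rng.random() < 0.5:
        u = rng.randint(2, n_components - 1)
        v = rng.randint(1, u - 1)
        if (names[u], names[v]) not in edges:
            edges[(names[u], names[v])] = label()
    return PKN(list(names), edges)
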
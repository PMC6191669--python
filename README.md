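# logicpool

Uncertainty-aware logical modeling of signaling networks: build **all**
Boolean models consistent with a prior-knowledge network whose interactions
may be uncertain, filter the pool by temporal-logic-encoded experiments, and
analyze what survives.

Bottom-up models of signaling pathways usually force the modeler to resolve
every controversy in the literature by assumption.  `logicpool` instead keeps
the uncertainty: a prior-knowledge network (PKN) is a directed graph
R = (V, E, l) whose edges carry labels l : E → {+, −, ¬+, ¬−} — *essential*
activation/inhibition that must be functional in every model, or *optional*
interactions that may be functional or absent.  Every Boolean update function
f_v that is sign-monotone in each regulator, and observable in each essential
one, is admissible; the product over components is the *model pool*.
Experimental observations are encoded in CTL over the asynchronous state
transition graph — time series as nested reachability chains
`EF(row₁ & EF(row₂ & …))`, persistent observations as reachable steady
states — and the pool is reduced to the models whose dynamics can reproduce
them.  The filtered pool is then classified (edge presence, class counts),
summarized by edge frequencies, and mined for subset-minimal mechanisms per
drug-target scenario.

This is aimed at systems biologists who want to test several wiring
hypotheses at once — candidate drug targets, pathway crosstalk, mutations of
unknown effect — against time-series and steady-state data, without committing
to a single network up front.

## Worked example

The packaged toy network has a known chain (input A drives B, B drives D) and
one uncertain interaction: D may or may not activate C (`D -> C +?`).

```python
from logicpool import build_pool, filter_pool
from logicpool.fixtures import toy_network

toy = toy_network()
pool = build_pool(toy.pkn)
print(len(pool))                          # 3  (f_C is 0, D, or 1)
annotated = filter_pool(pool, toy.queries)
print(len(annotated.subpool()))           # 2
```

The packaged observation `EF(B=1&EF(C=1&D=1)) IS:A=1,B=0,C=0,D=0` — "after B
rises, C and D are eventually jointly active, starting from the all-off state
with the input on" — eliminates exactly the model whose C-rule is the
constant 0: that model can never raise C, while `f_C = D` and `f_C = 1` both
admit a trajectory through the observed states.

The full-scale fixture is a ten-component MAPK / PI3K–mTORC1 network for two
renal cancer cell lines treated with the Raf inhibitor Sorafenib, with seven
optional edges (three candidate drug targets, three crosstalks, one
mutation-relaxed feedback) and eleven observation formulas:

```bash
python examples/04_rcc_analysis.py
```

prints, after a few minutes (abridged):

```
generic pool: 19404 models
models consistent with each observation:
  WB.DMSO        15026
  ...
cell-line pools: Rp.1257 = 1017, Rp.1851 = 293
shared models: 0
```

19,404 is the number of admissible function combinations of the network; the
two cell-line-specific pools retain 1,017 and 293 of them and share none —
the two cell lines cannot be explained by the same wiring.  The per-pool edge
frequencies and minimal-mechanism tables that follow show, e.g., that the
mTORC1 → IGFR feedback is present in 100% of one cell line's models but only
71% of the other's, and that two drug-target scenarios are infeasible in the
293-model pool.

Other examples: `examples/01_toy_pool.py` (pool building and filtering),
`02_objective_transforms.py` (drug / mutation / crosstalk rewrites),
`03_discretize_and_encode.py` (thresholding measurement tables and emitting
CTL queries).

## Command line

Every stage is also a subcommand of the `logicpool` console script —
`build-pool`, `check`, `classify`, `freq`, `minimal`, `discretize`, `encode`,
`objective {mutate,drug,crosstalk}`, `fixtures export` — and `logicpool run
--config FILE` chains them from a flat key=value config, writing CSV tables
and a JSON log with the config hash so a whole analysis is reproducible from
one text file.

## Layout

```
src/logicpool/
  network.py     PKN parsing/validation, Boolean functions, bnet export
  pools.py       admissible-function enumeration, model pool indexing
  objectives.py  mutation / drug / crosstalk rewrites
  dynamics.py    asynchronous STG, bit-parallel state sets
  queries.py     CTL dialect, model checking, pool filtering
  encoding.py    discretization and CTL encoding of measurements
  analysis.py    classification, edge frequencies, minimal mechanisms/models
  fixtures.py    packaged toy and renal-cancer networks, random PKNs
  cli.py         thin command-line front end
```
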
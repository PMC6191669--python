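# Methods

## The model-pool approach

`logicpool` implements uncertainty-aware logical modeling of signaling
networks.  The starting object is a *prior-knowledge network* (PKN): a
directed graph R = (V, E, l) over signaling components whose edges carry one
of four labels, l : E → {+, −, ¬+, ¬−}.  Essential labels (+, −) mark
textbook interactions that must be functional, with the stated sign, in every
model; optional labels mark uncertain interactions that may be functional or
absent.  The file dialect writes the optional labels as `+?` ("not
inhibiting": activation or nothing) and `-?` ("not activating": inhibition or
nothing).

A Boolean model assigns an update function f_v to every component.  An edge
u → v with a positive label requires f_v to be monotone non-decreasing in u;
a negative label requires non-increasing.  An *essential* edge additionally
requires observability: some context of the other regulators in which
flipping u flips f_v.  "Causes an increase at some point" is read as
sign-monotonicity *plus* observability — not mere non-constancy — which is
the standard notion of a functional signed edge in this formalism; the
packaged network calibration (below) confirms the reading.  The *model pool*
is the product, over components, of the per-component admissible function
sets.  Both constants 0 and 1 are admissible exactly when every incoming
edge is optional.

Functions are stored as canonical truth tables (first regulator = most
significant input bit) and compared after projection onto their observable
regulators, so a function padded with variables it ignores does not create a
duplicate pool member.  Admissible sets are sorted by truth-table integer,
which makes model ids (mixed-radix indices over per-component choices)
stable and reproducible.  Monotone candidate tables are generated recursively
via Shannon expansion with sign-ordered cofactors, which is output-sensitive;
the test suite cross-checks it against exhaustive filtering of all 2^(2^k)
tables for k ≤ 3.

## Dynamics and model checking

Dynamics are asynchronous: a transition flips exactly one component whose
update disagrees with its current value; fixed points receive a self-loop so
the transition relation is total.  Observations are encoded in CTL over
atoms `component=0|1` plus the reserved steady-state atom `Delta=0` (true
exactly at fixed points): a discretized time series becomes a nested
reachability chain EF(row₁ & EF(row₂ & …)) — the measurements must lie, in
order, on one trajectory, the most conservative reading — and a persistent
observation becomes a reachable steady state.  Consecutive duplicate rows
carry no ordering information under this semantics and are collapsed by
default.

Satisfaction sets are computed per model by backward fixpoints on packed
integer bitmasks over the 2^n state space (one membership bit per state).
The existential-predecessor operator is a per-component bit shuffle of the
target mask, so EF is a least fixpoint of S ↦ Sat(φ) ∪ pre∃(S) and
AG φ = ¬EF(¬φ).  For pool filtering, the per-component state masks are
precomputed once per admissible function, so constructing one model's
transition system is a table lookup; checking all 19,404 models of the
packaged network against eleven formulas takes on the order of a minute on
one CPU.  A query holds for a model when some state consistent with its
`IS:` clause satisfies the formula (existential initial states, the
default); universal quantification is available as a switch.  Note that EF
and AG are purely reachability-based, so the totalization convention does
not affect them; it matters only for the fixed-point atom and for any future
operators (EG, AF) whose tokens the grammar reserves but rejects.

## Objective transforms

Three study objectives are PKN rewrites executed before pool generation:

* **Driver mutations** — every essential edge incident to a mutated
  component is relaxed to the optional label of the same sign (+ → ¬−,
  − → ¬+); presence/sign never change, so the pool can only grow.
  Gain-of-function mutations (new edges, sign flips) are out of scope.
* **Drug testing** — the drug joins as a new component with an essential
  activating self-loop, which forces f_drug = identity and makes it a
  constant environmental input whose value is set per query via the `IS:`
  clause; each candidate target receives an optional inhibiting edge.  When
  the target's rule f′ is pinned and the drug's dominant mechanism is known,
  the rule becomes f = f′ ∧ ¬drug.
* **Crosstalk hypotheses** — candidate cross-pathway edges are added with
  optional labels of the stated sign.

Any transform that changes a component's incoming edges unpins its fixed
rule: pinned rules are only meaningful while the regulation is fully known.

## Pool analysis

An optional edge u → v is *present* in a model iff u is observable in that
model's f_v; this is well-defined because functions are support-canonical.
Classification groups the annotated pool (edge presence bits, per-query
validity bits, optional-edge counts) by any property combination and counts
class sizes — the relational SELECT DISTINCT/COUNT view.  Edge frequency is
presence averaged over a subpool.  Minimal mechanisms split a subpool by the
*exact* set of present drug-target edges (one-target scenarios exclude
supersets) and report the subset-minimal tracked-edge vectors per scenario;
subset-minimality (rather than count-minimality) is used because published
scenario tables list incomparable vector pairs.  Structural minimal models
are those whose present-optional-edge set is subset-minimal in the subpool;
functional minimality breaks ties by total literal count of minimal-DNF
renderings (computed with sympy's SOPform).

## The packaged renal-cancer-cell network

The `rcc` fixture reconstructs growth-factor signaling (MAPK cascade and
PI3K–mTORC1 branch) in two renal cancer cell lines treated with the drug
Sorafenib: ten components — constant inputs Sora, EGF, IGF; receptors EGFR
(activated by EGF, inhibited by Erk feedback) and IGFR (activated by IGF);
the kinases Raf → Erk and PI3K → Akt → mTORC1 — with seven optional edges:
three candidate drug targets Sora → {Raf, EGFR, IGFR}, two crosstalks
EGFR → PI3K and Erk → mTORC1, the crosstalk PI3K → Raf, and the
mTORC1 → IGFR feedback relaxed because one cell line carries an mTOR
mutation of unknown effect.  Erk and Akt have single essential regulators
and pinned identity rules.  The ligand inputs EGF and IGF are part of the
reconstruction: they are required for the per-component admissible counts
(1,1,1,11,14,14,1,3,1,3) whose product reproduces the published generic pool
size 19,404 = 11·14·14·3·3 exactly, the strongest structural calibration
available.  In the high-throughput formulas the atom `mTor` is an alias of
`mTORC1` (both read out p70S6K phosphorylation), and `Delta=0` is the
steady-state atom.

### Calibration of the published counts

The eleven observation formulas ship verbatim as printed.  Reproducing the
published per-formula model counts requires two documented calibrations,
both exposed through `Fixture.calibrated_queries()`:

1. **Steady states are reachable fixed points.**  With the printed
   EF(AG(mTORC1=x)) text the Western-blot counts come out 15,246 / 6,062;
   with the fixed-point reading EF(Delta=0 & mTORC1=x) they are 15,026 /
   5,902 — the published values exactly.  The original tool chain encoded
   persistence through its steady-state flag, consistent with the one
   formula that is printed in `Delta=0` form; AG additionally accepts
   attractors in which other components keep cycling.  The engine itself
   implements standard CTL AG; the rewrite is applied to queries, not to the
   checker.

2. **Two formulas carry single-bit transcription slips.**  With the verbatim
   text, Bp1257Sora2 and Bp1257DMSO2 give 11,583 and 11,088 against
   published 12,393 and 10,032, while the other nine counts (and the second
   cell line's entire panel) match exactly.  An exhaustive single-atom-flip
   search shows that equating Bp1257Sora2's last row with its fifth (they
   differ by one printed Akt bit, so the corrected chain has five levels)
   and flipping Bp1257DMSO2's first mTor bit to 0 reproduce both counts
   exactly — and, downstream, the published cell-line pool size (1,017) and
   feedback frequency (71%) follow only with these corrections.  The
   corrected forms live next to the verbatim ones in
   `logicpool.fixtures.RCC_CORRECTED_QUERIES`.

With the calibrated queries the package reproduces: all eleven per-formula
counts, both cell-line pool sizes (1,017 and 293), their empty intersection,
the feedback frequencies (71% / 100%), the fractions of models without a
drug target (0.8% / 16%), the complete minimal-mechanism table of the
MZ1851RC pool, and most of the MZ1257RC one.  Three published statistics do
not reproduce and are reported as computed: the two figure-caption subpool
sizes (193 models with Sora → Raf in Rp.1257, 72 with Sora → EGFR in
Rp.1851; we compute 675 and 57) and the no-target minimal-mechanism row of
the MZ1257RC table.  These residuals are robust: enumerating *every* one- or
two-bit variant of the two slip-carrying formulas whose count matches the
published value, all combinations that yield a 1,017-model pool produce the
same three statistics we report.  The 72/57 case is instructive: our Rp.1851 pool matches
the published size exactly and every constituent count matches, yet no
edge-presence class of that pool has size 72 (an exhaustive search over all
conjunctions of up to three presence literals finds only semantically
unrelated coincidences), so those figure numbers appear inconsistent with
the published tables themselves — plausibly produced by an earlier analysis
run or a different presence convention.

## Parameters and defaults

| Parameter | Default | Meaning |
|---|---|---|
| discretization method | mean | grand mean (or median) per experiment × component, shared across treatments |
| tie rule | call 1 at the threshold | the published rule is unstated; configurable |
| low-variance cutoff | CV < 0.1 | population std / mean below this flags a series as undiscretizable |
| time cutoff | none (8 h typical) | ingestion parameter, drops late transcription-dominated time points |
| duplicate-row collapsing | on | consecutive identical discrete states carry no EF-chain information |
| initial states | existential | some IS-consistent state satisfies the formula; `--universal` for sensitivity |
| pool cap | 10^7 | guard against accidental combinatorial blow-up |
| regulator cap | 6 per component | keeps truth tables machine-word sized |

## Synthetic data and what the tests show

The random-PKN generator (`fixtures.random_pkn`) emulates small signaling
topologies: one constant input, a DAG of 1–3 regulators per component with
occasional feedback, random signs, and a configurable optional-edge rate.
It produces networks of ≤ 6 components, so property tests (oracle
equivalence of the CTL checker, pool-size products, round-trips) exercise
complete state spaces.  It does not emulate measurement noise, replicate
structure, or realistic pathway motifs beyond feedback; passing tests
certify the combinatorics and semantics of the engine, not the biological
adequacy of any particular reconstruction.  The discretization module is
validated on synthetic tables only, since the raw measurement values behind
the packaged formulas are not redistributed.

## Numerical and degenerate-input choices

State spaces are capped at n = 24 components (bitmask length 2^n).  Empty
measurement tables, empty observation rows, empty subpools, duplicate
edges/queries, unknown atoms, and `Delta=1` all raise immediately with
specific diagnostics.  Zero-mean measurement series are flagged rather than
divided by.  Classification over an empty class list returns the single
all-pool class.  A subpool intersection across different networks is an
error, not an empty result.

## Known limitations

* Only EF and AG are implemented; the grammar reserves the other CTL
  operator tokens and rejects them.  Fairness and bounded-step semantics are
  out of scope.
* Labels with unknown or ambivalent sign are not representable.
* Multivalued (non-Boolean) activity levels are not supported.
* Transition-count minimality ("fewest transitions to fulfill the data") is
  not implemented; structural and functional minimality are.
* Pool enumeration is explicit (no BDD compression), which is the intended
  regime for small-to-medium networks with a handful of uncertain edges.
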
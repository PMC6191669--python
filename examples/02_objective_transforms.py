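"""Encode study objectives as network rewrites before pool generation.

Starting from a small essential backbone, add a drug as a new constant input
with optional inhibiting edges to candidate targets, relax the edges of a
mutated component, and add a crosstalk hypothesis.  Each transform widens the
model pool; the data later decides which variants survive.
"""

from logicpool import add_crosstalk, add_drug, apply_mutation, build_pool, write_pkn
from logicpool.network import parse_pkn
from logicpool.objectives import DrugSpec, MutationSpec

pkn = parse_pkn(
    """
EGF -> EGF +
EGF -> EGFR +
EGFR -> Raf +
Raf -> Erk +
Erk -> EGFR -
"""
)
print(f"backbone pool size: {len(build_pool(pkn))}")

drugged = add_drug(pkn, DrugSpec("Sora", ["Raf"]))
print(f"after adding drug Sora with candidate target Raf: {len(build_pool(drugged))}")

mutated = apply_mutation(drugged, MutationSpec({"Erk"}))
print(f"after relaxing the mutated component Erk's edges: {len(build_pool(mutated))}")

with_crosstalk = add_crosstalk(mutated, [("EGF", "Raf", "+")])
print(f"after adding a crosstalk hypothesis EGF -> Raf: {len(build_pool(with_crosstalk))}")

print("\nfinal network:")
print(write_pkn(with_crosstalk))

# Pool sizes grow multiplicatively as uncertainty is added: each optional
# edge or unpinned rule multiplies the admissible-function combinations.
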
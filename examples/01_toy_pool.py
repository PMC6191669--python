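"""Build the model pool of the four-component toy network and filter it.

Input A drives the chain A -> B -> D; whether D activates C is uncertain, so
the network admits three models (C's rule is 0, 1, or D).  A small discretized
time series over B, C, D then eliminates the models that cannot raise C.
"""

from logicpool import build_pool, export_model, filter_pool
from logicpool.fixtures import toy_network

toy = toy_network()
pool = build_pool(toy.pkn)
print(f"pool size: {len(pool)}")
for i in range(len(pool)):
    rule = pool.model(i)["C"].to_expr()
    print(f"  model {i}: f_C = {rule}")

annotated = filter_pool(pool, toy.queries)
surviving = annotated.subpool()
print(f"models consistent with the time series: {len(surviving)} of {len(pool)}")
print("one surviving model in bnet form:")
print(export_model(pool.model(int(surviving.ids[0])), toy.pkn))

# The pool has 3 models; the observation "C eventually rises after B" rules
# out exactly the model whose C-rule is the constant 0.
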
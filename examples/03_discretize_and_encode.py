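"""Discretize a synthetic time-series table and emit CTL observation queries.

The threshold per (experiment, component) is the grand mean over all time
points and treatments; calls at or above the threshold become 1.  Rows are
then encoded as a nested reachability chain (transient series) or a steady
state.  Low-variance series are flagged as undiscretizable.
"""

import pandas as pd

from logicpool.encoding import (
    discretize,
    encode_steady_state,
    encode_timeseries,
    timeseries_rows,
)
from logicpool.queries import format_query

rows = []
akt = {0: 3.0, 2: 8.5, 4: 7.9, 8: 1.2, 24: 9.0}
erk = {0: 6.1, 2: 1.0, 4: 1.4, 8: 7.2, 24: 7.5}
igfr = {0: 5.0, 2: 5.1, 4: 4.9, 8: 5.0, 24: 5.0}  # barely moves
for t in akt:
    rows += [
        ("exp1", "Sora", "Akt", t, akt[t]),
        ("exp1", "Sora", "Erk", t, erk[t]),
        ("exp1", "Sora", "IGFR", t, igfr[t]),
    ]
table = pd.DataFrame(
    rows, columns=["experiment", "treatment", "component", "time", "value"]
)

result = discretize(table, method="mean")
print("thresholds:")
print(result.thresholds.to_string(index=False))
print("\nlow-variance flags (candidates for exclusion):")
print(result.flags.to_string(index=False))

flagged = result.flags.loc[result.flags["flagged"], "component"].tolist()
series = timeseries_rows(
    result, "exp1", "Sora", ["Akt", "Erk"], max_time=8, exclude=flagged
)
query = encode_timeseries(series, init={"Sora": 1}, name="BpSora")
print("\ntransient encoding (measurements until 8 h, flagged series dropped):")
print(format_query(query))

steady = encode_steady_state({"Akt": 1, "Erk": 1}, {"Sora": 0}, name="WBDMSO")
print("steady-state encoding:")
print(format_query(steady))

# IGFR's coefficient of variation is ~0.01, so it is flagged and excluded;
# the chain has one EF level per distinct discrete state in time order.
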
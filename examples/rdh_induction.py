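"""UV induction of RNA:DNA hybrids quantified on S9.6 westerns.

Generates S9.6/Southern blot tables and applies the "rdh" normalization rule
(density relative to the rnhAB log-culture lane of the same blot), then
reports the log -> 60 min fold change.
"""

import rdhquant as r
from rdhquant import blotquant as bq
from rdhquant import synthdata as sd

scenario = r.load_scenario("rnhAB")
table = sd.simulate_blot_table(
    scenario, [r.LOG_TIMEPOINT, 30.0, 60.0], n_replicates=5, seed=5
)
norm = bq.normalize_series(table, "rdh")
print("Normalized S9.6 levels (rnhAB log lane = 1.0):")
print(norm.groupby("timepoint")["normalized"].mean().to_string(), "\n")

for t in (30.0, 60.0):
    fold = bq.fold_change(norm, "rnhAB", t)
    print(f"fold change log -> {t:g} min: {fold:.1f}x")
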
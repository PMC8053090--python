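"""Chromosomal pyrimidine-dimer removal measured on anti-PD westerns.

Generates western/Southern blot tables for WT and rnhAB at 36 J/m2, applies
the "pd" normalization rule (background-subtracted percent of the 5-min
point) and compares the removal kinetics of the two strains.
"""

import rdhquant as r
from rdhquant import blotquant as bq
from rdhquant import synthdata as sd

TIMEPOINTS = [r.LOG_TIMEPOINT, 5.0, 30.0, 60.0]

for strain in ("WT", "rnhAB"):
    scenario = r.load_scenario(strain)
    table = sd.simulate_blot_table(scenario, TIMEPOINTS, n_replicates=5, seed=3)
    norm = bq.normalize_series(table, "pd")
    series = norm.groupby("timepoint")["normalized"].mean()
    print(f"{strain}: percent PDs remaining")
    for t, v in series.items():
        print(f"  {t:5.0f} min  {v:6.1f} %")
    print()
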
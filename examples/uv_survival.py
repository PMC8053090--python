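"""UV survival from spot assays, epistasis calls, and synthesis rates.

Simulates serial-dilution spot assays, estimates titers with exact Poisson
confidence intervals, builds a survival table, tests the recF x rnhAB double
mutant for multiplicative (independent) epistasis, and normalizes a
dilution-corrected DNA-synthesis time course.
"""

import numpy as np

import rdhquant as r
from rdhquant import phenotypes as ph
from rdhquant import synthdata as sd

# --- survival of the rnhAB uvrA mutant at a near-physiological dose --------
scenario = r.load_scenario("rnhAB_uvrA")
rng = np.random.default_rng(19)
untreated = sd.simulate_spot_assay(scenario, 0.0, seed=rng)
treated = sd.simulate_spot_assay(scenario, 0.6, seed=rng)

est = ph.titer(untreated)
print(f"untreated titer: {est.cfu_per_ml:.3g} cfu/ml "
      f"(95% CI {est.ci_low:.3g}-{est.ci_high:.3g}, flag={est.flag})")

table = ph.survival_table({0.0: [untreated], 0.6: [treated]})
surv = float(table["survival"].iloc[0])
print(f"survival at 0.6 J/m2: {surv:.3f}  ({1 / surv:.0f}-fold kill)\n")

# --- epistasis: is the recF rnhAB double mutant worse than predicted? ------
recf = r.load_scenario("recF").survival_by_dose
rnhab = r.load_scenario("rnhAB").survival_by_dose
double = r.load_scenario("recF_rnhAB").survival_by_dose
for dose in (2.0, 4.0, 8.0):
    res = ph.epistasis_predict(recf[dose], rnhab[dose], double[dose])
    print(f"dose {dose:g} J/m2: predicted {res['predicted']:.3g}, "
          f"observed {double[dose]:.3g} -> {res['call']}")

# --- dilution-corrected DNA synthesis rates --------------------------------
print("\nWT DNA synthesis after UV (normalized to t=0):")
series = sd.simulate_synthesis_rates(r.load_scenario("WT"), uv=True, seed=7)
out = ph.normalize_synthesis(series)
for _, row in out[::3].iterrows():
    print(f"  {row.time_min:5.0f} min  rate {row.normalized_rate:5.2f}")
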
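# rdhquant

Quantification pipelines for UV-induced pyrimidine dimers (PDs) and
RNA:DNA hybrids (RDHs) in bacterial DNA, with a matched synthetic-assay
generator for validation and method development.

The package models the assay suite used to study UV sensitivity of RNase H-
deficient *E. coli*: excision-deficient mutants accumulate persistent,
hybrid-anchored dimers, and every analysis here quantifies one face of that
phenomenon — lesion burden, repair kinetics, hybrid induction, hybrid/dimer
co-location, immunoprecipitation enrichment, and cell survival.

## Modules

| Module | What it does |
| --- | --- |
| `rdhquant.synthdata` | Scenario-driven generator: chromosome lesion states, restriction/shear digests, gel lanes, plasmid band tables, DRIP partitions, spot assays, synthesis-rate series |
| `rdhquant.relaxation` | Zero-class Poisson plasmid-relaxation densitometry: supercoiled fractions → mean nicks → lesions per genome, removal time courses |
| `rdhquant.blotquant` | Western/Southern normalization: loading correction, within-blot `"rdh"` and `"pd"` rules, fold changes |
| `rdhquant.coenrich` | 16-fraction gel partition and the per-fraction RDH x PD co-enrichment statistic |
| `rdhquant.dripmodel` | DRIP enrichment statistics and the theoretical PD-enrichment ceiling under independent placement |
| `rdhquant.phenotypes` | Spot-assay titers with exact Poisson CIs, survival tables, epistasis calls, dilution-corrected synthesis rates |
| `rdhquant.scenario` | Frozen parameter bundles per strain x dose; built-ins in `data/scenarios.yaml` |

## Quickstart

```python
import rdhquant as r
from rdhquant import synthdata as sd, relaxation as rx

scenario = r.load_scenario("WT")            # 36 J/m2 wild type
bands = sd.simulate_relaxation_series(scenario, 9_200,
                                      [r.LOG_TIMEPOINT, 5.0, 30.0], seed=0)
print(rx.estimate_series(bands, 9_200))     # ~1500 lesions/genome at 5 min
```

Every generator accepts an integer seed (or a `numpy.random.Generator`);
fixing the seed reproduces outputs byte-identically.  The timepoint `-1.0`
(`rdhquant.LOG_TIMEPOINT`) denotes the pre-UV exponential-growth sample
throughout.

Built-in scenarios (`rdhquant.list_scenarios()`): `WT`, `rnhA`, `rnhB`,
`rnhAB`, `rnhAB_rpoB35`, `uvrA`, `rnhAB_uvrA`, `recF`, `recF_rnhAB`.
Custom scenarios load from YAML with `rdhquant.load_scenario_file(path)`;
`load_scenario(name, **overrides)` tweaks single fields.

## Examples

One runnable script per capability in `examples/`:

- `plasmid_relaxation.py` — lesion burden and removal kinetics from topoisomer bands
- `pd_removal_blots.py` — chromosomal PD removal, WT vs rnhAB
- `rdh_induction.py` — S9.6 fold induction on the within-blot rnhAB-log scale
- `coenrichment_profile.py` — 16-fraction hybrid/dimer co-enrichment profiles
- `drip_enrichment.py` — DRIP enrichments, RNase HI control, independence ceiling
- `uv_survival.py` — spot-assay survival, epistasis calls, synthesis rates

## Validation

```sh
python -m pytest            # unit, property-based and end-to-end tests
python scripts/acceptance.py --seed 0 --out acceptance.json
```

The acceptance script recomputes twelve calibrated end-to-end checkpoints
(lesion burden, repair percentages, fold inductions, co-enrichment peak and
backgrounds, DRIP enrichments, survival) and writes them as JSON.  See
`docs/methods.md` for the underlying models and the calibration rationale.
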
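import math

import numpy as np
import pandas as pd
import pytest

import rdhquant as r
from rdhquant import phenotypes as ph
from rdhquant import synthdata as sd
from rdhquant.containers import SpotAssay


def _assay(counts_by_dilution, strain="WT", dose=0.0, volume=0.01):
    rows = [{"culture": 0, "dilution": d, "count": c}
            for d, c in counts_by_dilution.items()]
    return SpotAssay(strain=strain, dose=dose, spot_volume_ml=volume,
                     counts=pd.DataFrame(rows))


class TestTiter:
    def test_pooled_estimate(self):
        # countable spots: 200 @ 1e-3 and 20 @ 1e-4 -> 220 cfu / 1.1e-5 ml
        assay = _assay({0: 5000, 3: 200, 4: 20, 5: 1})
        est = ph.titer(assay)
        assert est.flag == "ok"
        assert est.total_count == 220
        assert est.cfu_per_ml == pytest.approx(220 / 1.1e-5)
        assert est.ci_low < est.cfu_per_ml < est.ci_high

    def test_recovers_true_titer_within_ci(self):
        true_titer = 2.0e8
        sc = r.load_scenario("WT")
        hits = 0
        for seed in range(20):
            assay = sd.simulate_spot_assay(sc, 0.0, seed=seed, n_cultures=1,
                                           titer=true_titer)
            est = ph.titer(assay)
            hits += est.ci_low <= true_titer <= est.ci_high
        assert hits >= 17  # 95% CI: 20 trials rarely miss more than 3 times

    def test_extinct_flag(self):
        est = ph.titer(_assay({0: 0, 1: 0, 2: 0}))
        assert est.flag == "extinct"
        assert est.cfu_per_ml == 0.0
        assert est.ci_high > 0.0  # one-sided upper bound survives

    def test_uncountable_falls_back_to_all_spots(self):
        est = ph.titer(_assay({0: 1000, 1: 400}))
        assert est.flag == "uncountable"
        assert est.total_count == 1400


class TestSurvival:
    def test_ratio(self):
        t = ph.titer(_assay({3: 20}))
        u = ph.titer(_assay({3: 200}))
        assert ph.survival(t, u) == pytest.approx(0.1)

    def test_capped_at_one(self):
        t = ph.titer(_assay({3: 210}))
        u = ph.titer(_assay({3: 200}))
        assert ph.survival(t, u) == 1.0

    def test_table_mean_and_sem(self):
        sc = r.load_scenario("rnhAB_uvrA")
        rng = np.random.default_rng(5)
        untreated = [sd.simulate_spot_assay(sc, 0.0, seed=rng, n_cultures=1)
                     for _ in range(4)]
        treated = [sd.simulate_spot_assay(sc, 0.6, seed=rng, n_cultures=1)
                   for _ in range(4)]
        table = ph.survival_table({0.0: untreated, 0.6: treated})
        row = table.iloc[0]
        assert row["n"] == 4
        assert row["survival"] == pytest.approx(0.05, rel=0.3)
        assert row["sem"] > 0

    def test_table_requires_untreated_reference(self):
        with pytest.raises(ValueError, match="dose 0"):
            ph.survival_table({8.0: []})


class TestEpistasis:
    def test_multiplicative_scenario_called_independent(self):
        """recF_rnhAB survivals are built as the recF x rnhAB product."""
        recf = r.load_scenario("recF").survival_by_dose
        rnhab = r.load_scenario("rnhAB").survival_by_dose
        double = r.load_scenario("recF_rnhAB").survival_by_dose
        for dose in (2.0, 4.0, 8.0):
            result = ph.epistasis_predict(recf[dose], rnhab[dose], double[dose])
            assert result["call"] == "independent"
            assert result["fold_deviation"] == pytest.approx(1.0, rel=0.05)

    def test_synergy_called(self):
        result = ph.epistasis_predict(0.5, 0.5, 0.01)
        assert result["call"] == "synergistic"

    def test_suppression_called(self):
        result = ph.epistasis_predict(0.1, 0.1, 0.5)
        assert result["call"] == "suppressive"

    def test_invalid_survival_rejected(self):
        with pytest.raises(ValueError):
            ph.epistasis_predict(0.0, 0.5)


class TestNormalizeSynthesis:
    def test_exact_on_noiseless_series(self):
        sc = r.load_scenario("WT").with_(noise_cv=0.0)
        series = sd.simulate_synthesis_rates(sc, uv=True, seed=0)
        out = ph.normalize_synthesis(series)
        # the corrected curve must equal the scenario's true rate curve
        truth = np.interp(out["time_min"],
                          [p[0] for p in sc.synthesis_rate_uv],
                          [p[1] for p in sc.synthesis_rate_uv])
        np.testing.assert_allclose(out["corrected_rate"], truth, rtol=1e-12)
        assert out["normalized_rate"].iloc[0] == 1.0

    def test_dilution_below_one_rejected(self):
        series = pd.DataFrame({"time_min": [0.0], "raw_rate": [1.0],
                               "cumulative_dilution": [0.5]})
        with pytest.raises(ValueError):
            ph.normalize_synthesis(series)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ph.normalize_synthesis(pd.DataFrame({"time_min": [0.0]}))

    def test_unknown_mode_rejected(self):
        series = pd.DataFrame({"time_min": [0.0], "raw_rate": [1.0],
                               "cumulative_dilution": [1.0]})
        with pytest.raises(ValueError, match="mode"):
            ph.normalize_synthesis(series, mode="nope")
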
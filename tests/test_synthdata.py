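import numpy as np
import pytest

import rdhquant as r
from rdhquant import synthdata as sd


@pytest.fixture(scope="module")
def rnhab():
    return r.load_scenario("rnhAB")


class TestChromosomeState:
    def test_pre_uv_has_no_lesions(self, rnhab):
        state = sd.simulate_chromosome_state(rnhab, r.LOG_TIMEPOINT, seed=0)
        assert state.n_pd == 0
        assert state.rdh_intervals.shape == (0, 2)
        assert state.total_hybrid_nt() > 0  # baseline hybrids only

    def test_lesion_count_matches_dose(self, rnhab):
        counts = [sd.simulate_chromosome_state(rnhab, 0.0, seed=s).n_pd
                  for s in range(40)]
        expected = rnhab.pd_count_mean()
        # Poisson mean over 40 genomes: 3 sigma band
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_anchors_lie_inside_hybrids(self, rnhab):
        state = sd.simulate_chromosome_state(rnhab, 30.0, seed=1)
        assert state.rdh_intervals.shape[0] > 0
        for (s, e), a in zip(state.rdh_intervals, state.rdh_anchor_index):
            p = state.pd_positions[a]
            assert s - 1 <= p <= e
            assert state.pd_slow[a]

    def test_invalid_timepoint_rejected(self, rnhab):
        with pytest.raises(ValueError):
            sd.simulate_chromosome_state(rnhab, -5.0, seed=0)


class TestDigest:
    def test_conservation(self, rnhab):
        state = sd.simulate_chromosome_state(rnhab, 30.0, seed=2)
        frags = sd.digest(state, "HaeII", seed=3)
        assert frags.total_length == state.genome_length
        assert int(frags.pd_counts.sum()) == state.n_pd
        assert float(frags.rdh_nt.sum()) == pytest.approx(state.total_hybrid_nt())

    def test_uncut_returns_single_fragment(self, rnhab):
        state = sd.simulate_chromosome_state(rnhab, 30.0, seed=2)
        frags = sd.digest(state, "uncut", seed=3)
        assert len(frags) == 1
        assert frags.total_length == state.genome_length

    def test_mean_fragment_length(self, rnhab):
        state = sd.simulate_chromosome_state(rnhab, r.LOG_TIMEPOINT, seed=4)
        frags = sd.digest(state, "HaeIII", seed=5)
        mean, lo, hi = sd.ENZYME_MODELS["HaeIII"]
        got = frags.lengths.mean()
        assert 0.7 * mean < got < 1.6 * mean  # partial-digest tail inflates slightly

    def test_hybrid_fragments_longer_than_bulk(self, rnhab):
        """Hybrids block cutting, so their fragments beat the bulk length."""
        frags = sd.pooled_digest(rnhab, 30.0, "HaeII", seed=6, n_genomes=10)
        with_h = frags.lengths[frags.rdh_nt > 1000]
        without = frags.lengths[frags.rdh_nt == 0]
        assert with_h.size > 0
        assert with_h.mean() > 2 * without.mean()

    def test_unknown_enzyme_rejected(self, rnhab):
        state = sd.simulate_chromosome_state(rnhab, 30.0, seed=2)
        with pytest.raises(ValueError, match="enzyme"):
            sd.digest(state, "NotI", seed=0)


class TestDeterminism:
    def test_blot_table_reproducible(self, rnhab):
        a = sd.simulate_blot_table(rnhab, [r.LOG_TIMEPOINT, 60.0], 3, seed=11)
        b = sd.simulate_blot_table(rnhab, [r.LOG_TIMEPOINT, 60.0], 3, seed=11)
        assert a.to_csv() == b.to_csv()

    def test_band_table_reproducible(self, rnhab):
        a = sd.simulate_relaxation_series(rnhab, 9_200, [5.0], seed=11)
        b = sd.simulate_relaxation_series(rnhab, 9_200, [5.0], seed=11)
        assert a.to_csv() == b.to_csv()

    def test_lane_set_reproducible(self, rnhab):
        a = sd.simulate_lane_set(rnhab, [5.0], seed=11, n_genomes=5)
        b = sd.simulate_lane_set(rnhab, [5.0], seed=11, n_genomes=5)
        assert a.keys() == b.keys()
        for key in a:
            np.testing.assert_array_equal(a[key].signal, b[key].signal)

    def test_different_seeds_differ(self, rnhab):
        a = sd.simulate_blot_table(rnhab, [60.0], 1, seed=1)
        b = sd.simulate_blot_table(rnhab, [60.0], 1, seed=2)
        assert a.to_csv() != b.to_csv()


class TestDrip:
    def test_mass_balance_exact(self):
        sc = r.load_scenario("rnhAB_uvrA")
        frags = sd.pooled_digest(sc, 30.0, "HaeII", seed=7, n_genomes=10)
        drip = sd.simulate_drip(frags, sc, seed=8)
        sig = drip.signals
        for channel in ("southern", "s96", "pd"):
            assert sig.loc["drip", channel] + sig.loc["eluate", channel] == \
                pytest.approx(sig.loc["input", channel], rel=1e-9)

    def test_rnase_depletes_hybrid_signal(self):
        sc = r.load_scenario("rnhAB_uvrA")
        frags = sd.pooled_digest(sc, 30.0, "HaeII", seed=7, n_genomes=10)
        plain = sd.simulate_drip(frags, sc, seed=8)
        treated = sd.simulate_drip(frags, sc, rnase_treated=True, seed=8)
        ratio = treated.signals.loc["input", "s96"] / plain.signals.loc["input", "s96"]
        assert ratio == pytest.approx(sc.rnase_survival, rel=1e-6)

    def test_hybrid_fragments_enriched(self):
        sc = r.load_scenario("rnhAB_uvrA")
        frags = sd.pooled_digest(sc, 30.0, "sheared", seed=9, n_genomes=10)
        drip = sd.simulate_drip(frags, sc, seed=10)
        dens = lambda f: drip.signals.loc[f, "s96"] / drip.signals.loc[f, "southern"]
        assert dens("drip") > 3 * dens("input")


class TestSpotAssay:
    def test_tenfold_dilution_scaling(self):
        sc = r.load_scenario("WT")
        assay = sd.simulate_spot_assay(sc, 0.0, seed=12, n_cultures=20)
        means = assay.counts.groupby("dilution")["count"].mean()
        # counts large enough to be stable in the first two dilutions
        assert means[0] / means[1] == pytest.approx(10.0, rel=0.05)

    def test_unknown_dose_rejected(self):
        sc = r.load_scenario("WT")
        with pytest.raises(KeyError):
            sd.simulate_spot_assay(sc, 1.23, seed=0)


class TestSynthesisRates:
    def test_dilutions_are_undoable_exactly(self):
        sc = r.load_scenario("WT").with_(noise_cv=0.0)
        series = sd.simulate_synthesis_rates(sc, uv=False, seed=0)
        corrected = series["raw_rate"] * series["cumulative_dilution"]
        np.testing.assert_allclose(corrected, 1.0)  # WT no-UV curve is flat 1.0

    def test_dilution_factors_logged(self):
        sc = r.load_scenario("WT")
        series = sd.simulate_synthesis_rates(sc, uv=True, seed=0)
        assert set(series["cumulative_dilution"]) == {1.0, 2.0, 4.0, 8.0}


class TestMigrationModel:
    def test_position_size_roundtrip(self):
        mig = sd.MigrationModel()
        sizes = np.array([400.0, 1_200.0, 9_000.0, 40_000.0])
        np.testing.assert_allclose(mig.size_at(mig.position(sizes)), sizes, rtol=1e-9)

    def test_monotone(self):
        mig = sd.MigrationModel()
        assert mig.position(1_000.0) > mig.position(10_000.0)  # small runs far
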
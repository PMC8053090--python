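import math

import numpy as np
import pandas as pd
import pytest

from rdhquant import relaxation as rx


class TestSupercoiledFraction:
    def test_basic(self):
        assert rx.supercoiled_fraction(3.0, 1.0) == 0.75

    def test_scale_invariant(self):
        assert rx.supercoiled_fraction(30.0, 10.0) == rx.supercoiled_fraction(3.0, 1.0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            rx.supercoiled_fraction(-1.0, 1.0)

    def test_rejects_empty_lane(self):
        with pytest.raises(ValueError):
            rx.supercoiled_fraction(0.0, 0.0)


class TestMeanNicks:
    def test_zero_class_formula(self):
        f = math.exp(-1.5)
        assert rx.mean_nicks(f, 1.0) == pytest.approx(1.5)

    def test_background_cancels(self):
        # same background factor in both lanes drops out of the ratio
        bg = 0.9
        assert rx.mean_nicks(bg * math.exp(-2.0), bg) == pytest.approx(2.0)

    def test_negative_clamped_to_zero(self):
        assert rx.mean_nicks(0.8, 0.7) == 0.0

    def test_saturated_returns_inf(self):
        assert rx.mean_nicks(0.0, 0.9) == math.inf

    def test_zero_untreated_rejected(self):
        with pytest.raises(ValueError):
            rx.mean_nicks(0.5, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rx.mean_nicks(1.2, 0.9)


class TestLesionsPerGenome:
    def test_spec_arithmetic(self):
        # 1.5 nicks on a 9,200-nt plasmid scale to 1500 per 9.2e6-nt genome
        assert rx.lesions_per_genome(1.5, 9_200, 9_200_000) == pytest.approx(1500.0)

    def test_estimate_dataclass_consistency(self):
        est = rx.LesionDensityEstimate(1.5, 9_200, 9_200_000)
        assert est.lesions_per_genome == pytest.approx(1500.0)
        assert est.nt_per_lesion == pytest.approx(9_200 / 1.5)

    def test_zero_nicks_infinite_spacing(self):
        est = rx.LesionDensityEstimate(0.0, 9_200, 9_200_000)
        assert est.nt_per_lesion == math.inf
        assert est.lesions_per_genome == 0.0


def _poisson_band_table(lam, n_reps, n_molecules, rng):
    rows = []
    for rep in range(n_reps):
        for treatment, rate in (("T4PDG", lam), ("none", 0.0)):
            nicks = rng.poisson(rate, size=n_molecules)
            sc = float((nicks == 0).sum())
            rows.append({"sample": f"r{rep}", "time_min": 5.0,
                         "treatment": treatment, "sc_signal": sc,
                         "rc_signal": float(n_molecules - sc)})
    return pd.DataFrame(rows)


@pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 2.0, 3.0])
def test_estimator_consistent_with_poisson_oracle(lam, rng):
    """Mean estimate over 200 replicates is within 3 SE of the true lambda."""
    n_reps, n_mol = 200, 2000
    table = _poisson_band_table(lam, n_reps, n_mol, rng)
    per_rep = []
    for _, grp in table.groupby("sample"):
        est = rx.estimate_series(grp, plasmid_length_nt=1.0, genome_length_nt=1.0)
        per_rep.append(float(est["mean_nicks"].iloc[0]))
    per_rep = np.asarray(per_rep)
    se = per_rep.std(ddof=1) / math.sqrt(n_reps)
    assert abs(per_rep.mean() - lam) < 3 * se + 1e-12


def test_estimate_series_requires_untreated_lane():
    df = pd.DataFrame([{"sample": "a", "time_min": 5.0, "treatment": "T4PDG",
                        "sc_signal": 10.0, "rc_signal": 10.0}])
    with pytest.raises(ValueError, match="none"):
        rx.estimate_series(df, 9_200)


def test_estimate_series_pooling_modes_agree_without_noise(rng):
    table = _poisson_band_table(1.0, 10, 5000, rng)
    a = rx.estimate_series(table, 9_200, pool="estimates")
    b = rx.estimate_series(table, 9_200, pool="fractions")
    assert a["mean_nicks"].iloc[0] == pytest.approx(b["mean_nicks"].iloc[0], rel=0.05)


class TestPercentRemaining:
    def test_background_subtraction_and_reference(self):
        est = {-1.0: 45.0, 5.0: 1545.0, 30.0: 795.0, 60.0: 195.0}
        out = rx.percent_remaining(est)
        assert -1.0 not in set(out["time_min"])
        by_t = dict(zip(out["time_min"], out["percent_remaining"]))
        assert by_t[5.0] == pytest.approx(100.0)
        assert by_t[30.0] == pytest.approx(50.0)
        assert by_t[60.0] == pytest.approx(10.0)

    def test_negative_clipped(self):
        out = rx.percent_remaining({-1.0: 50.0, 5.0: 150.0, 60.0: 40.0})
        by_t = dict(zip(out["time_min"], out["percent_remaining"]))
        assert by_t[60.0] == 0.0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            rx.percent_remaining({30.0: 10.0})


def test_read_band_table_roundtrip(tmp_path):
    df = pd.DataFrame([{"sample": "a", "time_min": 5.0, "treatment": "T4PDG",
                        "sc_signal": 1.0, "rc_signal": 2.0}])
    path = tmp_path / "bands.tsv"
    df.to_csv(path, sep="\t", index=False)
    back = rx.read_band_table(path)
    pd.testing.assert_frame_equal(back, df)


def test_read_band_table_missing_columns(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("a\tb\n1\t2\n")
    with pytest.raises(ValueError, match="missing columns"):
        rx.read_band_table(path)
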
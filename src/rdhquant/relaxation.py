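"""Poisson zero-class lesion densitometry from plasmid topoisomer bands.

A nicking treatment (T4 PD-glycosylase for pyrimidine dimers, RNase HII/HI
for DNA-ribonucleotides) relaxes every plasmid carrying at least one
cleavable lesion.  The supercoiled band therefore collects the Poisson zero
class, and the mean number of nicks per plasmid is

    n = -ln(F_treated / F_untreated)

where F is the supercoiled fraction of the monomer bands and the buffer-only
lane accounts for background nicking.  Scaling by genome/plasmid length (both
in double-stranded nt) converts the per-plasmid mean to lesions per genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import LOG_TIMEPOINT

__all__ = [
    "supercoiled_fraction",
    "mean_nicks",
    "lesions_per_genome",
    "LesionDensityEstimate",
    "estimate_density",
    "estimate_series",
    "percent_remaining",
    "read_band_table",
]

logger = logging.getLogger(__name__)

DEFAULT_GENOME_NT = 9_200_000


def supercoiled_fraction(supercoiled_signal: float, relaxed_signal: float) -> float:
    """Fraction of the monomer signal in the supercoiled band, SC/(SC+RC)."""
    if supercoiled_signal < 0 or relaxed_signal < 0:
        raise ValueError("band signals must be >= 0")
    total = supercoiled_signal + relaxed_signal
    if total <= 0:
        raise ValueError("cannot quantify a lane with zero total monomer signal")
    return supercoiled_signal / total


def mean_nicks(f_treated: float, f_untreated: float) -> float:
    """Mean nicks per plasmid from the zero class: -ln(F_treated/F_untreated).

    F_treated > F_untreated (a negative estimate) is blot noise, not signal:
    it is clamped to 0 with a logged warning.  F_treated == 0 means every
    plasmid was nicked; the density is saturated and +inf is returned.
    """
    for name, f in (("f_treated", f_treated), ("f_untreated", f_untreated)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {f!r}")
    if f_untreated == 0:
        raise ValueError("f_untreated must be > 0 to normalize background nicking")
    if f_treated == 0:
        logger.warning("supercoiled band empty after treatment: density saturated "
                       "(every plasmid nicked); returning inf")
        return math.inf
    if f_treated > f_untreated:
        logger.warning(
            "F_treated (%.4g) > F_untreated (%.4g): negative nick estimate "
            "clamped to 0 (blot noise)", f_treated, f_untreated)
        return 0.0
    return -math.log(f_treated / f_untreated)


def lesions_per_genome(
    mean_nicks_per_plasmid: float,
    plasmid_length_nt: float,
    genome_length_nt: float = DEFAULT_GENOME_NT,
) -> float:
    """Scale a per-plasmid nick mean to a per-genome lesion count.

    Lengths are double-stranded nt (2 x bp).
    """
    if plasmid_length_nt <= 0:
        raise ValueError("plasmid_length_nt must be > 0")
    if mean_nicks_per_plasmid < 0:
        raise ValueError("mean nicks must be >= 0")
    return genome_length_nt * mean_nicks_per_plasmid / plasmid_length_nt


@dataclass(frozen=True)
class LesionDensityEstimate:
    """One timepoint's lesion density on all three scales."""

    mean_nicks: float
    plasmid_length_nt: float
    genome_length_nt: float

    def __post_init__(self) -> None:
        if self.mean_nicks < 0:
            raise ValueError("mean_nicks must be >= 0")
        if self.plasmid_length_nt <= 0:
            raise ValueError("plasmid length must be > 0")

    @property
    def nt_per_lesion(self) -> float:
        return math.inf if self.mean_nicks == 0 else self.plasmid_length_nt / self.mean_nicks

    @property
    def lesions_per_genome(self) -> float:
        value = lesions_per_genome(self.mean_nicks, self.plasmid_length_nt,
                                   self.genome_length_nt)
        # algebraic identity linking the three scales
        assert value == self.genome_length_nt * self.mean_nicks / self.plasmid_length_nt
        return value


def estimate_density(
    treated_sc: float, treated_rc: float,
    untreated_sc: float, untreated_rc: float,
    plasmid_length_nt: float,
    genome_length_nt: float = DEFAULT_GENOME_NT,
) -> LesionDensityEstimate:
    """Full zero-class pipeline for one treated/untreated lane pair."""
    f_t = supercoiled_fraction(treated_sc, treated_rc)
    f_u = supercoiled_fraction(untreated_sc, untreated_rc)
    return LesionDensityEstimate(mean_nicks(f_t, f_u), plasmid_length_nt,
                                 genome_length_nt)


def estimate_series(
    band_table: pd.DataFrame,
    plasmid_length_nt: float,
    genome_length_nt: float = DEFAULT_GENOME_NT,
    treatment: str = "T4PDG",
    pool: str = "estimates",
) -> pd.DataFrame:
    """Per-timepoint lesion estimates from a band table.

    Expects columns time_min, treatment, sc_signal, rc_signal, with a
    buffer-only ("none") lane per timepoint.  Replicate gels are pooled by
    averaging per-gel estimates (default) or by averaging supercoiled
    fractions first (``pool="fractions"``).

    Returns a DataFrame with columns time_min, mean_nicks, lesions_per_genome.
    """
    if pool not in ("estimates", "fractions"):
        raise ValueError("pool must be 'estimates' or 'fractions'")
    rows = []
    for t, grp in band_table.groupby("time_min", sort=True):
        treated = grp[grp["treatment"] == treatment]
        untreated = grp[grp["treatment"] == "none"]
        if treated.empty or untreated.empty:
            raise ValueError(f"timepoint {t}: need both {treatment!r} and 'none' lanes")
        f_t = [supercoiled_fraction(r.sc_signal, r.rc_signal) for r in treated.itertuples()]
        f_u = [supercoiled_fraction(r.sc_signal, r.rc_signal) for r in untreated.itertuples()]
        if pool == "fractions":
            nicks = mean_nicks(float(np.mean(f_t)), float(np.mean(f_u)))
        else:
            pairs = min(len(f_t), len(f_u))
            nicks = float(np.mean([mean_nicks(f_t[i], f_u[i]) for i in range(pairs)]))
        rows.append({
            "time_min": t,
            "mean_nicks": nicks,
            "lesions_per_genome": lesions_per_genome(nicks, plasmid_length_nt,
                                                     genome_length_nt),
        })
    return pd.DataFrame(rows)


def percent_remaining(
    estimates_by_time: pd.DataFrame | dict,
    reference_timepoint: float = 5.0,
    background_timepoint: float = LOG_TIMEPOINT,
) -> pd.DataFrame:
    """Removal time course: background-subtracted percent of the reference.

    The pre-UV estimate (timepoint ``background_timepoint``, the procedure
    background of ~45 nicks/genome) is subtracted from every point, and each
    point is expressed as a percentage of the (subtracted) reference, the
    5-min post-UV sample by convention.  Negative background-subtracted
    values are clipped at 0 with a logged warning.
    """
    if isinstance(estimates_by_time, dict):
        df = pd.DataFrame({"time_min": list(estimates_by_time),
                           "lesions_per_genome": list(estimates_by_time.values())})
    else:
        df = estimates_by_time.copy()
    times = df["time_min"].to_numpy(dtype=float)
    values = df["lesions_per_genome"].to_numpy(dtype=float)

    background = 0.0
    if background_timepoint is not None and (times == background_timepoint).any():
        background = float(values[times == background_timepoint][0])
    if not (times == reference_timepoint).any():
        raise ValueError(f"reference timepoint {reference_timepoint} missing")

    adj = values - background
    if (adj < 0).any():
        logger.warning("%d background-subtracted estimates were negative; clipped to 0",
                       int((adj < 0).sum()))
        adj = np.clip(adj, 0.0, None)
    ref = float(adj[times == reference_timepoint][0])
    if ref <= 0:
        raise ValueError("reference estimate is zero after background subtraction")
    out = df[["time_min"]].copy()
    out["lesions_per_genome"] = adj
    out["percent_remaining"] = 100.0 * adj / ref
    return out[out["time_min"] != background_timepoint].reset_index(drop=True)


def read_band_table(path) -> pd.DataFrame:
    """Read the TSV band-table schema (sample, time_min, treatment, sc_signal, rc_signal)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"time_min", "treatment", "sc_signal", "rc_signal"} - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    return df
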
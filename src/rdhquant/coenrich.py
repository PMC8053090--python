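"""Per-fraction co-enrichment of RNA:DNA hybrids and pyrimidine dimers.

Each gel lane (Southern, S9.6 western, anti-PD western of the same restriction
digest) is partitioned into 16 equal migration windows from the well down to a
bottom size cutoff.  Per fraction, western signals are divided by the Southern
signal (loading/DNA correction), then normalized:

* RDH: post-UV density over the pre-UV (log) density of the same fraction;
* PD:  later-timepoint density over the early (5 min) density — the fraction
  of dimers still unrepaired there.

The co-enrichment statistic is the product normalized-RDH x normalized-PD per
fraction; a peak well above the other fractions means hybrids and unrepaired
dimers sit on the same restriction fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import LaneProfile
from .synthdata import MigrationModel

__all__ = [
    "FractionSeries",
    "CoenrichmentProfile",
    "partition_lane",
    "fraction_densities",
    "normalize_fractions",
    "coenrichment_profile",
    "fraction_size_map",
    "coenrichment_from_lanes",
]

logger = logging.getLogger(__name__)

N_FRACTIONS = 16
BOTTOM_CUTOFF_KB = 0.35


@dataclass(frozen=True)
class FractionSeries:
    """Integrated signal of one lane in each of the n migration fractions."""

    strain: str
    timepoint: float
    channel: str
    values: np.ndarray
    edges: np.ndarray  # n+1 migration coordinates, increasing

    def __post_init__(self) -> None:
        if self.values.ndim != 1 or self.edges.shape != (self.values.size + 1,):
            raise ValueError("need n values and n+1 edges")
        if (np.diff(self.edges) <= 0).any():
            raise ValueError("fraction edges must increase")
        if (self.values < -1e-12).any():
            raise ValueError("fraction signals must be >= 0")

    @property
    def n(self) -> int:
        return int(self.values.size)


def partition_lane(
    lane: LaneProfile,
    n_fractions: int = N_FRACTIONS,
    bottom_cutoff_kb: float = BOTTOM_CUTOFF_KB,
    migration_model: MigrationModel | None = None,
) -> FractionSeries:
    """Integrate a lane profile over n equal migration windows.

    The windows run from the well (migration 0) to the position of the bottom
    size cutoff; signal below the cutoff (degraded / very short fragments) is
    excluded.  The sum of the fraction signals equals the lane integral over
    the partitioned span (conservation).
    """
    if n_fractions < 2:
        raise ValueError("need at least 2 fractions")
    mig = migration_model or MigrationModel()
    if not mig.s_bot * (1 - 1e-9) <= bottom_cutoff_kb * 1000.0 <= mig.s_top * (1 + 1e-9):
        raise ValueError("bottom cutoff outside the migration model's size range")
    x_cut = float(mig.position(bottom_cutoff_kb * 1000.0))
    if x_cut > lane.position[-1] + 1e-9:
        raise ValueError("lane profile ends above the bottom cutoff position")
    edges = np.linspace(0.0, x_cut, n_fractions + 1)
    values = np.array([lane.integral(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])])
    return FractionSeries(lane.strain, lane.timepoint, lane.channel,
                          values, edges)


def fraction_densities(western: FractionSeries, southern: FractionSeries) -> np.ndarray:
    """Per-fraction western density over Southern DNA signal.

    Fractions with no detectable DNA are flagged missing (NaN), not zero.
    """
    if western.n != southern.n or not np.allclose(western.edges, southern.edges):
        raise ValueError("western and Southern series use different partitions")
    s = southern.values
    out = np.full(western.n, np.nan)
    ok = s > 0
    if not ok.all():
        logger.warning("%d fraction(s) have zero Southern signal; density flagged "
                       "missing (NaN)", int((~ok).sum()))
    out[ok] = western.values[ok] / s[ok]
    return out


def normalize_fractions(test: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Element-wise ratio of density vectors; NaN propagates as missing."""
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("density vectors have different lengths")
    out = np.full(test.shape, np.nan)
    with np.errstate(invalid="ignore"):
        ok = (reference > 0) & ~np.isnan(test)
    bad = (reference == 0) & ~np.isnan(test) & (test > 0)
    if bad.any():
        logger.warning("%d fraction(s) have zero reference density with nonzero "
                       "test density; flagged missing", int(bad.sum()))
    out[ok] = test[ok] / reference[ok]
    return out


@dataclass(frozen=True)
class CoenrichmentProfile:
    """Per-fraction co-enrichment with its peak summary."""

    strain: str
    timepoint: float
    values: np.ndarray          # n fractions; NaN = missing
    size_intervals_kb: np.ndarray  # (n, 2), [upper, lower] kb per fraction

    def __post_init__(self) -> None:
        if self.values.ndim != 1 or self.size_intervals_kb.shape != (self.values.size, 2):
            raise ValueError("need one size interval per fraction")

    @property
    def peak_fraction(self) -> int:
        """1-based index of the maximal fraction (ties -> lowest index)."""
        v = self.values
        if np.isnan(v).all():
            raise ValueError("all fractions missing; no peak")
        idx = int(np.nanargmax(v))
        ties = np.flatnonzero(np.isclose(v, v[idx], equal_nan=False))
        if ties.size > 1:
            logger.info("co-enrichment peak tie among fractions %s; reporting "
                        "the lowest index", (ties + 1).tolist())
            idx = int(ties[0])
        return idx + 1

    @property
    def peak_value(self) -> float:
        return float(self.values[self.peak_fraction - 1])

    @property
    def non_peak_mean(self) -> float:
        mask = np.ones(self.values.size, dtype=bool)
        mask[self.peak_fraction - 1] = False
        return float(np.nanmean(self.values[mask]))

    @property
    def peak_size_kb(self) -> tuple[float, float]:
        hi, lo = self.size_intervals_kb[self.peak_fraction - 1]
        return float(hi), float(lo)


def fraction_size_map(
    migration_model: MigrationModel | None = None,
    n_fractions: int = N_FRACTIONS,
    bottom_cutoff_kb: float = BOTTOM_CUTOFF_KB,
) -> np.ndarray:
    """(n, 2) array of [upper, lower] fragment sizes (kb) per fraction."""
    mig = migration_model or MigrationModel()
    x_cut = float(mig.position(bottom_cutoff_kb * 1000.0))
    edges = np.linspace(0.0, x_cut, n_fractions + 1)
    sizes = mig.size_at(edges) / 1000.0
    return np.column_stack([sizes[:-1], sizes[1:]])


def coenrichment_profile(
    normalized_rdh: np.ndarray,
    normalized_pd: np.ndarray,
    strain: str = "",
    timepoint: float = float("nan"),
    migration_model: MigrationModel | None = None,
    bottom_cutoff_kb: float = BOTTOM_CUTOFF_KB,
) -> CoenrichmentProfile:
    """Combine normalized RDH and PD vectors into a co-enrichment profile."""
    rdh = np.asarray(normalized_rdh, dtype=float)
    pdv = np.asarray(normalized_pd, dtype=float)
    if rdh.shape != pdv.shape:
        raise ValueError("RDH and PD vectors have different lengths")
    values = rdh * pdv
    sizes = fraction_size_map(migration_model, rdh.size, bottom_cutoff_kb)
    return CoenrichmentProfile(strain, timepoint, values, sizes)


def coenrichment_from_lanes(
    lanes: dict,
    rdh_timepoint: float = 30.0,
    rdh_reference_timepoint: float = -1.0,
    pd_timepoint: float = 30.0,
    pd_reference_timepoint: float = 5.0,
    n_fractions: int = N_FRACTIONS,
    bottom_cutoff_kb: float = BOTTOM_CUTOFF_KB,
    migration_model: MigrationModel | None = None,
) -> CoenrichmentProfile:
    """Full pipeline from a ``{(timepoint, channel): LaneProfile}`` lane set.

    Needs Southern + S9.6 lanes at *rdh_timepoint* and its pre-UV reference,
    and Southern + anti-PD lanes at *pd_timepoint* and its early reference.
    """
    def density(timepoint: float, channel: str) -> np.ndarray:
        try:
            western = lanes[(timepoint, channel)]
            southern = lanes[(timepoint, "southern")]
        except KeyError as err:
            raise KeyError(f"lane set is missing {err.args[0]!r}") from None
        part = lambda lane: partition_lane(lane, n_fractions, bottom_cutoff_kb,
                                           migration_model)
        return fraction_densities(part(western), part(southern))

    norm_rdh = normalize_fractions(density(rdh_timepoint, "s96"),
                                   density(rdh_reference_timepoint, "s96"))
    norm_pd = normalize_fractions(density(pd_timepoint, "pd"),
                                  density(pd_reference_timepoint, "pd"))
    strain = lanes[(rdh_timepoint, "s96")].strain
    return coenrichment_profile(norm_rdh, norm_pd, strain=strain,
                                timepoint=rdh_timepoint,
                                migration_model=migration_model,
                                bottom_cutoff_kb=bottom_cutoff_kb)
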
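"""Shared in-memory containers for the assay pipelines.

Tabular data (band tables, blot measurements, spot counts, synthesis series)
travels as pandas DataFrames with documented column schemas; the structured
objects below hold what a DataFrame would obscure (coordinate arrays, per-
fragment lesion bookkeeping, paired per-fraction signals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeState",
    "FragmentSet",
    "LaneProfile",
    "DripFractions",
    "SpotAssay",
    "CHANNELS",
]

#: Blot channels: Southern genomic DNA, S9.6 anti-hybrid western, anti-PD western.
CHANNELS = ("southern", "s96", "pd")


@dataclass(frozen=True)
class ChromosomeState:
    """Lesion configuration of one genome at one post-UV timepoint.

    Coordinates are 0-based nt on a single linear genome; hybrid intervals are
    half-open ``[start, end)``.  ``rdh_intervals`` are the UV-induced hybrids,
    each anchored at one slow (TEC-stalling) pyrimidine dimer whose index into
    the PD arrays is ``rdh_anchor_index``.  ``background_hybrids`` are the
    short growth-associated / dispersed hybrids that carry S9.6 signal but are
    not anchored at a lesion.
    """

    genome_length: int
    timepoint: float
    pd_positions: np.ndarray          # surviving PDs only, sorted
    pd_slow: np.ndarray               # bool, same length
    rdh_intervals: np.ndarray         # (n, 2) int
    rdh_anchor_index: np.ndarray      # (n,) int, indexes pd_positions
    background_hybrids: np.ndarray    # (m, 2) int

    def __post_init__(self) -> None:
        g = self.genome_length
        pos = self.pd_positions
        if pos.size and (pos.min() < 0 or pos.max() >= g):
            raise ValueError("PD positions outside [0, genome_length)")
        for name in ("rdh_intervals", "background_hybrids"):
            iv = getattr(self, name)
            if iv.size and (
                (iv[:, 0] >= iv[:, 1]).any() or iv.min() < 0 or iv.max() > g
            ):
                raise ValueError(f"{name}: degenerate or out-of-genome interval")
        if self.rdh_intervals.shape[0] != self.rdh_anchor_index.shape[0]:
            raise ValueError("one anchor per RDH interval required")
        for (s, e), a in zip(self.rdh_intervals, self.rdh_anchor_index):
            p = self.pd_positions[a]
            if not (s - 1 <= p <= e):  # contains or abuts
                raise ValueError("RDH interval does not contain/abut its anchor")

    @property
    def n_pd(self) -> int:
        return int(self.pd_positions.size)

    def hybrid_intervals(self) -> np.ndarray:
        """All hybrid intervals (anchored + background), merged and sorted."""
        ivs = [iv for iv in (self.rdh_intervals, self.background_hybrids) if iv.size]
        if not ivs:
            return np.empty((0, 2), dtype=np.int64)
        iv = np.concatenate(ivs)
        iv = iv[np.argsort(iv[:, 0])]
        merged = [iv[0].tolist()]
        for s, e in iv[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.asarray(merged, dtype=np.int64)

    def total_hybrid_nt(self) -> int:
        iv = self.hybrid_intervals()
        return int((iv[:, 1] - iv[:, 0]).sum()) if iv.size else 0


@dataclass(frozen=True)
class FragmentSet:
    """Restriction (or shear) fragments of one chromosome state.

    ``rdh_nt`` is the hybrid content of each fragment in nt; PD counts and
    hybrid nt are conserved totals of the digested state.
    """

    enzyme: str
    lengths: np.ndarray
    pd_counts: np.ndarray
    rdh_nt: np.ndarray

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            raise ValueError("fragment lengths must be > 0")
        if (self.pd_counts < 0).any():
            raise ValueError("PD counts must be >= 0")
        if (self.rdh_nt > self.lengths + 1e-9).any():
            raise ValueError("hybrid nt cannot exceed fragment length")

    def __len__(self) -> int:
        return int(self.lengths.size)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())


@dataclass(frozen=True)
class LaneProfile:
    """One gel lane in one channel: signal density along the migration axis.

    ``position`` increases strictly from the well (0) toward the lane bottom.
    """

    strain: str
    timepoint: float
    channel: str
    position: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; use {CHANNELS}")
        if self.position.size < 32:
            raise ValueError("lane profile needs >= 32 samples")
        if (np.diff(self.position) <= 0).any():
            raise ValueError("positions must increase strictly from the well")
        if (self.signal < 0).any():
            raise ValueError("signals must be >= 0")

    def integral(self, lo: float | None = None, hi: float | None = None) -> float:
        x, y = self.position, self.signal
        lo = x[0] if lo is None else lo
        hi = x[-1] if hi is None else hi
        grid = np.unique(np.concatenate([x[(x >= lo) & (x <= hi)], [lo, hi]]))
        return float(np.trapezoid(np.interp(grid, x, y), grid))


@dataclass(frozen=True)
class DripFractions:
    """Signals of one DRIP experiment: input / DRIP (bound) / eluate (unbound).

    ``signals`` is a 3x3 DataFrame (rows input, drip, eluate; columns
    southern, s96, pd).  ``simulated`` marks tables generated by the package,
    for which the exact mass balance drip + eluate = input is guaranteed.
    """

    digest: str
    rnase_treated: bool
    signals: pd.DataFrame
    simulated: bool = True

    def __post_init__(self) -> None:
        want_rows = ["input", "drip", "eluate"]
        if list(self.signals.index) != want_rows or set(self.signals.columns) != set(CHANNELS):
            raise ValueError("signals must be indexed input/drip/eluate x channels")
        if (self.signals.to_numpy() < 0).any():
            raise ValueError("signals must be >= 0")


@dataclass(frozen=True)
class SpotAssay:
    """Serial-dilution spot counts for one strain at one dose.

    ``counts`` columns: culture (int), dilution (exponent, 0-based), count.
    """

    strain: str
    dose: float
    spot_volume_ml: float
    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        c = self.counts
        if not {"culture", "dilution", "count"} <= set(c.columns):
            raise ValueError("counts needs columns culture, dilution, count")
        if (c["count"] < 0).any():
            raise ValueError("colony counts must be >= 0")
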
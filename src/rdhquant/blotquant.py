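"""Western/Southern blot normalization and fold changes.

Whole-lane western signals (S9.6 anti-hybrid, anti-PD) are first converted to
densities by dividing by the Southern (total DNA) signal of the same lane,
which cancels loading differences.  Two normalization rules are used:

* ``"rdh"`` — every S9.6 density on a blot (batch) is divided by the density
  of that blot's rnhAB log-culture lane, so RDH levels are comparable across
  strains and blots on a single scale.
* ``"pd"`` — each strain's anti-PD series is background-subtracted (the
  pre-UV lane measures the nonspecific floor) and expressed as a percentage
  of its own early post-UV reference point, giving a removal time course.
"""

from __future__ import annotations

import logging

import pandas as pd

from .scenario import LOG_TIMEPOINT

__all__ = ["band_density", "normalize_series", "fold_change"]

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("batch", "strain", "channel", "timepoint", "western", "southern")


def band_density(western_signal: float, southern_signal: float) -> float:
    """Loading-corrected density: western signal per unit Southern signal."""
    if western_signal < 0:
        raise ValueError("western signal must be >= 0")
    if southern_signal <= 0:
        raise ValueError("southern signal must be > 0 (no DNA in lane?)")
    return western_signal / southern_signal


def _check_columns(measurements: pd.DataFrame) -> None:
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")


def normalize_series(
    measurements: pd.DataFrame,
    rule: str,
    reference_strain: str = "rnhAB",
    reference_timepoint: float = 5.0,
    background_timepoint: float | None = LOG_TIMEPOINT,
) -> pd.DataFrame:
    """Apply a normalization rule to a table of blot measurements.

    ``measurements`` columns: batch, strain, channel, timepoint, western,
    southern (one row per lane).  Normalization never mixes batches: each
    blot carries its own reference lane.

    rule ``"rdh"``: keeps the ``s96`` rows; ``normalized`` is the density
    relative to the *reference_strain* lane at the pre-UV (log) timepoint of
    the same batch.

    rule ``"pd"``: keeps the ``pd`` rows; per batch and strain, the pre-UV
    density (``background_timepoint``; pass None to disable) is subtracted as
    the nonspecific antibody floor and the series is expressed as percent of
    its value at *reference_timepoint*.

    Returns the selected rows with added ``density`` and ``normalized``
    columns, sorted by batch, strain, timepoint.
    """
    _check_columns(measurements)
    if rule not in ("rdh", "pd"):
        raise ValueError("rule must be 'rdh' or 'pd'")
    channel = "s96" if rule == "rdh" else "pd"
    df = measurements[measurements["channel"] == channel].copy()
    if df.empty:
        raise ValueError(f"no {channel!r} rows to normalize")
    df["density"] = [band_density(w, s) for w, s in zip(df["western"], df["southern"])]

    out = []
    for batch, grp in df.groupby("batch", sort=True):
        grp = grp.copy()
        if rule == "rdh":
            ref_rows = grp[(grp["strain"] == reference_strain)
                           & (grp["timepoint"] == LOG_TIMEPOINT)]
            if ref_rows.empty:
                raise ValueError(
                    f"batch {batch!r}: missing {reference_strain} log reference lane")
            ref = float(ref_rows["density"].mean())
            if ref <= 0:
                raise ValueError(f"batch {batch!r}: zero reference density")
            grp["normalized"] = grp["density"] / ref
            out.append(grp)
        else:
            for strain, sgrp in grp.groupby("strain", sort=True):
                sgrp = sgrp.copy()
                bg = 0.0
                if background_timepoint is not None:
                    bg_rows = sgrp[sgrp["timepoint"] == background_timepoint]
                    if bg_rows.empty:
                        logger.warning(
                            "batch %r strain %r: no background lane at t=%s; "
                            "skipping background subtraction",
                            batch, strain, background_timepoint)
                    else:
                        bg = float(bg_rows["density"].mean())
                ref_rows = sgrp[sgrp["timepoint"] == reference_timepoint]
                if ref_rows.empty:
                    raise ValueError(
                        f"batch {batch!r} strain {strain!r}: missing reference "
                        f"timepoint {reference_timepoint}")
                ref = float(ref_rows["density"].mean()) - bg
                if ref <= 0:
                    raise ValueError(
                        f"batch {batch!r} strain {strain!r}: reference density "
                        "is zero after background subtraction")
                adj = (sgrp["density"] - bg).clip(lower=0.0)
                sgrp["normalized"] = 100.0 * adj / ref
                out.append(sgrp[sgrp["timepoint"] != background_timepoint])
    result = pd.concat(out, ignore_index=True)
    return result.sort_values(["batch", "strain", "timepoint"]).reset_index(drop=True)


def fold_change(
    normalized: pd.DataFrame,
    strain: str,
    timepoint: float,
    reference_timepoint: float = LOG_TIMEPOINT,
) -> float:
    """Ratio of a strain's normalized level between two timepoints.

    Replicate batches are averaged per timepoint before taking the ratio.
    """
    sub = normalized[normalized["strain"] == strain]
    if sub.empty:
        raise ValueError(f"strain {strain!r} not present in the normalized table")
    by_time = sub.groupby("timepoint")["normalized"].mean()
    for t in (timepoint, reference_timepoint):
        if t not in by_time.index:
            raise ValueError(f"strain {strain!r}: no measurement at t={t}")
    ref = float(by_time.loc[reference_timepoint])
    if ref <= 0:
        raise ValueError("reference level is zero; fold change undefined")
    return float(by_time.loc[timepoint]) / ref
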
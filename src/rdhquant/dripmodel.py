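"""DRIP enrichment statistics and the theoretical co-occurrence ceiling.

DRIP (DNA:RNA immunoprecipitation with the S9.6 antibody) splits a digest
into a bound (DRIP) and an unbound (eluate) fraction.  Enrichment of a marker
(hybrids themselves, or pyrimidine dimers) is its density in a fraction —
western signal per Southern DNA signal — relative to the input density.

If dimers and hybrids occur independently, the expected PD enrichment in the
DRIP fraction is capped: a captured fragment of S nt carries, beyond the one
dimer that may have anchored its hybrid, only the Poisson-expected lambda*S
bystander dimers, so

    E[PD enrichment] <= (1 + lambda*S) / (lambda*S)

with S the larger of the mean captured-fragment length and the mean hybrid
length (the capturable footprint).  Observed enrichment above this ceiling
would falsify independent placement.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .containers import CHANNELS, DripFractions

__all__ = [
    "fraction_density",
    "enrichment",
    "overall_enrichment",
    "enrichment_table",
    "expected_max_pd_enrichment",
    "mass_balance_report",
]

logger = logging.getLogger(__name__)


def fraction_density(drip: DripFractions, fraction: str, channel: str) -> float:
    """Western density (signal per Southern DNA) of one fraction."""
    if channel not in CHANNELS or channel == "southern":
        raise ValueError("channel must be 's96' or 'pd'")
    row = drip.signals.loc[fraction]
    dna = float(row["southern"])
    if dna <= 0:
        raise ValueError(f"{fraction!r} fraction contains no DNA; density undefined")
    return float(row[channel]) / dna


def enrichment(drip: DripFractions, channel: str, fraction: str = "drip") -> float:
    """Density of a fraction relative to the input density."""
    ref = fraction_density(drip, "input", channel)
    if ref <= 0:
        raise ValueError(f"input has no {channel} signal; enrichment undefined")
    return fraction_density(drip, fraction, channel) / ref


def overall_enrichment(drip: DripFractions, channel: str) -> float:
    """DRIP density over eluate density — the bound/unbound contrast.

    An eluate fully depleted of the marker makes the ratio infinite; +inf is
    returned with a logged warning rather than raising, since complete
    depletion is a legitimate (very strong) outcome.
    """
    num = fraction_density(drip, "drip", channel)
    den = fraction_density(drip, "eluate", channel)
    if den == 0:
        logger.warning("eluate carries no %s signal: overall enrichment is "
                       "infinite (complete depletion)", channel)
        return math.inf
    return num / den


def enrichment_table(drip: DripFractions) -> pd.DataFrame:
    """Enrichment vs input for both westerns in both fractions, plus overall."""
    rows = []
    for channel in ("s96", "pd"):
        rows.append({
            "channel": channel,
            "drip_vs_input": enrichment(drip, channel, "drip"),
            "eluate_vs_input": enrichment(drip, channel, "eluate"),
            "drip_vs_eluate": overall_enrichment(drip, channel),
        })
    return pd.DataFrame(rows).set_index("channel")


def expected_max_pd_enrichment(
    pd_density_per_nt: float,
    mean_fragment_nt: float,
    mean_rdh_nt: float,
) -> float:
    """Ceiling on DRIP PD enrichment under independent PD/hybrid placement.

    (1 + lambda*S)/(lambda*S) with lambda the genomic PD density per nt and
    S = max(mean captured-fragment length, mean hybrid length).
    """
    if pd_density_per_nt <= 0:
        raise ValueError("PD density must be > 0 (no dimers, no enrichment)")
    if mean_fragment_nt <= 0 or mean_rdh_nt <= 0:
        raise ValueError("mean lengths must be > 0")
    lam_s = pd_density_per_nt * max(mean_fragment_nt, mean_rdh_nt)
    return (1.0 + lam_s) / lam_s


def mass_balance_report(drip: DripFractions, rtol: float = 1e-6) -> pd.DataFrame:
    """Check drip + eluate == input per channel.

    For simulated tables the balance is exact and any violation is a bug; for
    real data losses during immunoprecipitation are expected and the check is
    reported as not applicable.
    """
    rows = []
    for channel in CHANNELS:
        col = drip.signals[channel]
        total = float(col["drip"] + col["eluate"])
        inp = float(col["input"])
        if not drip.simulated:
            status = "not applicable (real data: IP losses expected)"
        elif math.isclose(total, inp, rel_tol=rtol, abs_tol=rtol):
            status = "balanced"
        else:
            status = "VIOLATED"
        rows.append({"channel": channel, "input": inp,
                     "drip_plus_eluate": total, "status": status})
    report = pd.DataFrame(rows).set_index("channel")
    if (report["status"] == "VIOLATED").any():
        logger.warning("simulated DRIP table violates mass balance:\n%s", report)
    return report
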
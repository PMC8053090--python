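"""UV phenotypes: spot-titer survival, epistasis calls, synthesis rates.

Titers come from serial-dilution spot assays.  Only spots in the countable
window (default 3-300 colonies) are used; pooling their counts against their
total plated volume is the Poisson maximum-likelihood estimate and is
equivalent to inverse-variance weighting of the per-spot estimates.
Confidence intervals are exact Poisson (gamma) intervals on the pooled count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SpotAssay

__all__ = [
    "TiterEstimate",
    "titer",
    "survival",
    "survival_table",
    "epistasis_predict",
    "normalize_synthesis",
]

logger = logging.getLogger(__name__)

COUNTABLE_WINDOW = (3, 300)


@dataclass(frozen=True)
class TiterEstimate:
    """Pooled CFU/ml estimate with its exact Poisson confidence interval."""

    cfu_per_ml: float
    ci_low: float
    ci_high: float
    total_count: int
    #: Total plated volume in undiluted-culture equivalents (ml).
    effective_volume_ml: float
    flag: str = "ok"   # "ok", "extinct" (all spots empty), "uncountable"

    def __post_init__(self) -> None:
        if self.cfu_per_ml < 0 or self.effective_volume_ml < 0:
            raise ValueError("titer and volume must be >= 0")
        if not self.ci_low <= self.cfu_per_ml <= self.ci_high:
            raise ValueError("estimate must lie inside its confidence interval")


def _poisson_ci(count: int, exposure: float, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if count == 0 else stats.gamma.ppf(alpha / 2, count) / exposure
    hi = stats.gamma.ppf(1 - alpha / 2, count + 1) / exposure
    return float(lo), float(hi)


def titer(
    assay: SpotAssay,
    countable_window: tuple[int, int] = COUNTABLE_WINDOW,
    level: float = 0.95,
) -> TiterEstimate:
    """Pooled Poisson titer from the countable spots of one assay.

    Spots above the window are confluent (undercounted) and spots below it
    are statistically unreliable; both are excluded.  If every spot is empty
    the culture is flagged "extinct" and the one-sided upper bound is
    reported; if spots exist but none are countable the estimate falls back
    to all spots with flag "uncountable".
    """
    lo_n, hi_n = countable_window
    c = assay.counts
    exposure = assay.spot_volume_ml * 10.0 ** (-c["dilution"].to_numpy(dtype=float))
    counts = c["count"].to_numpy()

    flag = "ok"
    use = (counts >= lo_n) & (counts <= hi_n)
    if not use.any():
        if (counts == 0).all():
            flag = "extinct"
            use = np.ones_like(use)
        else:
            flag = "uncountable"
            logger.warning("%s at %g J/m^2: no spot in the countable window "
                           "%s; using all spots", assay.strain, assay.dose,
                           countable_window)
            use = np.ones_like(use)
    total = int(counts[use].sum())
    vol = float(exposure[use].sum())
    est = total / vol
    ci_low, ci_high = _poisson_ci(total, vol, level)
    return TiterEstimate(est, ci_low, ci_high, total, vol, flag)


def survival(treated: TiterEstimate, untreated: TiterEstimate) -> float:
    """Surviving fraction, capped at 1 (a ratio > 1 is counting noise)."""
    if untreated.cfu_per_ml <= 0:
        raise ValueError("untreated titer is zero; survival undefined")
    s = treated.cfu_per_ml / untreated.cfu_per_ml
    if s > 1.0:
        logger.warning("survival %.3g > 1 capped at 1 (counting noise)", s)
        return 1.0
    return s


def survival_table(
    assays_by_dose: dict[float, list[SpotAssay]],
    countable_window: tuple[int, int] = COUNTABLE_WINDOW,
) -> pd.DataFrame:
    """Mean survival and SEM over replicate cultures, per dose.

    ``assays_by_dose`` maps dose -> list of per-culture SpotAssay objects and
    must include dose 0.0 (the untreated reference).  Cultures are paired by
    list position.
    """
    if 0.0 not in assays_by_dose:
        raise ValueError("need dose 0.0 assays as the untreated reference")
    refs = [titer(a, countable_window) for a in assays_by_dose[0.0]]
    rows = []
    for dose in sorted(assays_by_dose):
        if dose == 0.0:
            continue
        assays = assays_by_dose[dose]
        if len(assays) != len(refs):
            raise ValueError(f"dose {dose}: replicate count differs from dose 0")
        s = np.array([survival(titer(a, countable_window), r)
                      for a, r in zip(assays, refs)])
        rows.append({
            "dose": dose,
            "survival": float(s.mean()),
            "sem": float(s.std(ddof=1) / math.sqrt(s.size)) if s.size > 1 else math.nan,
            "n": int(s.size),
        })
    return pd.DataFrame(rows)


def epistasis_predict(
    survival_a: float,
    survival_b: float,
    observed_double: float | None = None,
    threshold: float = 3.0,
) -> dict:
    """Multiplicative (no-interaction) prediction for a double mutant.

    If the observed double-mutant survival is supplied, the interaction is
    called "independent" when observed and predicted agree within *threshold*-
    fold, "synergistic" when the double mutant is more than threshold-fold
    sicker than predicted, and "suppressive"/"epistatic" when it is more than
    threshold-fold healthier.
    """
    for name, s in (("survival_a", survival_a), ("survival_b", survival_b)):
        if not 0.0 < s <= 1.0:
            raise ValueError(f"{name} must be in (0, 1]")
    predicted = survival_a * survival_b
    result = {"predicted": predicted, "call": None, "fold_deviation": None}
    if observed_double is not None:
        if observed_double <= 0:
            raise ValueError("observed survival must be > 0")
        fold = observed_double / predicted
        result["fold_deviation"] = fold
        if fold < 1.0 / threshold:
            result["call"] = "synergistic"
        elif fold > threshold:
            result["call"] = "suppressive"
        else:
            result["call"] = "independent"
    return result


def normalize_synthesis(series: pd.DataFrame, mode: str = "uv_zero") -> pd.DataFrame:
    """Dilution-correct and normalize a DNA-synthesis rate series.

    ``series`` columns: time_min, raw_rate, cumulative_dilution.  The
    corrected per-culture-equivalent rate is raw_rate * cumulative_dilution.
    ``mode`` picks the normalization reference: ``"uv_zero"`` divides by the
    corrected rate at the earliest timepoint of this series; ``"first"`` is a
    synonym kept for series that start pre-UV.
    """
    need = {"time_min", "raw_rate", "cumulative_dilution"}
    if not need <= set(series.columns):
        raise ValueError(f"series missing columns: {sorted(need - set(series.columns))}")
    if mode not in ("uv_zero", "first"):
        raise ValueError("mode must be 'uv_zero' or 'first'")
    out = series.sort_values("time_min").reset_index(drop=True).copy()
    if (out["cumulative_dilution"] < 1).any():
        raise ValueError("cumulative dilution factors must be >= 1")
    out["corrected_rate"] = out["raw_rate"] * out["cumulative_dilution"]
    ref = float(out["corrected_rate"].iloc[0])
    if ref <= 0:
        raise ValueError("reference rate is zero; cannot normalize")
    out["normalized_rate"] = out["corrected_rate"] / ref
    return out
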
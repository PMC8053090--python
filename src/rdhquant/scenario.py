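"""Scenario bundles: per-strain/per-dose parameters for the synthetic assays.

A :class:`Scenario` collects everything the generator needs to emulate one
strain under one UV dose: lesion induction and two-class repair kinetics,
RNA:DNA-hybrid (RDH) abundance and length parameters, blot channel gains and
noise, immunoprecipitation capture parameters, and phenotype tables (survival,
DNA-synthesis rates).  The built-in strain calibrations live in
``data/scenarios.yaml`` and are loaded with :func:`load_scenario`.

Units: genome coordinates and lengths are nucleotides (nt) on a single linear
genome; times are minutes after UV; doses are J/m^2.  The timepoint ``-1``
encodes the pre-UV ("log") sample throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = ["Scenario", "load_scenario", "list_scenarios", "LOG_TIMEPOINT"]

#: Timepoint label for the pre-UV exponential-growth ("log") sample.
LOG_TIMEPOINT = -1.0


def _as_float_dict(d: Mapping) -> dict[float, float]:
    return {float(k): float(v) for k, v in d.items()}


@dataclass(frozen=True)
class Scenario:
    """Generator parameter bundle for one strain at one UV dose."""

    strain: str
    dose: float
    #: PDs induced per J/m^2 per genome (default ~42).
    pd_induction_rate: float = 41.7
    genome_length: int = 9_200_000
    #: Probability that a PD stalls a transcription elongation complex and is
    #: therefore a slow-repair, RDH-anchoring lesion.
    slow_pd_fraction: float = 0.0
    #: Exponential-removal half-lives (min); ``inf`` disables repair (uvrA).
    fast_half_life: float = 7.0
    slow_half_life: float = 100.0
    #: Excision does not start until this long after UV (min).
    repair_lag: float = 5.0
    #: Arithmetic mean and log-normal sigma of anchored RDH lengths (nt).
    rdh_length_mean: float = 3500.0
    rdh_length_dispersion: float = 0.75
    #: Total hybrid nt in the rnhAB log culture; the unit of the fold table.
    reference_rdh_nt: float = 23_000.0
    #: Length of short growth-associated background hybrids (nt).
    baseline_hybrid_length: float = 300.0
    #: Share of the baseline/dispersed hybrid nt carried by long hybrids
    #: (drawn from the anchored length distribution) instead of short ones.
    baseline_long_fraction: float = 0.0
    #: Whole-lane RDH density relative to the rnhAB log culture, by timepoint
    #: (min); linearly interpolated.  ``rdh_log_fold`` is the strain's own
    #: pre-UV level on the same scale.
    rdh_log_fold: float = 1.0
    rdh_fold_table: dict[float, float] = field(default_factory=dict)
    #: Fraction of the UV-induced hybrid signal placed uniformly over the
    #: genome instead of anchored at slow PDs.
    rdh_dispersed_fraction: float = 0.0
    channel_gains: dict[str, float] = field(
        default_factory=lambda: {"southern": 1.0, "s96": 1.0, "pd": 1.0}
    )
    #: Coefficient of variation of the multiplicative log-normal band noise.
    noise_cv: float = 0.15
    #: CV of the blot-wide (batch x channel) gain shared by all lanes of one
    #: blot; within-batch normalization exists to cancel this component.
    batch_noise_cv: float = 0.25
    #: Nonspecific anti-PD western signal on gel lanes, in PD-equivalents per
    #: nt of DNA (dot blots are modelled without it).
    pd_channel_background: float = 0.0
    #: Nonspecific S9.6 signal, in hybrid-nt-equivalents per nt of DNA.
    s96_channel_background: float = 0.0
    #: S9.6 immunoprecipitation: capture probability of a saturating
    #: hybrid-bearing fragment, nonspecific capture probability, and the
    #: hybrid-content scale (nt) at which capture saturates (None = any
    #: overlap saturates).
    p_capture_specific: float = 0.65
    p_capture_background: float = 0.008
    capture_saturation_nt: float | None = 800.0
    #: Fraction of hybrid signal surviving RNase HI treatment.
    rnase_survival: float = 0.01
    background_nicks_per_genome: float = 45.0
    #: True survival per dose, for the spot-assay generator.
    survival_by_dose: dict[float, float] = field(default_factory=dict)
    #: True DNA synthesis rate curves [(min, rate), ...] with and without UV.
    synthesis_rate_uv: list[tuple[float, float]] = field(default_factory=list)
    synthesis_rate_no_uv: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        def _bad(name: str, why: str) -> None:
            raise ValueError(f"Scenario.{name} {why} (strain={self.strain!r})")

        if self.dose < 0:
            _bad("dose", "must be >= 0")
        for name in ("pd_induction_rate", "rdh_length_mean", "fast_half_life",
                     "slow_half_life", "reference_rdh_nt",
                     "baseline_hybrid_length"):
            if not getattr(self, name) > 0:
                _bad(name, "must be > 0")
        for name in ("slow_pd_fraction", "rdh_dispersed_fraction",
                     "baseline_long_fraction",
                     "p_capture_specific", "p_capture_background",
                     "rnase_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                _bad(name, "must be in [0, 1]")
        if self.genome_length <= 0:
            _bad("genome_length", "must be > 0")
        if self.rdh_log_fold < 0 or any(v < 0 for v in self.rdh_fold_table.values()):
            _bad("rdh_fold_table", "folds must be >= 0")
        for s in self.survival_by_dose.values():
            if not 0.0 < s <= 1.0:
                _bad("survival_by_dose", "survivals must be in (0, 1]")
        if self.noise_cv < 0:
            _bad("noise_cv", "must be >= 0")
        if self.batch_noise_cv < 0:
            _bad("batch_noise_cv", "must be >= 0")
        for name in ("pd_channel_background", "s96_channel_background"):
            if getattr(self, name) < 0:
                _bad(name, "must be >= 0")

    # -- derived quantities -------------------------------------------------

    def pd_count_mean(self) -> float:
        """Expected number of PDs per genome right after irradiation."""
        return self.dose * self.pd_induction_rate

    def repair_survival(self, timepoint: float, slow: bool) -> float:
        """Probability that a PD of the given class persists at *timepoint*."""
        if timepoint < 0:  # pre-UV sample: no UV lesions at all
            return 0.0
        t = max(0.0, timepoint - self.repair_lag)
        hl = self.slow_half_life if slow else self.fast_half_life
        if math.isinf(hl):
            return 1.0
        return 2.0 ** (-t / hl)

    def rdh_fold(self, timepoint: float) -> float:
        """Whole-lane RDH density vs the rnhAB log culture, interpolated."""
        if timepoint < 0:
            return self.rdh_log_fold
        table = dict(self.rdh_fold_table)
        table.setdefault(0.0, self.rdh_log_fold)
        times = np.array(sorted(table))
        folds = np.array([table[t] for t in times])
        return float(np.interp(timepoint, times, folds))

    def with_(self, **overrides) -> "Scenario":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


def _scenario_from_dict(name: str, raw: dict) -> Scenario:
    raw = dict(raw)
    raw.setdefault("strain", name)
    if "rdh_fold_table" in raw:
        raw["rdh_fold_table"] = _as_float_dict(raw["rdh_fold_table"])
    if "survival_by_dose" in raw:
        raw["survival_by_dose"] = _as_float_dict(raw["survival_by_dose"])
    for key in ("synthesis_rate_uv", "synthesis_rate_no_uv"):
        if key in raw:
            raw[key] = [(float(t), float(r)) for t, r in raw[key]]
    for key in ("fast_half_life", "slow_half_life"):
        if key in raw and raw[key] is None:
            raw[key] = math.inf
    return Scenario(**raw)


def _load_registry() -> dict[str, dict]:
    text = resources.files("rdhquant").joinpath("data/scenarios.yaml").read_text()
    doc = yaml.safe_load(text)
    return doc["scenarios"]


def list_scenarios() -> list[str]:
    """Names of the built-in strain x dose calibrations."""
    return sorted(_load_registry())


def load_scenario(name: str, **overrides) -> Scenario:
    """Load a built-in scenario by name, optionally overriding fields."""
    registry = _load_registry()
    if name not in registry:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(registry))}"
        )
    sc = _scenario_from_dict(name, registry[name])
    return sc.with_(**overrides) if overrides else sc


def load_scenario_file(path) -> Scenario:
    """Load a single-document scenario YAML file (schema v1)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema", 1) != 1:
        raise ValueError(f"unsupported scenario schema {doc.get('schema')!r}")
    raw = {k: v for k, v in doc.items() if k != "schema"}
    return _scenario_from_dict(raw.get("strain", "scenario"), raw)
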
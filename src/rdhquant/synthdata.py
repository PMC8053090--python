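"""Scenario-driven generator of synthetic assay data.

Generates, with the statistical structure the analysis pipelines assume:
chromosome lesion states (Poisson PD placement, two-class repair, hybrid
intervals anchored at slow PDs), restriction/shear fragment sets, gel lane
profiles per blot channel, plasmid-relaxation band tables, DRIP partitions,
serial-dilution spot assays, and ³H DNA-synthesis time courses.

Every operation takes an integer seed (or a ``numpy.random.Generator``);
fixing the seed reproduces outputs exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .containers import CHANNELS, ChromosomeState, DripFractions, FragmentSet, LaneProfile, SpotAssay
from .scenario import LOG_TIMEPOINT, Scenario

__all__ = [
    "ENZYME_MODELS",
    "MigrationModel",
    "simulate_chromosome_state",
    "digest",
    "pooled_digest",
    "render_lane",
    "simulate_lane_set",
    "simulate_band_table",
    "simulate_relaxation_series",
    "simulate_drip",
    "simulate_spot_assay",
    "simulate_synthesis_rates",
    "simulate_blot_table",
]

#: enzyme label -> (mean fragment length nt, lower bound, upper bound);
#: "uncut" is the intact genome.  "sheared" models the mechanical breakage
#: of genomic preps (tens of kb) and is what an "uncut" DRIP sample is made of.
ENZYME_MODELS: dict[str, tuple[float, float, float] | None] = {
    "uncut": None,
    "sheared": (13_000.0, 3_000.0, 100_000.0),
    "EcoRI+BamHI": (4_000.0, 100.0, 50_000.0),
    "HaeII": (1_200.0, 100.0, 50_000.0),
    "HaeIII": (600.0, 100.0, 50_000.0),
}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return np.asarray(merged, dtype=np.int64)


def _inside(points: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """Membership of points in merged, sorted, half-open intervals."""
    if merged.size == 0 or points.size == 0:
        return np.zeros(points.size, dtype=bool)
    idx = np.searchsorted(merged[:, 0], points, side="right") - 1
    ok = idx >= 0
    out = np.zeros(points.size, dtype=bool)
    out[ok] = points[ok] < merged[idx[ok], 1]
    return out


# ---------------------------------------------------------------------------
# chromosome state
# ---------------------------------------------------------------------------

def simulate_chromosome_state(scenario: Scenario, timepoint: float, seed) -> ChromosomeState:
    """Draw one genome's PD and hybrid configuration at *timepoint* (min).

    PDs are placed Poisson at ``dose x pd_induction_rate``; each is slow
    (TEC-stalling) with probability ``slow_pd_fraction``.  Survival to
    *timepoint* is exponential per class after a short excision lag.  UV-
    induced hybrids are anchored at surviving slow PDs, with lengths drawn
    log-normal, in numbers set by the scenario's whole-lane fold table; PDs
    that happen to lie inside an anchored hybrid are masked from excision
    (they decay with the slow half-life).  The dispersed part of the induced
    signal, and the pre-UV baseline, are short unanchored hybrids placed
    uniformly.
    """
    if timepoint < 0 and timepoint != LOG_TIMEPOINT:
        raise ValueError(f"timepoint must be >= 0 or the log label {LOG_TIMEPOINT}")
    if scenario.dose < 0:
        raise ValueError("dose must be >= 0")
    rng = _rng(seed)
    g = scenario.genome_length
    pre_uv = timepoint < 0

    # -- lesions ------------------------------------------------------------
    if pre_uv or scenario.dose == 0:
        n0 = 0
    else:
        n0 = int(rng.poisson(scenario.pd_count_mean()))
    pos = np.sort(rng.integers(0, g, size=n0))
    slow = rng.random(n0) < scenario.slow_pd_fraction

    p_fast = scenario.repair_survival(timepoint, slow=False) if not pre_uv else 0.0
    p_slow = scenario.repair_survival(timepoint, slow=True) if not pre_uv else 0.0

    slow_pos = pos[slow]
    slow_alive = rng.random(slow_pos.size) < p_slow
    slow_surv = slow_pos[slow_alive]

    # -- anchored hybrids ---------------------------------------------------
    induced_nt = 0.0
    if not pre_uv and scenario.dose > 0:
        induced_nt = max(0.0, (scenario.rdh_fold(timepoint) - scenario.rdh_log_fold)
                         ) * scenario.reference_rdh_nt
    anchored_nt = induced_nt * (1.0 - scenario.rdh_dispersed_fraction)
    n_anchor = min(int(round(anchored_nt / scenario.rdh_length_mean)), slow_surv.size)

    anchor_pos = rng.choice(slow_surv, size=n_anchor, replace=False) if n_anchor else np.empty(0, dtype=np.int64)
    sigma = scenario.rdh_length_dispersion
    mu = math.log(scenario.rdh_length_mean) - sigma * sigma / 2.0
    lengths = np.maximum(50, rng.lognormal(mu, sigma, size=n_anchor)).astype(np.int64)
    offs = (rng.random(n_anchor) * lengths).astype(np.int64)
    starts = np.clip(anchor_pos - offs, 0, None)
    ends = np.minimum(starts + lengths, g)
    starts = np.maximum(np.minimum(starts, ends - 1), 0)
    anchored = np.column_stack([starts, ends]) if n_anchor else np.empty((0, 2), dtype=np.int64)

    # -- masking: fast PDs inside anchored hybrids repair slowly -------------
    fast_pos = pos[~slow]
    masked = _inside(fast_pos, _merge_intervals(anchored.copy()))
    keep_p = np.where(masked, p_slow, p_fast)
    fast_surv = fast_pos[rng.random(fast_pos.size) < keep_p]

    surv_pos = np.concatenate([slow_surv, fast_surv])
    surv_slow = np.concatenate([
        np.ones(slow_surv.size, dtype=bool), np.zeros(fast_surv.size, dtype=bool)
    ])
    order = np.argsort(surv_pos, kind="stable")
    surv_pos, surv_slow = surv_pos[order], surv_slow[order]

    # anchors' indexes in the final arrays (slow survivors occupy the first
    # block before sorting; map through the argsort)
    rank = np.empty(order.size, dtype=np.int64)
    rank[order] = np.arange(order.size)
    anchor_in_slowblock = np.searchsorted(slow_surv, anchor_pos)  # slow_surv unsorted? ensure sorted
    # slow_surv inherits sortedness from pos; anchors drawn from it keep values.
    anchor_idx = rank[anchor_in_slowblock] if n_anchor else np.empty(0, dtype=np.int64)

    # -- background hybrids (baseline + dispersed induced) -------------------
    # A share of the baseline population is long (same length law as the
    # anchored hybrids); the rest are short.  Both are placed uniformly.
    bg_nt = scenario.rdh_log_fold * scenario.reference_rdh_nt
    bg_nt += induced_nt * scenario.rdh_dispersed_fraction
    long_nt = bg_nt * scenario.baseline_long_fraction
    short_nt = bg_nt - long_nt
    blen = int(scenario.baseline_hybrid_length)
    n_short = rng.poisson(short_nt / blen)
    n_long = rng.poisson(long_nt / scenario.rdh_length_mean)
    short_len = np.full(n_short, blen, dtype=np.int64)
    long_len = np.maximum(
        50, rng.lognormal(mu, sigma, size=n_long)).astype(np.int64)
    bg_len = np.minimum(np.concatenate([short_len, long_len]), g - 1)
    bs = rng.integers(0, np.maximum(1, g - bg_len)) if bg_len.size else np.empty(0, dtype=np.int64)
    background = (np.column_stack([bs, bs + bg_len]) if bg_len.size
                  else np.empty((0, 2), dtype=np.int64))

    return ChromosomeState(
        genome_length=g,
        timepoint=timepoint,
        pd_positions=surv_pos,
        pd_slow=surv_slow,
        rdh_intervals=anchored,
        rdh_anchor_index=anchor_idx,
        background_hybrids=background,
    )


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

#: Probability that a drawn spacing comes from the partial-digestion tail
#: (incompletely cut stretches, ~5x the nominal mean); this keeps a small
#: but nonzero DNA continuum in every gel fraction, as on real blots.
PARTIAL_DIGEST_P = 0.02
PARTIAL_DIGEST_SCALE = 5.0


def _draw_fragment_lengths(rng, mean: float, lo: float, hi: float, total: int) -> np.ndarray:
    """Truncated-exponential lengths (bounds lo..hi) tiling at least *total* nt.

    A small fraction of spacings comes from a 12x-longer exponential,
    modelling partial digestion.
    """
    scale = mean - lo
    out = []
    acc = 0.0
    while acc < total:
        n = max(16, int((total - acc) / mean * 1.2))
        x = lo + rng.exponential(scale, size=n)
        partial = rng.random(n) < PARTIAL_DIGEST_P
        if partial.any():
            x[partial] = lo + rng.exponential(scale * PARTIAL_DIGEST_SCALE,
                                              size=int(partial.sum()))
        x = x[x <= hi]
        out.append(x)
        acc += x.sum()
    return np.concatenate(out)


def digest(state: ChromosomeState, enzyme_model: str, seed) -> FragmentSet:
    """Cut a chromosome state into fragments.

    Cut positions are tiled from a truncated-exponential length distribution;
    positions falling inside a hybrid interval are discarded (the RNA:DNA
    duplex is not a cleavable substrate), which is what makes hybrid-bearing
    fragments systematically longer than the bulk.  Lesion and hybrid totals
    are conserved exactly.
    """
    if enzyme_model not in ENZYME_MODELS:
        raise ValueError(
            f"unknown enzyme label {enzyme_model!r}; use one of {sorted(ENZYME_MODELS)}"
        )
    rng = _rng(seed)
    g = state.genome_length
    model = ENZYME_MODELS[enzyme_model]
    if model is None:
        bounds = np.array([0, g], dtype=np.int64)
    else:
        mean, lo, hi = model
        lens = _draw_fragment_lengths(rng, mean, lo, hi, g)
        cuts = np.cumsum(lens).astype(np.int64)
        cuts = cuts[cuts < g]
        hybrids = state.hybrid_intervals()
        cuts = cuts[~_inside(cuts, hybrids)]
        bounds = np.concatenate([[0], cuts, [g]])

    lengths = np.diff(bounds)
    pd_counts = np.diff(np.searchsorted(state.pd_positions, bounds))

    rdh_nt = np.zeros(lengths.size)
    for s, e in state.hybrid_intervals():
        i0 = np.searchsorted(bounds, s, side="right") - 1
        i1 = np.searchsorted(bounds, e, side="left") - 1
        for i in range(i0, min(i1, lengths.size - 1) + 1):
            rdh_nt[i] += min(e, bounds[i + 1]) - max(s, bounds[i])

    return FragmentSet(enzyme=enzyme_model, lengths=lengths,
                       pd_counts=pd_counts, rdh_nt=rdh_nt)


# ---------------------------------------------------------------------------
# gel lanes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MigrationModel:
    """Log-size agarose migration: size(x) = S_top * (S_bot/S_top)**x.

    x is the migration coordinate in [0, 1] from the well; defaults place
    8-10 kb fragments in fraction #6 of a 16-fraction partition.
    """

    s_top: float = 50_000.0
    s_bot: float = 350.0

    def position(self, size_nt) -> np.ndarray:
        s = np.clip(np.asarray(size_nt, dtype=float), self.s_bot, self.s_top)
        return np.log(self.s_top / s) / math.log(self.s_top / self.s_bot)

    def size_at(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.s_top * (self.s_bot / self.s_top) ** x


def render_lane(
    fragments: FragmentSet,
    channel: str,
    migration_model: MigrationModel | None = None,
    gain: float = 1.0,
    noise_cv: float = 0.0,
    seed=None,
    *,
    strain: str = "",
    timepoint: float = float("nan"),
    n_points: int = 512,
    band_sigma: float = 0.012,
) -> LaneProfile:
    """Electrophorese + blot a fragment set into one channel's lane profile.

    Each fragment contributes ``gain x weight`` (weight = length for
    southern, hybrid nt for s96, PD count for pd) at its size's migration
    coordinate, spread by a Gaussian band kernel and multiplied by unit-mean
    log-normal noise of the given CV.  The returned profile is a signal
    density whose trapezoid integral equals the total deposited signal.
    """
    if len(fragments) == 0:
        raise ValueError("cannot render an empty FragmentSet")
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; use {CHANNELS}")
    if gain <= 0:
        raise ValueError("gain must be > 0")
    mig = migration_model or MigrationModel()
    rng = _rng(seed)

    weight = {
        "southern": fragments.lengths.astype(float),
        "s96": fragments.rdh_nt.astype(float),
        "pd": fragments.pd_counts.astype(float),
    }[channel]
    weight = gain * weight * _lognormal_noise(rng, noise_cv, weight.size)

    x = np.linspace(0.0, 1.0, n_points)
    dx = x[1] - x[0]
    bins = np.clip(np.round(mig.position(fragments.lengths) / dx).astype(int), 0, n_points - 1)
    dens = np.zeros(n_points)
    np.add.at(dens, bins, weight / dx)
    dens = gaussian_filter1d(dens, sigma=band_sigma / dx, mode="nearest")
    return LaneProfile(strain=strain, timepoint=timepoint, channel=channel,
                       position=x, signal=np.maximum(dens, 0.0))


def pooled_digest(
    scenario: Scenario,
    timepoint: float,
    enzyme: str,
    seed,
    n_genomes: int = 50,
) -> FragmentSet:
    """Digest of a cell population: *n_genomes* independent chromosome states.

    A gel lane holds DNA from millions of cells, so fragment statistics are
    those of an ensemble, not one genome; pooling a modest number of states
    reproduces that averaging at simulation cost.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = _rng(seed)
    parts = [digest(simulate_chromosome_state(scenario, timepoint, rng),
                    enzyme, rng) for _ in range(n_genomes)]
    return FragmentSet(
        enzyme=enzyme,
        lengths=np.concatenate([p.lengths for p in parts]),
        pd_counts=np.concatenate([p.pd_counts for p in parts]),
        rdh_nt=np.concatenate([p.rdh_nt for p in parts]),
    )


#: Western backgrounds by channel: (scenario attribute, signal per nt DNA).
_LANE_BACKGROUNDS = {"pd": "pd_channel_background",
                     "s96": "s96_channel_background"}


def simulate_lane_set(
    scenario: Scenario,
    timepoints,
    enzyme: str = "HaeII",
    seed=0,
    migration_model: MigrationModel | None = None,
    n_genomes: int = 50,
) -> dict[tuple[float, str], LaneProfile]:
    """Generate the southern/s96/pd lane triplet for each timepoint.

    One pooled digest per timepoint; the three channels are blotted from the
    same fragments (split sample, identical gels), each with its own gain and
    band noise, as in the co-enrichment assay.  Both westerns include their
    nonspecific background, which follows the DNA distribution.
    """
    rng = _rng(seed)
    lanes: dict[tuple[float, str], LaneProfile] = {}
    for t in timepoints:
        frags = pooled_digest(scenario, t, enzyme, rng, n_genomes)
        for channel in CHANNELS:
            lane = render_lane(
                frags, channel, migration_model,
                gain=scenario.channel_gains.get(channel, 1.0),
                noise_cv=scenario.noise_cv, seed=rng,
                strain=scenario.strain, timepoint=t,
            )
            bg = getattr(scenario, _LANE_BACKGROUNDS.get(channel, ""), 0.0) \
                if channel in _LANE_BACKGROUNDS else 0.0
            if bg > 0:
                extra = render_lane(
                    frags, "southern", migration_model,
                    gain=scenario.channel_gains.get(channel, 1.0) * bg,
                    noise_cv=scenario.noise_cv, seed=rng,
                    strain=scenario.strain, timepoint=t,
                )
                lane = LaneProfile(
                    strain=lane.strain, timepoint=lane.timepoint,
                    channel=channel, position=lane.position,
                    signal=lane.signal + extra.signal,
                )
            lanes[(t, channel)] = lane
    return lanes


# ---------------------------------------------------------------------------
# plasmid relaxation band tables
# ---------------------------------------------------------------------------

_TREATMENTS = ("none", "T4PDG", "RNaseHII", "RNaseHI")


def simulate_band_table(
    scenario: Scenario,
    plasmid_length: int,
    timepoint: float,
    treatment: str,
    n_molecules: int = 2000,
    seed=None,
    sample: str | None = None,
) -> pd.DataFrame:
    """Simulate one gel lane of the plasmid-relaxation assay.

    Each molecule carries Poisson(plasmid_length x cleavable density) nicks
    after the treatment; the supercoiled band collects the zero-nick
    molecules.  "none" exposes only the background nicking of the procedure.
    The plasmid reports bulk excision kinetics (fast class only): it carries
    no stalled chromosomal transcription complexes.
    """
    if plasmid_length <= 0:
        raise ValueError("plasmid_length must be > 0")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if treatment not in _TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; use {_TREATMENTS}")
    rng = _rng(seed)
    g = scenario.genome_length

    background = scenario.background_nicks_per_genome / g
    density = background
    if treatment == "T4PDG" and timepoint >= 0:
        pd_per_nt = (scenario.pd_count_mean() / g) * scenario.repair_survival(timepoint, slow=False)
        density += pd_per_nt
    # RNase H treatments cleave at DNA-ribonucleotides; their density does not
    # increase after UV, so they expose background nicking only.

    nicks = rng.poisson(plasmid_length * density, size=n_molecules)
    sc = float((nicks == 0).sum())
    rc = float(n_molecules - sc)
    noise = _lognormal_noise(rng, scenario.noise_cv, 2)
    return pd.DataFrame([{
        "sample": sample or f"{scenario.strain}_{timepoint:g}min",
        "time_min": timepoint,
        "treatment": treatment,
        "sc_signal": sc * noise[0],
        "rc_signal": rc * noise[1],
    }])


def simulate_relaxation_series(
    scenario: Scenario,
    plasmid_length: int,
    timepoints,
    n_molecules: int = 2000,
    seed=0,
) -> pd.DataFrame:
    """Paired T4PDG/buffer-only lanes per timepoint (incl. pre-UV at -1)."""
    rng = _rng(seed)
    rows = []
    for t in timepoints:
        for treatment in ("T4PDG", "none"):
            rows.append(simulate_band_table(
                scenario, plasmid_length, t, treatment, n_molecules, rng))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# DRIP
# ---------------------------------------------------------------------------

def simulate_drip(
    fragments: FragmentSet,
    scenario: Scenario,
    rnase_treated: bool = False,
    seed=None,
) -> DripFractions:
    """Partition fragments into DRIP (S9.6-bound) and eluate fractions.

    A fragment's capture probability rises with its hybrid content
    (saturating at ``capture_saturation_nt``) up to ``p_capture_specific``;
    hybrid-free fragments are captured at ``p_capture_background``.  RNase HI
    treatment leaves ``rnase_survival`` (~1%) of the hybrid signal.  DRIP and
    eluate signals sum exactly to the input per channel.
    """
    rng = _rng(seed)
    content = fragments.rdh_nt * (scenario.rnase_survival if rnase_treated else 1.0)
    p_spec, p_bg = scenario.p_capture_specific, scenario.p_capture_background
    kappa = scenario.capture_saturation_nt
    if kappa is None:
        sat = (content > 0).astype(float)
    else:
        sat = 1.0 - np.exp(-content / kappa)
    p = p_bg + (p_spec - p_bg) * sat
    captured = rng.random(len(fragments)) < p

    def row(mask) -> dict:
        return {
            "southern": float(fragments.lengths[mask].sum()),
            "s96": float(content[mask].sum()),
            "pd": float(fragments.pd_counts[mask].sum()),
        }

    drip, eluate = row(captured), row(~captured)
    total = {c: drip[c] + eluate[c] for c in CHANNELS}
    signals = pd.DataFrame([total, drip, eluate], index=["input", "drip", "eluate"])
    return DripFractions(digest=fragments.enzyme, rnase_treated=rnase_treated,
                         signals=signals[list(CHANNELS)], simulated=True)


# ---------------------------------------------------------------------------
# phenotype assays
# ---------------------------------------------------------------------------

def simulate_spot_assay(
    scenario: Scenario,
    dose: float,
    seed=None,
    n_cultures: int = 6,
    titer: float = 2.0e8,
    spot_volume_ml: float = 0.01,
    max_dilution: int = 5,
) -> SpotAssay:
    """Serial-dilution spot counts: Poisson(titer x survival x 10^-d x volume)."""
    if dose not in scenario.survival_by_dose:
        raise KeyError(
            f"scenario {scenario.strain!r} has no configured survival for dose {dose!r}"
        )
    survival = scenario.survival_by_dose[dose]
    rng = _rng(seed)
    rows = []
    for culture in range(n_cultures):
        for d in range(max_dilution + 1):
            lam = titer * survival * 10.0 ** (-d) * spot_volume_ml
            rows.append({"culture": culture, "dilution": d,
                         "count": int(rng.poisson(lam))})
    return SpotAssay(strain=scenario.strain, dose=dose,
                     spot_volume_ml=spot_volume_ml, counts=pd.DataFrame(rows))


def simulate_synthesis_rates(
    scenario: Scenario,
    uv: bool = True,
    seed=None,
    timepoints=None,
    dilution_times=(50.0, 90.0, 150.0),
) -> pd.DataFrame:
    """³H-incorporation series with logged 2-fold culture dilutions.

    Raw counts are the true rate divided by the cumulative dilution factor
    (x unit-mean noise); the ``cumulative_dilution`` column lets the analysis
    undo the dilutions exactly.
    """
    rng = _rng(seed)
    if timepoints is None:
        timepoints = np.arange(0.0, 181.0, 10.0)
    curve = scenario.synthesis_rate_uv if uv else scenario.synthesis_rate_no_uv
    if not curve:
        raise ValueError(f"scenario {scenario.strain!r} has no synthesis-rate curve")
    ct = np.array([p[0] for p in curve])
    cr = np.array([p[1] for p in curve])
    rows = []
    for t in timepoints:
        cum = float(2.0 ** sum(1 for dt in dilution_times if t >= dt))
        rate = float(np.interp(t, ct, cr))
        raw = rate / cum * float(_lognormal_noise(rng, scenario.noise_cv, 1)[0])
        rows.append({"time_min": float(t), "raw_rate": raw,
                     "cumulative_dilution": cum})
    out = pd.DataFrame(rows)
    out.attrs["strain"] = scenario.strain
    out.attrs["uv"] = uv
    return out


# ---------------------------------------------------------------------------
# chromosomal blot tables
# ---------------------------------------------------------------------------

def simulate_blot_table(
    scenario: Scenario,
    timepoints,
    n_replicates: int = 1,
    seed=0,
) -> pd.DataFrame:
    """Western/Southern band intensities for whole-chromosome blots.

    One chromosome state per replicate x timepoint; the S9.6 western reads
    total hybrid nt, the anti-PD western reads surviving PD count plus the
    nonspecific per-nt background, the Southern reads total DNA.  Each
    replicate is one batch (its own gels), matching the normalization rules'
    batch semantics: all lanes of a batch x channel share one blot-wide gain
    (``batch_noise_cv``, the dominant component that within-batch
    normalization cancels) and each band adds its own smaller lane noise
    (``noise_cv``).

    Returns the blotquant TSV schema:
    batch, strain, channel, timepoint, western, southern.
    """
    rng = _rng(seed)
    g = scenario.genome_length
    gains = scenario.channel_gains
    rows = []
    for rep in range(n_replicates):
        batch_gain = {c: g_ * gains.get(c, 1.0) for c, g_ in zip(
            CHANNELS, _lognormal_noise(rng, scenario.batch_noise_cv, len(CHANNELS)))}
        for t in timepoints:
            state = simulate_chromosome_state(scenario, t, rng)
            # Band densitometry isolates the compact chromosomal band, so the
            # diffuse nonspecific backgrounds of the lane channels do not
            # contribute here (unlike the in-gel fraction quantification).
            for channel, true_w in (("s96", float(state.total_hybrid_nt())),
                                    ("pd", float(state.n_pd))):
                noise = _lognormal_noise(rng, scenario.noise_cv, 2)
                rows.append({
                    "batch": f"rep{rep}",
                    "strain": scenario.strain,
                    "channel": channel,
                    "timepoint": t,
                    "western": batch_gain[channel] * true_w * noise[0],
                    "southern": batch_gain["southern"] * g * noise[1],
                })
    return pd.DataFrame(rows)
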
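# Methods and models

This document describes the quantitative models behind each pipeline and the
matching structure of the synthetic-assay generator.  Units: lengths in
nucleotides (nt) on a single linear genome (9.2 x 10^6 nt by default), times
in minutes after UV, doses in J/m^2.  The timepoint `-1.0` is the pre-UV
exponential-growth ("log") sample.

## 1. Lesion induction and two-class repair

UV places pyrimidine dimers (PDs) Poisson-uniformly at
`dose x pd_induction_rate` per genome (default 41.7/J/m^2, i.e. ~1500 PDs at
36 J/m^2).  Each PD independently stalls a transcription elongation complex
with probability `slow_pd_fraction`; stalled ("slow") lesions anchor RNA:DNA
hybrids and are shielded from nucleotide excision repair.

Repair is exponential per class after a short lag:

    S_class(t) = 2^(-(t - repair_lag)/half_life),   t > repair_lag

with `fast_half_life` (~7 min, bulk excision) and `slow_half_life`
(~100 min in rnhAB; the RDH-anchored class).  NER-deficient (`uvrA`)
scenarios use infinite half-lives.  Fast PDs that happen to lie inside an
anchored hybrid are masked and decay with the slow half-life.

Two assays view this process differently, and the package keeps them
distinct on purpose:

* the **plasmid relaxation assay** reports the fast class only — the
  reporter plasmid carries no stalled chromosomal transcription complexes;
* **chromosomal anti-PD blots** see both classes, which is why excision-
  proficient rnhAB cells still retain ~10% of their dimers at 60 min while
  plasmid dimers are long gone.

## 2. Zero-class Poisson plasmid densitometry (`relaxation`)

A nicking treatment (T4 PDG for PDs; RNase HII/HI for ribonucleotides)
relaxes every plasmid with >= 1 cleavable lesion, so the supercoiled band is
the Poisson zero class:

    F = SC / (SC + RC)
    n_nicks = -ln(F_treated / F_untreated)
    lesions/genome = genome_nt x n_nicks / plasmid_nt

The buffer-only ("none") lane normalizes away background nicking
(~45 nicks/genome-equivalent from the procedure), which cancels in the
ratio.  Negative estimates (noise) clamp to 0 with a warning; an empty
supercoiled band means saturation and returns +inf.  Replicate gels pool by
averaging per-gel estimates (default) or supercoiled fractions
(`pool="fractions"`).  `percent_remaining` subtracts the pre-UV estimate
before forming percentages of the 5-min reference.

## 3. Blot normalization (`blotquant`)

Lane signals divide by the Southern signal of the same lane (loading
correction).  Each blot ("batch") carries one shared gain per channel
(generator: log-normal, CV 0.25) plus smaller per-band noise (CV 0.05);
within-batch normalization cancels the shared gain exactly, which is why
both rules never mix batches:

* `"rdh"`: every S9.6 density divides by the rnhAB log-culture lane of the
  same blot, putting all strains on one scale (rnhAB log = 1.0);
* `"pd"`: per strain, the pre-UV lane (nonspecific antibody floor) is
  subtracted and the series is expressed as percent of the 5-min value.

Band densitometry isolates the compact chromosomal band, so the diffuse
nonspecific channel backgrounds of in-gel lanes do not enter blot tables.

## 4. Gel lanes, digestion and co-enrichment (`coenrich`)

Restriction digestion is modelled as truncated-exponential cut spacings
(HaeII mean 1.2 kb, HaeIII 0.6 kb, EcoRI+BamHI 4 kb) with a small
partial-digestion tail (2% of spacings, 5x scale) that keeps a DNA continuum
in every gel fraction, as on real blots.  **Cut sites inside a hybrid
interval are not cleavable** (the RNA:DNA duplex is not a substrate), so
hybrid-bearing fragments are systematically longer than the bulk: a hybrid
of ~6 kb plus its uncut flanks lands near 8-10 kb regardless of the 1.2-kb
bulk mode.  Lanes pool 50 independent chromosome states (a lane holds DNA of
~10^9 cells; pooling reproduces the ensemble averaging).  Migration is
log-linear between 50 kb and 350 nt; each fragment deposits its
channel weight (length / hybrid nt / PD count) at its size's coordinate.
Both westerns add a nonspecific background that follows the DNA
distribution (S9.6: 5e-4 hybrid-nt-equivalents per nt; anti-PD: 1.1e-4
PD-equivalents per nt).

The co-enrichment pipeline partitions each lane into 16 equal migration
windows from the well to a 350-nt cutoff, forms per-fraction densities
(western/Southern), normalizes RDH to the pre-UV lane and PD to the 5-min
lane, and multiplies the two.  A peak in fraction #6 (7.8-10.6 kb) means
hybrids and persistent dimers sit on the same protected fragments; its value
reaches ~29 in rnhAB, while NER+ strains show only the multiplicative floor
(~0.5) and uvrA a flat ~2 profile (no repair, low uniform hybrid signal).

## 5. DRIP (`dripmodel`)

S9.6 immunoprecipitation captures a fragment with probability

    p = p_bg + (p_spec - p_bg) x (1 - exp(-hybrid_nt / kappa))

(saturating in hybrid content), splitting the digest into DRIP (bound) and
eluate; the generator conserves mass exactly (drip + eluate = input per
channel), and `mass_balance_report` flags any violation.  Enrichment of a
marker is its density (signal per Southern) relative to the input;
`overall_enrichment` is DRIP density over eluate density.  RNase HI
treatment leaves ~1% of the hybrid signal (`rnase_survival`) and collapses
all hybrid-dependent enrichments — the specificity control.

Under **independent** placement of dimers and hybrids, a captured fragment
of S nt carries one anchoring dimer plus Poisson(lambda x S) bystanders, so
the PD enrichment is capped:

    E[PD enrichment] <= (1 + lambda S) / (lambda S),
    S = max(mean captured-fragment length, mean hybrid length)

(`expected_max_pd_enrichment`).  At ~1 PD per 10 kb and 4-10 kb fragments
the ceiling is ~2; HaeII digestion shortens the captured footprint and
raises the observed enrichment to >= 3, the co-location signature.  The
"uncut" DRIP preparation is mechanically sheared genomic DNA (modelled as a
truncated exponential, mean 13 kb).

## 6. Phenotypes (`phenotypes`)

Spot-assay titers pool colony counts in the countable window (3-300) against
their total plated volume — the Poisson maximum-likelihood estimate,
equivalent to inverse-variance weighting — with exact gamma/Poisson
confidence intervals; empty assays flag "extinct", assays with no countable
spot fall back to all spots with flag "uncountable".  Survival is the
treated/untreated titer ratio (capped at 1), aggregated as mean +/- SEM over
paired cultures.  `epistasis_predict` compares a double mutant with the
multiplicative (no-interaction) product of the single-mutant survivals and
calls synergy/suppression beyond a threshold-fold deviation.
`normalize_synthesis` undoes logged culture dilutions
(rate x cumulative_dilution) and normalizes to the earliest timepoint.

## 7. Scenarios and calibration

All strain-level constants — induction rates, repair half-lives, slow-PD
fractions, hybrid fold tables and length laws, capture probabilities,
survival tables — live in `src/rdhquant/data/scenarios.yaml`, not in code.
The built-in values were calibrated once so that the documented checkpoint
values hold (see `scripts/acceptance.py`), then frozen.  Two lesion-density
anchors coexist deliberately: the 36 J/m^2 scenarios use 41.7 PDs/J/m^2
per genome, while the low-dose DRIP scenario (`rnhAB_uvrA`, 8 J/m^2) uses
1 PD per 10 kb; the underlying measurements disagree and the package does
not force them to agree.  Generator-structural constants (partial-digest
fraction, band width, pooling depth) live in code: they describe the
apparatus, not the strain.
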
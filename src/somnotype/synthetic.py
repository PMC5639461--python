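"""Synthetic input generation for every stage of the pipeline.

Four kinds of input are emulated:

1. Mouse passive-infrared activity traces: a two-state alternating-renewal
   process (active / immobile) whose run lengths are drawn from a four-
   category log-normal mixture (matching the sub-minute, 1–10 min,
   10 min – 1 h and > 1 h bout classes) and gated by a circadian
   oscillator: run lengths scale up (active) or down (immobile) with the
   circadian phase, per-bin activity intensity follows the phase, and the
   subjective dusk / dawn transitions truncate rest and activity runs
   (clock-gated arousal — what gives real rodent actograms their sharp
   activity onsets). Under entrained (LD) blocks the oscillator runs at
   24 h, phase-locked to the lighting; under constant conditions it
   free-runs at tau(lux) = intrinsic_tau_h + aschoff_slope * log10(lux+1),
   an Aschoff-rule-like lengthening of period with light intensity.
2. Ultra-long human sleep-wake diaries (hourly resolution, 27–28 days,
   cycle lengths far beyond 24 h).
3. A pedigree VCF for a father / mother / two-affected-sons quartet with
   planted candidate variants for each inheritance model and background
   variants guaranteed to fail at least one downstream filter.
4. Sigmoidal agonist dose-response tables.

All generators are deterministic given their seed; cohort seeds are split
hierarchically per subject so individual traces are reproducible on their
own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import (
    ActivityTrace,
    DiarySeries,
    LightingSchedule,
    ParameterError,
    Pedigree,
    PedigreeMember,
    SECONDS_PER_DAY,
    SECONDS_PER_HOUR,
    VariantRecord,
)

# ---------------------------------------------------------------------------
# Mouse cohorts
# ---------------------------------------------------------------------------

#: Bout length categories in seconds: [<1 min, 1–10 min, 10 min–1 h, >1 h]
LENGTH_CATEGORY_EDGES_S = (0.0, 60.0, 600.0, 3600.0, math.inf)


@dataclass(frozen=True)
class BoutMixture:
    """Log-normal run-length mixture over the four length categories.

    ``weights`` are the relative rates at which runs of each category are
    initiated; ``median_s`` and ``sigma`` parameterise the log-normal
    length within a category (median in seconds, sigma on the log scale).
    """

    weights: tuple[float, float, float, float]
    median_s: tuple[float, float, float, float] = (25.0, 180.0, 1200.0, 5400.0)
    sigma: tuple[float, float, float, float] = (0.5, 0.5, 0.4, 0.25)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
            raise ParameterError("mixture weights must be non-negative, sum > 0")
        if any(m <= 0 for m in self.median_s):
            raise ParameterError("mixture medians must be positive")


@dataclass(frozen=True)
class GenotypeParams:
    """Per-genotype generator settings."""

    intrinsic_tau_h: float = 23.8
    aschoff_slope: float = 0.2  # hours of tau lengthening per log10(lux+1)
    activity_mix: BoutMixture = BoutMixture(weights=(0.55, 0.33, 0.10, 0.02))
    immobility_mix: BoutMixture = BoutMixture(
        weights=(0.35, 0.45, 0.18, 0.02),
        median_s=(25.0, 200.0, 1500.0, 5400.0),
    )
    brief_bout_deficit: float = 1.0  # multiplies the sub-minute weight

    def __post_init__(self) -> None:
        if self.intrinsic_tau_h <= 0:
            raise ParameterError("intrinsic_tau_h must be positive")
        if not (0 < self.brief_bout_deficit <= 1):
            raise ParameterError("brief_bout_deficit must be in (0, 1]")


#: Default study conditions: wild-type vs hemizygous mutant littermates,
#: the mutant with a 40% sub-minute bout deficit and a steeper response of
#: tau to constant light.
DEFAULT_GENOTYPES: dict[str, GenotypeParams] = {
    "WT": GenotypeParams(),
    "MUT": GenotypeParams(aschoff_slope=0.35, brief_bout_deficit=0.6),
}


@dataclass(frozen=True)
class MouseCohortSpec:
    """Cohort-level settings for activity-trace simulation."""

    n_per_genotype: int = 6
    days: int = 7
    bin_seconds: int = 10
    genotypes: dict[str, GenotypeParams] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPES)
    )
    nocturnality: float = 2.0  # base of the circadian gain on run lengths
    gate_strength: float = 2.5  # exponent sharpening the circadian gate
    intensity_depth: float = 0.8  # phase modulation of per-bin percent-active
    active_percent_mean: float = 60.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_genotype <= 0 or self.days <= 0:
            raise ParameterError("n_per_genotype and days must be positive")
        if self.bin_seconds <= 0 or 60 % self.bin_seconds != 0:
            raise ParameterError("bin_seconds must be positive and divide 60")
        if self.nocturnality <= 0:
            raise ParameterError("nocturnality must be positive")
        if not (0 <= self.intensity_depth <= 1):
            raise ParameterError("intensity_depth must be in [0, 1]")
        if not self.genotypes:
            raise ParameterError("at least one genotype required")


def _phase_per_bin(
    schedule: LightingSchedule, params: GenotypeParams, n_bins: int, bin_s: int
) -> tuple[np.ndarray, np.ndarray]:
    """Circadian phase (radians; 0 = mid subjective night) at each bin
    start, plus the per-bin phase increment.

    Entrained (LD) blocks pin the phase to the 24 h lighting cycle with
    mid-dark at phase 0; constant-condition blocks integrate
    d(phi)/dt = 2*pi / tau(lux), continuing from the phase reached at the
    block boundary.
    """
    t = np.arange(n_bins, dtype=float) * bin_s
    phi = np.empty(n_bins)
    dphi = np.empty(n_bins)
    # mid-dark of an LD day at block-relative 18 h (lights on 0–12 h)
    mid_dark_s = 18 * SECONDS_PER_HOUR
    phi_prev = -2 * math.pi * mid_dark_s / SECONDS_PER_DAY  # entrained start
    for block in schedule.blocks:
        m = (t >= block.start_s) & (t < block.end_s)
        if not m.any():
            continue
        if block.condition == "LD":
            rel = (t[m] - block.start_s) % SECONDS_PER_DAY
            phi[m] = 2 * math.pi * (rel - mid_dark_s) / SECONDS_PER_DAY
            dphi[m] = 2 * math.pi * bin_s / SECONDS_PER_DAY
        else:
            tau_h = params.intrinsic_tau_h + params.aschoff_slope * math.log10(
                block.effective_lux + 1.0
            )
            step = 2 * math.pi * bin_s / (tau_h * SECONDS_PER_HOUR)
            phi[m] = phi_prev + step * np.arange(1, int(m.sum()) + 1)
            dphi[m] = step
        phi_prev = phi[m][-1]
    return phi, dphi


def _effective_weights(mix: BoutMixture, deficit: float) -> np.ndarray:
    w = np.asarray(mix.weights, dtype=float)
    w = w.copy()
    w[0] *= deficit
    return w / w.sum()


def _simulate_subject(
    rng: np.random.Generator,
    params: GenotypeParams,
    spec: MouseCohortSpec,
    schedule: LightingSchedule,
    subject_id: str,
    genotype: str,
) -> ActivityTrace:
    bin_s = spec.bin_seconds
    n_bins = int(schedule.end_s - schedule.start_s) // bin_s
    phase, dphi = _phase_per_bin(schedule, params, n_bins, bin_s)

    w_act = _effective_weights(params.activity_mix, params.brief_bout_deficit)
    w_imm = _effective_weights(params.immobility_mix, params.brief_bout_deficit)
    med_act = np.asarray(params.activity_mix.median_s)
    med_imm = np.asarray(params.immobility_mix.median_s)
    sig_act = np.asarray(params.activity_mix.sigma)
    sig_imm = np.asarray(params.immobility_mix.sigma)

    # alternating renewal with circadian gating: run lengths scale with
    # nocturnality^(gate_strength * cos(phase)) for active runs (inverse
    # for immobile), and the subjective dusk / dawn transitions truncate
    # rest / activity runs respectively (clock-gated arousal, which is
    # what makes real actogram onsets sharp). Night is cos(phase) > 0.
    state = bool(rng.integers(0, 2))  # True = active
    states: list[bool] = []
    lengths: list[int] = []
    pos = 0
    two_pi = 2 * math.pi
    log_gain = spec.gate_strength * math.log(spec.nocturnality)
    while pos < n_bins:
        phi = phase[pos]
        c = math.cos(phi)
        gain = math.exp(log_gain * c)
        if state:
            k = int(rng.choice(4, p=w_act))
            run_s = med_act[k] * math.exp(sig_act[k] * rng.standard_normal()) * gain
            if c > 0:  # activity run may not outlive the night gate
                bins_to_dawn = ((math.pi / 2 - phi) % two_pi) / dphi[pos]
                run_s = min(run_s, max(bin_s, bins_to_dawn * bin_s))
        else:
            k = int(rng.choice(4, p=w_imm))
            run_s = med_imm[k] * math.exp(sig_imm[k] * rng.standard_normal()) / gain
            if c < 0:  # day rest ends at subjective dusk
                bins_to_dusk = ((-math.pi / 2 - phi) % two_pi) / dphi[pos]
                run_s = min(run_s, max(bin_s, bins_to_dusk * bin_s))
        nb = max(1, int(round(run_s / bin_s)))
        states.append(state)
        lengths.append(nb)
        pos += nb
        state = not state

    active = np.repeat(np.array(states, dtype=bool), np.array(lengths))[:n_bins]
    values = np.zeros(n_bins)
    n_active = int(active.sum())
    if n_active:
        # activity is more vigorous at the circadian peak
        mean_pct = spec.active_percent_mean * (
            1.0 - spec.intensity_depth * 0.5 * (1.0 - np.cos(phase[active]))
        )
        pct = rng.normal(mean_pct, spec.noise_sd)
        values[active] = np.clip(pct, 1.0, 100.0)
    return ActivityTrace(
        subject_id=subject_id,
        genotype=genotype,
        values=values,
        bin_seconds=bin_s,
        start_time=int(schedule.start_s),
        schedule=schedule,
    )


def simulate_mouse_activity(
    spec: MouseCohortSpec, schedule: LightingSchedule
) -> list[ActivityTrace]:
    """Simulate one activity trace per subject for the whole schedule.

    Subjects are named ``{genotype}{index}``; each gets an independent
    random stream spawned from the cohort seed, so the cohort is
    reproducible subject-wise.
    """
    if schedule.total_days < spec.days:
        raise ParameterError(
            f"schedule covers {schedule.total_days:g} days, "
            f"spec requests {spec.days}"
        )
    n_subjects = spec.n_per_genotype * len(spec.genotypes)
    streams = np.random.SeedSequence(spec.seed).spawn(n_subjects)
    traces = []
    i = 0
    for genotype, params in spec.genotypes.items():
        for j in range(spec.n_per_genotype):
            rng = np.random.default_rng(streams[i])
            traces.append(
                _simulate_subject(
                    rng, params, spec, schedule, f"{genotype}{j + 1}", genotype
                )
            )
            i += 1
    return traces


# ---------------------------------------------------------------------------
# Sleep diaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiarySpec:
    """Ultra-long sleep-wake cycle diary settings (hourly resolution)."""

    cycle_length_h: float = 72.0
    sleep_fraction: float = 0.35
    days: int = 28
    resolution_h: int = 1
    jitter: float = 0.05  # log-normal sigma on wake/sleep episode lengths
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_length_h <= 24:
            raise ParameterError("cycle_length_h must exceed 24 h")
        if not (0 < self.sleep_fraction < 1):
            raise ParameterError("sleep_fraction must be in (0, 1)")
        if self.days not in (27, 28):
            raise ParameterError("diaries cover 27 or 28 days")
        if self.resolution_h != 1:
            raise ParameterError("only hourly diary resolution is supported")


def simulate_sleep_diary(spec: DiarySpec, subject_id: str = "P1") -> DiarySeries:
    """Alternating wake/sleep episodes of jittered length at the set cycle."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_hours = 24 * spec.days
    flags = np.zeros(n_hours, dtype=int)
    t = 0.0
    asleep = False
    while t < n_hours:
        frac = spec.sleep_fraction if asleep else 1 - spec.sleep_fraction
        dur = spec.cycle_length_h * frac * math.exp(
            spec.jitter * rng.standard_normal()
        )
        lo, hi = int(round(t)), min(n_hours, int(round(t + dur)))
        if asleep:
            flags[lo:hi] = 1
        t += dur
        asleep = not asleep
    return DiarySeries(subject_id=subject_id, flags=flags, days=spec.days)


# ---------------------------------------------------------------------------
# Pedigree VCF
# ---------------------------------------------------------------------------

INHERITANCE_MODELS = ("x_linked", "recessive", "compound_het", "shared_denovo", "none")

#: Consequence classes that downstream filtering treats as protein-altering.
DAMAGING_CONSEQUENCES = (
    "nonsynonymous_snv",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "inframe_indel",
    "splice_site",
)
BENIGN_CONSEQUENCES = ("synonymous_snv", "intronic", "intergenic", "utr")

FATHER, MOTHER, SON1, SON2 = "FATHER", "MOTHER", "SON1", "SON2"


def quartet_pedigree() -> Pedigree:
    """Father / mother / two affected sons."""
    return Pedigree(
        members={
            FATHER: PedigreeMember(FATHER, "male", False),
            MOTHER: PedigreeMember(MOTHER, "female", False),
            SON1: PedigreeMember(SON1, "male", True, father=FATHER, mother=MOTHER),
            SON2: PedigreeMember(SON2, "male", True, father=FATHER, mother=MOTHER),
        }
    )


@dataclass(frozen=True)
class PlantedVariant:
    """One variant (or gene-level pair, for compound_het) to plant."""

    model: str = "x_linked"
    af: float = 0.0
    consequence: str = "nonsynonymous_snv"
    gll_margin: float = 6.0  # log10 units; margin < 5 fails the de novo rule

    def __post_init__(self) -> None:
        if self.model not in INHERITANCE_MODELS:
            raise ParameterError(f"unknown inheritance model {self.model!r}")


@dataclass(frozen=True)
class PedigreeVcfSpec:
    n_background_variants: int = 500
    planted: tuple[PlantedVariant, ...] = (PlantedVariant(),)
    seed: int = 0


def _gll_table(genotype: str, margin: float, hemizygous: bool) -> dict[str, float]:
    space = ("0", "1") if hemizygous else ("0/0", "0/1", "1/1")
    table = {}
    rank = 0
    for gt in space:
        if gt == genotype:
            table[gt] = 0.0
        else:
            rank += 1
            table[gt] = -margin * rank
    return table


def _make_record(
    chrom: str,
    pos: int,
    gene: str,
    consequence: str,
    genotypes: dict[str, str],
    af: float = 0.0,
    gll_margin: float = 8.0,
    **kwargs,
) -> VariantRecord:
    hemi = chrom.lstrip("chr").upper() == "X"
    gll = {
        s: _gll_table(gt, gll_margin, hemi and s in (FATHER, SON1, SON2))
        for s, gt in genotypes.items()
    }
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="G",
        alt="A",
        gene=gene,
        consequence=consequence,
        af_thousand_genomes=af,
        af_esp=af,
        af_gnomad=af,
        genotypes=genotypes,
        gll=gll,
        **kwargs,
    )


def _planted_records(pv: PlantedVariant, idx: int, pos0: int) -> list[VariantRecord]:
    gene = f"CAND_{pv.model.upper()}_{idx}"
    if pv.model == "none":
        return []
    if pv.model == "x_linked":
        return [
            _make_record(
                "chrX", pos0, gene, pv.consequence,
                {FATHER: "0", MOTHER: "0/1", SON1: "1", SON2: "1"},
                af=pv.af, gll_margin=pv.gll_margin,
            )
        ]
    if pv.model == "recessive":
        return [
            _make_record(
                "chr2", pos0, gene, pv.consequence,
                {FATHER: "0/1", MOTHER: "0/1", SON1: "1/1", SON2: "1/1"},
                af=pv.af, gll_margin=pv.gll_margin,
            )
        ]
    if pv.model == "compound_het":
        return [
            _make_record(
                "chr3", pos0, gene, pv.consequence,
                {FATHER: "0/1", MOTHER: "0/0", SON1: "0/1", SON2: "0/1"},
                af=pv.af, gll_margin=pv.gll_margin,
            ),
            _make_record(
                "chr3", pos0 + 500, gene, pv.consequence,
                {FATHER: "0/0", MOTHER: "0/1", SON1: "0/1", SON2: "0/1"},
                af=pv.af, gll_margin=pv.gll_margin,
            ),
        ]
    if pv.model == "shared_denovo":
        return [
            _make_record(
                "chr5", pos0, gene, pv.consequence,
                {FATHER: "0/0", MOTHER: "0/0", SON1: "0/1", SON2: "0/1"},
                af=pv.af, gll_margin=pv.gll_margin,
            )
        ]
    raise ParameterError(f"cannot generate model {pv.model!r}")


_SPOILER_KINDS = ("common_af", "benign_consequence", "cohort_hets",
                  "gnomad_hom_hemi", "non_segregating")

# genotype patterns that fit no inheritance model for this quartet
_NON_SEGREGATING = (
    {FATHER: "0/1", MOTHER: "0/0", SON1: "0/0", SON2: "0/0"},
    {FATHER: "0/0", MOTHER: "0/1", SON1: "0/1", SON2: "0/0"},
    {FATHER: "0/0", MOTHER: "0/0", SON1: "0/0", SON2: "0/1"},
    {FATHER: "0/1", MOTHER: "0/1", SON1: "0/1", SON2: "0/1"},
)


def _background_record(rng: np.random.Generator, i: int) -> VariantRecord:
    """A background variant guaranteed to fail >= 1 downstream filter."""
    chrom = f"chr{rng.integers(1, 23)}"
    spoiler = _SPOILER_KINDS[rng.integers(0, len(_SPOILER_KINDS))]
    consequence = (
        BENIGN_CONSEQUENCES[rng.integers(0, len(BENIGN_CONSEQUENCES))]
        if spoiler == "benign_consequence"
        else DAMAGING_CONSEQUENCES[rng.integers(0, len(DAMAGING_CONSEQUENCES))]
    )
    af = float(rng.uniform(0.01, 0.5)) if spoiler == "common_af" else 0.0
    genotypes = dict(_NON_SEGREGATING[rng.integers(0, len(_NON_SEGREGATING))])
    return _make_record(
        chrom,
        int(1_000_000 + i * 1_000 + rng.integers(0, 900)),
        f"BG{i:05d}",
        consequence,
        genotypes,
        af=af,
        cohort_hets=int(rng.integers(6, 40)) if spoiler == "cohort_hets" else 0,
        gnomad_hom_hemi=spoiler == "gnomad_hom_hemi",
    )


def make_toy_pedigree_vcf(
    spec: PedigreeVcfSpec,
) -> tuple[list[VariantRecord], Pedigree]:
    """Background + planted variants for the quartet, sorted by position.

    Every background record carries at least one disqualifying feature
    (common allele frequency, benign consequence, cohort hits, gnomAD
    hom/hemi presence, or a genotype pattern fitting no inheritance
    model); planted records satisfy exactly their tagged model.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    records = [
        _background_record(rng, i) for i in range(spec.n_background_variants)
    ]
    for idx, pv in enumerate(spec.planted):
        records.extend(_planted_records(pv, idx, pos0=900_000_000 + idx * 10_000))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records, quartet_pedigree()


# ---------------------------------------------------------------------------
# Dose-response tables
# ---------------------------------------------------------------------------

#: Default agonist concentrations (mM), log-spaced across the transition,
#: including the 10 mM normalisation reference.
DEFAULT_CONCENTRATIONS_MM = (0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)


def simulate_dose_response(
    ec50_mM: float = 0.53,
    top: float | None = None,
    bottom: float = 0.0,
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS_MM,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_mM: float = 10.0,
) -> "pd.DataFrame":
    """Relative responses from a Hill-slope-1 sigmoid.

    Response(C) = bottom + (top − bottom) · C / (C + EC50). When ``top`` is
    None it is solved so that the response at ``reference_mM`` equals 1,
    reproducing the convention of normalising currents to the response at
    10 mM agonist.
    """
    import pandas as pd

    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ParameterError("concentrations must be positive")
    if ec50_mM <= 0:
        raise ParameterError("ec50 must be positive")
    if conc.min() > ec50_mM or conc.max() < ec50_mM:
        raise ParameterError("concentrations must span the EC50")
    if top is None:
        frac_ref = reference_mM / (reference_mM + ec50_mM)
        top = bottom + (1.0 - bottom) / frac_ref
    y = bottom + (top - bottom) * conc / (conc + ec50_mM)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return pd.DataFrame({"concentration_mM": conc, "response": y})
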
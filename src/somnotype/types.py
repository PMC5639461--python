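"""Core domain containers shared across the pipeline.

Time is kept as integer seconds from the start of the recording (day 0,
lights-on for entrained protocols); there are no timezones. Activity bins
are half-open intervals [t, t + bin_seconds), indexed from 0. VCF
coordinates are 1-based, following the format convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SECONDS_PER_DAY = 86_400
SECONDS_PER_HOUR = 3_600


class ParameterError(ValueError):
    """Raised when a spec or configuration value is outside its domain."""


class ValidationError(ValueError):
    """Raised when loaded or constructed data violates an invariant."""


# ---------------------------------------------------------------------------
# Lighting schedule
# ---------------------------------------------------------------------------

#: Minimum uninterrupted block length (days) for a lighting condition to be
#: usable for circadian analysis.
ANALYSIS_GRADE_MIN_DAYS = 9


@dataclass(frozen=True)
class LightBlock:
    """One contiguous lighting condition.

    ``condition`` is one of ``"LD"`` (12 h light : 12 h dark, lights on at
    the start of each day of the block), ``"DD"`` (constant darkness) or
    ``"LL"`` (constant light). ``lux`` is the illuminance during the light
    phase (LD) or throughout (LL); it is ignored for DD, which is < 1 lux
    by definition and treated as 0.
    """

    start_s: int
    end_s: int
    condition: str
    lux: float = 0.0

    def __post_init__(self) -> None:
        if self.condition not in ("LD", "DD", "LL"):
            raise ParameterError(f"unknown lighting condition {self.condition!r}")
        if self.end_s <= self.start_s:
            raise ParameterError("lighting block must have positive duration")
        if self.lux < 0:
            raise ParameterError("lux must be >= 0")

    @property
    def duration_days(self) -> float:
        return (self.end_s - self.start_s) / SECONDS_PER_DAY

    @property
    def analysis_grade(self) -> bool:
        return self.duration_days >= ANALYSIS_GRADE_MIN_DAYS

    @property
    def effective_lux(self) -> float:
        """Illuminance driving the circadian system in constant conditions."""
        return 0.0 if self.condition == "DD" else self.lux

    def is_dark(self, t_s: np.ndarray) -> np.ndarray:
        """Boolean darkness mask for absolute times ``t_s`` (seconds)."""
        t_s = np.asarray(t_s)
        if self.condition == "DD":
            return np.ones(t_s.shape, dtype=bool)
        if self.condition == "LL":
            return np.zeros(t_s.shape, dtype=bool)
        # LD 12:12 with lights on for the first half of each block-relative day
        rel = (t_s - self.start_s) % SECONDS_PER_DAY
        return rel >= SECONDS_PER_DAY // 2


@dataclass(frozen=True)
class LightingSchedule:
    """Ordered, contiguous, non-overlapping lighting blocks."""

    blocks: tuple[LightBlock, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ParameterError("schedule must contain at least one block")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt.start_s != prev.end_s:
                raise ValidationError(
                    f"schedule blocks must be contiguous: block ending at "
                    f"{prev.end_s}s followed by block starting at {nxt.start_s}s"
                )

    @property
    def start_s(self) -> int:
        return self.blocks[0].start_s

    @property
    def end_s(self) -> int:
        return self.blocks[-1].end_s

    @property
    def total_days(self) -> float:
        return (self.end_s - self.start_s) / SECONDS_PER_DAY

    def block_at(self, t_s: float) -> LightBlock:
        for b in self.blocks:
            if b.start_s <= t_s < b.end_s:
                return b
        raise ValidationError(f"time {t_s}s outside schedule")

    def is_dark(self, t_s: np.ndarray) -> np.ndarray:
        t_s = np.asarray(t_s)
        out = np.zeros(t_s.shape, dtype=bool)
        for b in self.blocks:
            m = (t_s >= b.start_s) & (t_s < b.end_s)
            out[m] = b.is_dark(t_s[m])
        return out


def ld_schedule(days: int, lux: float = 200.0) -> LightingSchedule:
    """Convenience 12:12 LD schedule starting at lights-on."""
    return LightingSchedule((LightBlock(0, days * SECONDS_PER_DAY, "LD", lux),))


def dd_schedule(days: int) -> LightingSchedule:
    return LightingSchedule((LightBlock(0, days * SECONDS_PER_DAY, "DD", 0.0),))


# ---------------------------------------------------------------------------
# Activity / sleep series
# ---------------------------------------------------------------------------


@dataclass
class ActivityTrace:
    """Percent-active per fixed-width bin from a passive-infrared sensor.

    ``values[i]`` is the percentage of bin ``[start_time + i*bin_seconds,
    start_time + (i+1)*bin_seconds)`` during which the sensor reported
    movement; values lie in [0, 100].
    """

    subject_id: str
    genotype: str
    values: np.ndarray
    bin_seconds: int = 10
    start_time: int = 0
    schedule: Optional[LightingSchedule] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("activity values must be one-dimensional")
        if self.bin_seconds <= 0:
            raise ParameterError("bin_seconds must be positive")
        bad = np.flatnonzero((self.values < 0) | (self.values > 100))
        if bad.size:
            raise ValidationError(
                f"percent-active out of [0, 100] at bin {bad[0]} "
                f"(value {self.values[bad[0]]:g})"
            )

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> int:
        return self.n_bins * self.bin_seconds

    def bin_times(self) -> np.ndarray:
        """Absolute start time (s) of every bin."""
        return self.start_time + np.arange(self.n_bins) * self.bin_seconds


@dataclass
class SleepSeries:
    """Per-bin behavioural sleep flags on the parent trace's grid."""

    subject_id: str
    flags: np.ndarray
    bin_seconds: int
    start_time: int = 0
    immobility_threshold_bins: int = 4
    onset: str = "fourth_bin"

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.flags.size

    @property
    def total_sleep_s(self) -> int:
        return int(self.flags.sum()) * self.bin_seconds


@dataclass
class DiarySeries:
    """Hourly sleep (1) / wake (0) flags from a sleep diary."""

    subject_id: str
    flags: np.ndarray
    days: int

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=int)
        if not np.isin(self.flags, (0, 1)).all():
            raise ValidationError("diary flags must be binary")
        if self.flags.size != 24 * self.days:
            raise ValidationError(
                f"diary length {self.flags.size} != 24 h x {self.days} days"
            )


# ---------------------------------------------------------------------------
# Bouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bout:
    """One maximal run of consecutive bins in a single behavioural state.

    ``intensity`` (activity bouts only) is the mean per-bin percent-active
    over the bout — i.e. the percentage of the whole bout during which the
    sensor was active.
    """

    kind: str  # "activity" | "sleep"
    start_bin: int
    n_bins: int
    bin_seconds: int
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("activity", "sleep"):
            raise ParameterError(f"unknown bout kind {self.kind!r}")
        if self.n_bins < 1:
            raise ValidationError("bout must span at least one bin")
        if self.kind == "activity":
            if self.intensity is None or not (0 < self.intensity <= 100):
                raise ValidationError("activity bout intensity must be in (0, 100]")

    @property
    def duration_s(self) -> int:
        return self.n_bins * self.bin_seconds


# ---------------------------------------------------------------------------
# Rhythm analysis results
# ---------------------------------------------------------------------------


@dataclass
class Periodogram:
    """Chi-square periodogram over a grid of candidate periods.

    ``qp[i]`` is the rhythmicity statistic at ``periods_h[i]``;
    ``threshold[i]`` is the chi-square critical value (df = period-in-bins
    − 1) above which the period is significant at ``alpha`` (per-period,
    uncorrected — the single diagonal line of the classical plot).
    """

    periods_h: np.ndarray
    qp: np.ndarray
    df: np.ndarray
    threshold: np.ndarray
    alpha: float
    bin_seconds: float


@dataclass
class RhythmResult:
    """Per subject x lighting-block circadian summary."""

    subject_id: str
    genotype: str
    condition: str
    lux: float
    tau_h: Optional[float]
    peak_qp: float
    significant: bool
    mean_daily_activity: float
    tau_adjusted_activity: Optional[float]


# ---------------------------------------------------------------------------
# Variants & pedigree
# ---------------------------------------------------------------------------

#: Genotype encoding used throughout: diploid "0/0", "0/1", "1/1";
#: hemizygous "0", "1"; missing "./." or ".".
DIPLOID_GENOTYPES = ("0/0", "0/1", "1/1")
HEMIZYGOUS_GENOTYPES = ("0", "1")


@dataclass
class VariantRecord:
    """One biallelic, pre-annotated variant with quartet genotypes.

    Allele frequencies default to 0 (novel) when the variant is absent
    from the reference panels. ``genotypes`` maps sample id to a genotype
    string; ``gll`` maps sample id to log10 genotype likelihoods per
    genotype (same key convention), or None when unavailable.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    af_thousand_genomes: float = 0.0
    af_esp: float = 0.0
    af_gnomad: float = 0.0
    gnomad_hom_hemi: bool = False
    cohort_hets: int = 0
    cohort_hom_hemi: int = 0
    genotypes: dict[str, str] = field(default_factory=dict)
    gll: Optional[dict[str, dict[str, float]]] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError("VCF positions are 1-based; pos must be >= 1")

    @property
    def is_x(self) -> bool:
        return self.chrom.lstrip("chr").upper() == "X"

    def genotype(self, sample: str) -> Optional[str]:
        gt = self.genotypes.get(sample)
        if gt in (None, ".", "./."):
            return None
        return gt

    def gll_margin(self, sample: str) -> Optional[float]:
        """log10 L(best alternative genotype) − log10 L(called genotype).

        Non-positive by construction when the call is the maximum-likelihood
        genotype; more negative means a more confident call. None when
        likelihoods are unavailable.
        """
        if not self.gll or sample not in self.gll:
            return None
        gt = self.genotype(sample)
        if gt is None:
            return None
        table = self.gll[sample]
        if gt not in table:
            return None
        others = [v for k, v in table.items() if k != gt]
        if not others:
            return None
        return max(others) - table[gt]


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    sex: str  # "male" | "female"
    affected: bool
    father: Optional[str] = None
    mother: Optional[str] = None


@dataclass
class Pedigree:
    """Family structure; the filtering stage requires a quartet of
    father, mother and two affected sons."""

    members: dict[str, PedigreeMember]

    def __post_init__(self) -> None:
        for m in self.members.values():
            if m.sex not in ("male", "female"):
                raise ValidationError(f"sex missing or invalid for {m.sample_id}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.members)

    def quartet(self) -> tuple[PedigreeMember, PedigreeMember, PedigreeMember, PedigreeMember]:
        """Return (father, mother, son1, son2) or raise if not a supported quartet."""
        children = [m for m in self.members.values() if m.father and m.mother]
        parents = [m for m in self.members.values() if not (m.father or m.mother)]
        if len(children) != 2 or len(parents) != 2:
            raise ValidationError("pedigree must be a two-parent, two-child quartet")
        fathers = [p for p in parents if p.sex == "male"]
        mothers = [p for p in parents if p.sex == "female"]
        if len(fathers) != 1 or len(mothers) != 1:
            raise ValidationError("quartet must have one father and one mother")
        if not all(c.affected for c in children):
            raise ValidationError("both children must be affected for this design")
        if not all(c.sex == "male" for c in children):
            raise ValidationError("X-linked model requires two affected sons")
        sons = sorted(children, key=lambda m: m.sample_id)
        return fathers[0], mothers[0], sons[0], sons[1]
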
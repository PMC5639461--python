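"""Family-quartet candidate-variant prioritisation.

Three filter stages, each a pure subset operation, applied in sequence
with a per-stage funnel count:

1. consequence — keep protein-altering classes only (nonsynonymous SNV,
   stop gain/loss, frameshift or inframe indel, splice site);
2. frequency — drop variants with reference-panel allele frequency
   > 0.005, any cohort homozygote/hemizygote, more than five cohort
   heterozygotes, or any gnomAD homozygote/hemizygote;
3. inheritance — test the surviving variants against four models for a
   father / mother / two-affected-sons quartet: simple recessive,
   compound heterozygous (gene-level pairs, one allele from each
   heterozygous parent), X-linked recessive, and a shared de novo event
   (both sons heterozygous, parents reference) supported by a genotype
   log-likelihood margin stricter than -5 log10 units in all four
   members.

Because the stages are independent predicates, their order does not
change the final candidate set — only the funnel counts.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .types import ParameterError, Pedigree, VariantRecord

DEFAULT_CONSEQUENCE_WHITELIST = frozenset(
    {
        "nonsynonymous_snv",
        "stopgain",
        "stoploss",
        "frameshift_indel",
        "inframe_indel",
        "splice_site",
    }
)

MODELS = ("recessive", "compound_het", "x_linked", "shared_denovo")


@dataclass(frozen=True)
class FilterConfig:
    max_af: float = 0.005
    max_cohort_hets: int = 5
    disallow_cohort_hom_hemi: bool = True
    disallow_gnomad_hom_hemi: bool = True
    consequence_whitelist: frozenset[str] = DEFAULT_CONSEQUENCE_WHITELIST
    denovo_gll_threshold: float = -5.0

    def __post_init__(self) -> None:
        if not (0 <= self.max_af <= 1):
            raise ParameterError("max_af must be a frequency in [0, 1]")
        if self.denovo_gll_threshold >= 0:
            raise ParameterError("de novo GLL threshold must be negative")


@dataclass
class CandidateSet:
    """Candidates per inheritance model; compound-het candidates are
    gene-level pairs (lists of >= 2 records)."""

    recessive: list[VariantRecord] = field(default_factory=list)
    x_linked: list[VariantRecord] = field(default_factory=list)
    shared_denovo: list[VariantRecord] = field(default_factory=list)
    compound_het: dict[str, list[VariantRecord]] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return (
            len(self.recessive)
            + len(self.x_linked)
            + len(self.shared_denovo)
            + sum(len(v) for v in self.compound_het.values())
        )


def filter_consequence(
    records: list[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Keep protein-altering variants; records with no consequence
    annotation are dropped with a warning (they cannot be assessed)."""
    missing = sum(1 for r in records if not r.consequence)
    if missing:
        warnings.warn(
            f"{missing} record(s) without consequence annotation dropped",
            stacklevel=2,
        )
    return [r for r in records if r.consequence in cfg.consequence_whitelist]


def filter_frequency(
    records: list[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Rarity filter. Exclusion is strict: AF greater than the threshold
    is removed, AF equal to it retained. Absent annotation counts as
    frequency 0 (novel)."""
    out = []
    for r in records:
        if max(r.af_thousand_genomes, r.af_esp) > cfg.max_af:
            continue
        if cfg.disallow_cohort_hom_hemi and r.cohort_hom_hemi > 0:
            continue
        if r.cohort_hets > cfg.max_cohort_hets:
            continue
        if cfg.disallow_gnomad_hom_hemi and r.gnomad_hom_hemi:
            continue
        out.append(r)
    return out


def _gt(record: VariantRecord, sample: str) -> str | None:
    return record.genotype(sample)


def _matches_recessive(r: VariantRecord, f: str, m: str, s1: str, s2: str) -> bool:
    if r.is_x:
        return False
    gts = [_gt(r, s) for s in (f, m, s1, s2)]
    if any(g is None for g in gts):
        return False
    return gts[0] == "0/1" and gts[1] == "0/1" and gts[2] == "1/1" and gts[3] == "1/1"


def _matches_x_linked(r: VariantRecord, f: str, m: str, s1: str, s2: str) -> bool:
    if not r.is_x:
        return False
    gts = [_gt(r, s) for s in (f, m, s1, s2)]
    if any(g is None for g in gts):
        return False
    return gts[0] == "0" and gts[1] == "0/1" and gts[2] == "1" and gts[3] == "1"


def _matches_denovo(
    r: VariantRecord, f: str, m: str, s1: str, s2: str, threshold: float
) -> bool:
    gts = [_gt(r, s) for s in (f, m, s1, s2)]
    if any(g is None for g in gts):
        return False
    if not (gts[0] == "0/0" and gts[1] == "0/0" and gts[2] == "0/1" and gts[3] == "0/1"):
        return False
    for s in (f, m, s1, s2):
        margin = r.gll_margin(s)
        if margin is None or margin >= threshold:
            return False
    return True


def _compound_het_pairs(
    records: list[VariantRecord], f: str, m: str, s1: str, s2: str
) -> dict[str, list[VariantRecord]]:
    """Genes with >= 2 variants, one transmitted from each heterozygous
    parent, both affected sons carrying both alleles."""
    by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
    for r in records:
        if r.is_x:
            continue
        gts = {s: _gt(r, s) for s in (f, m, s1, s2)}
        if None in gts.values():
            continue
        if gts[s1] != "0/1" or gts[s2] != "0/1":
            continue
        paternal = gts[f] == "0/1" and gts[m] == "0/0"
        maternal = gts[m] == "0/1" and gts[f] == "0/0"
        if paternal or maternal:
            by_gene[r.gene].append(r)
    out = {}
    for gene, recs in by_gene.items():
        has_pat = any(_gt(r, f) == "0/1" for r in recs)
        has_mat = any(_gt(r, m) == "0/1" for r in recs)
        if has_pat and has_mat and len(recs) >= 2:
            out[gene] = recs
    return out


def apply_inheritance_models(
    records: list[VariantRecord], pedigree: Pedigree, cfg: FilterConfig = FilterConfig()
) -> CandidateSet:
    """Test records against the four quartet inheritance models. A record
    with a missing genotype in any member is ineligible for that model
    (not an error)."""
    father, mother, son1, son2 = pedigree.quartet()
    f, m, s1, s2 = father.sample_id, mother.sample_id, son1.sample_id, son2.sample_id
    cs = CandidateSet()
    for r in records:
        if _matches_recessive(r, f, m, s1, s2):
            cs.recessive.append(r)
        if _matches_x_linked(r, f, m, s1, s2):
            cs.x_linked.append(r)
        if _matches_denovo(r, f, m, s1, s2, cfg.denovo_gll_threshold):
            cs.shared_denovo.append(r)
    cs.compound_het = _compound_het_pairs(records, f, m, s1, s2)
    return cs


def run_full_filter(
    records: list[VariantRecord],
    pedigree: Pedigree,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[CandidateSet, pd.DataFrame]:
    """Consequence -> frequency -> inheritance, with a funnel report.

    The funnel table has one row per stage with records in, records out
    and records removed (in = out + removed at every stage).
    """
    stage1 = filter_consequence(records, cfg)
    stage2 = filter_frequency(stage1, cfg)
    candidates = apply_inheritance_models(stage2, pedigree, cfg)
    funnel = pd.DataFrame(
        [
            {"stage": "input", "n_in": len(records), "n_out": len(records),
             "n_removed": 0},
            {"stage": "consequence", "n_in": len(records), "n_out": len(stage1),
             "n_removed": len(records) - len(stage1)},
            {"stage": "frequency", "n_in": len(stage1), "n_out": len(stage2),
             "n_removed": len(stage1) - len(stage2)},
            {"stage": "inheritance", "n_in": len(stage2),
             "n_out": candidates.n_total,
             "n_removed": len(stage2) - candidates.n_total},
        ]
    )
    return candidates, funnel
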
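"""Readers and writers for the pipeline's external formats.

* Activity traces and diaries: CSV with ``#``-prefixed metadata header
  lines; the value grid round-trips exactly.
* Lighting schedules: YAML/JSON block lists.
* Pedigrees: 6-column PED (FID IID PAT MAT SEX PHENO).
* Variants: VCF v4.2 via pysam, with pre-populated annotation carried in
  INFO (gene, consequence class, panel allele frequencies, cohort
  het/hom-hemi counts, gnomAD hom/hemi flag) and GT + PL genotype fields.
  Multi-allelic sites are split into biallelic records on read so the
  frequency filters apply per alternate allele.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .types import (
    ActivityTrace,
    DiarySeries,
    LightBlock,
    LightingSchedule,
    ParameterError,
    Pedigree,
    PedigreeMember,
    SECONDS_PER_DAY,
    SleepSeries,
    ValidationError,
    VariantRecord,
)

# ---------------------------------------------------------------------------
# Activity / sleep / diary CSV
# ---------------------------------------------------------------------------


def _write_metadata(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}: {v}\n")


def _read_metadata(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    return meta


def write_activity_csv(trace: ActivityTrace, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_metadata(
            fh,
            {
                "subject_id": trace.subject_id,
                "genotype": trace.genotype,
                "bin_seconds": trace.bin_seconds,
                "start_time": trace.start_time,
            },
        )
        fh.write("bin_index,percent_active\n")
        for i, v in enumerate(trace.values):
            fh.write(f"{i},{v:.6g}\n")


def read_activity_csv(path, gap_policy: str = "error") -> ActivityTrace:
    """Load an activity trace; the bin grid must be uniform and complete.

    ``gap_policy``: ``"error"`` (default) raises with a gap report;
    ``"zero_fill"`` fills missing bins with 0 and warns.
    """
    if gap_policy not in ("error", "zero_fill"):
        raise ParameterError("gap_policy must be 'error' or 'zero_fill'")
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    if not {"bin_index", "percent_active"} <= set(df.columns):
        raise ValidationError("activity CSV needs bin_index,percent_active columns")
    idx = df["bin_index"].to_numpy()
    n = int(idx.max()) + 1 if idx.size else 0
    expected = np.arange(n)
    if idx.size != n or not np.array_equal(np.sort(idx), expected):
        missing = sorted(set(range(n)) - set(idx.tolist()))
        if gap_policy == "error":
            raise ValidationError(
                f"non-uniform bin grid; missing bins {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        warnings.warn(
            f"zero-filled {len(missing)} missing bin(s)", stacklevel=2
        )
        values = np.zeros(n)
        values[idx.astype(int)] = df["percent_active"].to_numpy()
    else:
        values = df.sort_values("bin_index")["percent_active"].to_numpy()
    return ActivityTrace(
        subject_id=meta.get("subject_id", path.stem),
        genotype=meta.get("genotype", ""),
        values=values,
        bin_seconds=int(meta.get("bin_seconds", 10)),
        start_time=int(meta.get("start_time", 0)),
    )


def write_sleep_csv(sleep: SleepSeries, path) -> None:
    """Per-bin sleep flags with the scoring parameters echoed in the
    header."""
    with open(path, "w") as fh:
        _write_metadata(
            fh,
            {
                "subject_id": sleep.subject_id,
                "bin_seconds": sleep.bin_seconds,
                "start_time": sleep.start_time,
                "immobility_threshold_bins": sleep.immobility_threshold_bins,
                "onset": sleep.onset,
            },
        )
        fh.write("bin_index,asleep\n")
        for i, v in enumerate(sleep.flags):
            fh.write(f"{i},{int(v)}\n")


def write_diary_csv(diary: DiarySeries, path) -> None:
    with open(path, "w") as fh:
        _write_metadata(fh, {"subject_id": diary.subject_id, "days": diary.days})
        fh.write("hour,asleep\n")
        for i, v in enumerate(diary.flags):
            fh.write(f"{i},{int(v)}\n")


def read_diary_csv(path) -> DiarySeries:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    return DiarySeries(
        subject_id=meta.get("subject_id", path.stem),
        flags=df.sort_values("hour")["asleep"].to_numpy(),
        days=int(meta.get("days", len(df) // 24)),
    )


# ---------------------------------------------------------------------------
# Lighting schedules (YAML / JSON)
# ---------------------------------------------------------------------------


def read_lighting_schedule(path) -> LightingSchedule:
    """Block list with either explicit ``start_s``/``end_s`` or sequential
    ``days`` per block; overlaps and gaps are rejected."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = doc["blocks"] if isinstance(doc, dict) else doc
    blocks = []
    cursor = 0
    for item in raw:
        if "start_s" in item:
            start, end = int(item["start_s"]), int(item["end_s"])
        else:
            start = cursor
            end = start + int(round(float(item["days"]) * SECONDS_PER_DAY))
        blocks.append(
            LightBlock(start, end, item["condition"], float(item.get("lux", 0.0)))
        )
        cursor = end
    for prev, nxt in zip(blocks, blocks[1:]):
        if nxt.start_s < prev.end_s:
            raise ValidationError("overlapping lighting blocks")
    return LightingSchedule(tuple(blocks))  # contiguity re-checked here


def write_lighting_schedule(schedule: LightingSchedule, path) -> None:
    doc = {
        "blocks": [
            {
                "start_s": b.start_s,
                "end_s": b.end_s,
                "condition": b.condition,
                "lux": b.lux,
            }
            for b in schedule.blocks
        ]
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh)


# ---------------------------------------------------------------------------
# Pedigree (PED)
# ---------------------------------------------------------------------------


def read_pedigree(path) -> Pedigree:
    members = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fid, iid, pat, mat, sex, pheno = line.split()[:6]
        members[iid] = PedigreeMember(
            sample_id=iid,
            sex={"1": "male", "2": "female"}.get(sex, ""),
            affected=pheno == "2",
            father=None if pat == "0" else pat,
            mother=None if mat == "0" else mat,
        )
    return Pedigree(members=members)


def write_pedigree(ped: Pedigree, path, family_id: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for m in ped.members.values():
            fh.write(
                f"{family_id}\t{m.sample_id}\t{m.father or 0}\t{m.mother or 0}\t"
                f"{'1' if m.sex == 'male' else '2'}\t{'2' if m.affected else '1'}\n"
            )


# ---------------------------------------------------------------------------
# VCF (pysam)
# ---------------------------------------------------------------------------

_CONTIGS = tuple(f"chr{c}" for c in list(range(1, 23)) + ["X"])


def _vcf_header(samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in _CONTIGS:
        header.contigs.add(contig)
    header.add_meta(
        "INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Gene symbol")]
    )
    header.add_meta(
        "INFO", items=[("ID", "CSQ"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Consequence class")]
    )
    for af_id, desc in (
        ("AF_1KG", "1000 Genomes allele frequency"),
        ("AF_ESP", "NHLBI ESP allele frequency"),
        ("AF_GNOMAD", "gnomAD allele frequency"),
    ):
        header.add_meta(
            "INFO", items=[("ID", af_id), ("Number", "A"), ("Type", "Float"),
                           ("Description", desc)]
        )
    header.add_meta(
        "INFO", items=[("ID", "GNOMAD_HOMHEMI"), ("Number", "0"),
                       ("Type", "Flag"),
                       ("Description", "Seen hom/hemi in gnomAD")]
    )
    for cid, desc in (
        ("COHORT_HETS", "Heterozygotes in the internal cohort"),
        ("COHORT_HOMHEMI", "Hom/hemizygotes in the internal cohort"),
    ):
        header.add_meta(
            "INFO", items=[("ID", cid), ("Number", "1"), ("Type", "Integer"),
                           ("Description", desc)]
        )
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    for s in samples:
        header.add_sample(s)
    return header


def _gt_tuple(gt: str) -> tuple:
    if gt in ("./.", "."):
        return (None,)
    if "/" in gt:
        a, b = gt.split("/")
        return (int(a), int(b))
    return (int(gt),)


def _pl_from_gll(table: dict[str, float]) -> tuple[int, ...]:
    order = ("0", "1") if set(table) <= {"0", "1"} else ("0/0", "0/1", "1/1")
    best = max(table.values())
    return tuple(int(round(-10.0 * (table[g] - best))) for g in order)


def write_vcf(records: list[VariantRecord], samples: list[str], path) -> None:
    """Write biallelic records as uncompressed VCF v4.2."""
    header = _vcf_header(samples)
    out = pysam.VariantFile(str(path), "w", header=header)
    for r in sorted(records, key=lambda r: (_CONTIGS.index(r.chrom), r.pos)):
        rec = out.new_record(
            contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
        )
        rec.info["GENE"] = r.gene
        rec.info["CSQ"] = r.consequence
        rec.info["AF_1KG"] = (r.af_thousand_genomes,)
        rec.info["AF_ESP"] = (r.af_esp,)
        rec.info["AF_GNOMAD"] = (r.af_gnomad,)
        if r.gnomad_hom_hemi:
            rec.info["GNOMAD_HOMHEMI"] = True
        rec.info["COHORT_HETS"] = r.cohort_hets
        rec.info["COHORT_HOMHEMI"] = r.cohort_hom_hemi
        for s in samples:
            gt = r.genotypes.get(s, "./.")
            rec.samples[s]["GT"] = _gt_tuple(gt)
            if r.gll and s in r.gll:
                rec.samples[s]["PL"] = _pl_from_gll(r.gll[s])
        out.write(rec)
    out.close()


def _split_gt(alleles: tuple, alt_index: int) -> str:
    """Biallelic view of a (possibly multi-allelic) genotype: the target
    alt maps to 1, every other allele to 0."""
    if alleles is None or all(a is None for a in alleles):
        return "./." if alleles and len(alleles) == 2 else "."
    mapped = ["1" if a == alt_index else "0" for a in alleles]
    if len(mapped) == 1:
        return mapped[0]
    return "/".join(sorted(mapped))


def _gll_from_pl(pl, n_alleles: int) -> dict[str, float] | None:
    if pl is None or any(v is None for v in pl):
        return None
    if len(pl) == 2:
        keys = ("0", "1")
    elif len(pl) == 3:
        keys = ("0/0", "0/1", "1/1")
    else:
        return None
    return {k: -v / 10.0 for k, v in zip(keys, pl)}


def _info_get(info, key, default=None):
    # pysam raises on lookups of keys absent from the header entirely
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _af(info, key: str, alt_index: int) -> float:
    val = _info_get(info, key)
    if val is None:
        return 0.0
    if isinstance(val, tuple):
        v = val[alt_index - 1] if len(val) >= alt_index else None
        return float(v) if v is not None else 0.0
    return float(val)


def read_vcf(path, pedigree: Pedigree) -> list[VariantRecord]:
    """Parse a VCF into annotated records for the pedigree's samples.

    Multi-allelic sites are split into one biallelic record per alternate
    allele; genotype likelihoods are carried over only for biallelic
    sites (the PL layout is not separable otherwise) and marked absent
    elsewhere.
    """
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    missing = [s for s in pedigree.sample_ids if s not in vcf_samples]
    if missing:
        raise ValidationError(f"pedigree samples absent from VCF: {missing}")
    records = []
    for rec in vf:
        alts = rec.alts or ()
        for k, alt in enumerate(alts, start=1):
            genotypes = {}
            gll: dict[str, dict[str, float]] = {}
            for s in pedigree.sample_ids:
                sample = rec.samples[s]
                genotypes[s] = _split_gt(sample.get("GT"), k)
                if len(alts) == 1:
                    table = _gll_from_pl(sample.get("PL"), 2)
                    if table is not None:
                        gll[s] = table
            records.append(
                VariantRecord(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=_info_get(rec.info, "GENE", ""),
                    consequence=_info_get(rec.info, "CSQ", ""),
                    af_thousand_genomes=_af(rec.info, "AF_1KG", k),
                    af_esp=_af(rec.info, "AF_ESP", k),
                    af_gnomad=_af(rec.info, "AF_GNOMAD", k),
                    gnomad_hom_hemi=bool(_info_get(rec.info, "GNOMAD_HOMHEMI", False)),
                    cohort_hets=int(_info_get(rec.info, "COHORT_HETS", 0)),
                    cohort_hom_hemi=int(_info_get(rec.info, "COHORT_HOMHEMI", 0)),
                    genotypes=genotypes,
                    gll=gll or None,
                )
            )
    vf.close()
    return records
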
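"""Readers and writers for the pipeline's file formats.

Audiograms travel as long-form CSV (one row per participant ear, one
column per frequency, ``f0.25`` ... ``f8`` in kHz, dB HL values, empty
cell = missing).  Per-caller variant calls travel as three VCFs (GATK
with an INFO ``TRANCHE`` tag; BCFtools and Freebayes with a PASS/fail
FILTER column); mitochondrial calls as a VCF with per-sample ``DP`` and
``AF`` FORMAT fields.  Annotations are a TSV keyed by variant id
(``chrom:pos:ref:alt``), gene lists one identifier per line.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .audiometry import Audiogram, Ear, NoiseHistory, Participant, Sex
from .consensus import CallerRecord, MitoCall, Tranche

__all__ = [
    "read_audiograms",
    "write_audiograms",
    "read_annotations",
    "write_annotations",
    "read_gene_list",
    "write_gene_list",
    "read_caller_vcfs",
    "write_caller_vcfs",
    "read_mito_vcf",
    "write_mito_vcf",
]

MITO_CONTIGS = {"chrM", "MT", "chrMT", "M"}


def _freq_columns(columns: Iterable[str]) -> dict[str, float]:
    out = {}
    for c in columns:
        if c.startswith("f"):
            try:
                out[c] = float(c[1:])
            except ValueError:
                continue
    return out


def read_audiograms(path) -> list[Participant]:
    """Read long-form audiogram CSV into Participant objects.

    Expects columns participant_id, sex {M,F}, age, noise_history
    {pos,neg,unknown}, ear {L,R}, then one ``f<kHz>`` column per
    frequency.  Both ears must be present for every participant.
    """
    df = pd.read_csv(path)
    freq_cols = _freq_columns(df.columns)
    participants = []
    for pid, sub in df.groupby("participant_id", sort=False):
        ears = {}
        meta = sub.iloc[0]
        for _, row in sub.iterrows():
            thresholds = {
                khz: float(row[col])
                for col, khz in sorted(freq_cols.items(), key=lambda kv: kv[1])
                if not pd.isna(row[col])
            }
            ear = Ear(row["ear"])
            ears[ear] = Audiogram(str(pid), ear, thresholds)
        if set(ears) != {Ear.LEFT, Ear.RIGHT}:
            raise ValueError(f"participant {pid} lacks both ears")
        participants.append(
            Participant(
                id=str(pid),
                sex=Sex(meta["sex"]),
                age_years=float(meta["age"]),
                noise_history=NoiseHistory(meta["noise_history"]),
                left=ears[Ear.LEFT],
                right=ears[Ear.RIGHT],
            )
        )
    return participants


def write_audiograms(participants: Sequence[Participant], path) -> None:
    freqs = sorted({f for p in participants
                    for f in (*p.left.thresholds, *p.right.thresholds)})
    rows = []
    for p in participants:
        for ag in (p.left, p.right):
            row = {
                "participant_id": p.id,
                "sex": p.sex.value,
                "age": p.age_years,
                "noise_history": p.noise_history.value,
                "ear": ag.ear.value,
            }
            for f in freqs:
                row[f"f{f:g}"] = ag.thresholds.get(f, "")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    """Annotation TSV indexed by variant_id (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene_id": str})
    required = {"variant_id", "gene_id", "impact_class", "ref_maf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return df.set_index("variant_id")


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=True, index_label="variant_id")


def read_gene_list(path) -> list[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def _variant_id(rec: pysam.VariantRecord) -> str:
    return f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"


_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def _code_from_gt(gt) -> int | None:
    if gt is None or any(a is None for a in gt):
        return None
    return _GT_CODE.get(tuple(gt))


def read_caller_vcfs(gatk_path, bcftools_path, freebayes_path) -> list[CallerRecord]:
    """Merge three per-caller VCFs into CallerRecords keyed by variant.

    The GATK VCF carries INFO ``TRANCHE`` (tranche1/tranche2/lower);
    BCFtools and Freebayes pass/fail state is their FILTER column.
    """
    records: dict[str, CallerRecord] = {}

    def _ingest(path, caller: str) -> None:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                vid = _variant_id(rec)
                cr = records.setdefault(
                    vid, CallerRecord(variant_id=vid, contig=rec.chrom))
                gts = {}
                for sample, call in rec.samples.items():
                    gts[sample] = _code_from_gt(call.get("GT"))
                cr.genotypes[caller] = gts
                if caller == "gatk":
                    tranche = rec.info.get("TRANCHE", "absent")
                    if isinstance(tranche, tuple):
                        tranche = tranche[0]
                    cr.gatk_tranche = Tranche(tranche)
                elif caller == "bcftools":
                    cr.bcftools_pass = "PASS" in rec.filter or len(rec.filter) == 0
                elif caller == "freebayes":
                    cr.freebayes_pass = "PASS" in rec.filter or len(rec.filter) == 0

    _ingest(gatk_path, "gatk")
    _ingest(bcftools_path, "bcftools")
    _ingest(freebayes_path, "freebayes")
    return list(records.values())


def _parse_vid(vid: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = vid.split(":")
    return chrom, int(pos), ref, alt


def _base_header(contigs: Iterable[str], samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in contigs:
        header.contigs.add(c, length=300_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.filters.add("FAIL", None, None, "Failed caller filter")
    for s in samples:
        header.add_sample(s)
    return header


_CODE_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_caller_vcfs(
    records: Sequence[CallerRecord],
    samples: Sequence[str],
    gatk_path,
    bcftools_path,
    freebayes_path,
) -> None:
    """Write CallerRecords back out as three per-caller VCFs (sorted)."""
    parsed = sorted(
        ((rec, *_parse_vid(rec.variant_id)) for rec in records),
        key=lambda t: (t[1], t[2]),
    )
    contigs = sorted({t[1] for t in parsed})

    def _write(path, caller: str) -> None:
        header = _base_header(contigs, samples)
        if caller == "gatk":
            header.info.add("TRANCHE", 1, "String", "VQSR tranche")
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for rec, chrom, pos, ref, alt in parsed:
                if caller not in rec.genotypes:
                    continue
                out = vf.new_record(contig=chrom, start=pos - 1, stop=pos,
                                    alleles=(ref, alt))
                if caller == "gatk":
                    out.info["TRANCHE"] = rec.gatk_tranche.value
                    out.filter.add("PASS")
                else:
                    passed = (rec.bcftools_pass if caller == "bcftools"
                              else rec.freebayes_pass)
                    out.filter.add("PASS" if passed else "FAIL")
                gts = rec.genotypes[caller]
                for s in samples:
                    code = gts.get(s)
                    out.samples[s]["GT"] = _CODE_GT.get(code, (None, None))
                vf.write(out)

    _write(gatk_path, "gatk")
    _write(bcftools_path, "bcftools")
    _write(freebayes_path, "freebayes")


def read_mito_vcf(path) -> list[MitoCall]:
    """Read per-sample mitochondrial calls (FORMAT DP and AF)."""
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            vid = _variant_id(rec)
            for sample, call in rec.samples.items():
                dp = call.get("DP")
                af = call.get("AF")
                if dp is None or af is None:
                    continue
                if isinstance(af, tuple):
                    af = af[0]
                calls.append(MitoCall(vid, sample, int(dp), float(af)))
    return calls


def write_mito_vcf(calls: Sequence[MitoCall], samples: Sequence[str], path) -> None:
    by_variant: dict[str, dict[str, MitoCall]] = {}
    for c in calls:
        by_variant.setdefault(c.variant_id, {})[c.participant_id] = c
    contigs = sorted({_parse_vid(v)[0] for v in by_variant})
    header = _base_header(contigs, samples)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AF", 1, "Float", "Variant allele fraction")
    ordered = sorted(by_variant, key=lambda v: _parse_vid(v)[1])
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for vid in ordered:
            chrom, pos, ref, alt = _parse_vid(vid)
            out = vf.new_record(contig=chrom, start=pos - 1, stop=pos,
                                alleles=(ref, alt))
            out.filter.add("PASS")
            for s in samples:
                call = by_variant[vid].get(s)
                if call is not None:
                    out.samples[s]["DP"] = call.depth
                    out.samples[s]["AF"] = call.vaf
                out.samples[s]["GT"] = (None, None)
            vf.write(out)
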
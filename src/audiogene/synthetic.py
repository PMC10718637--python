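"""Synthetic cohort generator with machine-readable ground truth.

Emulates the statistical structure the analysis assumes: audiograms built
from the two-component (metabolic + sensory) model with additive
per-frequency Gaussian noise, Hardy-Weinberg genotypes at rare-variant
MAFs, optional per-class gene-load enrichment (a carrier-rate multiplier
in a target phenotype class) and optional planted carrier threshold
shifts of stated dB magnitudes.  Every random draw comes from an
integer-indexed RNG stream (seed, kind, index) so output is reproducible
and independent of iteration order.

Default cohort conditions mirror the primary study cohort: ~500
participants, 55% female, ages 55-90, class mixture 19% Older-Normal /
29% Metabolic / 29% Sensory / 23% atypical, 8 audiometric frequencies
from 0.25 to 8 kHz, and 3 dB per-frequency threshold noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .audiometry import (
    Audiogram,
    Ear,
    NoiseHistory,
    Participant,
    ProfileBasis,
    Sex,
)
from .consensus import MISSING, CallerRecord, GenotypeMatrix, Tranche
from . import io as agio

__all__ = [
    "PlantedLoad",
    "PlantedEffect",
    "SimParams",
    "generate_cohort",
    "generate_genotypes",
    "as_caller_records",
    "write_fixture",
]

# alternative audiometric grid: starts at 0.125 kHz, omits 3 kHz (some
# clinics record this set instead of the default 0.25-8 kHz grid)
EXTENDED_LOW_FREQS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0)

# Uniform (low, high) ranges in dB for the metabolic and sensory
# component magnitudes of each planted class, placed well inside the
# classification rule regions.
DEFAULT_COMPONENTS = {
    "OlderNormal": ((2.0, 7.0), (2.0, 7.0)),
    "Metabolic": ((30.0, 50.0), (2.0, 12.0)),
    "Sensory": ((2.0, 12.0), (30.0, 50.0)),
    "UnclassifiedLike": ((30.0, 45.0), (30.0, 45.0)),
}
DEFAULT_MIXTURE = {
    "OlderNormal": 0.19,
    "Metabolic": 0.29,
    "Sensory": 0.29,
    "UnclassifiedLike": 0.23,
}


@dataclass(frozen=True)
class PlantedLoad:
    """Carrier-rate multiplier for every variant of one gene in one class."""

    gene_id: str
    target_class: str
    multiplier: float


@dataclass(frozen=True)
class PlantedEffect:
    """A variant whose carriers get a threshold shift.

    ``shift_db`` is added to the carriers' thresholds at
    ``frequencies_khz`` in both ears (negative = protective / better
    hearing).  Exactly ``n_carriers`` heterozygous carriers are assigned
    (optionally restricted to one sex) — the scan's minimum-carriers gate
    makes power sensitive to the realised count, so carriers are planted
    exactly rather than drawn from a MAF.
    """

    effect_id: str
    shift_db: float
    frequencies_khz: tuple
    n_carriers: int
    sex: str | None = None  # 'M', 'F' or None for either
    ref_maf: float = 0.01


@dataclass
class SimParams:
    n_participants: int = 500
    female_fraction: float = 0.55
    age_range: tuple = (55.0, 90.0)
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE))
    component_distributions: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENTS))
    noise_sd_db: float = 3.0
    frequencies_khz: tuple = ProfileBasis().frequencies_khz
    basis: ProfileBasis = field(default_factory=ProfileBasis)
    n_genes: int = 200
    variants_per_gene_mean: float = 2.0
    maf_range: tuple = (0.001, 0.1)
    planted_load: Sequence[PlantedLoad] = ()
    planted_effects: Sequence[PlantedEffect] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class mixture must sum to 1 (got {total})")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.1 + 1e-12):
            raise ValueError("MAF range must lie in (0, 0.1]")


def gene_name(i: int) -> str:
    return f"GENE{i:04d}"


def generate_cohort(params: SimParams) -> tuple[list[Participant], dict]:
    """Draw participants with two-component audiograms plus noise.

    Each participant draws a class, then (M, S) from the class's
    component distribution; thresholds are M*metabolic + S*sensory +
    N(0, noise_sd) independently per ear and frequency, clipped to
    [-10, 120] dB HL.
    """
    classes = list(params.class_mixture)
    probs = np.asarray([params.class_mixture[c] for c in classes])
    cum = np.cumsum(probs)
    shapes = params.basis.at(params.frequencies_khz)  # (F, 2)
    participants = []
    truth = {}
    for i in range(params.n_participants):
        rng = np.random.default_rng([params.seed, 1, i])
        sex = Sex.FEMALE if rng.random() < params.female_fraction else Sex.MALE
        age = rng.uniform(*params.age_range)
        cls = classes[int(np.searchsorted(cum, rng.random(), side="right"))]
        (m_lo, m_hi), (s_lo, s_hi) = params.component_distributions[cls]
        m = rng.uniform(m_lo, m_hi)
        s = rng.uniform(s_lo, s_hi)
        pid = f"P{i:04d}"
        ears = {}
        for ear in (Ear.LEFT, Ear.RIGHT):
            noise = rng.normal(0.0, params.noise_sd_db, len(params.frequencies_khz))
            vals = np.clip(shapes @ [m, s] + noise, -10.0, 120.0)
            ears[ear] = Audiogram(
                pid, ear, dict(zip(params.frequencies_khz, vals.round(1))))
        participants.append(
            Participant(pid, sex, round(age, 1), NoiseHistory.NEGATIVE,
                        ears[Ear.LEFT], ears[Ear.RIGHT])
        )
        truth[pid] = {"class": cls, "M": m, "S": s, "sex": sex.value}
    return participants, truth


def _hwe_probs(maf: float) -> np.ndarray:
    return np.asarray([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


def generate_genotypes(
    params: SimParams, participants: list[Participant], cohort_truth: dict
) -> tuple[list[Participant], GenotypeMatrix, pd.DataFrame, dict]:
    """Draw HWE genotypes, apply planted load and planted effect variants.

    Returns (participants, matrix, annotations, truth); participants are
    rebuilt when planted effects shift carrier thresholds.  Baseline
    genotypes are Hardy-Weinberg at each variant's MAF; for planted-load
    genes the het/hom probabilities are multiplied in the target class
    (capped so they still sum to at most 1).
    """
    pids = [p.id for p in participants]
    load_by_gene = {pl.gene_id: pl for pl in params.planted_load}

    # per-gene variant counts (at least one variant per gene)
    variant_rows = []
    for g in range(params.n_genes):
        rng = np.random.default_rng([params.seed, 2, g])
        n_var = 1 + rng.poisson(max(params.variants_per_gene_mean - 1.0, 0.0))
        for v in range(n_var):
            variant_rows.append((gene_name(g), g, v))

    codes = {}
    ann_rows = []
    truth_load = []
    classes = np.asarray([cohort_truth[pid]["class"] for pid in pids])
    for idx, (gene, g, v) in enumerate(variant_rows):
        rng = np.random.default_rng([params.seed, 3, idx])
        maf = rng.uniform(*params.maf_range)
        base = _hwe_probs(maf)
        probs = np.tile(base, (len(pids), 1))
        planted = load_by_gene.get(gene)
        if planted is not None:
            target = classes == planted.target_class
            het = np.minimum(base[1] * planted.multiplier, 1.0)
            hom = np.minimum(base[2] * planted.multiplier, 1.0 - het)
            probs[target] = [1.0 - het - hom, het, hom]
        u = rng.random(len(pids))
        cum = np.cumsum(probs, axis=1)
        gt = (u[:, None] > cum).sum(axis=1).astype(np.int8)
        chrom = str((g % 22) + 1)
        vid = f"{chrom}:{1000 + 10 * idx}:A:G"
        codes[vid] = gt
        ann_rows.append({"variant_id": vid, "gene_id": gene,
                         "impact_class": "high", "ref_maf": round(maf, 6)})
    for pl in params.planted_load:
        truth_load.append(asdict(pl))

    # planted effect variants: exact carrier counts, het genotype, shifted
    # thresholds at the affected frequencies in both ears
    truth_effects = []
    shift_map: dict[str, list[tuple[float, tuple]]] = {}
    for e_idx, eff in enumerate(params.planted_effects):
        rng = np.random.default_rng([params.seed, 4, e_idx])
        eligible = [
            pid for pid in pids
            if eff.sex is None or cohort_truth[pid]["sex"] == eff.sex
        ]
        if eff.n_carriers > len(eligible):
            raise ValueError(
                f"planted effect {eff.effect_id}: {eff.n_carriers} carriers "
                f"requested but only {len(eligible)} eligible participants")
        carriers = sorted(rng.choice(eligible, size=eff.n_carriers, replace=False))
        gt = np.zeros(len(pids), dtype=np.int8)
        carrier_set = set(carriers)
        for j, pid in enumerate(pids):
            if pid in carrier_set:
                gt[j] = 1
                shift_map.setdefault(pid, []).append(
                    (eff.shift_db, tuple(eff.frequencies_khz)))
        chrom = "22"
        vid = f"{chrom}:{900000 + 10 * e_idx}:C:T"
        gene = f"EFFGENE{e_idx:02d}"
        codes[vid] = gt
        ann_rows.append({"variant_id": vid, "gene_id": gene,
                         "impact_class": "high", "ref_maf": eff.ref_maf})
        truth_effects.append(
            {"effect_id": eff.effect_id, "variant_id": vid, "gene_id": gene,
             "shift_db": eff.shift_db,
             "frequencies_khz": list(eff.frequencies_khz),
             "carriers": list(carriers)}
        )

    if shift_map:
        rebuilt = []
        for p in participants:
            if p.id not in shift_map:
                rebuilt.append(p)
                continue
            ears = {}
            for ag in (p.left, p.right):
                thr = dict(ag.thresholds)
                for shift, freqs in shift_map[p.id]:
                    for f in freqs:
                        if f in thr:
                            thr[f] = float(np.clip(thr[f] + shift, -10.0, 120.0))
                ears[ag.ear] = Audiogram(p.id, ag.ear, thr)
            rebuilt.append(Participant(p.id, p.sex, p.age_years, p.noise_history,
                                       ears[Ear.LEFT], ears[Ear.RIGHT]))
        participants = rebuilt

    matrix = GenotypeMatrix(pd.DataFrame(codes, index=pids).T)
    annotations = pd.DataFrame(ann_rows).set_index("variant_id")
    truth = {
        "participants": cohort_truth,
        "planted_load": truth_load,
        "planted_effects": truth_effects,
    }
    return participants, matrix, annotations, truth


def as_caller_records(matrix: GenotypeMatrix) -> list[CallerRecord]:
    """Wrap consensus genotypes as three unanimous passing caller calls."""
    records = []
    for vid in matrix.variants:
        row = matrix.codes.loc[vid]
        gts = {pid: (None if g == MISSING else int(g)) for pid, g in row.items()}
        records.append(
            CallerRecord(
                variant_id=vid,
                gatk_tranche=Tranche.TRANCHE1,
                bcftools_pass=True,
                freebayes_pass=True,
                genotypes={"gatk": dict(gts), "bcftools": dict(gts),
                           "freebayes": dict(gts)},
                contig=vid.split(":", 1)[0],
            )
        )
    return records


def write_fixture(params: SimParams, directory) -> dict:
    """Generate a full cohort and write it in the pipeline's input formats.

    Emits audiograms.csv, gatk/bcftools/freebayes VCFs, annotations.tsv,
    planted_genes.txt and truth.json; returns the truth table.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    participants, cohort_truth = generate_cohort(params)
    participants, matrix, annotations, truth = generate_genotypes(
        params, participants, cohort_truth)

    agio.write_audiograms(participants, directory / "audiograms.csv")
    records = as_caller_records(matrix)
    agio.write_caller_vcfs(
        records, [p.id for p in participants],
        directory / "gatk.vcf", directory / "bcftools.vcf",
        directory / "freebayes.vcf",
    )
    agio.write_annotations(annotations, directory / "annotations.tsv")
    planted = [pl.gene_id for pl in params.planted_load] + [
        e["gene_id"] for e in truth["planted_effects"]]
    agio.write_gene_list(planted, directory / "planted_genes.txt")
    (directory / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth
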
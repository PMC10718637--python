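"""Multi-caller genotype consensus and variant quality control.

Variants are called by three callers (GATK HaplotypeCaller with VQSR
tranche annotation, BCFtools and Freebayes).  A site is kept when it
passed the top VQSR tranche together with at least one of the other two
callers, or the second tranche together with BCFtools.  Per-sample
genotypes are merged by majority vote; a three-way disagreement
(hom-ref / het / hom-alt) is resolved to heterozygous, and every other
combination — including single-caller-only calls and 1-vs-1 splits —
is recorded as missing.

Surviving sites then pass through a Hardy-Weinberg excess-heterozygosity
exact test (a signature of mismapped paralogous sites), a cohort
allele-frequency cap (cohort AF > reference MAF + 0.4 flags aligner
miscalls in low-complexity regions), and the final high-impact,
MAF < 0.1 restriction.  Mitochondrial calls are genotyped from read
depth and variant allele fraction: homoplasmy (VAF > 0.95) maps to a
homozygous call, heteroplasmy (VAF >= 0.40 with depth > 30x) to a
heterozygous call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "Tranche",
    "MISSING",
    "CallerRecord",
    "MitoCall",
    "QCParams",
    "GenotypeMatrix",
    "site_quality_gate",
    "merge_genotype",
    "excess_het_pvalue",
    "excess_het_filter",
    "cohort_af_filter",
    "mito_genotype",
    "impact_maf_filter",
    "apply_qc_pipeline",
    "percent_agreement",
]

# Genotype codes: 0 hom-ref, 1 het, 2 hom-alt; None / -1 missing.
MISSING = -1


class Tranche(str, Enum):
    TRANCHE1 = "tranche1"
    TRANCHE2 = "tranche2"
    LOWER = "lower"
    ABSENT = "absent"


@dataclass
class CallerRecord:
    """Per-site calls from the three callers.

    ``genotypes`` maps caller name ('gatk', 'bcftools', 'freebayes') to a
    mapping participant_id -> genotype code (0/1/2) or None for no-call.
    """

    variant_id: str
    gatk_tranche: Tranche = Tranche.ABSENT
    bcftools_pass: bool = False
    freebayes_pass: bool = False
    genotypes: dict = field(default_factory=dict)
    contig: str = ""

    @property
    def is_mitochondrial(self) -> bool:
        return self.contig in {"chrM", "MT", "chrMT", "M"}


@dataclass(frozen=True)
class MitoCall:
    variant_id: str
    participant_id: str
    depth: int
    vaf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("VAF must lie in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class QCParams:
    """Tunable QC thresholds.

    ``excess_het_alpha`` is not a published value; 1e-6 is a common
    exome-QC significance level for the excess-heterozygosity filter.
    """

    excess_het_alpha: float = 1e-6
    cohort_af_margin: float = 0.4
    maf_max: float = 0.1
    mito_min_depth: int = 30
    mito_het_vaf_min: float = 0.40
    mito_hom_vaf_min: float = 0.95
    missing_ref_maf: float = 0.0


def site_quality_gate(record: CallerRecord) -> bool:
    """Keep a site iff its caller combination was validated as accurate.

    tranche1 + (BCFtools or Freebayes pass), or tranche2 + BCFtools pass.
    """
    if record.gatk_tranche is Tranche.TRANCHE1:
        return record.bcftools_pass or record.freebayes_pass
    if record.gatk_tranche is Tranche.TRANCHE2:
        return record.bcftools_pass
    return False


def merge_genotype(calls: Iterable[int | None]) -> int:
    """Merge per-caller genotype codes into one consensus code.

    Unanimous or 2-vs-1 calls take the majority; a full three-way split
    {hom_ref, het, hom_alt} resolves to het; anything else (single-caller
    calls, 1-vs-1 splits, all-missing) is missing.  Symmetric in caller
    order.
    """
    observed = [c for c in calls if c is not None and c != MISSING]
    if len(observed) < 2:
        return MISSING
    counts = {g: observed.count(g) for g in set(observed)}
    if len(counts) == 1:
        return observed[0]
    top = max(counts.values())
    if top >= 2:
        winners = [g for g, n in counts.items() if n == top]
        if len(winners) == 1:
            return winners[0]
        return MISSING
    if set(counts) == {0, 1, 2}:
        return 1
    return MISSING


def _levene_haldane_logpmf(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of heterozygote counts conditional on allele counts.

    Returns (het_counts, logpmf) for the exact conditional distribution of
    the number of heterozygotes under Hardy-Weinberg equilibrium, given n
    diploid individuals and n_minor copies of the minor allele.
    """
    parity = n_minor % 2
    hs = np.arange(parity, min(n_minor, 2 * n - n_minor) + 1, 2)
    n_major = 2 * n - n_minor
    a = (n_minor - hs) // 2          # minor-allele homozygotes
    b = n - hs - a                   # major-allele homozygotes
    logw = (
        gammaln(n + 1) - gammaln(a + 1) - gammaln(hs + 1) - gammaln(b + 1)
        + hs * math.log(2)
    )
    logw -= logw.max()
    w = np.exp(logw)
    return hs, np.log(w / w.sum())


def excess_het_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided exact p-value for heterozygote excess.

    Conditional on the observed allele counts, sums the probability of
    all genotype configurations with at least the observed number of
    heterozygotes.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n <= 0:
        raise ValueError("undefined test: zero genotype total")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    hs, logpmf = _levene_haldane_logpmf(n, n_minor)
    return float(np.exp(logpmf[hs >= n_het]).sum().clip(max=1.0))


def excess_het_filter(
    genotype_counts: tuple[int, int, int], alpha: float = QCParams.excess_het_alpha
) -> bool:
    """Keep (True) unless the heterozygote-excess exact p falls below alpha."""
    p = excess_het_pvalue(*genotype_counts)
    return p >= alpha


def cohort_af_filter(cohort_af: float, ref_maf: float, margin: float = 0.4) -> bool:
    """Keep unless the cohort allele frequency exceeds reference MAF + margin."""
    return cohort_af <= ref_maf + margin


def mito_genotype(
    call: MitoCall,
    min_depth: int = QCParams.mito_min_depth,
    het_vaf_min: float = QCParams.mito_het_vaf_min,
    hom_vaf_min: float = QCParams.mito_hom_vaf_min,
) -> int:
    """Genotype a mitochondrial call from depth and variant allele fraction."""
    if call.depth < min_depth:
        return MISSING
    if call.vaf > hom_vaf_min:
        return 2
    if het_vaf_min <= call.vaf <= hom_vaf_min:
        return 1
    return MISSING


def impact_maf_filter(
    impact_class: str, ref_maf: float | None, maf_max: float = QCParams.maf_max,
    missing_ref_maf: float = QCParams.missing_ref_maf,
) -> bool:
    """Keep iff the variant is high impact with reference MAF strictly below the cap."""
    if ref_maf is None or (isinstance(ref_maf, float) and math.isnan(ref_maf)):
        ref_maf = missing_ref_maf
    return impact_class == "high" and ref_maf < maf_max


class GenotypeMatrix:
    """Consensus genotypes, variants x participants (codes 0/1/2, -1 missing)."""

    def __init__(self, codes: pd.DataFrame) -> None:
        self.codes = codes.astype(np.int8)

    @property
    def variants(self) -> list[str]:
        return list(self.codes.index)

    @property
    def participants(self) -> list[str]:
        return list(self.codes.columns)

    def cohort_af(self, variant_id: str, mitochondrial: bool = False) -> float:
        """Alternate-allele frequency among non-missing genotypes.

        Nuclear: dosage / (2 x non-missing).  Mitochondrial (haploid in
        effect): carriers / non-missing.
        """
        row = self.codes.loc[variant_id].to_numpy()
        called = row != MISSING
        if called.sum() == 0:
            return 0.0
        if mitochondrial:
            return float((row[called] > 0).sum() / called.sum())
        return float(row[called].sum() / (2 * called.sum()))

    def genotype_counts(self, variant_id: str) -> tuple[int, int, int]:
        row = self.codes.loc[variant_id].to_numpy()
        return (int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum()))

    def to_tsv(self, path) -> None:
        out = self.codes.astype(object).replace(MISSING, ".")
        out.index.name = "variant_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
        return cls(df.replace(".", MISSING).astype(np.int8))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenotypeMatrix) and self.codes.equals(other.codes)


def apply_qc_pipeline(
    records: Sequence[CallerRecord],
    annotations: pd.DataFrame | None,
    params: QCParams | None = None,
    mito_calls: Sequence[MitoCall] = (),
    participants: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Run the full site-level QC funnel and return the genotype matrix.

    Stage order: caller-combination quality gate -> genotype consensus
    merge -> excess-heterozygosity -> cohort-AF cap -> high-impact /
    MAF < 0.1.  Returns the surviving matrix and a per-stage retention
    report.  ``annotations`` must be indexed by variant_id with columns
    ``impact_class`` and ``ref_maf``; variants without a reference MAF are
    treated as novel (MAF = ``params.missing_ref_maf``).  Mitochondrial
    calls join after their VAF/depth genotyping and are exempt from the
    diploid quality gate and excess-heterozygosity test.
    """
    params = params or QCParams()
    if participants is None:
        seen: dict[str, None] = {}
        for rec in records:
            for caller_gts in rec.genotypes.values():
                for pid in caller_gts:
                    seen.setdefault(pid)
        for mc in mito_calls:
            seen.setdefault(mc.participant_id)
        participants = list(seen)

    n_input = len(records) + len({mc.variant_id for mc in mito_calls})

    # Stage 1: quality gate (nuclear sites only).
    gated = [r for r in records if site_quality_gate(r)]

    # Stage 2: consensus merge; mitochondrial VAF genotyping joins here.
    rows: dict[str, np.ndarray] = {}
    mito_ids: set[str] = set()
    for rec in gated:
        merged = np.full(len(participants), MISSING, dtype=np.int8)
        for j, pid in enumerate(participants):
            calls = [rec.genotypes.get(c, {}).get(pid) for c in rec.genotypes]
            merged[j] = merge_genotype(calls)
        rows[rec.variant_id] = merged
    by_variant: dict[str, dict[str, MitoCall]] = {}
    for mc in mito_calls:
        by_variant.setdefault(mc.variant_id, {})[mc.participant_id] = mc
    for vid, calls in by_variant.items():
        merged = np.full(len(participants), MISSING, dtype=np.int8)
        for j, pid in enumerate(participants):
            if pid in calls:
                merged[j] = mito_genotype(
                    calls[pid], params.mito_min_depth,
                    params.mito_het_vaf_min, params.mito_hom_vaf_min,
                )
            else:
                merged[j] = 0  # no mitochondrial variant reported
        rows[vid] = merged
        mito_ids.add(vid)
    n_merged = len(rows)
    matrix = GenotypeMatrix(
        pd.DataFrame(rows, index=list(participants)).T
        if rows else pd.DataFrame(index=pd.Index([], name="variant_id"),
                                  columns=list(participants), dtype=np.int8)
    )

    # Stage 3: excess heterozygosity (diploid sites only).
    keep3 = []
    for vid in matrix.variants:
        if vid in mito_ids:
            keep3.append(vid)
            continue
        counts = matrix.genotype_counts(vid)
        if sum(counts) == 0 or excess_het_filter(counts, params.excess_het_alpha):
            keep3.append(vid)
    n_het = len(keep3)

    # Stage 4: cohort allele frequency cap.
    def _ref_maf(vid: str) -> float:
        if annotations is None or vid not in annotations.index:
            return params.missing_ref_maf
        v = annotations.loc[vid, "ref_maf"]
        return params.missing_ref_maf if pd.isna(v) else float(v)

    keep4 = [
        vid for vid in keep3
        if cohort_af_filter(
            matrix.cohort_af(vid, mitochondrial=vid in mito_ids),
            _ref_maf(vid), params.cohort_af_margin,
        )
    ]
    n_af = len(keep4)

    # Stage 5: high impact + MAF < cap.
    keep5 = []
    for vid in keep4:
        impact = (
            str(annotations.loc[vid, "impact_class"])
            if annotations is not None and vid in annotations.index
            else "other"
        )
        if impact_maf_filter(impact, _ref_maf(vid), params.maf_max,
                             params.missing_ref_maf):
            keep5.append(vid)
    n_final = len(keep5)

    report = pd.DataFrame(
        {
            "stage": ["input", "quality_gate", "genotype_merge",
                      "excess_het", "cohort_af", "impact_maf"],
            "variants_retained": [n_input, len(gated) + len(by_variant),
                                  n_merged, n_het, n_af, n_final],
        }
    )
    final = GenotypeMatrix(matrix.codes.loc[keep5])
    return final, report


def percent_agreement(confusion: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Overall percent agreement of a square call-vs-truth matrix.

    100 x (sum of the diagonal) / (sum of all cells) — used to summarise
    concordance between sequencing calls and an orthogonal validation
    assay.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(100.0 * np.trace(m) / total)
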
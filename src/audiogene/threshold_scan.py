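"""Per-variant audiometric threshold-difference scan with permutation testing.

For every qualifying variant the cohort is split into carriers (any
alternate allele) and the homozygous-reference group, overall and within
each sex.  At each (ear, stimulus frequency) the carrier mean threshold
is compared with the reference mean: a frequency *passes* when the
difference is at least 20 dB and the carrier standard deviation stays
below a frequency-banded cap (15 dB up to 0.5 kHz, 20 dB up to 2 kHz,
25 dB up to 4 kHz, 30 dB above).  Variants with at least two passing
frequencies in each ear, all in one direction, go to permutation
testing: carrier-sized, sex-matched pseudo-groups are drawn 20,000 times
and the variant's empirical p-value is the fraction of shufflings that
reproduce a passing result at the observed frequencies.  Variants with
more than 1,000 similar shufflings (p > 0.05) are rejected; the retained
variants' p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .audiometry import Participant, Sex
from .consensus import MISSING, GenotypeMatrix
from .variant_load import adjust_pvalues

__all__ = [
    "ScanConfig",
    "CohortAudiograms",
    "Grouping",
    "FreqPassRecord",
    "Candidate",
    "empirical_p",
    "build_groupings",
    "frequency_pass",
    "variant_filter",
    "permutation_test",
    "bh_adjust",
    "scan_cohort",
    "ThresholdScan",
    "ThresholdScanResults",
]

# (upper frequency bound in kHz, maximum carrier SD in dB); half-open
# bands so each standard audiometric frequency maps to exactly one cap.
DEFAULT_SD_CAPS = ((0.5, 15.0), (2.0, 20.0), (4.0, 25.0), (math.inf, 30.0))


@dataclass(frozen=True)
class ScanConfig:
    """Settings of the threshold-difference scan.

    ``reject_count / n_perm`` is the nominal alpha of the permutation
    rejection rule (0.05 at the defaults of 1000 / 20000); scale both
    together when reducing ``n_perm``.
    """

    min_group: int = 5
    diff_min_db: float = 20.0
    sd_caps: tuple = DEFAULT_SD_CAPS
    min_pass_freqs_per_ear: int = 2
    n_perm: int = 20000
    reject_count: int = 1000
    perm_require_direction: bool = False
    perm_pass_mode: str = "observed_set"  # or "min_per_ear"
    chunk_size: int = 2000

    @property
    def alpha(self) -> float:
        return self.reject_count / self.n_perm

    def sd_cap(self, frequency_khz: float) -> float:
        for upper, cap in self.sd_caps:
            if frequency_khz <= upper:
                return cap
        raise ValueError(f"no SD cap covers frequency {frequency_khz}")


def empirical_p(similar_count: int, n_perm: int) -> float:
    """Empirical permutation p-value: similar shufflings / total shufflings."""
    if not 0 <= similar_count <= n_perm:
        raise ValueError("similar_count must lie in [0, n_perm]")
    return similar_count / n_perm


class CohortAudiograms:
    """Dense (participant, ear, frequency) threshold array for scanning."""

    EARS = ("L", "R")

    def __init__(self, ids: Sequence[str], sexes: Sequence[str],
                 frequencies: Sequence[float], thresholds: np.ndarray) -> None:
        self.ids = list(ids)
        self.sex = np.asarray(sexes)
        self.frequencies = np.asarray(frequencies, dtype=float)
        self.thresholds = np.asarray(thresholds, dtype=float)  # (n, 2, F)
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @classmethod
    def from_participants(cls, participants: Sequence[Participant]) -> "CohortAudiograms":
        freqs = sorted({f for p in participants
                        for f in (*p.left.thresholds, *p.right.thresholds)})
        fidx = {f: j for j, f in enumerate(freqs)}
        thr = np.full((len(participants), 2, len(freqs)), np.nan)
        for i, p in enumerate(participants):
            for e, ag in enumerate((p.left, p.right)):
                for f, v in ag.thresholds.items():
                    thr[i, e, fidx[f]] = v
        return cls([p.id for p in participants],
                   [p.sex.value for p in participants], freqs, thr)

    def indices(self, ids: Iterable[str]) -> np.ndarray:
        return np.asarray([self._index[i] for i in ids], dtype=int)


@dataclass(frozen=True)
class Grouping:
    variant_id: str
    stratum: str  # 'all', 'M', 'F'
    carriers: tuple
    reference: tuple


@dataclass(frozen=True)
class FreqPassRecord:
    ear: str
    frequency_khz: float
    mean_diff_db: float
    carrier_sd_db: float
    passed: bool
    direction: str  # 'worse' (carriers higher dB HL) or 'better'
    evaluable: bool = True


@dataclass(frozen=True)
class Candidate:
    grouping: Grouping
    pass_records: tuple
    direction: str

    @property
    def pass_set(self) -> tuple:
        return tuple((r.ear, r.frequency_khz) for r in self.pass_records)


def build_groupings(
    genotypes: Mapping[str, int], sexes: Mapping[str, str], variant_id: str
) -> list[Grouping]:
    """Carrier/reference groupings overall and per sex.

    Carriers pool heterozygous and homozygous-alternate participants;
    the reference group is homozygous-reference participants of the same
    stratum.  Missing genotypes are excluded from both.  Groupings with
    no carriers are omitted.
    """
    out = []
    for stratum in ("all", "M", "F"):
        carriers, reference = [], []
        for pid, g in genotypes.items():
            if g not in (0, 1, 2):
                continue
            if stratum != "all" and sexes[pid] != stratum:
                continue
            if g in (1, 2):
                carriers.append(pid)
            else:
                reference.append(pid)
        if carriers:
            out.append(Grouping(variant_id, stratum, tuple(carriers), tuple(reference)))
    return out


def frequency_pass(
    carrier_thresholds: np.ndarray,
    reference_thresholds: np.ndarray,
    ear: str,
    frequency_khz: float,
    config: ScanConfig | None = None,
) -> FreqPassRecord:
    """Evaluate one (ear, frequency) against the dB-difference and SD criteria."""
    config = config or ScanConfig()
    carr = np.asarray(carrier_thresholds, dtype=float)
    ref = np.asarray(reference_thresholds, dtype=float)
    carr = carr[np.isfinite(carr)]
    ref = ref[np.isfinite(ref)]
    if len(carr) < 2 or len(ref) < 1:
        return FreqPassRecord(ear, frequency_khz, math.nan, math.nan,
                              False, "worse", evaluable=False)
    diff = float(carr.mean() - ref.mean())
    sd = float(carr.std(ddof=1))
    passed = abs(diff) >= config.diff_min_db and sd <= config.sd_cap(frequency_khz)
    direction = "worse" if diff > 0 else "better"
    return FreqPassRecord(ear, frequency_khz, diff, sd, passed, direction)


def variant_filter(
    variant_id: str,
    genotypes: Mapping[str, int],
    cohort: CohortAudiograms,
    config: ScanConfig | None = None,
) -> list[Candidate]:
    """Pre-permutation filter for one variant.

    A grouping is eligible when its carrier count reaches ``min_group``;
    the variant is dropped only if every grouping is ineligible.  An
    eligible grouping becomes a candidate when at least
    ``min_pass_freqs_per_ear`` frequencies pass in each ear and all
    passing frequencies agree in direction.
    """
    config = config or ScanConfig()
    sexes = {pid: cohort.sex[cohort._index[pid]] for pid in genotypes}
    groupings = build_groupings(genotypes, sexes, variant_id)
    candidates = []
    for grouping in groupings:
        if len(grouping.carriers) < config.min_group:
            continue
        carr_idx = cohort.indices(grouping.carriers)
        ref_idx = cohort.indices(grouping.reference)
        records = []
        for e, ear in enumerate(cohort.EARS):
            for j, f in enumerate(cohort.frequencies):
                rec = frequency_pass(
                    cohort.thresholds[carr_idx, e, j],
                    cohort.thresholds[ref_idx, e, j],
                    ear, f, config,
                )
                if rec.passed:
                    records.append(rec)
        per_ear = {ear: sum(r.ear == ear for r in records) for ear in cohort.EARS}
        if any(n < config.min_pass_freqs_per_ear for n in per_ear.values()):
            continue
        directions = {r.direction for r in records}
        if len(directions) != 1:
            continue
        candidates.append(Candidate(grouping, tuple(records), directions.pop()))
    return candidates


def _pool_columns(cohort: CohortAudiograms, idx: np.ndarray,
                  pass_set: Sequence[tuple]) -> np.ndarray:
    ear_to_int = {"L": 0, "R": 1}
    freq_to_int = {f: j for j, f in enumerate(cohort.frequencies)}
    cols = [cohort.thresholds[idx, ear_to_int[e], freq_to_int[f]]
            for e, f in pass_set]
    return np.column_stack(cols) if cols else np.empty((len(idx), 0))


def permutation_test(
    candidate: Candidate,
    cohort: CohortAudiograms,
    config: ScanConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, float]:
    """Sex-preserving permutation null for one candidate.

    Pseudo-carrier groups of the observed size and sex composition are
    drawn without replacement from carriers ∪ reference (within sex, so
    the carrier group's sex make-up is preserved even in the combined
    stratum); the remainder forms the pseudo-reference.  A shuffling is
    *similar* when every (ear, frequency) in the observed passing set
    meets the dB-difference and SD criteria under the permuted labels
    (direction is not required by default).  Returns
    (similar_count, empirical p).
    """
    config = config or ScanConfig()
    rng = rng or np.random.default_rng()
    grouping = candidate.grouping
    pass_set = candidate.pass_set
    caps = np.asarray([config.sd_cap(f) for _, f in pass_set])
    obs_sign = 1.0 if candidate.direction == "worse" else -1.0

    # per-sex pools of carrier ∪ reference with the carrier quota to draw
    pools = []
    for sex in ("M", "F"):
        carr = [p for p in grouping.carriers
                if cohort.sex[cohort._index[p]] == sex]
        ref = [p for p in grouping.reference
               if cohort.sex[cohort._index[p]] == sex]
        if not carr and not ref:
            continue
        idx = cohort.indices(carr + ref)
        pools.append((_pool_columns(cohort, idx, pass_set), len(carr)))

    k_cols = len(pass_set)
    tot_sum = np.zeros(k_cols)
    tot_n = np.zeros(k_cols)
    for cols, _ in pools:
        finite = np.isfinite(cols)
        tot_sum += np.where(finite, cols, 0.0).sum(axis=0)
        tot_n += finite.sum(axis=0)

    similar = 0
    remaining = config.n_perm
    while remaining > 0:
        chunk = min(config.chunk_size, remaining)
        carr_sum = np.zeros((chunk, k_cols))
        carr_sumsq = np.zeros((chunk, k_cols))
        carr_n = np.zeros((chunk, k_cols))
        for cols, k in pools:
            if k == 0:
                continue
            n_pool = cols.shape[0]
            order = np.argsort(rng.random((chunk, n_pool)), axis=1)[:, :k]
            vals = cols[order]  # (chunk, k, k_cols)
            finite = np.isfinite(vals)
            v0 = np.where(finite, vals, 0.0)
            carr_sum += v0.sum(axis=1)
            carr_sumsq += (v0**2).sum(axis=1)
            carr_n += finite.sum(axis=1)
        ref_sum = tot_sum - carr_sum
        ref_n = tot_n - carr_n
        ok = (carr_n >= 2) & (ref_n >= 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_c = carr_sum / carr_n
            diff = mean_c - ref_sum / ref_n
            var = (carr_sumsq - carr_n * mean_c**2) / (carr_n - 1)
        sd = np.sqrt(np.clip(var, 0.0, None))
        col_pass = ok & (np.abs(diff) >= config.diff_min_db) & (sd <= caps)
        if config.perm_require_direction:
            col_pass &= np.sign(diff) == obs_sign
        if config.perm_pass_mode == "observed_set":
            similar += int(col_pass.all(axis=1).sum())
        else:  # min_per_ear: >= min_pass per ear among the observed frequencies
            ears = np.asarray([e for e, _ in pass_set])
            per_ear_ok = np.ones(chunk, dtype=bool)
            for ear in ("L", "R"):
                cols_e = col_pass[:, ears == ear]
                per_ear_ok &= cols_e.sum(axis=1) >= config.min_pass_freqs_per_ear
            similar += int(per_ear_ok.sum())
        remaining -= chunk
    return similar, empirical_p(similar, config.n_perm)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up over the retained variants (m = len)."""
    return adjust_pvalues(p_values, "benjamini_hochberg")


class ThresholdScan:
    """Model object: cohort-wide threshold-difference scan.

    Parameters
    ----------
    matrix : GenotypeMatrix
        Consensus genotypes after QC (codes 0/1/2, -1 missing).
    cohort : CohortAudiograms or sequence of Participant
    config : ScanConfig, optional
    """

    def __init__(self, matrix: GenotypeMatrix, cohort, config: ScanConfig | None = None) -> None:
        self.matrix = matrix
        if not isinstance(cohort, CohortAudiograms):
            cohort = CohortAudiograms.from_participants(cohort)
        self.cohort = cohort
        self.config = config or ScanConfig()

    def fit(self, seed: int = 0) -> "ThresholdScanResults":
        config = self.config
        stratum_code = {"all": 0, "M": 1, "F": 2}
        rows = []
        for v_idx, vid in enumerate(self.matrix.variants):
            row = self.matrix.codes.loc[vid]
            genotypes = {pid: int(g) for pid, g in row.items()
                         if g != MISSING and pid in self.cohort._index}
            for cand in variant_filter(vid, genotypes, self.cohort, config):
                rng = np.random.default_rng(
                    [seed, v_idx, stratum_code[cand.grouping.stratum]]
                )
                similar, p = permutation_test(cand, self.cohort, config, rng)
                sexes = [self.cohort.sex[self.cohort._index[c]]
                         for c in cand.grouping.carriers]
                rows.append(
                    {
                        "variant_id": vid,
                        "stratum": cand.grouping.stratum,
                        "n_carriers_m": sexes.count("M"),
                        "n_carriers_f": sexes.count("F"),
                        "direction": cand.direction,
                        "pass_freqs_L": ";".join(
                            str(f) for e, f in cand.pass_set if e == "L"),
                        "pass_freqs_R": ";".join(
                            str(f) for e, f in cand.pass_set if e == "R"),
                        "similar_count": similar,
                        "p": p,
                        "retained": similar <= config.reject_count,
                    }
                )
        candidates = pd.DataFrame(
            rows,
            columns=["variant_id", "stratum", "n_carriers_m", "n_carriers_f",
                     "direction", "pass_freqs_L", "pass_freqs_R",
                     "similar_count", "p", "retained"],
        )
        retained = candidates.loc[candidates["retained"].astype(bool)].copy()
        if not retained.empty:
            retained["p_adj"] = bh_adjust(retained["p"].to_numpy())
            retained = retained.sort_values(
                ["p_adj", "variant_id"]).reset_index(drop=True)
        else:
            retained["p_adj"] = pd.Series(dtype=float)
        return ThresholdScanResults(self, candidates, retained, seed)


class ThresholdScanResults:
    """Candidates, permutation counts and the BH-adjusted retained table."""

    def __init__(self, model: ThresholdScan, candidates: pd.DataFrame,
                 retained: pd.DataFrame, seed: int) -> None:
        self.model = model
        self.candidates = candidates
        self.frame = retained
        self.seed = seed

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Threshold-difference scan",
            "=" * 26,
            f"variants scanned:   {len(self.model.matrix.variants)}",
            f"candidate groupings:{len(self.candidates):5d}",
            f"retained:           {len(self.frame):5d}"
            f"  (rejection at > {cfg.reject_count} of {cfg.n_perm} shufflings)",
            f"seed: {self.seed}",
        ]
        for _, r in self.frame.iterrows():
            lines.append(
                f"  {r.variant_id:<24} {r.stratum:<4} {r.direction:<6} "
                f"similar={int(r.similar_count):5d}  p={r.p:.3g}  p_adj={r.p_adj:.3g}"
            )
        return "\n".join(lines)


def scan_cohort(matrix: GenotypeMatrix, cohort, config: ScanConfig | None = None,
                seed: int = 0) -> ThresholdScanResults:
    """Functional wrapper over :class:`ThresholdScan`."""
    return ThresholdScan(matrix, cohort, config).fit(seed)
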
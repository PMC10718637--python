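"""Validation experiments on synthetic cohorts.

Reusable parameter-recovery and error-control studies: they generate
cohorts with the synthetic module, run the corresponding analysis stage,
and score the result against the generator's truth table.  Problem sizes
default to the conditions the classifier and scan are expected to work
under (n = 500 participants, 3 dB audiogram noise, 30 dB planted shifts
in 8 carriers); permutation counts are reduced to 2,000 with the
rejection count scaled to keep the nominal alpha at 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .audiometry import AudiogramClassifier
from .synthetic import PlantedEffect, PlantedLoad, SimParams, generate_cohort, generate_genotypes
from .threshold_scan import ScanConfig, ThresholdScan
from .variant_load import default_plan, run_comparisons

__all__ = [
    "classification_recovery",
    "scan_power",
    "scan_null_retention",
    "planted_load_flagged",
    "load_null_outlier_rate",
]


def classification_recovery(n_participants: int = 500, noise_sd_db: float = 3.0,
                            seed: int = 0) -> float:
    """Fraction of planted phenotype classes recovered by the classifier."""
    params = SimParams(n_participants=n_participants, noise_sd_db=noise_sd_db,
                       seed=seed)
    participants, truth = generate_cohort(params)
    labels = AudiogramClassifier(participants).fit().labels
    expected = pd.Series({pid: t["class"] for pid, t in truth.items()}).replace(
        "UnclassifiedLike", "Unclassified")
    return float((labels == expected.loc[labels.index]).mean())


def _scan_config(n_perm: int) -> ScanConfig:
    return ScanConfig(n_perm=n_perm, reject_count=max(1, n_perm // 20))


def scan_power(
    n_seeds: int = 20,
    seed0: int = 0,
    shift_db: float = 30.0,
    n_carriers: int = 8,
    n_participants: int = 500,
    n_perm: int = 2000,
    alpha: float = 0.05,
) -> float:
    """Fraction of seeds in which a planted shift variant is retained
    with BH-adjusted p below ``alpha``."""
    hits = 0
    for s in range(n_seeds):
        params = SimParams(
            n_participants=n_participants, seed=seed0 + s, n_genes=2,
            planted_effects=[
                PlantedEffect("e", shift_db, (3.0, 4.0, 6.0, 8.0), n_carriers)],
        )
        participants, truth = generate_cohort(params)
        participants, matrix, _, tr = generate_genotypes(params, participants, truth)
        res = ThresholdScan(matrix, participants, _scan_config(n_perm)).fit(
            seed=seed0 + s)
        vid = tr["planted_effects"][0]["variant_id"]
        rows = res.frame[res.frame["variant_id"] == vid]
        if len(rows) and (rows["p_adj"] < alpha).any():
            hits += 1
    return hits / n_seeds


def scan_null_retention(
    n_seeds: int = 20,
    seed0: int = 0,
    n_variants: int = 200,
    n_participants: int = 500,
    n_perm: int = 2000,
) -> float:
    """Fraction of null variants (no planted effect) retained by the scan."""
    retained = 0
    total = 0
    for s in range(n_seeds):
        params = SimParams(n_participants=n_participants, seed=seed0 + s,
                           n_genes=n_variants, variants_per_gene_mean=1.0)
        participants, truth = generate_cohort(params)
        participants, matrix, _, _ = generate_genotypes(params, participants, truth)
        res = ThresholdScan(matrix, participants, _scan_config(n_perm)).fit(
            seed=seed0 + s)
        retained += res.frame["variant_id"].nunique()
        total += len(matrix.variants)
    return retained / total


def _label_frame(participants, truth) -> pd.DataFrame:
    labels = AudiogramClassifier(participants).fit().table[["label"]].copy()
    labels["sex"] = pd.Series({p.id: p.sex.value for p in participants})
    return labels


def planted_load_flagged(
    seed: int = 0,
    multiplier: float = 8.0,
    n_participants: int = 500,
    n_genes: int = 500,
    target_class: str = "Sensory",
) -> bool:
    """Whether a gene with a planted carrier-rate multiplier in one class
    appears in that class's high-load outlier list of the Older-Normal
    comparison."""
    gene = "GENE0010"
    params = SimParams(
        n_participants=n_participants, seed=seed, n_genes=n_genes,
        maf_range=(0.01, 0.05),
        planted_load=[PlantedLoad(gene, target_class, multiplier)],
    )
    participants, truth = generate_cohort(params)
    participants, matrix, ann, _ = generate_genotypes(params, participants, truth)
    labels = _label_frame(participants, truth)
    out = run_comparisons(
        labels, matrix, ann,
        plan=default_plan(strata=("all",)), min_group_size=20,
    )
    res = out["results"].get(f"OlderNormal_vs_{target_class}_all")
    return res is not None and gene in res.high_in_y


def load_null_outlier_rate(
    n_seeds: int = 20,
    seed0: int = 0,
    n_genes: int = 2000,
    n_participants: int = 500,
) -> float:
    """Fraction of (gene, comparison) pairs flagged as outliers on null data."""
    flagged = 0
    total = 0
    for s in range(n_seeds):
        params = SimParams(n_participants=n_participants, seed=seed0 + s,
                           n_genes=n_genes)
        participants, truth = generate_cohort(params)
        participants, matrix, ann, _ = generate_genotypes(params, participants, truth)
        labels = _label_frame(participants, truth)
        out = run_comparisons(labels, matrix, ann,
                              plan=default_plan(strata=("all",)),
                              min_group_size=20)
        for res in out["results"].values():
            flagged += len(res.high_in_y) + len(res.high_in_x)
            total += len(res.frame)
    return flagged / total if total else 0.0
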
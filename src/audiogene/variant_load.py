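"""Per-gene variant-load outlier regression and gene-set enrichment.

For two phenotype groups (for example Older-Normal hearing vs Metabolic
hearing loss), the total qualifying variant load per gene in one group
is regressed on the load in the other by ordinary least squares.  A gene
is called an outlier when its residual lies above Q3 + 6D or below
Q1 - 6D, where Q1/Q3 are the residual quartiles and D the interquartile
distance.  Because the expectation is set by the comparison group, a
large gene with many variants is not automatically an outlier, and a
small gene can be.  Outlier lists are then tested for over-representation
of curated gene sets (known deafness genes, highly variable genes) with
an upper-tail hypergeometric test, with Benjamini-Hochberg adjustment
across the tests of a cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .consensus import MISSING, GenotypeMatrix

__all__ = [
    "count_variants_per_gene",
    "VariantLoadModel",
    "VariantLoadResults",
    "regress_and_flag",
    "enrichment_test",
    "adjust_pvalues",
    "ComparisonPlan",
    "run_comparisons",
]

logger = logging.getLogger(__name__)


def count_variants_per_gene(
    matrix: GenotypeMatrix,
    annotations: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    mode: str = "allele",
) -> pd.DataFrame:
    """Total variant load per gene per participant group.

    ``annotations`` is indexed by variant_id with a ``gene_id`` column.
    In ``allele`` mode (default) a heterozygote contributes 1 and a
    homozygote 2 (homoplasmic mitochondrial calls are coded homozygous
    upstream, so they contribute 2); in ``carrier`` mode any non-reference
    genotype contributes 1.  Missing genotypes contribute 0.  Variants
    without a gene assignment are excluded with a warning.
    """
    if mode not in {"allele", "carrier"}:
        raise ValueError(f"unknown counting mode {mode!r}")
    codes = matrix.codes.to_numpy()
    dosage = np.where(codes == MISSING, 0, codes)
    if mode == "carrier":
        dosage = (dosage > 0).astype(int)

    gene_of = annotations["gene_id"].reindex(matrix.variants)
    unknown = gene_of.index[gene_of.isna()]
    if len(unknown):
        warnings.warn(
            f"{len(unknown)} variant(s) without a gene assignment excluded "
            f"from gene counts (first: {unknown[0]})")
    keep = ~gene_of.isna().to_numpy()
    if not keep.any():
        return pd.DataFrame(columns=list(groups))
    genes = gene_of.to_numpy()[keep]
    dosage = dosage[keep]

    col_index = {pid: j for j, pid in enumerate(matrix.participants)}
    out = {}
    for name, members in groups.items():
        cols = [col_index[m] for m in members if m in col_index]
        per_variant = dosage[:, cols].sum(axis=1) if cols else np.zeros(keep.sum(), dtype=int)
        out[name] = pd.Series(per_variant, index=genes).groupby(level=0).sum()
    table = pd.DataFrame(out).fillna(0).astype(int)
    table.index.name = "gene_id"
    return table


class VariantLoadModel:
    """OLS of per-gene variant load in group y on group x, with IQR-rule outliers.

    Parameters
    ----------
    counts_x, counts_y : pandas Series indexed by gene
        Variant loads in the predictor and response groups.
    multiplier : float
        Residuals beyond Q3 + multiplier*D or Q1 - multiplier*D are
        flagged (D = Q3 - Q1, quartiles by linear interpolation).
    """

    def __init__(
        self,
        counts_x: pd.Series,
        counts_y: pd.Series,
        multiplier: float = 6.0,
        name_x: str = "x",
        name_y: str = "y",
    ) -> None:
        if multiplier <= 0:
            raise ValueError("multiplier must be positive")
        common = counts_x.index.intersection(counts_y.index)
        if len(common) < 3:
            raise ValueError("insufficient data: need at least 3 genes")
        x = counts_x.loc[common].astype(float)
        if x.nunique() == 1:
            raise ValueError("degenerate regression: predictor counts are constant")
        self.x = x
        self.y = counts_y.loc[common].astype(float)
        self.multiplier = float(multiplier)
        self.name_x = name_x
        self.name_y = name_y

    def fit(self) -> "VariantLoadResults":
        X = sm.add_constant(self.x.to_numpy())
        ols = sm.OLS(self.y.to_numpy(), X).fit()
        intercept, slope = ols.params
        predicted = intercept + slope * self.x
        residuals = self.y - predicted
        q1, q3 = np.quantile(residuals.to_numpy(), [0.25, 0.75])
        d = q3 - q1
        hi = residuals > q3 + self.multiplier * d
        lo = residuals < q1 - self.multiplier * d
        frame = pd.DataFrame(
            {
                "observed_x": self.x,
                "observed_y": self.y,
                "residual": residuals,
                "direction": np.where(hi, "high_in_y", np.where(lo, "high_in_x", "")),
            }
        )
        return VariantLoadResults(self, float(slope), float(intercept),
                                  float(q1), float(q3), frame)


class VariantLoadResults:
    def __init__(
        self,
        model: VariantLoadModel,
        slope: float,
        intercept: float,
        q1: float,
        q3: float,
        frame: pd.DataFrame,
    ) -> None:
        self.model = model
        self.slope = slope
        self.intercept = intercept
        self.q1 = q1
        self.q3 = q3
        self.iqr = q3 - q1
        self.frame = frame

    @property
    def residuals(self) -> pd.Series:
        return self.frame["residual"]

    def outliers(self, direction: str | None = None) -> pd.DataFrame:
        out = self.frame[self.frame["direction"] != ""]
        if direction is not None:
            out = out[out["direction"] == direction]
        return out

    @property
    def high_in_y(self) -> list[str]:
        return list(self.outliers("high_in_y").index)

    @property
    def high_in_x(self) -> list[str]:
        return list(self.outliers("high_in_x").index)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Variant load regression: {m.name_y} ~ {m.name_x}",
            f"  genes: {len(self.frame)}",
            f"  slope: {self.slope:.4f}  intercept: {self.intercept:.4f}",
            f"  residual Q1/Q3: {self.q1:.3f} / {self.q3:.3f}  (D = {self.iqr:.3f})",
            f"  outliers high in {m.name_y}: {len(self.high_in_y)}",
            f"  outliers high in {m.name_x}: {len(self.high_in_x)}",
        ]
        return "\n".join(lines)


def regress_and_flag(
    counts_x: pd.Series,
    counts_y: pd.Series,
    multiplier: float = 6.0,
    name_x: str = "x",
    name_y: str = "y",
) -> VariantLoadResults:
    """Functional wrapper around :class:`VariantLoadModel`."""
    return VariantLoadModel(counts_x, counts_y, multiplier, name_x, name_y).fit()


def enrichment_test(
    outlier_list: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> dict:
    """Upper-tail hypergeometric over-representation test.

    Draws ``len(outlier_list)`` genes from the universe containing
    ``|gene_set ∩ universe|`` successes; p = P(X >= observed overlap).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("undefined test: empty universe")
    outliers = set(outlier_list)
    if not outliers <= universe:
        raise ValueError("outlier list must be a subset of the universe")
    in_univ = set(gene_set) & universe
    overlap = len(outliers & in_univ)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(in_univ), len(outliers)))
    return {
        "universe_size": len(universe),
        "set_in_universe": len(in_univ),
        "list_size": len(outliers),
        "overlap": overlap,
        "p": min(p, 1.0),
    }


def adjust_pvalues(p_list: Sequence[float], method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing adjustment (BH step-up, Bonferroni, or none)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    key = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]


@dataclass(frozen=True)
class ComparisonPlan:
    """One variant-load comparison: predictor group vs response group.

    ``group_x`` / ``group_y`` are phenotype label values; ``group_y`` may
    be the pseudo-label ``"AllHL"`` meaning everyone not in ``group_x``
    (including Unclassified and Unselected participants).  ``stratum``
    restricts both groups to one sex ('all', 'M' or 'F').
    """

    name: str
    group_x: str
    group_y: str
    stratum: str = "all"


DEFAULT_COMPARISONS = [
    ("OlderNormal", "AllHL"),
    ("OlderNormal", "Metabolic"),
    ("OlderNormal", "Sensory"),
    ("Metabolic", "Sensory"),
]


def default_plan(strata: Sequence[str] = ("all", "M", "F")) -> list[ComparisonPlan]:
    plans = []
    for gx, gy in DEFAULT_COMPARISONS:
        for s in strata:
            plans.append(ComparisonPlan(f"{gx}_vs_{gy}_{s}", gx, gy, s))
    return plans


def _group_members(
    labels: pd.DataFrame, group: str, other: str, stratum: str
) -> list[str]:
    sel = labels
    if stratum != "all":
        sel = sel[sel["sex"] == stratum]
    if group == "AllHL":
        return list(sel.index[sel["label"] != other])
    return list(sel.index[sel["label"] == group])


def run_comparisons(
    labels: pd.DataFrame,
    matrix: GenotypeMatrix,
    annotations: pd.DataFrame,
    plan: Sequence[ComparisonPlan] | None = None,
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    multiplier: float = 6.0,
    min_group_size: int = 20,
    mode: str = "allele",
    adjust_method: str = "benjamini_hochberg",
) -> dict:
    """Run a set of variant-load comparisons with gene-set enrichment.

    ``labels`` is indexed by participant_id with columns ``label`` and
    ``sex``.  Comparisons whose smaller group falls below
    ``min_group_size`` are skipped with a warning (small strata cannot
    support the regression).  Returns a dict with per-comparison results,
    an enrichment table (BH-adjusted across all tests run), the combined
    deduplicated candidate list with per-comparison provenance, and the
    names of skipped comparisons.
    """
    plan = list(plan) if plan is not None else default_plan()
    unknown = {c.group_x for c in plan} | {c.group_y for c in plan}
    valid = set(labels["label"].unique()) | {"AllHL", "OlderNormal", "Metabolic",
                                            "Sensory", "Unclassified", "Unselected"}
    if not unknown <= valid:
        raise ValueError(f"unknown labels in comparison plan: {unknown - valid}")

    results: dict[str, VariantLoadResults] = {}
    skipped: list[str] = []
    provenance: dict[str, list[str]] = {}
    enrich_rows = []

    for comp in plan:
        members_x = _group_members(labels, comp.group_x, comp.group_y, comp.stratum)
        members_y = _group_members(labels, comp.group_y, comp.group_x, comp.stratum)
        if min(len(members_x), len(members_y)) < min_group_size:
            logger.warning(
                "skipping %s: group sizes %d vs %d below minimum %d",
                comp.name, len(members_x), len(members_y), min_group_size,
            )
            skipped.append(comp.name)
            continue
        counts = count_variants_per_gene(
            matrix, annotations, {"x": members_x, "y": members_y}, mode=mode
        )
        res = regress_and_flag(counts["x"], counts["y"], multiplier,
                               name_x=comp.group_x, name_y=comp.group_y)
        results[comp.name] = res
        universe = list(counts.index)
        for direction, gene_list in (("high_in_y", res.high_in_y),
                                     ("high_in_x", res.high_in_x)):
            for gene in gene_list:
                provenance.setdefault(gene, []).append(f"{comp.name}:{direction}")
            if gene_sets:
                for set_id, genes in gene_sets.items():
                    row = enrichment_test(gene_list, genes, universe)
                    row.update(
                        {"comparison": comp.name, "direction": direction,
                         "gene_set_id": set_id}
                    )
                    enrich_rows.append(row)

    enrichment = pd.DataFrame(enrich_rows)
    if not enrichment.empty:
        enrichment["p_adj"] = adjust_pvalues(enrichment["p"].to_numpy(), adjust_method)

    combined = pd.DataFrame(
        {
            "gene_id": list(provenance),
            "comparisons": [";".join(v) for v in provenance.values()],
            "n_comparisons": [len(v) for v in provenance.values()],
        }
    ).set_index("gene_id") if provenance else pd.DataFrame(
        columns=["comparisons", "n_comparisons"]
    )

    return {
        "results": results,
        "enrichment": enrichment,
        "combined_candidates": combined,
        "skipped": skipped,
    }
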
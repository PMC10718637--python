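# Methods

This note records the models behind `audiogene`, the parameters that
matter, the numerical choices that had to be pinned down, and what the
synthetic-data experiments do and do not demonstrate.

## Audiogram decomposition and classification

Age-related hearing loss is modelled as a mixture of two cochlear
pathologies with distinct audiometric signatures.  *Metabolic* (strial)
loss — degeneration of the cochlear lateral wall — produces mildly
elevated thresholds at low frequencies sloping gently downwards towards
high frequencies.  *Sensory* loss — lesions of the organ of Corti or
its neural components — leaves low frequencies near normal with a steep
high-frequency slope.  An ear's audiogram is fitted as

y(f) = m·P_met(f) + s·P_sen(f) + ε(f),  m, s ≥ 0,

by non-negative least squares (scipy's active-set NNLS).  The profiles
are unit-peak normalised, so the coefficients are in dB and represent
each component's contribution at its worst frequency — commensurate
with the 15–25 dB rule thresholds below.  The **line-fit error** is the
RMS residual in dB over the ear's frequencies.  No intercept is fitted:
a free intercept would absorb metabolic-like flat loss into a
nuisance term.

**The profile shapes are stand-ins.**  Published typical profiles exist
(estimated from 402 older-adult audiograms) but their numeric values
are not reproduced here; the defaults
(metabolic `0.70…1.00` rising gently over 0.25–8 kHz, sensory
`0.00…1.00` rising steeply above 2 kHz) follow the verbal description
of the two configurations.  Any real study should supply its own
profiles via `ProfileBasis`; everything downstream is agnostic to the
exact shapes.  Profiles are resampled to an audiogram's frequency grid
by interpolation linear in log2(frequency), clamped at the grid edges
(relevant for cohorts recording 0.125 kHz).

Classification applies four rules strictly in sequence, on the fits of
the two ears restricted to their common frequency set:

1. **Unselected** — line-fit error ≥ 15 dB in *either* ear (a pair is
   unusable if one ear is atypical, e.g. a corner audiogram);
2. **Older-Normal** — mean(m) + mean(s) < 20 dB, and each component's
   left–right difference < 10 dB;
3. **Metabolic** — mean(m) ≥ 20, |m_L − m_R| ≤ 15, mean(s) < 20,
   mean(m) > mean(s);
4. **Sensory** — mean(s) ≥ 15, |s_L − s_R| ≤ 20, mean(m) < 25,
   mean(s) > mean(m);
5. otherwise **Unclassified**.

Where the published wording does not say whether magnitude criteria
apply per-ear, to the worse ear, or to the mean, this package uses the
across-ear mean for magnitudes and the absolute left–right difference
of each component for asymmetries — the most conservative symmetric
reading; every threshold is a field of `ClassificationRules`.
Manual by-eye additions and removals performed in the original study
are deliberately not reproduced: classification here is purely
rule-based.

## Consensus genotypes and QC

The caller-combination gate keeps a site iff it is in the top VQSR
tranche and passed BCFtools or Freebayes, or in the second tranche and
passed BCFtools.  Genotype consensus is a majority vote over the
(≤ 3) per-caller calls; the full three-way split hom-ref/het/hom-alt
resolves to het; everything else — including sites called by a single
caller and 1-vs-1 splits — is missing.

**Excess heterozygosity.**  Mismapped paralogous sites show more
heterozygotes than Hardy-Weinberg allows.  The test is the exact
conditional (Levene–Haldane) distribution of the heterozygote count
given the allele counts, summed one-sided over configurations with at
least the observed heterozygote count; it is computed in log space via
`gammaln`.  This is hand-written because no installed library exposes a
one-sided heterozygote-excess exact test; the test suite checks it
against exact-integer enumeration for every genotype table with total
≤ 30.  The significance level is not a published value; the default is
1e-6, a common exome-QC choice, and is configurable.

**Cohort allele frequency.**  Sites with cohort AF > reference MAF
+ 0.4 are removed (aligner miscalls in low-complexity regions).  Cohort
AF is alternate-dosage / (2 × non-missing) for nuclear sites and
carriers / non-missing for mitochondrial sites.  Variants absent from
the reference MAF source are treated as novel (MAF 0) for both this cap
and the final filter — novel variants are overwhelmingly rare — and
this default is configurable.

**Mitochondrial genotyping.**  Calls need > 30× depth; VAF > 0.95 is
homoplasmic and coded homozygous (dosage 2), VAF in [0.40, 0.95] is
heteroplasmic and coded heterozygous, anything else is missing.  The
40% heteroplasmy floor and 30× depth floor reflect the reliability
limits of off-target mitochondrial reads in exome data.  Participants
with no reported mitochondrial call at a surviving site are coded
homoplasmic reference.

**Final filter** keeps high-impact variants with reference MAF
strictly below 0.1.  Impact classification is consumed as a
precomputed annotation column, never re-derived.

The funnel order is fixed (gate → merge → excess-het → AF cap →
impact/MAF) and every stage's retention count is reported, so a cohort
run exposes its own filtering funnel.

## Variant-load outlier regression

For a comparison (e.g. Older-Normal vs Metabolic), per-gene loads are
the sum of genotype dosages over a group's members — het = 1,
hom = 2 by default ("allele" mode), since homoplasmic mitochondrial
calls are explicitly treated as homozygotes; a "carrier" mode
(any non-ref = 1) is provided because "number of variants" can also be
read as presence counts.  Counts are not normalised by group size: the
regression slope absorbs the size ratio.

The OLS fit (statsmodels) predicts the second group's load from the
first; residual quartiles use linear interpolation between order
statistics (the common default — the convention had to be pinned for
reproducibility and is configurable), and genes beyond Q3 + 6·D /
Q1 − 6·D are flagged.  With the multiplier at 6 this is a deliberately
extreme fence: on normal-ish residuals it sits at ≈ 9 SD, so null data
produce essentially no outliers (measured below).

Enrichment of an outlier list in a curated gene set is the upper-tail
hypergeometric probability, with the universe defined as all genes with
at least one variant call in the cohort and gene sets intersected with
that universe first.  Adjustment across a cohort's tests defaults to
Benjamini-Hochberg (configurable to Bonferroni or none; the adjustment
used for the original study's enrichment table is not stated, so no
numeric equivalence is claimed there).  Comparisons whose smaller group
falls below 20 participants are skipped with a warning, mirroring the
fact that a 12-member stratum cannot support the regression.

## Threshold-difference scan

Carriers (het + hom-alt pooled) are compared with the
homozygous-reference group, overall and within each sex with
sex-matched references.  A grouping must have ≥ 5 carriers; a variant
is dropped only when every grouping is too small.  A frequency passes
when |carrier mean − reference mean| ≥ 20 dB and the carrier SD is at
most the band cap — 15 dB for f ≤ 0.5 kHz, 20 for 0.5 < f ≤ 2, 25 for
2 < f ≤ 4, 30 above 4 kHz (half-open bands so every standard frequency
maps to exactly one cap).  A candidate needs ≥ 2 passing frequencies in
each ear, all in one direction, which gives it a single Better/Worse
label.

The permutation null redraws carrier-sized pseudo-groups without
replacement from carriers ∪ reference, within sex, preserving the
carrier group's sex composition even in the combined stratum.  A
shuffling is *similar* when every (ear, frequency) in the observed
passing set meets the magnitude and SD criteria under the permuted
labels.  Two conventions here were genuinely open and are configurable:

- similarity is magnitude-only by default (a permuted replicate need
  not match the observed direction), since the original description
  names only "the relevant stimulus frequencies tested using the same
  settings";
- the similarity predicate is the observed pass-set, not a fresh
  ≥ 2-per-ear search over those frequencies (`perm_pass_mode`
  switches to the latter).

The empirical p is `similar_count / n_perm` — not the (c+1)/(n+1)
variant — pinned by the published arithmetic (38/20,000 = 1.90×10⁻³).
Variants with more than `reject_count` similar shufflings are rejected
(1,000 of 20,000, nominal α = 0.05; scale both together when reducing
`n_perm`).  BH adjustment runs over the retained variants only, with m
equal to the number retained — statistically unusual (the rejected
variants' tests are silently discarded) but faithful to the procedure
being reimplemented.  Missing thresholds exclude a participant from
that frequency only; a frequency with < 2 carrier observations is
unevaluable.  Permutations are vectorised in chunks (means and SDs from
running sums), and each (variant, stratum) pair derives its own RNG
stream from (seed, variant index, stratum), so results are bit-identical
for a given seed and independent of evaluation order.

## Synthetic cohorts

The generator emulates exactly the structure the analyses assume.  Each
participant draws a class from the mixture (defaults 19% Older-Normal,
29% Metabolic, 29% Sensory, 23% atypical — the classified proportions
of a ~500-person older-adult cohort), then component magnitudes from
per-class uniform ranges placed well inside the rule regions
(Older-Normal M,S ∈ [2,7]; Metabolic M ∈ [30,50], S ∈ [2,12]; Sensory
mirrored; atypical M,S ∈ [30,45] so both the Metabolic and Sensory
rules fail on the opposing component).  Thresholds are
m·P_met + s·P_sen + N(0, 3 dB) per ear and frequency, clipped to
[−10, 120].  The atypical class plays the role of Unclassified;
"Unselected" audiogram shapes (high line-fit error) are not generated
because they are defined by departure from the very model the generator
uses.

Genotypes are Hardy-Weinberg draws at per-variant MAFs uniform on
(0.001, 0.1).  Planted load genes multiply the het/hom probabilities in
a target class (capped); a multiplier of 1 is bit-identical to the null
because the same uniform draws decide genotypes either way.  Planted
effect variants assign an exact number of heterozygous carriers
(optionally sex-restricted) and add the shift to those carriers'
already-generated thresholds at the affected frequencies in both ears —
applied additively so planted effects are orthogonal to class
structure, which isolates precisely what the scan should detect; exact
counts rather than MAF draws because the ≥ 5-carrier gate makes power
sensitive to the realised count.  All draws come from
integer-indexed RNG streams ((seed, kind, index)), so output is
deterministic and order-independent.

**What passing tests show — and don't.**  Recovery and error-control
results on these cohorts validate the machinery under the model's own
assumptions: no linkage disequilibrium, no relatedness, no population
stratification, no age–threshold drift, noise independent across
frequencies, and class-conditional component distributions that are
cleanly separated.  Real audiometric and exome data violate several of
these; the experiments bound algorithmic error, not real-world
operating characteristics.

## Validation experiments (`audiogene.experiments`)

Problem sizes were chosen to exercise the full pipeline at realistic
cohort scale while keeping each experiment to seconds: n = 500
participants throughout; 20 replicate seeds; permutation tests at
n_perm = 2,000 with the rejection count scaled to 100 (α still 0.05);
200 variants for scan error control and 2,000 genes for load error
control.  Measured behaviour (reported by `scripts/acceptance.py`, seed
1): planted-class recovery 100% at 3 dB noise; a planted 8× load gene
is flagged in the correct outlier list; power to retain a planted
30 dB / 8-carrier variant ≈ 85–95% across seed batches; null scan
retention ≈ 0.3% of variants; null load outliers ≈ 0% of gene-
comparison pairs.

## Known limitations

- The component profiles are stand-ins; absolute m/s estimates (and
  hence classification boundaries) shift with the true profiles.
- The scan tests no covariates (age, noise history) and assumes
  exchangeability of participants within sex under the null.
- BH over retained-only variants does not control FDR over the full
  scanned set.
- The per-caller quality gate consumes caller outputs; it cannot detect
  errors the callers agree on.
- Enrichment p-values depend on the variant-calling universe, so they
  are not comparable across cohorts with different capture designs.
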
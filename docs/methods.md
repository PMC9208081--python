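# Methods

## Overview

`organoscore` quantifies in-vitro drug responses of patient-derived organoids
(PDOs) and relates them to clinical outcome through an *organoid score*. The
chain of quantities is:

1. **Viability fraction** — each well signal is divided by the mean of the
   vehicle-control wells of its plate group, so vehicle viability is exactly 1.
2. **AUC** — per organoid × drug, the trapezoidal area under mean viability
   versus log10 concentration over the measured dose grid. Dividing by the
   log10 span gives `auc_span` ∈ [0, top], a unitless resistance summary that
   exists even when a parametric fit fails. Higher AUC = more resistant.
3. **Normalized AUC** — `auc_span` divided by the cohort maximum for that
   drug, so the most resistant organoid per drug has `auc_norm` = 1.
4. **Drug score** — the cohort's `auc_norm` values for one drug are cut at
   their quartiles; scores 1 (most sensitive) through 4 (most resistant).
5. **Organoid score** — for a patient who received drugs
   d₁ … d_n from the screened panel, the arithmetic mean of the corresponding
   drug scores: score = (Σᵢ sᵢ)/n ∈ [1, 4]. A score ≥ 2.5 defines the
   high-risk class.
6. **Association** — Spearman rank correlation of organoid score against %
   tumor-size change (RECIST-like) on the palliative subset, and
   Kaplan–Meier / log-rank / Mantel–Haenszel hazard-ratio comparison of
   progression-free survival (PFS) between risk classes.

## Dose–response model

Viability is modelled with the four-parameter logistic (4PL) on log10 dose:

    V(c) = bottom + (top − bottom) / (1 + (c / IC50)^hill)

fitted by bounded least squares (`scipy.optimize.curve_fit`), with top ∈
[0.5, 1.5], bottom ∈ [0, 1], hill ∈ [0.1, 10] and IC50 within two decades of
the tested range. The IC50 parameter is fitted on the log10 scale for
numerical stability; starting values come from the data extremes and the
half-maximal crossing.

**Censoring rule.** When the fitted curve never drops below 0.5 within the
tested range, the IC50 is reported as right-censored at the top dose with a
flag, instead of an extrapolated value. Extrapolated IC50s from flat curves
can reach absurd magnitudes that are pure fit artifacts; ranks — which the
scoring uses — are preserved by treating censored values as maximal.

**AUC from measured points.** The AUC integrates the measured per-dose means,
not the fitted curve (viability clipped at 0 first). This makes the score
independent of fit convergence. A fitted-curve mode
(`compute_auc_from_fit`) is available for comparison, but the pipeline
default is the measured-grid trapezoid; on the standard 6-point grid the two
differ only through fit error.

## Quartile convention

Cut-points Q1–Q3 are linear-interpolation quantiles (`numpy.quantile`
default) of the per-drug `auc_norm` vector; a value ≤ Q1 scores 1, ≤ Q2
scores 2, ≤ Q3 scores 3, else 4. This convention is deterministic, assigns
tied values identical scores, and on distinct values yields group sizes
differing by at most one. The probability levels are exposed
(`QuartileDrugScorer(quantiles=...)`) because other quantile conventions can
move boundary organoids by one group. Drug scores are always assigned on the
full cohort before any patient-level exclusion.

## Regimen mapping

Clinical regimen strings resolve through an editable alias table: FOLFOX →
{5-FU, oxaliplatin}; FOLFIRI → {5-FU, SN38} (irinotecan is scored via its
active metabolite SN38, the screened compound); "+ Cetuximab" adds
cetuximab. Bevacizumab is excluded with reason "not evaluable in organoids"
(its anti-angiogenic action has no counterpart in epithelial-only cultures);
any other unmapped component is excluded as "no screened counterpart"
(capecitabine is deliberately not aliased to 5-FU by default; the alias
table accepts such an override). A regimen with zero scoreable components is
flagged not-scoreable rather than raising.

## Statistics

All tests are two-sided.

- **Spearman** — average-rank rho; exact permutation p (full n! enumeration,
  vectorized) for n ≤ 9, t-approximation otherwise; the method used is
  reported with the result.
- **Kaplan–Meier** — product-limit estimator via `lifelines`; censored
  subjects leave the risk set after their time.
- **Log-rank** — two-group statistic with hypergeometric variance at each
  pooled event time; p from χ² with 1 df, no continuity correction. The χ²
  and p agree with `lifelines.statistics.logrank_test` to 1e-6 (tested).
  Note that at very small samples (≈ 12 subjects) the χ² approximation
  deviates from the exact permutation distribution of the statistic by a few
  hundredths in p — an intrinsic property of the asymptotic test, documented
  here because the package targets cohorts of tens of patients.
- **Mantel–Haenszel HR** — HR = exp((O₁ − E₁)/V) from the log-rank O/E/V,
  with 95% CI exp((O₁ − E₁ ± 1.96 √V)/V); group 1 = high risk, so HR > 1
  means faster progression in the high-score class. The alternative Pike
  estimate (O₁/E₁)/(O₂/E₂) is available via `method="pike"`. This score-based
  estimator is mildly conservative for large true hazard ratios.
- **Mann–Whitney / Kruskal–Wallis** — delegated to scipy; exact Mann-Whitney
  enumeration when n ≤ 16 without ties, tie-corrected normal approximation
  otherwise.

**Exclusion logic** is data-driven: the clinical table carries boolean flag
columns (best supportive care, low organoid–tissue concordance,
post-treatment sample, loss to follow-up) and a `setting` column
(palliative/adjuvant); `associate_cohort` filters on them and never
hard-codes patient ids.

## Genomics

Variant calls are consumed from VCF (via cyvcf2) with effect annotations
from INFO fields or a sidecar table — no annotator is reimplemented. Keys
are normalized (chr prefix stripped, indels left-aligned and parsimonious)
so caller dialects agree. Organoid–tissue concordance is
100·|shared|/|union| by default — symmetric, with SNV/indel breakdown — and
the shared / organoid-only / tissue-only counts are reported alongside; a
tissue-denominator mode (`denominator="tissue"`, the fraction of tissue
calls recovered in the organoid) is available since published definitions of
"concordance" vary.
Mutation burden is calls per callable megabase (callable size is a
parameter, default 40 Mb — a typical exome callable territory);
hypermutation requires strictly more than 10 mutations per Mb. Genotype
flags: anti-EGFR resistance (KRAS/NRAS codons 12/13/61 missense, BRAF V600E,
PIK3CA E545K/H1047R), RNF43 loss of function (frameshift, nonsense or
homozygous deletion — predictive of porcupine-inhibitor sensitivity), APC
truncation. Evidence (gene, protein change, VAF) rides along so ambiguous
cases — e.g. a high-VAF RNF43 frameshift next to a low-VAF APC point
mutation — are reported for review, never auto-adjudicated.

## Repurposing screen

Duplicate library screens are compared per organoid by Pearson r across
drugs (affine-invariant, so plate-scale differences between replicates do
not matter). Mean AUC is standardized per drug across organoids (sample sd,
n − 1): negative z = relatively sensitive. The per-drug axis is used because
the question is "which organoids respond unusually well to this drug";
standardizing per organoid would instead rank drugs within an organoid's
overall sensitivity level. Within-target-class agreement — the mean pairwise
Pearson r of member drugs' z-vectors, with a label-permutation null (≥ 10³
reassignments of equal-sized label sets over the drug panel, +1-corrected
one-sided p) — is this package's formalization of the qualitative
observation that same-target drugs respond alike; it is added machinery, not
a standard assay statistic. Candidate ranking sorts by ascending z with ties
broken by ascending |AUC| then drug name (a deterministic total order).

## Synthetic cohort generator

No public patient-level dataset accompanies this analysis, so every stage is
exercised against a generative model with known ground truth.

**Latent resistance.** ρ[o,d] = clip(w·u[o] + (1 − w)·v[o,d] + shifts, 0, 1)
with u, v ~ Beta(1.5, 1.5) and organoid weight w = 0.7. The Beta mixture
yields a continuous, non-dichotomous spread of IC50s across the cohort — the
qualitative picture such screens show — with a dominant organoid-level
resistance factor plus drug-specific variation. log10 IC50[o,d] = lo_d +
ρ·(hi_d − lo_d) maps resistance onto per-drug ranges (defaults, log10 µM:
5-FU [−1, 1], oxaliplatin [0, 1.7], SN38 [−3, −1], cetuximab [−1, 2] —
spanning sensitive-to-resistant at the plausible potency scale of each
agent).

**Assay.** 6-point, 10-fold serial dilution from 10 µM, 3 replicates, with 2
vehicle wells per organoid × drug × replicate; true viability follows the
4PL with top 1, bottom 0.1, hill 1; observed signal = plate scale × true
viability × (1 + N(0, cv)) floored at 0, cv = 0.10 (typical for ATP-based
3D viability assays; the protocol itself states no noise figure). Plate
scale is a per-organoid lognormal-like factor so raw signals, not fractions,
are stored.

**Genotype coupling.** Anti-EGFR hotspot genotype (probability 0.4) adds
+0.4 to cetuximab ρ; RNF43 LoF (probability 0.1 in the cohort, 0.2 in the
refractory screen sub-cohort) adds −0.4 to the porcupine-inhibitor analog's
ρ. In the screen generator, same-target drugs share a latent class factor
(weight 0.8 within the drug-specific component) so shared-target agreement
is recoverable above noise.

**Clinical outcomes.** Tumor-size change (palliative patients only) =
−60 + 80·mean(ρ over regimen drugs) + N(0, 10) percent. PFS is exponential
proportional hazards on the latent score s = 1 + 3·mean(ρ) (the
organoid-score scale): hazard = λ₀·exp(β·s) with λ₀ = 6×10⁻⁴/day and
β = ln 2 per score unit, censored Uniform(200, 800) days. λ₀ gives a median
PFS ≈ 200 days at score 2.5 and ~80% observed events — the simplest
proportional-hazards setting in which the 2.5-cutoff KM comparison has a
recoverable signal at n ≈ 40. The "per unit latent score" parametrization is
used (rather than per unit mean ρ) precisely so the default log-HR of ln 2
produces a clinically meaningful group separation at the 2.5 cutoff.

**Cohort composition.** 54 organoids; 10 best-supportive-care patients, 2
low-concordance, 1 post-treatment sample, 1 lost to follow-up → 40 evaluable
patients, of whom 13 are palliative with measurable tumor-size change.
Cetuximab-containing regimens are assigned only to hotspot-wild-type
patients, as in practice.

**What the generator does not emulate:** plate-position/edge effects, drug
interactions within combination regimens (regimen response is the mean of
single-agent latent resistances), non-proportional hazards, informative
censoring, multi-line therapy sequencing, intra-tumor heterogeneity, and
measurement error in RECIST reads beyond additive Gaussian noise. Passing
tests therefore demonstrate that the analysis recovers effects under a
well-specified generative model of this shape — not that real screens are
free of these complications.

## Problem sizes and numerical choices

Simulation-backed checks use: 100 curves for IC50 recovery (median
|Δlog10 IC50| as the error metric, censored fits excluded), 200 null cohorts
for calibration of the Spearman and log-rank tests, 100 cohorts for effect
recovery, 100 replications of a 200-per-group exponential experiment for
hazard-ratio recovery, and a 10-organoid × 16-drug duplicate screen. These
sizes put Monte-Carlo error comfortably below the effect sizes being checked
while keeping a full run around a minute on one CPU. Ties in quartile
cut-points resolve to the lower group; ties at the cohort AUC maximum all
normalize to 1; the candidate-ranking tie-break is ascending |AUC| then drug
name. Degenerate inputs (all-censored KM, zero-variance correlation inputs,
empty genotype groups, regimens with no scoreable component) raise typed
errors or are flagged, as documented per function.

## Known limitations

- The quartile convention at boundaries is one of several defensible
  choices; boundary organoids can shift one group under rank-based fourths.
- The Mantel–Haenszel (score-based) HR is conservative for large effects;
  for HR ≫ 3 the Pike variant or a parametric model estimates closer.
- Concordance uses the union denominator; against a tissue-denominator
  definition the same data read ~lower when organoid-only calls dominate.
- Combination-regimen viability is not modelled (no Bliss/Loewe synergy);
  the score treats components independently by construction.
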
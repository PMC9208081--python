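# organoscore

Analysis toolkit for patient-derived organoid (PDO) drug screens in
colorectal cancer: from raw plate viability to per-drug quartile scores, a
regimen-matched **organoid score**, and its association with clinical
outcome — plus genotype annotation, organoid–tissue variant concordance and
FDA-library repurposing-screen analysis. It is written for translational
groups who screen tumor organoids against standard-of-care drugs and want a
reproducible, testable path from luminescence counts to "did the dish
predict the patient".

## The score

For each of the screened drugs (5-FU, oxaliplatin, SN38 — irinotecan's
active metabolite — and cetuximab), the area under the viability-vs-log10
concentration curve (AUC) is normalized by the cohort maximum for that drug,
the cohort is cut at its AUC quartiles, and each organoid gets a drug score
s ∈ {1, 2, 3, 4} (1 = most sensitive quartile). For a patient who received
drugs d₁ … d_n from the screened panel,

    organoid score = (s_{d₁} + … + s_{d_n}) / n  ∈ [1, 4],

where n counts only scoreable regimen components (FOLFOX contributes 5-FU
and oxaliplatin; bevacizumab is excluded as not evaluable in organoids).
A score ≥ 2.5 defines the high-risk class. The package then computes
Spearman correlation of score against % tumor-size change, and
Kaplan–Meier / log-rank / Mantel–Haenszel hazard-ratio comparisons of
progression-free survival between risk classes.

Because the matched patient data such analyses run on are not publicly
distributable, the package ships a synthetic-cohort generator
(`organoscore.simulate`) with the same statistical structure — latent
per-organoid drug resistance driving viability curves, genotype shifts
(anti-EGFR hotspots → cetuximab resistance, RNF43 loss of function →
porcupine-inhibitor sensitivity), and outcomes linked to resistance through
a linear tumor-size model and exponential proportional hazards. Every
pipeline stage is tested against this ground truth; see `docs/methods.md`.

## Worked example

```python
import organoscore as osc
from organoscore.io import fit_stage, score_stage, associate_stage

cohort = osc.simulate_cohort(seed=1)            # 54 organoids, 4 drugs
curves = fit_stage(cohort.viability, fit_ic50=False)
profiles = score_stage(curves, cohort.clinical)
print(profiles[["organoid", "organoid_score", "risk_class",
                "regimen"]].head(5).to_string(index=False))
report = associate_stage(profiles, cohort.clinical)
sp, hr = report.spearman, report.hr_overall
print(f"Spearman rho = {sp.rho:.3f} (p = {sp.p:.4f}, n = {sp.n})")
print(f"overall HR (high vs low) = {hr.hr:.2f} "
      f"[{hr.ci_low:.2f}, {hr.ci_high:.2f}], n = {report.n_overall}")
```

prints

```
organoid  organoid_score risk_class               regimen
 ORG-001             NaN             Best supportive care
 ORG-002        2.000000        low               FOLFIRI
 ORG-003             NaN             Best supportive care
 ORG-004        3.333333       high   FOLFIRI + Cetuximab
 ORG-005        4.000000       high FOLFIRI + Bevacizumab
Spearman rho = 0.624 (p = 0.0226, n = 13)
overall HR (high vs low) = 1.47 [0.68, 3.21], n = 40
```

ORG-001 received best supportive care only, so no regimen component is
scoreable and it is excluded from the clinical comparison. ORG-004's
FOLFIRI + cetuximab regimen scores three drugs (5-FU, SN38, cetuximab); its
mean drug score of 3.33 puts it in the high-risk class. Across the 13
palliative patients the organoid score correlates positively with tumor-size
change (higher score → less regression), and the 40 evaluable patients split
into risk classes whose hazard ratio exceeds 1 — on this seed the effect
sizes match the generator's defaults in direction, with CIs wide at n = 40.

The same pipeline runs from the shell:

```bash
organoscore simulate --seed 1 --out run/
organoscore fit --viability run/viability.csv --out run/curves.csv
organoscore score --curves run/curves.csv --clinical run/clinical.csv --out run/profiles.csv
organoscore associate --profiles run/profiles.csv --clinical run/clinical.csv --out run/assoc/
```

plus `flags` / `concordance` (VCF genotype utilities), `screen`
(repurposing-screen analysis) and `run` (end-to-end with a JSON manifest).

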
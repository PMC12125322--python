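# cmslike

Immunohistochemistry-based surrogate subtyping of colorectal cancer into
the four consensus-molecular-subtype-resembling (CMS-like) groups, with
the quantification, validation, association and survival machinery that
goes with it.

Transcriptomic CMS calling (CMS1 immune / CMS2 canonical / CMS3
metabolic / CMS4 mesenchymal) is too costly for routine pathology.  A
practical surrogate works from stained tissue-microarray (TMA) spots:

1. **MMR gate** — tumors deficient in DNA mismatch repair
   (loss of MLH1/MSH2/PMS2/MSH6) are called **CMS1-like**.
2. **Five-marker spot classifier** — each of up to four 1-mm TMA spots
   is scored for CDX2, FRMD6, HTR2B, ZEB1 and cytokeratin (KER); a
   logistic model over the panel, with ZEB1 entered as a presence
   indicator (≥ 2 % cutoff), gives the spot's probability of being
   epithelial.  The majority vote over spots separates **CMS2/3-like**
   (epithelial) from **CMS4-like** (mesenchymal); an exact tie is
   inconclusive.
3. **β-catenin split** — CMS2/3-like tumors with a positive nuclear
   β-catenin consensus (score ≥ 2 in intensity 0–3 *or* percentage
   category 0–4, majority over spots) are **CMS2-like**, otherwise
   **CMS3-like**.

Spot scores come from classical image quantification: Beer–Lambert
separation of hematoxylin and DAB optical densities, threshold +
morphology segmentation of the epithelium, mean positive-pixel DAB
density calibrated to the 0–3 intensity scale (rounded by the scoring
convention 0–0.499 → 0, 0.5–1.499 → 1, …), and percent of the
compartment above a positivity threshold.

Around the classifier the package implements:

* a **synthetic-data module** generating cohorts (latent subtypes,
  marker panels with epithelial/mesenchymal directionality, β-catenin
  scores, clinicopathological covariates, Weibull proportional-hazards
  survival with independent censoring) and synthetic TMA spot images
  with exact ground truth — everything downstream is testable without
  patient data;
* **validation metrics**: area-overlap precision |M∩A|/|M|, sensitivity
  |M∩A|/|A|, their harmonic mean F1, and the matching-intensity
  percentage between model and human scores;
* **exact association tests** on r×c contingency tables with fixed
  margins — Freeman–Halton probability-mass ordering and the
  Pearson-statistic ordering, by full enumeration (2×c) or Monte-Carlo
  sampling of tables (Patefield);
* **survival analysis** implemented from first principles:
  Kaplan–Meier with Greenwood CIs, the k-sample log-rank test, Cox
  proportional hazards (Newton–Raphson, Efron ties, Wald inference),
  the enter-method univariable→multivariable convention, and scaled
  Schoenfeld residual diagnostics.

## Worked example

```python
from cmslike import (CohortConfig, generate_cohort, classify_cohort,
                     cohort_classification_report, fisher_exact_rxc,
                     load_reference_counts, km_estimate, survival_at)

patients, spots, bcat = generate_cohort(CohortConfig(n_patients=300, seed=7))
calls = classify_cohort(patients, spots, bcat)
rep = cohort_classification_report(calls)
print("counts:", rep["counts"])
print("classified fraction: %.1f%%" % rep["classified_fraction_pct"])

age = load_reference_counts()["age_group"]
print("age p-value: %.3f" % fisher_exact_rxc(age, method="exact",
                                             ordering="pearson"))

merged = patients.merge(calls, on="patient_id")
cms2 = merged[merged.cms_label == "CMS2-like"]
curve = km_estimate(cms2.os_time, cms2.os_event)
s, lo, hi = survival_at(curve, 5.0)
print("CMS2-like 5-year OS: %.1f%% (95%% CI %.1f-%.1f%%)"
      % (100 * s, 100 * lo, 100 * hi))
```

prints

```
counts: {'CMS1-like': 48, 'CMS2-like': 93, 'CMS3-like': 115, 'CMS4-like': 31, 'unclassified': 13}
classified fraction: 95.7%
age p-value: 0.027
CMS2-like 5-year OS: 67.7% (95% CI 58.9-77.9%)
```

The 300 simulated tumors fall into the three classification paths; 13
are unclassified (tied spot votes or tied β-catenin consensus).  The
age row of the packaged reference contingency table gives an exact
p = 0.027 for association between age group and subtype, and the
product-limit estimate for the simulated CMS2-like group's five-year
overall survival comes with its Greenwood confidence interval.

A command-line interface wraps the same pipeline:

```bash
cmslike --seed 1 --outdir out run              # simulate ... validate
cmslike reference-pvalues --ordering pearson   # packaged counts -> p-values
```

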
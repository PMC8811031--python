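# unidiag

**Unifying-diagnosis identification and prediction from multi-code diagnostic
records, embedding the ICD-9 disease-ontology structure.**

Critically ill patients typically leave hospital with a dozen or more ICD-9
diagnosis codes — fine-grained, highly related, and ordered by clinical
priority. A *unifying diagnosis* (UD) is the small set of primary diseases
that explains a patient group's clinical picture, separated from its
complications. `unidiag` is a toolkit for clinical-informatics researchers
who want to recover such unifying diagnoses from EMR diagnosis tables
(e.g. the MIMIC-III `DIAGNOSES_ICD` dialect) and to predict them from
admission features.

## Method

Given per-admission records `D = {(dc₁, Ord(dc₁)), (dc₂, Ord(dc₂)), …}` the
pipeline runs five stages:

1. **Ontology-embedded patient similarity.** ICD-9 codes are placed in a
   five-level ontology (root → 19 chapters → sections → 3-digit categories →
   4-digit subcategories → 5-digit extensions); the information content of a
   code is its depth, `IC(dc) = level(dc → Root)`. Code similarity is
   `s(dcᵢ, dcⱼ) = 2·IC(LCA(dcᵢ, dcⱼ)) / (IC(dcᵢ) + IC(dcⱼ))`, and patient
   similarity is the best-match average of `s` over both deduplicated code
   sets. Dice / Jaccard / cosine / overlap exact-match baselines are included.
2. **Affinity propagation clustering** of the similarity matrix, with the
   exemplar preference set by `p = median(S_offdiag) − p_coe·N`
   (default `p_coe = 0.025`). Cluster quality is summarised by per-cluster
   support `|C_k|/N` and the sum of member-to-exemplar similarities (SS).
3. **Typical-code pattern extraction (TDCCoP).** Within each cluster's core
   zone (the `n` most exemplar-similar patients, default 800, or a similarity
   threshold τ), codes with occurrence probability > δ₁ (default 0.3) are
   *typical*; they are re-ranked by their average position (AOrd) in the
   core patients' ordered code lists.
4. **UD identification.** Typical codes sharing a chapter merge under their
   least common ancestor (LCoP); a conditional co-occurrence matrix
   `CCoM(i,j) = P(dⱼ|dᵢ)` over the entries reveals asymmetries — an entry
   whose conditional or marginal probability exceeds another's by the
   dominance ratio ρ (default 1.5) is the more primary disease. The UD is
   the order-sorted prefix maximising net dominance over the suffix.
5. **UD prediction.** Admission features — demographics, 16 text-extracted
   symptom flags, 19 labs × (min, max, median, mean, variance), severity
   scores — are fused, screened by information gain (keep IG > δ₂ = 0.005),
   and fed to logistic regression, decision tree, random forest, SVM and
   XGBoost under stratified Z-fold cross-validation (default Z = 10), with
   per-fold imputation, selection and minority oversampling so no held-out
   row can leak into training.

A seeded synthetic-cohort generator with known group structure
(`unidiag.default_config()`) makes every stage testable without access to
restricted clinical databases.

## Worked example

```python
import numpy as np
import unidiag as u
from unidiag.prediction import split_blocks

cfg = u.default_config(n_patients=200, seed=0)      # 3 latent disease groups
patients, labels = u.generate_diagnoses(cfg)

model = u.UnifyingDiagnosisIdentifier(random_state=0).fit(patients)
print("K =", model.K_, " supports =", np.round(model.clustering_.supports, 3))

for k in range(model.K_):
    print(model.tdccops_[k].entries.round(3).to_string(index=False))
    print("  UD:", model.ud_results_[k].primaries)

X = u.fuse_features(*split_blocks(u.generate_admission_features(cfg, labels)))
report = u.train_and_evaluate(X, model.labels_,
                              classifiers=("logistic", "forest", "xgboost"),
                              Z=10, seed=0)
print(report.metrics.round(3))
```

prints

```
K = 3  supports = [0.285 0.395 0.32 ]
  code  probability  average_order  rank
518.81        0.947          1.315     1
   486        0.895          1.843     2
491.21        0.789          2.600     3
  UD: ['460–519']
...
          auc    acc    pre    rec     f1  cv_error
logistic  1.0  1.000  1.000  1.000  1.000     0.000
forest    1.0  1.000  1.000  1.000  1.000     0.000
xgboost   1.0  0.995  0.995  0.995  0.995     0.005
```

The clustering recovers the three planted groups exactly; each cluster's
typical codes are its configured signature (probabilities ≈ the configured
0.95/0.90/0.85, average orders ≈ the configured priorities 1/2/3), the three
respiratory codes merge into the chapter entry 460–519 which becomes that
cluster's unifying diagnosis, and the admission features predict the cluster
label almost perfectly because the generator plants strong lab shifts.

The same pipeline is scriptable from the shell:

```bash
unidiag simulate --n 200 --seed 0 --out-dir cohort/
unidiag run-all --diagnoses cohort/diagnoses.csv --features cohort/features.csv \
    --out-dir run/ --z 10
```

which writes `similarity.csv`, `clusters.csv`, `cluster_meta.json`,
`tdccop.json`, `ud.json`, `metrics.json` and the resolved configuration.

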
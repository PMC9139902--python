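# hccradiomics

Feature selection and small-cohort model building for MRI radiomics of
hepatocellular carcinoma (HCC). The package implements, as a tested and
reusable pipeline, the analysis workflow used to ask two questions of a
multi-sequence liver MRI feature table: can radiomic features separate HCC
lesions from normal hepatic tissue (HT), and can they predict the
histologic grade (G1 well-, G2 moderately-, G3 poorly-differentiated)?

It is aimed at radiomics researchers who have a per-VOI feature table
(e.g. a PyRadiomics export from T2 and arterial/portal/tardive
post-contrast DCE-MRI phases) and need the full small-sample protocol:
redundancy filtering, univariate screening, mutual-information ranking,
imbalance-adjusted bootstrap model building with 0.632+ correction, model
order selection and DeLong model comparison — together with a synthetic
cohort generator so every stage can be exercised and validated without
patient data.

## The method

Each classification task (HCC vs HT on paired VOIs; G3 vs G1+G2, G2 vs
G1, G3 vs G1, G3 vs G2 on lesion VOIs, the more aggressive class coded
positive) runs the same protocol on its own rows:

1. **Redundancy filter.** The pairwise |Spearman ρ| matrix is computed
   once; while any pair exceeds ρ<sub>max</sub> = 0.8, the member of the
   worst pair with the larger mean |ρ| against the surviving features is
   removed.
2. **Univariate screen.** Two-sided Wilcoxon rank-sum test per feature
   (exact null distribution when the smaller group has ≤ 10 samples and
   no ties); features with p < 0.05 survive. For HCC vs HT a paired
   signed-rank screen over subject-matched VOIs is reported alongside.
3. **Mutual-information ranking.** Each survivor is discretized into
   equal-frequency bins (⌈√n⌉, capped at 10) and the plug-in mutual
   information with the class label (in nats) ranks them; the top 5 are
   the model candidates.
4. **Model building (IABR + 0.632+).** Logistic models

   g(x<sub>i</sub>) = β₀ + Σ<sub>j=1..v</sub> β<sub>j</sub> x<sub>ij</sub>,  P(y<sub>i</sub>=1 | x<sub>i</sub>) = e<sup>g</sup> / (1 + e<sup>g</sup>)

   of order v = 1…5 are grown by forward selection: at each order the
   candidate maximizing the 0.632+ bootstrap AUC joins the model.
   Bootstrap samples (B = 1000) are *imbalance-adjusted*: each in-bag
   draw picks a class with probability ½, then an instance uniformly
   within it, so the minority class is not under-trained. Out-of-bag
   instances form each replicate's test set, and apparent (Ā) and
   out-of-bag (m̄) performance are blended as

   est = (1 − w)·Ā + w·m′,  m′ = max(m̄, 0.5),  w = 0.632 / (1 − 0.368·R),
   R = (Ā − m′)/(Ā − 0.5) clipped to [0, 1],

   for AUC, sensitivity, specificity and accuracy alike.
5. **Order selection and comparison.** The simplest order within ε = 0.01
   of the best 0.632+ AUC is chosen (optionally resolved by specificity),
   and all per-order models are compared pairwise with the DeLong test
   for correlated ROC AUCs under Bonferroni correction.

The default feature catalogue mirrors a standard PyRadiomics extraction:
14 shape features computed once per VOI plus 18 first-order and 75
texture features (GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5) for each
of the four sequences — 14 + 4 × 93 = 386 features, named
`<sequence>_<group>_<BaseName>` with both space- and underscore-separated
dialects accepted on input.

## Worked example

```bash
python analysis/01_simulate_cohort.py            # 76 x 386 synthetic cohort
python analysis/02_select_features.py            # three-step selection per task
python analysis/03_build_models.py --b-samples 200
```

The simulated cohort reproduces the reference study structure (38
patients, grades 7/15/16, one paired HT VOI per patient) with two planted
2-SD informative features per task. The selection step prints, per task,
the survivor counts of each stage, e.g.

```
HCC_vs_HT: step I 107, step II 13 (paired screen: 13), step III top-5: T2_glrlm_LongRunHighGrayLevelEmphasis, ...
G1G2_vs_G3: step I 115, step II 8, step III top-5: PORT_gldm_LargeDependenceLowGrayLevelEmphasis, ...
```

— 386 features collapse to ~110 after the redundancy filter, ~10 survive
screening, and the planted features lead the MI ranking. Model building
then reports the chosen model per task in equation form:

```
HCC_vs_HT: order 2 (AUC632 98%, sens 98%, spec 95%, acc 96%)
  g_HCC_vs_HT(x_i) = 4.82 x (T2 glrlm Long Run High Gray Level Emphasis) +3.25 x (T2 gldm Dependence Non Uniformity Normalized) -0.39
```

i.e. the order-2 model recovered exactly the two planted features, with a
0.632+ AUC of 98% on this strongly separable synthetic cohort.
`analysis/04_recovery_experiment.py` repeats this over seeds (planted
pair recovered in ≥ 90% of cohorts) and, on all-noise cohorts, quantifies
the post-selection optimism of the protocol (chosen-model 0.632+ AUC
≈ 0.7 on pure noise — see `docs/methods.md` for why).

The same pipeline is available as a CLI (`hccradiomics simulate | select |
fit | run | compare | report`) for use on real feature tables.

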
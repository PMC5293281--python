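# dceradiomics

Radiomic analysis of bilateral-breast DCE-MRI for predicting the four
molecular subtypes of breast cancer — luminal A, luminal B,
HER2-over-expressing and basal-like — as a tested, reusable pipeline.

Dynamic contrast-enhanced MRI acquires a precontrast volume S-0 and
postcontrast volumes S-1, S-2 after injection of a gadolinium agent.
Tumors and the normal fibroglandular tissue (background parenchymal
enhancement, BPE) take up contrast at rates that differ between molecular
subtypes, and the spatial pattern of that uptake is quantifiable. The
pipeline:

1. **registers** S-1 and S-2 to S-0 by a translational scheme — Sobel
   filtering, maximum-information window search, window correlation
   matching, integer linear shifting;
2. **segments** the breast region (excluding the chest wall) and, from a
   seed voxel, the tumor — spatial fuzzy C-means refined by a
   Markov-random-field pass propagated across slices;
3. **extracts 90 features** per case: age and menopausal status, tumor
   first-order statistics (skewness, kurtosis, max, mean, sd per series),
   morphology (volume, diameter, radius sd, roughness, compactness
   36πV²/A³), 3D gray-level co-occurrence texture (contrast, correlation,
   energy, homogeneity, entropy per series), kinetic statistics of the
   subtraction maps S-1−S-0, S-2−S-0, S-2−S-1 and of the relative
   enhancement r = (I_T − I_0)/I_0, BPE statistics over the top-1% most
   enhancing parenchymal voxels of each breast, and the bilateral
   (lesion-side minus contralateral) differences;
4. **selects features** with a genetic algorithm over 90-bit inclusion
   chromosomes whose fitness is the cross-validated one-vs-rest AUC of the
   classifier (population 500, 200 generations, crossover 0.6, mutation
   0.01 at study scale);
5. **classifies** subtypes with one-against-others ridge-logistic models
   under leave-one-out cross-validation with inner greedy wrapper
   selection, reporting per-class ROC/AUC with DeLong 95% confidence
   intervals, best-threshold sensitivity/specificity operating points, a
   selection-frequency table and a Kruskal–Wallis screen.

No patient data ships with the package. A first-class synthetic-data
module generates bilateral-breast phantoms with known tumors,
subtype-dependent kinetics, BPE and planted inter-series shifts, so every
stage is testable against ground truth (see `docs/methods.md` for the
phantom model and its limits).

## Worked example

```python
import dceradiomics as dr

# one phantom case: HER2 subtype, known ground truth
case, truth = dr.generate_case("HER2", seed=1)

# register S-1/S-2 to S-0 and compare with the planted shifts
registered, shifts = dr.register_series(case)
print("estimated:", (shifts["s1"].dx, shifts["s1"].dy), "planted:", truth.shifts["s1"])

# segment breast and tumor, then extract the 90-feature vector
breast = dr.segment_breast(registered.s0)
breast.laterality_of_lesion = truth.laterality
registered.breast_mask = breast
registered.tumor_mask = dr.segment_tumor(registered, case.tumor_mask.seed)
vec = dr.extract_features(registered)
print("features:", len(vec.values), " tumor volume (mm3): %.0f" % vec[18])

# cohort-level analysis on a planted feature table
table = dr.planted_feature_table(n_per_class=15, seed=1)
best, _ = dr.ea_search(table, dr.EAConfig(population=60, generations=40, rng_seed=1))
report = dr.loocv_evaluate(table, best.feature_indices, dr.PipelineConfig(seed=1))
print("selected pool:", best.feature_indices)
print("held-out overall AUC: %.3f" % report.overall_auc_weighted)
```

prints

```
estimated: (1, -3) planted: (1, -3)
features: 90  tumor volume (mm3): 226
selected pool: (3, 27, 32, 40, 43, 44, 46, 47, 53, 54, 58, 62, 64, 66, 74, 83, 85)
held-out overall AUC: 0.985
```

The planted shift is recovered exactly; the genetic search finds the three
informative features (3, 40, 83) planted in the table, plus noise features
that the inner wrapper selection then mostly discards; the held-out AUC
reflects the planted effect size, not any patient data.

A CLI mirrors the stages: `dceradiomics simulate|register|segment|extract|
select|classify|report`, each accepting `--config` (YAML of
`PipelineConfig` keys) and `--seed`.

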
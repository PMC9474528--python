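# petrad

A tested, reusable PET/CT radiomics pipeline for identifying the genetic
cluster (cluster 1 / cluster 2 / sporadic) of catecholamine-producing
tumours from [18F]FDG-PET/CT:

1. **synthetic_cohort** — phantom simulation of a 40-lesion cohort
   (13 cluster 1, 18 cluster 2, 9 sporadic) with cluster-dependent uptake,
   size, texture heterogeneity and dichotomous biochemistry flags.
2. **segmentation** — background-corrected adaptive-threshold PET
   delineation: SUV_peak (12-mm-diameter sphere), local background shell,
   threshold `T = 0.41 * (SUV_peak - background) + background`, 26-connected
   component, 64-voxel minimum-size QC filter, optional boxing.
3. **radiomics** — 105 features per modality (18 first-order, 14 shape,
   73 texture across GLCM/GLRLM/GLSZM/NGTDM/GLDM) plus total lesion
   glycolysis (TLG = SUV_mean x MTV) = 211 values per lesion. CT is
   resampled to 1.5 mm isotropic (cubic B-spline); PET stays native. Fixed
   bin sizes: 0.5 g/mL (PET) and 25 HU (CT).
4. **dimred** — per-training-fold z-scaling, Spearman redundancy filtering
   (|rho| >= 0.95), ML factor analysis with varimax rotation
   (one factor per ten training subjects), KMO sampling adequacy,
   regression-score projection of test lesions.
5. **classify** — stratified 5-fold multinomial logistic regression over a
   menu of nine models (biochemistry, SUV_max, PET 3-factor, PET/CT
   3-factor, PET 3-feature, each +/- biochemistry), scored by the mean of
   all pairwise two-class AUCs (multiclass AUC), plus a 100-iteration
   label-shuffling sham null that refits the entire pipeline per shuffle.
6. **pipeline_cli** — one-config orchestration with reproducible seeds.

## CLI

```bash
petrad simulate --n1 13 --n2 18 --ns 9 --seed 0 --out run/volumes
petrad segment  --pet run/volumes/L000_pet.nii.gz --out voi.nii.gz --report seg.json
petrad extract  --pet ... --pet-mask ... --ct ... --ct-mask ... --out features.csv
petrad reduce   --features features.csv --folds folds.csv --out models/
petrad evaluate --features features.csv --spec pet3factor --k 5 --seed 0 --out results.json
petrad sham     --features features.csv --spec pet3factor --iterations 100 --seed 0 --out sham.json
petrad run-all  --out run/            # full pipeline with default config
petrad run-all --print-default-config --out -   # show the documented defaults
```

Volumes and masks are NIfTI-1 (arrays indexed x,y,z; mm world coordinates);
lesion tables are CSV with one row per lesion (cluster label, three
biochemistry flags, 211 feature columns).

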
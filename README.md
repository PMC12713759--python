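# sickstate

Different immune challenges — bacterial endotoxin (LPS), a viral RNA mimic
(pI:C), a parasite antigen (STAg), an allergen (bee-venom PLA2), chemically
induced colitis (DSS) — put an animal into measurably different *sickness
states*. `sickstate` is a Python library that implements, as tested and
reusable components, the quantitative machinery for discriminating those
states from three kinds of evidence:

1. **Brain-wide immediate-early-gene activity.** An animal × brain-region
   FOS-intensity matrix (the study design is 48 animals × 641 atlas regions)
   is Yeo-Johnson normalized, reduced by repeated Boruta shadow-feature
   selection (confirmation-frequency cut at the top 5%, ties kept), and
   classified with a custom multinomial logistic regression under an
   elastic-net penalty

   `F(B,b) = -(1/n) Σ_i log softmax(x_i Bᵀ + b)_{y_i} + λ(α‖B‖₁ + (1-α)/2‖B‖²_F)`

   evaluated by repeated nested stratified cross-validation (75–25 outer
   split, inner 4-fold tuning of (λ, α), 100 repetitions). Region-level
   interpretation uses the linear SHAP attribution
   `SHAP(i,j,c) = X_std(i,j) · β(j,c)` and the hybrid importance score
   `H(j,c) = mean|SHAP(·,j,c)| · |B̄(j,c)|`, plus silhouette /
   Calinski-Harabasz validation of the selected feature set.

2. **Ultrasonic vocalizations.** Call tables (35 acoustic features
   including four temporal metrics; calls shorter than 5 ms excluded) are
   classified by an ensemble of 50 random forests fitted to balanced
   per-class subsamples with stratified 80/20 splits, scored by macro F1
   against a jointly-shuffled-label chance baseline (≈ 1/K).

3. **Spatial transcriptomics.** Moran's I over a k-nearest-neighbor weight
   graph, its treated-minus-control difference ΔI (positive = focal,
   region-specific upregulation; near zero = broad), and per-gene counting
   of upregulated cell types from differential-expression tables at strict
   (p_adj < 0.01, log2FC > 2) or lax (p_adj < 0.05, log2FC ≥ 1) thresholds.

Every input has a synthetic generator with planted, recoverable ground
truth (`sickstate.simulate`), so the whole pipeline is testable without
access to the original animal data. The library is aimed at computational
neuroscientists and biostatisticians who want these protocols as callable,
seed-reproducible functions.

## Worked example

`examples/fos_state_signatures.py` simulates a 48-animal, 60-region matrix
with 6 planted regions per condition at 2.5 sd and runs the full pipeline:

```
Selection retained 24 of 60 regions; recall of planted regions = 1.00
Held-out accuracy over 10 repetitions: 0.975 +/- 0.040
Row-normalized confusion matrix (diagonal = correct calls):
        DSS  LPS  PLA2  STAg  Saline   pIC
DSS     1.0  0.0   0.0   0.0    0.00  0.00
...
Top regions for LPS by hybrid importance (mean|SHAP| x |mean beta|):
             hybrid  mean_shap  mean_coef    direction
region_0005   8.603      5.237     -3.305  suppressing
region_0003   2.006      2.523      1.620    promoting
```

Reading: selection recovered every planted region; held-out assignment of
the six states is near-perfect; and for the LPS state the top-ranked region
is a planted *suppressed* one — its coefficient is negative and its
class-conditional SHAP positive, i.e. reduced activity there pushes the
prediction toward LPS. The clustering block prints silhouette rising from
0.056 (all regions) to 0.204 (selected), the quantitative sense in which
selection sharpens the state clusters.

The other examples print the USV real-vs-shuffled macro-F1 gap
(`examples/usv_shuffled_baseline.py`) and the focal/broad/null ΔI contrast
with specificity counts (`examples/spatial_focal_vs_broad.py`), e.g.
ΔI = +0.67 for a planted focal gene vs 0.00 for a broad one.

## Layout

- `sickstate.simulate` — generators for FOS, USV and spatial inputs
- `sickstate.transform` — Yeo-Johnson fitting and fold-safe standardization
- `sickstate.select` — Boruta runs and the repeated frequency cut
- `sickstate.classify` — elastic-net multinomial fit and nested CV
- `sickstate.attribute` — linear SHAP, hybrid importance, rankings
- `sickstate.clustermetrics` — silhouette, Calinski-Harabasz, 2-D embedding
- `sickstate.usv` — call filtering, temporal metrics, forest ensemble
- `sickstate.spatial` — Moran's I, ΔI, specificity counting
- `sickstate.pipeline` / `sickstate.io` — orchestration and delimited-text I/O

See `docs/methods.md` for the modeling assumptions, parameter defaults and
numerical choices.
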
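# heteroduo

Dual-modality quantification of intratumoral heterogeneity, with the
downstream prognostic statistics, for breast-tumor imaging studies that
pair digitized immunohistochemistry (IHC) slides with ¹⁸F-FDG PET.

Tumors that look uniform on one modality can be patchy on another, and the
*spatial arrangement* of hormone-receptor staining or of metabolic uptake —
not just its average level — may carry prognostic information. `heteroduo`
implements both measurement chains and the statistics that connect them to
outcome:

- **Slide heterogeneity** (`heteroduo.ihc`): the tumor region of an RGB
  slide is cut into square tiles (default 2000 px at 0.5 µm/px, i.e. 1 mm²
  each); each tile's *stained ratio* (DAB-brown pixels / tissue pixels, by
  color deconvolution) is ranked into ten 10 %-wide levels; the rank map
  yields a normalized co-occurrence matrix **P** and the classical Haralick
  summaries — contrast `Σ(i−j)²p(i,j)`, homogeneity, dissimilarity,
  entropy (bits), energy, correlation — plus the skewness and (excess)
  kurtosis of the per-tile ratio distribution.
- **PET heterogeneity** (`heteroduo.pet`): within a tumor VOI, SUVmax;
  histogram skewness/kurtosis/entropy/uniformity; six GLCM features
  averaged over the 13 unique 3-D directions; and NGLDM coarseness,
  contrast and busyness — all after *absolute resampling* of SUV into 64
  fixed bins over [0, 32] (bin width 0.5), so features are comparable
  across lesions.
- **Prognostic chain** (`heteroduo.stats`): Spearman correlation matrices
  between the feature blocks; a 100-tree bagged-CART random forest with
  out-of-bag (OOB) error and permutation (mean-decrease-accuracy)
  importance for the binary event-within-8-years label; Mann-Whitney group
  comparisons; ROC with Hanley–McNeil standard errors and Youden-index
  cut-offs; Kaplan-Meier / log-rank at those cut-offs; multivariable Cox
  regression (Efron ties) with likelihood-ratio, score and Wald global
  tests and a proportional-hazards check.
- **Synthetic data** (`heteroduo.simulate`): seeded generators for
  correlated Beta-marginal stained-ratio fields rendered as RGB slides,
  ellipsoidal SUV lesions with tunable texture, and proportional-hazards
  survival cohorts with a planted feature effect — each shipping its latent
  ground truth so every stage can be validated without patient data.
- **Orchestration** (`heteroduo.pipeline`, CLI `heteroduo`): manifest-driven
  per-patient feature extraction into one cohort table, the full chain, and
  JSON/CSV reports stamped with a configuration hash.

## Worked example

`examples/survival_chain.py` plants a threefold hazard per unit of the
slide-skewness feature in a 120-patient simulated cohort and runs the full
chain:

```
cohort: 120 patients, 40 events, planted HR per unit skewness = 3.0

random forest OOB error: 0.308
top variables by mean decrease accuracy:
           skewness_er: +0.0394
     molecular_subtype: +0.0003
        clinical_stage: -0.0001

ROC for skewness_er: AUC 0.778 +/- 0.051, cutoff 0.072 (>)
log-rank at the skewness_er cutoff: chi2 26.04, p 3.35e-07

multivariable Cox hazard ratios:
              age: HR 1.00 [0.97, 1.02], p 0.728
        stage_iii: HR 2.34 [1.23, 4.42], p 0.009
      skewness_er: HR 3.98 [2.50, 6.31], p 0.000
```

The planted feature dominates the importance ranking, its Youden cut-off
splits survival sharply, and the multivariable hazard-ratio interval covers
the planted value 3. The other examples cover the slide pipeline
(`ihc_features.py`), PET feature extraction (`pet_features.py`) and the
file-based end-to-end run (`end_to_end.py`).

The same things are scriptable from a shell:

```bash
heteroduo simulate inputs --n 12 --seed 3 --out run/inputs
heteroduo run-all --manifest run/inputs/manifest.csv \
    --clinical run/inputs/clinical.csv --seed 3 --out run/out
```

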
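# Methods

## Slide-level heterogeneity

The slide chain measures how unevenly a DAB-stained receptor is expressed
across a tumor region, at the spatial scale of 1 mm².

**Segmentation.** Tissue: a pixel is tissue iff its HSV value is below
0.92 (darker than blank glass) *and* its saturation exceeds 0.04 (both
configurable). Stain: the RGB image is deconvolved into
hematoxylin/eosin/DAB optical densities with the standard published stain
matrix (scikit-image's `rgb2hed`); a pixel is stained iff its DAB optical
density exceeds 0.15. An HSV hue-range classifier is available behind
`IhcConfig.stain_method="hsv"` for stains that deconvolve poorly. These
rules are deterministic, so the whole chain is.

**Tiling and ranking.** The grid is anchored at the image origin with
square tiles of `tile_px` pixels (default 2000 px; at the default
0.5 µm/px that is a 1 mm side, hence 1 mm² per tile). Partial edge tiles
are kept. A tile's stained ratio is stained/tissue counted over
tile ∩ ROI ∩ tissue; tiles whose tissue ∩ ROI fraction falls below
`min_tissue_fraction` (default 0.05) carry no ratio and are excluded
everywhere downstream. Ratios are ranked into ten intervals: level 0 is
[0, 0.10], level k is (0.10k, 0.10(k+1)] — the upper boundary belongs to
the lower level. Ranking uses a 1e-9 slack so that values like 0.3, which
binary floating point stores fractionally above 0.3, stay in their
mathematical interval.

**Texture.** Co-occurrence counts every pair of adjacent ranked tiles at
offset distance 1; the default neighborhood is 8-connected (4-connected
behind config), accumulation is symmetric, and the matrix is normalized to
sum 1. Haralick features follow the classical definitions with entropy in
base 2 (shared with the PET module so entropies are comparable).
Correlation is reported missing (NaN) when a marginal is degenerate —
undefined features are never silently 0. Skewness and excess kurtosis use
the population central-moment estimators m₃/m₂^{3/2} and m₄/m₂²−3, applied
by default to the continuous per-tile ratios; computing them on the ten
ranks instead is a config switch (`shape_on="ranks"`). Which variant the
original slide analyses used is not documented anywhere we know of; the
ratio variant discards less information, so it is the default.

## PET heterogeneity

SUV values inside the VOI are discretized by *absolute resampling*:
bin = floor((v − lo)/w) with 64 bins over [0, 32] SUV, so w = 0.5; v = 32
maps to the top bin and values above the range are clamped rather than
rejected (the range maximum describes one cohort's data; other data may
exceed it). Histogram entropy (bits) and uniformity are computed over
occupied-bin occupancy fractions; histogram skewness/kurtosis are the
shape statistics of the bin-index sample, consistent with the discretized
values feeding all texture features (raw-SUV shape statistics are a config
variant).

GLCM matrices are built per direction for the 13 unique 3-D offsets at
Chebyshev distance 1 (voxel anisotropy is ignored for neighbor definitions,
the common convention at distance 1), symmetrized, normalized; directions
with no in-VOI pair are dropped. Features are computed per direction and
averaged unweighted (LIFEx-style); merging matrices before computing is
available behind `PetConfig.glcm_aggregation="merge_matrices"`. GLCM
correlation is averaged over the directions where it is defined.

NGLDM: for each occupied level i, p_i is the fraction of VOI voxels at
that level and s_i the summed absolute difference between each such voxel
and the mean level of its in-VOI 26-neighbors. Coarseness = 1/Σp_i s_i,
capped at 10⁶ for a uniform VOI; contrast and busyness follow the
Amadasun-style closed forms (busyness denominator over ordered level pairs
i ≠ j) and are missing for a single-level VOI. VOIs below 64 voxels are
rejected as too small to texture-analyze.

## Statistical chain

The chain runs in a fixed order: Spearman maps → random forest →
Mann-Whitney → ROC/Youden → Kaplan-Meier/log-rank → multivariable Cox.

- **Spearman** uses mid-rank coefficients with pairwise deletion and the
  two-sided t approximation; cells with fewer than 4 complete pairs are
  missing. Raw p < 0.05 is flagged; no multiplicity correction is applied
  by default (a Benjamini–Hochberg step would be easy to add, but the
  default mirrors how such exploratory maps are usually read).
- **Random forest**: 100 unpruned CART trees on bootstrap resamples
  (Breiman defaults: unlimited depth, minimum leaf 1). OOB error is the
  misclassification rate of the out-of-bag majority vote. Importance is
  mean decrease accuracy: per tree, the drop in OOB accuracy after
  permuting one variable among that tree's OOB rows, averaged over trees.
  Stage and grade enter as ordinal integers (they are genuinely ordered);
  nominal categories as stable integer codes; one-hot encoding is a config
  matter for the caller since the table is a plain DataFrame.
- **Variable selection**: the top variables by importance (cap 7) with
  positive mean decrease accuracy, restricted to imaging features, proceed
  to Mann-Whitney; those significant at α = 0.05 proceed to ROC.
- **ROC/Youden**: AUC is the mid-rank U statistic over n₀n₁ (identical to
  the trapezoidal empirical ROC area); SE by Hanley–McNeil; the 95 % CI is
  the normal interval truncated to [0, 1]; the p-value is the normal test
  of AUC = 0.5 (the usual choice when none is stated). The direction is
  chosen so AUC ≥ 0.5 and the cut-off is the observed score maximizing
  J = sens + spec − 1, ties broken toward higher specificity.
- **Survival**: Kaplan-Meier product-limit curves per group and the
  two-group log-rank test (lifelines). The Cox model uses Efron tie
  handling — ties are expected at coarse follow-up resolution. lifelines
  performs the fit; a damped Newton polish on this package's own Efron
  score/information then drives the estimate to the exact
  partial-likelihood maximum (lifelines' adaptive stepping can stop about
  1e-4 short on very small datasets). Per-covariate Wald tests, hazard
  ratios with 95 % CIs, global likelihood-ratio/score/Wald tests (df =
  number of covariates) and a scaled-Schoenfeld proportional-hazards check
  are reported. A monotone partial likelihood (separation) raises an
  explicit error — detected as a standardized log-HR beyond 15 per unit
  SD — rather than returning silently absurd estimates.
- The 8-year event-free label used by the forest is 1 iff an event is
  observed within 8 years. The crude event-free proportion
  100·(1 − events/N) and the Kaplan-Meier estimate at the horizon are both
  reported, since with administrative censoring before the horizon they
  can differ.

## Synthetic data: what it emulates, and what it does not

- **Ratio fields**: Gaussian white noise blurred with a kernel of sd =
  `correlation_length` (in tiles), then mapped through a rank-based
  quantile transform onto a Beta(a, b) marginal. The marginal is therefore
  exact (an order-statistic sample) while spatial ordering follows the
  correlated field; `correlation_length = 0` gives spatially independent
  tiles.
- **Slide rendering**: per tile, `tissue_fraction` of pixels are tissue
  (pink, RGB 220/170/195) and exactly round(ratio · n_tissue) of those are
  DAB brown (RGB 110/65/35), with seeded Gaussian color jitter (sd 6 by
  default) on tissue; glass is pure white. The colors were fixed by
  checking, on color patches, that the default classifiers detect ≥ 95 %
  of brown pixels and essentially all tissue under the default jitter — so
  the segmentation thresholds are genuinely exercised, not bypassed. Not
  emulated: nuclei and texture within tissue, scanner illumination
  gradients, compression artifacts, out-of-focus regions; recovery results
  on renders are upper bounds on real-slide accuracy.
- **PET lesions**: ellipsoidal masks on the configured spacing (default
  1.3 × 1.3 × 1.9 mm); SUV = base + amplitude × correlated unit-variance
  field clipped at ±3 sd (so suv_max ≥ base − 3·amplitude by
  construction), floored at 0, uniform low background outside. Not
  emulated: partial-volume blur, reconstruction noise correlation
  structure, respiratory motion.
- **Cohorts**: the planted feature is standard normal; event times are
  exponential with hazard λ·exp(β·feature), λ = 0.043/year (≈ 29 % events
  by 8 years at feature 0, matching an 11-of-38 event cohort),
  administrative censoring at 9 years, default β = log 3. Age, stage,
  grade, histology and molecular subtype are drawn with the frequencies of
  a typical luminal breast-cancer cohort; eight independent noise features
  accompany the planted one. A design-phase power check (before freezing
  anything) showed β = log 3 gives ~90 % end-to-end detection at n = 40,
  so the default doubles as the planted-signal validation condition.

## Numerical choices

- Entropies in base 2 everywhere.
- Normalized matrices must sum to 1 within 1e-9; symmetric accumulation is
  used for all co-occurrence counting.
- Rank boundaries carry 1e-9 slack (see above); SUV discretization uses
  exact floor with clamping.
- Undefined statistics (zero-variance shape, degenerate correlation,
  single-level NGLDM contrast/busyness) are NaN in memory and `null` in
  JSON reports.
- Mann-Whitney uses exact enumeration for small tie-free samples and the
  tie-corrected normal approximation *without* continuity correction
  otherwise, so a perfectly symmetric configuration returns p = 1 exactly.
- Youden ties break toward higher specificity; the cut-off is always an
  observed score value.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run entirely on generated
data, sized for a desk machine: slides of 5–10 × 5–10 tiles at 24–48 px
per tile, lesions of a few thousand voxels, cohorts of 40 patients for the
operating-characteristic replicates (50 planted + 50 null) and 500 for
Cox parameter recovery (50 replicates) and null CI coverage (200
replicates). Exhaustive oracle checks cover all 2×2 and 2×3 rank grids
over 4 levels plus 500 random 4×4 grids, and all 2×2×2 volumes over 3
levels; the features are linear-time functionals of pair counts, so
correctness at these sizes transfers to larger grids.

## Known limitations

- The stain and tissue classifiers are threshold rules on deconvolved /
  HSV channels; heavily hemosiderin-laden or necrotic tissue would need a
  trained classifier.
- VOI delineation is out of scope: masks are inputs.
- SUV computation from raw DICOM activity (dose/weight/decay bookkeeping)
  and scanner harmonization are out of scope; volumes are expected already
  in SUV units.
- Third-order texture families (GLRLM/GLSZM) are deliberately not
  implemented.
- The random-forest stage treats nominal covariates as integer codes by
  default; with many-level nominal variables this understates their
  importance relative to one-hot encoding.
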
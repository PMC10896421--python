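# Methods

## Overview

`cryoredox` quantifies tissue mitochondrial redox state from 3D
cryo-imaging data: serial block-face fluorescence acquisition in which a
frozen organ is alternately sliced and imaged in two autofluorescence
channels — NADH (reduced nicotinamide adenine dinucleotide, excited
~350 nm / emitting ~460 nm) and FAD (oxidized flavin adenine
dinucleotide, ~437 / ~537 nm).  The per-voxel redox ratio

    RR(v) = NADH(v) / FAD(v)

indexes the balance of the mitochondrial electron-transport-chain
cofactor pool: a lower RR means a more oxidized state.  The pipeline
compares wild-type (WT) and *Mblac1* knockout (KO) mice — a
metallo-β-lactamase-domain gene whose loss is studied as a risk model
for neurodegeneration — across two factorial designs: liver (N=8 per
genotype, 4 male / 4 female, 100 µm slices) and kidney (N=18 per
genotype, 11 male / 7 female, 30 µm slices).

## Processing model

Each animal contributes two raw stacks (one per channel, ~200 slices at
full acquisition depth).  Per slice the pipeline applies, in order:

1. **Calibration.**  `corrected = clip0(raw − dark) / flat / gain`,
   where `dark` is a per-channel dark-current frame (counts), `flat`
   the illumination pattern normalized to unit mean (so flat-field
   division does not change the image's overall scale), and `gain` an
   explicit per-session scalar for day-to-day intensity drift
   (default 1; the estimator for it is deliberately not inferred from
   the data).  Whether the instrument's own corrections are purely
   multiplicative, additive, or both is not documentable from available
   sources; dark-then-flat is the standard CCD model and is exactly
   invertible on the package's own forward model.  Negative values
   after dark subtraction are clipped to zero because fluorescence
   counts are physically nonnegative and downstream ratios require it.
   Calibrating twice is an error, not a silent no-op.

2. **Segmentation.**  Per-slice thresholding — Otsu by default
   (parameter-free, scale-invariant), or a fixed threshold — on the
   NADH channel (brighter in liver; configurable to FAD or the
   per-pixel channel mean), followed by a radius-1 morphological
   opening and retention of the largest connected component.  The block
   face shows one organ cross-section per slice, so a single component
   is the correct prior; the opening removes speckle without biasing
   bulk-tissue statistics.  Slices with no surviving pixels (end slices
   past the organ) are excluded with a warning rather than failing the
   animal.  Whether the original analysis thresholded globally or per
   slice, and on which channel, is not verifiable; both are exposed as
   configuration.

3. **Ratio volume.**  RR is computed voxel-wise on tissue voxels,
   stacked in z with no inter-slice smoothing or registration (the
   block face is imaged in situ, so slices are aligned by
   construction).  Tissue voxels whose FAD intensity falls below a
   floor — default 1% of the masked FAD median — are *excluded and
   counted*, never set to 0 or ∞: the ratio is numerically meaningless
   there.  If more than half the mask is excluded the animal fails
   hard, since that indicates a calibration or segmentation failure
   rather than a few dim voxels.

4. **Summary.**  Each animal is summarized by the arithmetic mean of RR
   over its retained tissue voxels, `mean = Σ RR(v) / N`.  The
   denominator is the retained tissue-voxel count, not the full
   Nx×Ny×Nz image grid: a grid denominator would dilute the mean with
   zero-valued background toward ~0, inconsistent with the magnitude
   this statistic is meant to carry (liver RR ≈ 2.6 on mostly-empty
   frames).  The full-grid variant remains available
   (`volume_mean(..., full_grid=True)`, config key
   `mean_denominator: full_grid`) for comparison.  Histograms are
   density-normalized (100 bins over [0, 99.9th percentile] by default,
   robust to ratio outliers); they are presentational only — the stored
   mean and SD always come from the voxels, so they are
   binning-independent.  Voxels are equally weighted even though they
   are anisotropic (pixel size ≠ slice thickness); the volume mean is
   an unweighted sum and anisotropy is recorded as metadata only.

## Cohort statistics

The unit of analysis is the animal (its mean RR); no voxel-level or
mixed-effects modeling is attempted.  Per tissue:

1. **Two-way fixed-effects ANOVA** of per-animal mean RR on genotype,
   sex, and their interaction.  Type II sums of squares by default —
   each main effect adjusted for the other, the appropriate choice for
   the unbalanced kidney design (11M/7F) when the interaction is not
   the object of inference; Types I and III are available via
   configuration.  The decomposition is computed directly via nested
   least-squares model comparisons with sum-to-zero coding (it is
   exercised tens of thousands of times in the calibration
   simulations); the unit tests verify exact agreement with
   statsmodels' `anova_lm(typ=2)` on balanced and unbalanced fixtures
   and with a from-scratch cell-mean decomposition on balanced ones.

2. **Sex pooling.**  Sexes are combined if and only if neither the sex
   effect nor the interaction is significant at α = 0.05.  Pooling
   against the ANOVA's verdict is refused explicitly (per-sex t-tests
   are returned instead); α is fixed at 0.05 and no multiple-testing
   correction is applied across tissues or analytes, which the output
   metadata records.

3. **Student's t-test** (pooled variance) of WT vs KO on the pooled
   animals; Welch's variant is available via config.  Sidedness
   defaults to two-sided; the liver preset in the analysis drivers uses
   one-sided with direction WT > KO, the directional hypothesis of the
   liver comparison.

4. **Percent change** is reported as `100·(mean_WT − mean_KO)/mean_KO`.
   The KO-denominator convention is deliberate: it is the only
   arithmetic consistent with the benchmark group means this package
   reproduces ((2.59−1.77)/1.77 = 46.33%, (0.85−0.69)/0.69 = 23.19%),
   although "percent decrease" prose usually implies a WT denominator.
   The WT-denominator variant is available (`baseline="wt"`); serum
   elevations are reported WT-based, as elevations of KO over WT.

The same machinery applies unchanged to serum analytes
(`compare_serum`), treating each analyte as the response.

## Synthetic data: what it emulates and what it does not

No raw data accompany the study, so a seeded forward model stands in:

    raw(s,i,j) = dark + illumination(i,j) · field_c(s,i,j) + ε,  clip ≥ 0

* **Tissue geometry**: per-slice ellipses with axes shrinking toward
  the end slices (an ellipsoid-like organ), giving a nontrivial mask
  boundary and genuinely empty end slices.
* **Illumination**: a centered 2D Gaussian vignette with configurable
  peak/edge ratio (default 1.3), normalized to unit mean — the typical
  arc-lamp pattern.
* **Noise**: additive Gaussian read noise (default SD 5 counts on
  ~1000-count signals) plus a constant dark level (100 counts);
  Poisson shot noise is available behind `poisson=True`.  The real
  sensor's noise distribution is not documented; Gaussian is the
  simplest model sufficient for validating the calibration algebra.
* **Within-tissue structure**: a shared lognormal brightness texture
  (CV 0.1) multiplying both channels (tissue structure affects both
  cofactor signals), plus an independent lognormal RR texture
  (CV 0.35, matching the magnitude of the observed voxel-level RR
  spread relative to its mean) applied to NADH only.  The realized RR
  texture is renormalized to tissue-mean 1, so each phantom's true mean
  RR equals its nominal value *exactly* — the manifest's
  `true_mean_rr` is an exact oracle, not an expectation.
* **Cohort structure**: per-animal true RR = genotype mean × a mean-1
  lognormal multiplier (lognormal keeps intensities positive).
  Genotype means default to the benchmark values (liver 2.59/1.77,
  kidney 0.85/0.69).  The genotype effect is carried by the NADH
  channel by default (`effect_channel="nadh"`): FAD levels are shared
  across genotypes, reflecting the observation that the RR difference
  is driven predominantly by lower NADH.  Between-animal CV defaults to
  0.15 (liver) and 0.45 (kidney): published spread values are ambiguous
  between voxel-level SD and animal-level SEM, so animal-level and
  voxel-level spread are *independent knobs*, with defaults chosen so
  that the liver comparison is reliably significant at N=8/group and
  the kidney comparison is borderline at N=18/group — the qualitative
  pattern the designs exhibited.
* **Serum panels**: young-adult preset with BUN +17.5%, glucose +23.8%,
  heart weight +11.5% and null analytes (cholesterol, insulin,
  creatinine) at N=10/group; aged preset with glucose +79.9% and a
  small cholesterol decrease (fold 0.93, a chosen value — the decrease
  is reported as significant but its size is not printed) at N=6/group.

The generator does **not** model optical physics (point-spread,
scattering, depth attenuation), microtome artifacts or tissue cracks,
spectral bleed-through between channels, or spatial autocorrelation of
the textures.  Passing the recovery tests therefore demonstrates that
the *algebra and statistics* of the pipeline are correct and unbiased
under realistic intensity structure — not that segmentation or
calibration would be robust to every artifact of real cryo-imaging
data.

## Numerical choices

* Phantom stacks default to 40 slices (full 200 available via
  configuration); the validation suite and acceptance script use
  12-slice 48×48 stacks and 11 cohort replicates, sizes at which the
  per-animal mean RR is already recovered to ~0.05 absolute and the
  full validation completes in under a minute.  Type-I-error rates use
  10,000 statistic-only replicates (no images).
* Otsu on a constant slice is undefined and treated as an empty slice.
* Degenerate histograms (all voxels equal) widen the range by a
  relative 1e−6 so the single bin still integrates to 1.
* The FAD floor is tied to the masked FAD median, making every RR
  statistic invariant under a common positive rescaling of both
  channels (verified to 1e−9).
* Per-animal seeds are spawned from the cohort seed via
  `numpy.random.SeedSequence`, so cohorts are reproducible
  animal-by-animal and all derived seeds stay below 2³¹.

## Known limitations

* RR is relative, not molar: no absolute cofactor quantification and no
  optical-property correction.
* The per-animal t statistic of the original liver comparison is not
  reproducible from published summary values under either reading of
  the printed spreads; the pipeline's own synthetic cohorts are the
  benchmark for the statistical machinery instead.
* Gain estimation across imaging sessions is an explicit input, not
  inferred; runs without calibration frames proceed with identity
  calibration and a warning.
* Segmentation assumes one dominant tissue component per slice and no
  anatomical substructure (cortex/medulla, lobes).
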
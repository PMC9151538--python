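# Methods

## The measurement model

The package treats an RF-ablation experiment as a 5 × 8 factorial design:
catheter contact angle ∈ {0, 30, 45, 60, 90}° × contact force
∈ {2, 4, 6, 10, 15, 20, 30, 40} gf, six replicate ablations per
condition (240 lesions).  Each lesion contributes two photographs: a top
view, from which area, axes and morphology class are measured, and a
bisected view (cut along the lesion diameter), from which maximum depth
below the tissue surface is measured.  The packaged reference tables
hold the per-condition mean ± SD of area (mm²) and depth (mm), and the
per-condition ratio of lesion area to catheter contact area; contact
area itself is recovered as `lesion_area / ratio`.  The recovery treats
the printed ratios as ratios of means — the contact-area measurements
came from a separate ink-transfer experiment and are not paired with the
ablation replicates — which is the convention under which the reported
contact-area log fits are recoverable to ±0.02.

## Morphometry pipeline

Steps, in execution order, with the conventions chosen where the
procedure admits more than one reading:

* **Calibration.** Explicit mm/px, or two annotated points with a known
  separation.  Row 0 is the image top; depth increases downward; a pixel
  belongs to the region whose inside-test its centre passes.
* **Segmentation.** Candidate lesions are 8-connected components of the
  thresholded frame with area ≥ 1 mm² (default), ordered by centroid row
  then column.  Touching lesions merge into one candidate — a documented
  limitation, not an error.
* **Grayscale.** Rec.601 luminance (0.299, 0.587, 0.114), divided by the
  frame maximum.  A fixed convention is required for reproducibility; no
  colour space was mandated by the procedure being reproduced.
* **40% threshold.** A pixel is lesion when its normalized intensity is
  ≥ 0.40 of the white level.  The alternative reading — a 40%
  local-neighbourhood fraction of white pixels — is noted but not
  implemented; the per-pixel cutoff is deterministic and reproduces
  hard-edge masks exactly.  Raising the threshold can only shrink the
  mask (tested invariant).
* **Hole filling.** Background components not reachable from the image
  border become foreground; the foreground never shrinks; idempotent.
* **Region measurement.** Area = pixel count × (mm/px)²; centroid = mean
  foreground pixel centre; major/minor axis lengths and orientation from
  normalized second central moments (ellipse-equivalent axes, the
  standard morphometric definition — not bounding-box extents).
* **Alignment.** Rotation about the canvas centre by the measured
  orientation, nearest-neighbour resampled and re-binarized at 0.5 so
  masks stay binary; area drift is bounded (≈0.1% observed, 1% contract)
  and alignment is idempotent.  Rotations below 0.5° are skipped.
* **Depth.** The tissue surface row is the median over columns of the
  first row whose normalized intensity clears a tissue/saline contrast
  threshold (default 0.15, configurable, optionally restricted to a
  lateral window).  Depth is the full pixel extent from the surface row
  to the lowest lesion row.  With pixel-centre rasterization the
  quantization error is about half a pixel, so bisected views intended
  for ≤2% depth error on shallow (≈1.7 mm) lesions should be imaged at
  ≤0.025 mm/px.
* **Morphology class.** On the aligned mask: *circle* when major/minor
  ≤ 1.15; otherwise *oval* when the half-area asymmetry about the
  midpoint of the vertical extent is ≥ 0.05; otherwise *ellipse*.  The
  asymmetry of the generator's egg curve is analytically 2·ovality/(3π),
  so the default oval (ovality 0.4) sits at ≈0.085, comfortably above
  the cut, and symmetric ellipses sit at 0.
* **Replicate summary.** Mean and sample SD (denominator n−1, matching
  the mean ± SD convention of the reference tables); the "average lesion
  morphology" is the pixelwise mean of centroid-registered aligned masks.

## Synthetic frames

The generator emulates the photographs, not the physics.  Lesions are
drawn from one parametric family: an ellipse whose local half-width is
modulated linearly along the major axis by an *ovality* factor
(half_width(u) = b·(1 + o·u/2a)·√(1−(u/a)²)).  The modulation is odd in
u, so the enclosed area is exactly π·a·b for every ovality — area
targeting is independent of shape class.  Contact angle maps to shape:
0° → 2:1 ellipse, 30/45/60° → 1.5:1 oval with ovality 0.4,
90° → circle; replicate areas and depths are log-normal with the
reference cell's mean and SD (moments matched exactly), and both
half-axes scale by a common factor so the drawn area is hit exactly.

Intensity model (8-bit): tissue 60, lesion core 230, saline 10, additive
Gaussian read noise (default SD 4), and a linear ramp of default width
0.4 mm centred on the true lesion boundary standing in for the
reversible-injury rim.  Because the 40% threshold of the white level
(intensity 92) sits below the ramp midpoint (145), thresholded masks of
rimmed lesions run ≈0.31 × rim-width outside the true boundary — a
known, deliberate bias that exercises the threshold on a graded border.
Noise-free, rim-free frames close the loop exactly: measured area is
within 1% of ground truth across the study's size range.  Default
working scale is 0.05 mm/px with auto-sized single-lesion frames
(multi-lesion frames up to 1200 × 800 px are supported); the rim width
and contrast are stipulations, not estimates, and no tissue texture,
specular highlights or colour charts are modelled — passing tests
demonstrate pipeline correctness on idealized photographs, not
robustness to real-world imaging artefacts.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give bit-identical frames, and every output records its seed.

## Statistics

* Pearson's r; two-sided p from the exact t distribution with n−2 df via
  t = r·√(n−2)/√(1−r²).  Spearman's r_s is Pearson on average ranks
  (tie-corrected) with the same transform; no permutation option.
* The sample for each correlation follows the convention that uniquely
  reproduces the reported coefficient/p pairs: force-vs-measurement uses
  the replicate-level reconstruction (n = 240); angle-vs-measurement and
  both ratio rank-correlations use the 40 condition-level values;
  contact-area-vs-lesion-area uses the 40 recovered/reported mean pairs.
* Balanced-design identity: with the predictor constant within cells and
  equal replicates n_c, the raw cross-product is n_c × the between-cell
  cross-product and the raw response SS is n_c × SS_between +
  Σ(n_c−1)·SD²; with n_c = 1 or all SDs 0 it degenerates exactly to the
  condition-mean Pearson (tested).
* Evans bands label |r|: <0.20 very weak, <0.40 weak, <0.60 moderate,
  <0.80 strong, otherwise very strong; exactly 0 → none.
* Fits are OLS, linear in x or in ln z, with R² = 1 − SS_res/SS_tot;
  model comparison takes the higher R², ties going to the simpler linear
  form.  Reported precision (4 decimals for r, 3–4 for fit
  coefficients) is applied only at the reporting layer.
* Group comparisons are pooled-variance Student t-tests (the named
  test), with angle groups pooling all forces; where only cell summaries
  exist, groups are expanded by a deterministic moment-matching
  construction (half the points at mean ± c·SD with c chosen so the
  ddof = 1 SD is exact).

## Scope of the reproduction report

The `reproduce` command flags the correlation table and the per-angle
contact-area log fits against their reported values with explicit
tolerances (±0.005 on replicate-level coefficients, ±0.001 on
condition-mean coefficients, ±0.02 on quantities limited by the
2-decimal rounding of the printed ratios).  Two reported quantity
families are deliberately *informational only*, because no convention
recoverable from cell summaries reproduces them: the per-angle
log-vs-linear R² values for the force fits (the means-only and
balanced-raw reconstructions bracket but do not match them), and the
lesion-area-on-contact-area linear coefficients (the recovered
condition means give a different slope).  Pairwise angle t-tests are
likewise informational: exact p-values need the raw replicates, though
the moment-matched reconstruction reproduces the qualitative
significance pattern (e.g. parallel vs perpendicular lesion area
differs at p < 0.05).

## Problem sizes in the test suite

Tests run on down-scaled frames (0.05 mm/px, auto-sized single-lesion
panels; 0.025 mm/px for bisected precision checks), 100-lesion recovery
sweeps, 1000-instance oracle-equivalence sweeps, and a 10⁴-draw Monte
Carlo check of the generator's area targeting — sizes chosen so the
whole suite completes in well under a minute while every contract is
exercised at full resolution-independent (mm-unit) tolerance.
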
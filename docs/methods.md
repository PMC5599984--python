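# Methods

## Signal model and T2 estimation

The package assumes monoexponential transverse decay, S(TE) = A·exp(−TE/T2),
sampled at exactly two echo times.  With two points the maximum-likelihood
and least-squares fits coincide with the closed form
T2 = (TE₂ − TE₁)/ln(S₁/S₂); no iterative fitting is involved and multiecho
(CPMG-style) estimation is deliberately out of scope.  Defaults follow a 3T
epilepsy protocol: TE 30/119 msec, coronal slices of 4 mm with ~0.43 mm
in-plane voxels.

The estimator is undefined for non-decaying voxels.  Policy: voxels with
S₁ ≤ 0, S₂ ≤ 0 or S₁ ≤ S₂ are *masked* (validity mask, NaN in the map)
rather than clamped or raised on, because such voxels are expected in
background and at low SNR and must simply drop out of downstream
statistics.  A configurable ceiling (default 3000 msec, comfortably above
CSF at 3T) also marks voxels invalid so that near-flat decays cannot
produce arbitrarily large finite values.  Computation is double precision;
on disk maps are float32 with a uint8 companion mask.

Under magnitude (Rician) noise the log-ratio estimator is positively
biased.  The test suite quantifies this by Monte-Carlo: at late-echo
SNR ≥ 50 the bias is below 1% of true T2 for hippocampal values; at SNR ~ 5
the positive bias is gross.  This motivates measuring on a few hundred
pooled voxels rather than single voxels.

## ROI chain

Order is fixed: resample → erode → CSF-exclude → summarise.

* **Resampling** is nearest-neighbour pull-back (each reference voxel
  centre mapped through the inverse world transform into the source grid),
  which can never invent fractional labels.  Rigid transforms are read as
  4×4 plain-text matrices in source-world → target-world convention; an
  `--invert-transform` flag covers tools that store the reverse.
* **Erosion** defaults to one iteration with a 3×3 in-plane square
  element.  With 4 mm slices and sub-millimetre in-plane voxels, 3-D
  erosion would eat whole slices from the anterior/posterior ends of the
  structure; in-plane erosion shaves the lateral boundary where the CSF
  interface lies.  A `full-3d` mode (6-connected cross) exists for
  isotropic data.
* **CSF exclusion** removes voxels with fitted T2 strictly above the
  threshold (default 170 msec) or with invalid fits.  The comparison is
  strict: a voxel at exactly the threshold is retained.
* **Summary** is the voxel-pooled mean and SD (n−1 denominator) over all
  retained valid voxels across slices — not a mean of per-slice means.
  The per-slice view is exposed separately as an anteroposterior profile
  (slices ordered by ascending index along the slice axis), whose
  count-weighted mean equals the pooled mean by construction.
  Measurements with fewer than `min_voxels` (default 20, a degeneracy
  guard) retained voxels are flagged unreliable; an empty ROI is an error
  naming the label.

## CSF threshold calibration

The shipped 170 msec cutoff suits the default protocol.  For other
scanners the cutoff can be re-derived from control data: T2 samples are
pooled per tissue class from a tissue segmentation (hard labels; when
probability maps are supplied, only voxels with p > 0.9 are used, keeping
partial-volume voxels out), and the cutoff minimises the equal-weight
misclassification loss — fraction of gray matter above the cutoff plus
fraction of CSF below it — on a 1 msec grid between the class medians,
ties broken toward the lower candidate.  Calibration is pooled across
subjects, requires ≥ 100 samples per class, and refuses non-separated
medians.  Note the equal-weight loss favours the *low* end of any
zero-loss gap; on well-separated data any value in the gap (the shipped
170 msec included) is equivalent under this loss.

## Volumetry and cohort statistics

ICV correction uses the regression-residual method: an OLS slope b of
volume on ICV fitted in controls, then corrected = raw − b·(ICV − mean
control ICV).  Centering at the control mean keeps volumes in cm³, leaves
the control mean unchanged and makes corrected control volumes exactly
uncorrelated with ICV.  Left and right hippocampi share one pooled model.

Reference ranges are mean ± 1.96 SD of controls, reported at 0.1 msec /
0.01 cm³ precision.  The bilateral range combines sides with the exact
concatenation moments ((n−1)(s_L²+s_R²) + n((m_L−m)² + (m_R−m)²))/(2n−1),
the only pooling consistent with treating both sides as one sample.

Classification is per-side binary logistic regression on corrected volume
and mean T2 (each alone and combined), fitted by IRLS (tolerance 1e-8 on
the largest coefficient change, cap 100 iterations).  Perfect separation
makes the likelihood unbounded; the model is then returned at the
iteration cap with `converged=False` rather than raising.  The decision
threshold is 0.5.  Labelling convention: a left hippocampus is pathologic
in left-sided and bilateral disease and nonpathologic in controls and
right-sided disease, mirrored on the right; this is configurable through
the group sets in `reference_data`.  Group comparisons are two-tailed
pooled-variance t-tests; no multiple-testing correction is applied.
Scan-rescan agreement reports the mean and SD (n−1) of paired differences,
limits of agreement at ±1.96 SD, a paired t-test and Pearson r.

## The phantom generator: what it does and does not emulate

`generate_phantom` builds, on a default 128×128×32 grid at 0.43×0.43×4 mm
(a 4× in-plane downscale of the 512×512 acquisition matrix, keeping test
runtimes in seconds), a brain ellipsoid with a white-matter core and
gray-matter rim, two ≥ 500-voxel hippocampal ellipsoids with their long
axis along the slice direction, a one-voxel CSF sheet 6-adjacent to each
hippocampus, and a gray-matter cuff outside the sheet.  Default T2: WM 80,
GM 110, hippocampus 115, CSF 2000 msec; proton densities 700/800/800/1000.
Echo images follow the forward model with independent Rician noise per
echo (default σ = 5, late-echo hippocampal SNR ≈ 55, typical of 3T fast
spin echo).  The returned segmentation overreaches one dilation step into
the CSF sheet, emulating a structural-image segmentation whose boundary
straddles the interface — so CSF partial-volume contamination is present
by construction, and the noiseless chain must remove it exactly to pass.
All generators are pure functions of their seed.

What it does **not** emulate: realistic anatomy or partial-volume mixing
(compartments are pure, interfaces are sharp), B1/flip-angle effects,
stimulated echoes, motion beyond placement jitter, or k-space artifacts.
Consequences worth keeping in mind when reading test results: (1) passing
phantoms shows the chain is correct, not that scanner data will be as
clean; (2) the sharp hippocampus/CSF interface makes any CSF inclusion
maximally costly, so the simulated *manual* method's error is exaggerated
relative to real raters reading smoothly mixed boundaries — the
scan-rescan experiment therefore validates the *direction* (automated
interscan SD below manual), not the magnitudes.

The manual-measurement emulation places a ~20 mm² ellipse per coronal
slice at the structure centroid plus Gaussian placement jitter (default
1 mm SD per in-plane axis).  The ellipse copies the cross-section's own
shape scaled to the target area (shrunk 10% for discretisation safety),
and slices whose cross-section is under 1.5× the ROI area are skipped —
both choices mimic how raters mould and place small ROIs to avoid CSF.
ROIs are placed on the true structure (a rater reads anatomy, not the
automated segmentation).  With zero jitter on a noiseless phantom the
emulated manual value equals truth exactly; jitter produces the
characteristic upward CSF bias.

The cohort generator draws per-hippocampus (corrected volume, mean T2)
rows from per-group Gaussians; the defaults are the bundled normative
group statistics (controls n=50, left HS n=27, right HS n=18, bilateral HS
n=5).  Left/right values within a subject are correlated at 0.3 — a
realism choice, not a fitted quantity; within-side volume and T2 are drawn
independently.

## Simulation sizes and numerical choices

* Scan-rescan: 200 pairs on a 96×96×24 phantom, σ = 5, segmentation
  repositioned by a uniform integer offset in {−1,0,+1}³ per scan, manual
  jitter 1 mm.
* Classification: 200 cohorts at the normative group sizes; mean training
  accuracy of the combined two-feature models is reported per side
  (typically ≈ 98%, comfortably above the 90% floor the tests assert).
* Calibration, fit accuracy and CSF-exclusion checks run on single 96×96×24
  phantoms.
* Oracle cross-checks: resampling and erosion against per-voxel
  brute-force loops on ≤ 32³ grids; IRLS against a BFGS likelihood
  maximiser (agreement to 1e-6); the t-test's type-I error against 10⁴
  null replicates.
* Tie-breaks and edge cases: calibration ties go to the lowest grid
  candidate; SD of a single voxel is reported as 0 with the measurement
  flagged unreliable; a paired comparison with identical differences
  returns t = 0, p = 1 (offset-free) or an infinite t (constant offset).

## Known limitations

* Dual-echo T2 is sequence-dependent; values are not comparable across
  protocols, and the 170 msec cutoff and normative ranges travel with the
  acquisition, not with the method.
* The two-point fit cannot detect multicomponent decay or fit failures
  beyond the validity rules.
* Rigid-transform *estimation*, hippocampal segmentation and tissue
  segmentation are external inputs by design.
* The bundled normative statistics describe one scanner and cohort;
  studies on other hardware should refit ranges and classifiers from their
  own controls (`cohort-stats`, `calibrate-threshold`).
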
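# Methods

## The quantification problem

Magnetic particle imaging (MPI) detects superparamagnetic iron oxide
(SPION) tracers directly: voxel intensity is linear in local iron mass
and there is no tissue background. Quantifying a SPION-labeled graft
therefore reduces to (i) deciding which voxels belong to the tracer
signal and (ii) converting the summed intensity of those voxels into
micrograms of iron. `mpiquant` does this with per-slice k-means++
intensity clustering, connected-component separation of fiducial markers
from the graft, and a fiducial standard curve; the result is a total
iron value (TIV, µg) per scan.

## Segmentation model

Each slice of the volume (axis 0, 32–36 slices in a typical scan) is
clustered independently on pixel *intensity* alone with k-means++ and
k = 4 centroids. Four tiers match the structure of an MPI slice —
background, two shells of partial-volume signal, and core — and k = 4 was
selected by the elbow method (`elbow_select_k` reimplements that
selection: it fits k over a range and picks the greatest curvature of
the WCSS–k curve on a log scale; on the raw scale the second difference
is dominated by the first, largest drops and misses elbows that bottom
out near zero).

The ROI of a slice is the single brightest cluster (`top1`). This
captures only the core of a blurred source — typically 50–90 % of its
mass — which is acceptable *because the fiducial markers are segmented by
exactly the same procedure*: the capture fraction enters both the
numerator (graft sum) and the calibration slope and cancels. Two
implementation details protect this cancellation:

* **Shared per-slice RNG streams.** `segment_volume` clusters every
  slice with an identical generator state. k-means++ seeding and Lloyd
  updates are scale-covariant, so two slices that differ only in overall
  amplitude receive identical masks, making the capture fraction
  amplitude-invariant. (With independently spawned streams, occasional
  different local optima broke capture equality at the few-per-mil
  level.)
* **Sorted centroids.** Centroids are sorted ascending after fitting, so
  "cluster k−1" is always the brightest — a stable contract for the
  selection policy. Assignment ties go to the lower cluster index.

`topm:<m>` (the m brightest clusters) is available for scenes where a
bright fiducial shares slices with a much dimmer graft and would absorb
the whole top cluster; the default phantom layout avoids that geometry,
and in development comparisons `top1` was both the most noise-robust and
the most linear policy.

Two guards handle noise; both vanish identically on noise-free volumes:

* **Signal floor.** Slices whose brightest centroid falls below
  6 × a noise-scale estimate yield an empty mask. Without it, k-means on
  a signal-free slice promotes the upper noise tail into the ROI. The
  noise scale is the 90th percentile of the volume divided by
  Φ⁻¹(0.9) = 1.2816 — exact for a zero-clipped Gaussian background,
  robust to the few percent of bright signal voxels, and exactly zero for
  mostly-zero (noise-free) volumes. The factor 6 keeps the gate several
  standard deviations above the largest order statistic of ~10⁵
  background voxels.
* **Minimum component size** (pipeline default 5 voxels, 26-connectivity)
  removes isolated noise voxels that survive the floor on slices that do
  contain signal.

Fiducial/graft separation is spatial, not intensity-based: connected
components of the 3-D ROI mask are greedily matched (nearest first) to
the expected fiducial positions within each marker's search radius
(default 5 voxels); every unmatched component is graft. A fiducial with
no component in range aborts quantification — a calibration against a
missing marker would be silently wrong.

## Calibration and TIV

The three fiducial markers are dilutions of VivoTrax stock (5.5 mg/ml
iron) at 10, 20 and 40 % in 1 µl, i.e. 0.55, 1.10 and 2.20 µg of iron
(mg/ml × µl = µg). Their segmented 3-D pixel sums x_i against known
masses y_i give the standard curve by least squares. The default mode
forces the line through the origin (slope = Σxy/Σx²): zero signal means
zero iron, and only a zero intercept makes the per-slice TIVs sum
independently of how the graft mass is partitioned across slices.
Intercept mode is retained for fidelity experiments; negative per-slice
predictions there are clamped to zero with a warning.

Per-slice graft pixel sums are mapped through the curve and summed over
all slices to the scan's TIV. The alternative *ratio method* multiplies
the ratio of graft to reference-fiducial pixel sums by the reference
mass (the 40 % marker, 2.2 µg); it equals an origin-mode curve fitted to
that single point, and both methods agree on well-formed scans.

## Synthetic phantoms

No scanner data is deposited for this problem, so the generator is the
test bed. It emulates exactly the properties the pipeline relies on and
nothing more:

* each iron source deposits a delta at its voxel, scaled by
  `signal_per_ug` (default 1000 intensity units/µg — arbitrary, since
  calibration divides it out), then the scene is blurred with a Gaussian
  PSF (default σ = (1.0, 1.5, 1.5) voxels (z, y, x)). The discrete kernel
  is normalised, so an interior blob's voxel sum equals
  `signal_per_ug × iron_ug` exactly; blobs near edges lose the truncated
  kernel mass. No drive-field physics or x-space reconstruction is
  simulated — signal linearity is assumed, not derived;
* noise is applied after the blur: per-voxel multiplicative Gaussian
  (CV 1 %), then additive Gaussian (SD 0.5 % of the peak noise-free
  fiducial intensity), then clipping at zero. The defaults are modest by
  design: MPI phantom scans are high-SNR, and the reported phantom
  linearity is only achievable under low noise;
* default grid 36×64×64 (z, y, x), inside the 32–36-layer range of real
  scans; 1 mm isotropic voxels;
* the three fiducials sit at fixed positions along one edge (y ≈ 8),
  each in its own z-slab (z ≈ 5, 13, 21), and the graft occupies its own
  slab (z ≈ 29, centred in-plane). The same layout in every scan mirrors
  the fixed marker placement on a scanner bed, and the slab separation
  means no slice mixes sources of very different brightness — the
  geometry under which the `top1` policy and the capture-fraction
  cancellation are exact;
* the phantom dilution series places one graft source of
  `count × iron_per_organoid_ug` (default 0.01 µg/organoid — the
  per-organoid loading is not a published quantity, so it is an exposed
  free parameter at a plausible scale) for counts 0–400; the
  longitudinal series prescribes a TIV per imaging day, defaulting to
  {day 1: 4, day 7: 5, day 28: 2} µg — a rise from day 1 to 7 followed
  by a fall by day 28, the pattern seen in graft monitoring.

What the generator does **not** emulate — and what passing tests
therefore do not show: reconstruction artefacts and streaks, non-Gaussian
or spatially correlated noise, PSF anisotropy beyond a fixed σ,
partial-volume effects of extended (non-point) sources, animal motion,
and background signal from liver uptake of the tracer. Results on real
scans depend on those factors; the synthetic suite validates the
algorithmic chain, not scanner performance.

## Agreement statistics

Rater-vs-algorithm validation uses the intraclass correlation for a
two-way model with absolute agreement — McGraw & Wong's ICC(A,1) and
ICC(A,k), the variant SPSS labels "two-way mixed, absolute agreement".
From the two-way ANOVA decomposition of an n×k ratings matrix (MSR
between subjects, MSC between raters, MSE residual):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))
    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

with F = MSR/MSE on (n−1, (n−1)(k−1)) degrees of freedom for the test of
"true value 0", and 95 % confidence intervals from the McGraw–Wong
formulas with a Satterthwaite-approximated denominator df; average-
measures bounds are the Spearman–Brown step-up of the single-measures
bounds. A constant matrix raises (ICC undefined); identical but
non-constant rater columns give ICC 1 with a degenerate CI. The
implementation is cross-checked in the test suite against pingouin's
ICC(A,1)/ICC(A,k) on random matrices to 1e-8.

Phantom linearity is summarised by OLS of estimated TIV on organoid
count (slope, intercept, R², two-sided slope p-value).

## Numerical choices and degenerate inputs

* k-means: n_init = 10 restarts (20 in the small-instance oracle tests),
  max_iter = 300, convergence when the largest centroid shift is below
  1e-6 of the data range (range-relative, hence affine-invariant); empty
  clusters are re-seeded at the point farthest from its centroid. Fixed
  default seed 42 everywhere for reproducibility; all seeds overridable.
* A slice with fewer distinct values than k falls back to the largest
  feasible k and is flagged; an all-zero slice yields an empty mask.
* Degenerate calibrations (all pixel sums equal or zero, non-positive
  slope) raise rather than warn: a wrong standard curve corrupts every
  downstream number.
* Scan axes are (z, y, x) with slice = axis 0 end to end; intensities are
  never rescaled on load. NIfTI is the reference format; DICOM support is
  read-only single-frame series sorted by instance number.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
six-scan dilution series and three-scan longitudinal series on the
36×64×64 default grid (a series quantifies in ~15 s), 200 random
small instances for the exhaustive k-means oracle, and 50 random
matrices for the ICC reference comparison. The paper-scale in-vivo
ICC values and the phantom-vs-ICP-OES comparison require scanner data
that was never deposited and are out of scope.

## Known limitations

* The per-slice capture-fraction cancellation assumes sources of similar
  in-plane extent; a graft much larger than a fiducial tube would have a
  different shell-to-core ratio and a small systematic bias that the
  curve cannot cancel.
* The signal floor's quantile estimator assumes background occupies the
  large majority of voxels; volumes dominated by signal would
  overestimate the floor and gate real slices.
* Fiducial matching uses unweighted component centroids; strongly
  asymmetric truncation at volume edges could shift a centroid outside
  the search radius.
* `elbow_select_k` requires at least three k values and reports only the
  curvature maximiser; inspect the returned curve rather than trusting a
  single number on unfamiliar data.
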
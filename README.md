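# mpiquant

Quantification of superparamagnetic-tracer signal in 3-D magnetic
particle imaging (MPI) scans: per-slice **k-means++ segmentation** of
tracer signal, **fiducial-marker standard-curve calibration**, and
**total iron value (TIV)** estimation for SPION-labeled cell grafts —
plus a synthetic phantom generator and the agreement statistics used to
validate the pipeline against human raters.

It is aimed at preclinical imaging groups tracking labeled cells (islet
organoids, stem-cell grafts, CAR-T products) with MPI, where the signal
is linear in iron mass and quantification means turning segmented pixel
sums into micrograms of tracer iron.

## Method in brief

Each slice z of a scan is clustered on pixel intensity with k-means++
(k = 4; D²-weighted seeding, Lloyd iterations, best of 10 restarts) and
the brightest cluster forms the slice ROI. Connected components of the
3-D ROI mask are matched to the expected positions of three fiducial
markers — dilutions of VivoTrax stock (5.5 mg/ml iron) at 10/20/40 % in
1 µl, i.e. 0.55/1.10/2.20 µg iron; the remaining components are the
graft. The fiducial pixel sums x_i and known masses m_i give the
standard curve through the origin,

    m = s · x,   s = Σ x_i m_i / Σ x_i²,

and the graft's per-slice pixel sums mapped through the curve and summed
over all slices give the scan's TIV in µg. A single-fiducial *ratio
method* (graft sum / reference-fiducial sum × 2.2 µg) is provided as the
manual-rater convention. Agreement between raters/algorithms is measured
by the two-way absolute-agreement ICC (McGraw–Wong A,1 and A,k) with F
test and 95 % confidence intervals. See `docs/methods.md` for the full
model, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from mpiquant import (PhantomConfig, default_fiducials, make_phantom_series,
                      quantify_scan, linear_regression)

fids = default_fiducials()
counts = [0, 25, 50, 100, 200, 400]
series = make_phantom_series(counts, iron_per_organoid_ug=0.01,
                             config=PhantomConfig(rng_seed=1))
tivs = []
for (scan, truth), n in zip(series, counts):
    res = quantify_scan(scan, fids, seed=1)
    tivs.append(res.tiv.total_tiv_ug)
    print(f"count {n:4d}: true iron {truth.total_graft_iron_ug:.3f} ug, "
          f"estimated TIV {res.tiv.total_tiv_ug:.4f} ug")
reg = linear_regression(np.asarray(counts, float), np.asarray(tivs))
print(f"TIV vs organoid count: R^2 = {reg.r_squared:.5f}")
```

prints

```
count    0: true iron 0.000 ug, estimated TIV 0.0000 ug
count   25: true iron 0.250 ug, estimated TIV 0.2611 ug
count   50: true iron 0.500 ug, estimated TIV 0.4215 ug
count  100: true iron 1.000 ug, estimated TIV 1.0236 ug
count  200: true iron 2.000 ug, estimated TIV 1.9966 ug
count  400: true iron 4.000 ug, estimated TIV 3.9991 ug
TIV vs organoid count: R^2 = 0.99944
```

Six phantoms containing 0–400 labeled organoids (0.01 µg iron each) are
rendered with realistic noise, quantified blind to the ground truth, and
the estimated TIV tracks the loaded iron linearly — the phantom
experiment that establishes MPI's quantitative linearity, here run
entirely in software.

The same pipeline is available from the shell:

```sh
mpiquant simulate phantom-series --counts 0,25,50,100,200,400 --seed 1 --out-dir scans/
mpiquant quantify --input scans/phantom_0100.nii.gz \
                  --fiducials scans/fiducials.json --out report/
mpiquant validate-icc --ratings ratings.csv --out icc.json
```

`quantify` writes `report.json` (standard curve, per-slice pixel sums
and TIVs, total TIV, cluster diagnostics), `slices.csv`, and ROI/graft
masks aligned with the input volume.

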
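# Methods

`choroquant` quantifies the choroid on radial SS-OCT B-scans — boundary
segmentation, Niblack binarization, radial volumetrics and repeatability
statistics — and pairs that pipeline with a synthetic acquisition simulator
so the effect of B-scan frame averaging on the derived parameters can be
studied end to end without patient data.  This note describes the models,
the defaults and why they are what they are, and what the synthetic results
do and do not demonstrate.

## The measurement pipeline

**Geometry.** A scan session is an 18-line radial pattern through the
fovea: angles 0°–170° in 10° steps, 9 mm wide, 3 mm deep, with native
sampling of 6.3 µm axially and 20 µm laterally.  Metrics integrate over the
6-mm-diameter fovea-centred disc.

**Segmentation.** The upper choroidal boundary (RPE–Bruch's membrane
junction) is the lower edge of the brightest ridge: a shortest-path search
(exact dynamic program, at most `max_jump` = 2 rows of movement per column)
over a brightness cost built from the CLAHE-enhanced image, smoothed only
laterally so the thin RPE band is not diluted into the much broader bright
sclera.  The lower boundary (choroidal–scleral interface, CSI) is a second
shortest path over a dark-to-bright vertical-gradient cost, restricted to a
window 50–800 µm below the upper boundary.  The CSI stage runs on the raw
display image: adaptive equalisation renormalises local contrast, which
would decouple the edge evidence from the physical signal-to-noise ratio of
the scan.

Because the scleral side of the interface is textureless while the choroidal
side is vessel texture, the gradient cost is smoothed anisotropically
(80 µm axially × 1000 µm laterally) and the path is given a constant
localisation offset (+11 µm) that recentres the smoothed gradient peak onto
the interface; both are calibrated on noise-free sections (residual error
≈ 0.2 px RMS).

**Edge confidence.** An ideal shortest path integrates contrast across all
columns and therefore finds the interface even when it is far below the
noise floor — something no human grader or practical algorithm does.  The
CSI call therefore carries an explicit confidence model:

* pixel noise is estimated from lateral first differences in the sclera
  just below the detected path (structure-free, so the estimate tracks
  speckle and read noise and falls as 1/√N under N-frame averaging);
* the speckle grain is estimated from the lag-1/lag-2 autocorrelation
  ratio of the same patch (the ratio cancels any white-noise floor), and
  the pixel-level estimate is propagated through the smoothing/derivative
  kernel to a gradient-noise SD;
* if the median per-column gradient drop one pixel above the path is
  within `csi_confidence_kappa` (= 0.68) of that noise level, the
  interface is judged indistinct and the whole boundary is re-called
  conservatively: each column walks up while the gradient stays within the
  confidence width, and the path is shifted up coherently by the median
  walk (bounded by 2 px).  A scan-level flag (`low_confidence`) records
  the re-call.

This gate is what reproduces, in simulation, the clinical observation that
poorly averaged scans read systematically thinner: at 4 averaged frames
most scans are re-called conservatively, at 8 about half, at 16 and above
almost none — so thickness and the volumes climb with averaging and then
plateau.  The choice of κ is part of the shipped calibration (below).

**Binarization.** Niblack's local threshold T = m + k·s with a 31 px
window (native scale) and k = −0.1, computed with exact box-filter window
statistics (reflect padding), on the raw display image.  Pixels strictly
below their local threshold are luminal; the strict inequality sends
constant regions to stroma.  k is kept mildly negative (dark-object
convention): at k = −0.2 the speckle-inflated window SD at low averaging
moves the threshold enough to make the vascularity index itself
level-dependent, which the source data contradict.

**Volumetrics.** Areas are pixel counts times pixel area inside the ±3 mm
window.  Volumes use the polar sector quadrature natural to radial scans:
each scan contributes two half-meridians, V = Δθ·Σ_m ∫ f_m(r)·r·dr with
Δθ = 2π/36, f = thickness for TCV and f = lumen column height for LV
(trapezoid rule anchored at the pole, which carries zero weight).
SV = TCV − LV by definition and CVI = LV/TCV.  CT is the uniform-in-r mean
of the thickness profile — the subfovea-weighted summary that matches how
radial patterns sample the macula — rather than the area-weighted mean
TCV/(πR²).

**Statistics.** Within-subject SD is the rooted two-replicate ANOVA
within-mean-square, Sw = √(mean d²/2); CoR = 1.96·√2·Sw (for CVI reported
in percentage points, i.e. computed on CVI×100); ICC is the two-way
absolute-agreement single-measurement form (McGraw–Wong A,1; a config
switch to the consistency form C,1 is not provided because intra-observer
absolute agreement is the question being asked); Bland–Altman limits are
d̄ ± 1.96·SD(d) with a t-based CI for d̄.  The averaging comparison is a
one-way repeated-measures ANOVA on per-eye repeat means (no sphericity
correction) with Bonferroni-corrected paired t-tests; the "plateau" of a
parameter is the smallest level above which no adjusted pairwise
comparison is significant at 0.05.

## The synthetic eye and acquisition model

**Phantom.** Per eye, mean choroidal thickness ~ N(288, 65²) µm truncated
above 100 µm and luminal volume fraction ~ N(0.62, 0.03²) truncated to
(0.3, 0.9).  Thickness over the field is a foveal dome with a mild
horizontal tilt times a per-eye random low-order harmonic texture (RMS 4%)
— the texture is what makes two mounts at slightly different cyclotorsion
angles disagree.  Vessel lumina are ellipses attached to the 36
half-meridians of the radial pattern ("wagon wheel"), in three strata:
small vessels in the inner third, mid-depth vessels above 0.9 of the
thickness, and wide flat vessels resting on the basal margin the way
Haller's vessels rest on the sclera.  Lumina are added (with overlap,
union-counted) until the analytic luminal fraction over the 6 mm disc
matches the eye's draw within ±0.01.  All per-eye truths (LV, SV, TCV, CT,
CVI) come from the same sector quadrature evaluated analytically on the
geometry; a brute-force polar voxelisation serves as the test oracle.

**Reflectivity.** Amplitudes (vitreous 0.05, retina 0.35, RPE 0.95,
stroma 0.55, lumen 0.12, sclera 0.75, arbitrary units) make the RPE the
brightest band and the choroid–sclera contrast modest.  Below the RPE the
signal decays with a 600 µm 1/e depth — without attenuation the interface
contrast never becomes noise-limited and averaging would have nothing to
improve.

**Speckle and averaging.** Fully developed speckle: intensity
I = S²·E with E unit-mean exponential, spatially correlated over ~2 px,
plus additive read noise, clipped at zero.  N-frame averaging is a plain
mean of independent frames, so homogeneous-region contrast falls as 1/√N.
Display is log-compressed, D = log(1 + I/0.01), rescaled to [0, 1].

**The mount model.** The within-subject error of disc-integrated metrics
cannot come from small fixation jitter — the integrals average thousands of
columns, and rotating angular harmonics integrates to zero over a full
disc.  What real repeats change is the *quality* of the mount, coherently
across all 18 lines.  Each measurement (one chinrest mount) draws:

* a cyclotorsion offset (SD 4°) that resamples the thickness texture and
  the nearest vasculature meridian;
* a frame-registration efficiency (N_eff = N × clip(N(0.85, 0.16²)),
  floor 0.5) — imperfect alignment of the averaged frames;
* a focus/tear-film factor on the speckle grain (SD 0.45);
* an illumination gain on the whole reflectivity map (SD 0.18);
* a lumen reflectivity factor (SD 0.25; blood scattering varies);
* plus a per-line lateral fixation offset (SD 40 µm).

These drive the boundary-confidence gate and the binarization margins
coherently per mount, producing test–retest variability of the realistic
size (CoR of CVI ≈ 1 percentage point) while between-eye variance stays an
order of magnitude larger (ICC ≥ 0.97).

**Exclusion gate.** Each acquisition gets a 0–10 signal-strength index,
10·clip(1 − σ_bg/0.25, 0, 1) from the residual SD of the vitreous rows;
acquisitions under 6 are re-drawn with a fresh seed, mirroring clinical
practice.  Under the default calibration exclusions are rare.

## Calibration

The defaults above are a calibration, not a physical-fidelity claim: they
were chosen so that the simulated study reproduces the qualitative findings
of real frame-averaging experiments — CVI indifferent to averaging; LV,
TCV and CT depressed at 4 and 8 frames and stable from 16; SV stable from
8 — at the published relative magnitudes (thickness ≈ 7% low at N=4,
≈ 3% at N=8).  `scripts/calibrate.py` re-runs the neighbourhood of the
shipped values over a grid of the three most influential dials (speckle
correlation, confidence width κ, registration-efficiency spread) and ranks
candidates by distance to the published R4/R8-to-plateau ratios.  The
plateau findings are statistical statements about borderline Bonferroni
comparisons, so their reproduction is itself stochastic: under the shipped
calibration the stromal-volume plateau lands at 8 frames for most master
seeds but can land at 16 when an 8-versus-high-level comparison crosses
p = 0.05.

## Problem sizes

The default study uses 22 eyes × 2 repeats × 5 levels × 18 radial lines at
half resolution (12.6 × 40 µm pixels, 238 × 225 images) — 3,960 averaged
acquisitions, about 6 minutes on one core.  Full resolution is a config
change (`scale = 1.0`) and roughly 8× slower.  Phantom truths use a 5 µm
radial quadrature step; halving the step changes volumes by well under
0.5%.

## Numerical conventions

Rows are depth (increasing downward), columns lateral; 0-based indices;
the choroid is the half-open row interval [upper, lower).  The shortest
path breaks ties toward the smaller row index, making segmentations
reproducible bit-for-bit.  All randomness flows from a single master seed
through named `SeedSequence` streams (`[master, 0]` cohort; `[master, 5,
eye, repeat, level]` mount; `[master, eye, repeat, level, angle, attempt]`
acquisition), so any scan can be regenerated in isolation and study
outputs are byte-stable.

## Known limitations

* The phantom's layering is minimal (one retina slab, a three-row RPE
  band); the boundary detectors exploit exactly the contrasts the phantom
  provides, so passing tests demonstrate internal consistency of the
  pipeline and the plausibility of the averaging mechanisms — not accuracy
  on real scans.
* Absolute volumes are integrals over the stated 6 mm disc; published
  device outputs for the same cohort sizes are several-fold larger and are
  deliberately not matched (the device integration region is unknown).
* CLAHE's tile grid is anchored to the image, so exact
  translation-equivariance holds only for the core searches (tested with
  enhancement disabled).
* Frames within one acquisition are independent given the seed; there is
  no frame-to-frame decorrelation or motion model beyond the single mount
  offset, and no eye-motion/fatigue trend at long scan times.
* The comparison *between* reliability values across averaging levels
  (whether CoR itself changes with N) is reported but not tested
  inferentially.
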
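# Methods

## Radiometric model

A radiometric LWIR sensor in TLinear mode encodes absolute scene
temperature linearly in its pixel counts:

    T[K] = ρ · c,        T[°C] = ρ · c − 273.15

with resolution ρ = 0.01 K/count by default (the high-gain dialect: count
30000 ↔ 300.00 K ↔ 26.85 °C); ρ is configurable for the 0.1 K/count
low-resolution dialect some sensors use. Counts are stored as unsigned
16-bit integers — centikelvin values for body temperatures (~31 000)
exceed the 14 bits of the sensor's raw flux mode, and the worked value
above requires the larger container. Frames whose TLinear flag is off
carry scene flux, for which no temperature model exists; every conversion
refuses them rather than guessing. No emissivity, reflected-temperature or
atmospheric correction is applied: skin emissivity is close to unity at
bedside distances and the acquisition protocol holds ambient conditions
fixed, so the linear model is used as the sensor reports it.

The inverse map `counts = round((T + 273.15)/ρ)` quantizes to the nearest
count; a round trip through Celsius is exact for integer counts, and any
Celsius value is reproduced to within ρ/2 (±0.005 °C at the default
resolution). That quantization bound recurs as the tolerance of several
phantom-recovery tests.

## Planar registration

The IR and color cameras view an approximately planar scene, so their
views are related by a 3×3 projective homography. Estimation is a direct
linear transform with Hartley normalization (each point set translated to
zero centroid and scaled to RMS radius √2 before the SVD solve) — the
normalization matters because the two frames differ by roughly a factor 4
in scale, which otherwise conditions the design matrix badly. A projective
(8-DOF) model is used rather than affine: it subsumes affine and matches
planar-scene superposition. Degenerate (rank-deficient, e.g. collinear)
configurations are detected from the second-smallest singular value and
rejected. No lens-distortion model is included.

An optional robust mode runs a seeded random-minimal-sample consensus
(4-point samples, 500 trials, 2 px reprojection inlier threshold) before
the final least-squares fit, for corner sets contaminated by gross
detection failures. Registration quality is reported as the reprojection
RMSE of the fitted correspondences.

Warping inverse-maps each output pixel through the homography and samples
the source with nearest or bilinear interpolation (scikit-image backend);
out-of-source locations receive a declared fill value. The documented
default direction is IR → RGB; the inverse transform is a first-class
object, so the opposite direction is equally available.

Coordinate convention everywhere: pixel centers at integer coordinates,
origin (0, 0) top-left, x rightward, y downward.

### Checkerboard corner detection

No installed library provides a checkerboard detector, so the package
carries one designed for rendered/binarized boards: inner corners are
saddle points of intensity, localized by a determinant-of-Hessian saddle
response (Gaussian pre-smoothing, σ = 1.2 px), picked as the rows×cols
strongest peaks, refined to sub-pixel precision with the Förstner
corner refiner, and ordered into a row-major grid by fitting a unit-grid
homography through the four extreme detections. Ordering uses point
geometry only, so the printed (color) and contrast-inverted (thermal)
renderings of the same pose yield identical orderings. The grid origin is
the extreme corner nearest the image origin, which resolves the board's
180° ambiguity deterministically for the poses the phantom generates; on
synthetic boards the detector achieves ~0.1 px RMS. Performance on natural
photographs (strong blur, perspective foreshortening, clutter) is not a
design goal — field calibrations used dedicated calibration software, and
this detector exists to close the loop on synthetic imagery.

## Temperature sampling, gradients and profiles

Landmark temperatures are window aggregates over an odd square window
(default 3×3): the **median** for skin and limb points, robust to isolated
artefact pixels, and the **maximum** for the inner canthus, which is a
small local hot spot in a 160×120 frame and is conventionally read at its
hottest pixel; `window=1` reproduces single-pixel manual reads. The caller
chooses the core label — `inner_canthus` normally, `thorax` when the eyes
are obstructed — and the result records which label produced θ_c. Note the
canthus maximum is upward-biased under sensor noise by roughly the
expected maximum of 9 i.i.d. Gaussian deviates (~1.5 σ ≈ 0.07 °C at 50 mK);
noiseless phantom tests are unaffected, and real reads share the bias with
the manual hottest-pixel convention.

The gradient is Δθ = θ_c − θ_l (positive when the core is warmer) and the
ratio r = θ_l/θ_c, computed on the **Celsius** scale: observed cohort
ratios of 0.8–1.03 are only meaningful as Celsius ratios (on the Kelvin
scale all such ratios collapse to ≈0.99). The ratio is undefined for
θ_c ≤ 0 °C, and r > 1 ⇔ Δθ < 0 for θ_c > 0 — a coupling the tests assert.
A published cohort description that reports an outlier with ratio 1.03
alongside a gradient of +1.14 °C is internally inconsistent for exactly
this reason; the package treats the negative gradient as the true reading.

Line profiles sample the field at equal arc-length spacing along a
polyline (default one sample per pixel of arc length, bilinear
interpolation). Artefact flagging marks maximal contiguous runs of samples
outside a plausible skin band, default 28–38 °C — healthy skin sits at
33–36 °C; the band is widened for critically ill children and is fully
configurable. Flagged intervals are excluded from the limb slope, an
ordinary least-squares fit of temperature against arc length over a chosen
segment, reported in °C/px (or °C/mm given a scale).

## Cohort statistics

Axillary reference temperatures get the clinical +0.5 °C rectal-equivalence
offset; rectal readings pass through. Summaries are median [Q1–Q3] with
type-7 (linear-interpolation) quantiles — the convention is configurable
because other quantile types can be needed for comparisons. Histograms use
half-open, lower-closed fixed-width bins; defaults bin gradients at 2 °C
from origin −2 °C and ratios at 0.05 from origin 0.

Spearman's ρ is implemented as the Pearson correlation of average-ranked
data. The p-value is an exhaustive two-sided permutation enumeration for
n ≤ 8 (exact where cheap: 8! = 40 320 permutations) and the
t-approximation `t = ρ√((n−2)/(1−ρ²))` with n − 2 df at cohort scale.
Constant vectors raise rather than returning NaN. Group comparisons report
mean ± sample SD (n − 1 denominator) per binary clinical flag and the
Spearman correlation of the metric against the 0/1 flag — a
rank-biserial-style statistic. No multiple-testing correction is applied;
reports state the number of tests performed.

## Synthetic phantoms

**Body phantom.** A 2-D silhouette — circle head, ellipse torso, four
axis-aligned capsule limbs — over a constant PICU-ambient background
(default 21.5 °C, the unit holds 21–22 °C). Head and torso sit at the core
temperature θ_core (default 34 °C); each limb stays at the proximal
temperature up to an integer-coordinate ramp anchor just outside the
torso, then declines linearly to θ_limb_end (default 30 °C) at its tip.
Overlapping components resolve to the warmest value, which keeps the field
continuous where limbs emerge from the torso. Artefact patches (bandage,
diaper) are uniform regions at a configurable temperature, default
ambient + 3 °C; published profile figures show them as sharp troughs, but
no quantitative artefact temperature is available, so the default is a
declared assumption. Sensor noise is i.i.d. Gaussian with sd 0.05 K — the
upper bound of the sensor's < 50 mK sensitivity — with no fixed-pattern or
drift component; the field is then quantized to TLinear counts. The color
frame classifies each pixel against the same analytic geometry through the
inverse of the ground-truth homography, so landmark pairs satisfy the
transform exactly. Its default size is 480×640, a 4:1 linear scale over
the IR frame: this preserves the resolution-mismatch regime of the real
rig (4096×3072 vs 160×120 would be 25:1) while keeping tests fast.

Limb axes are horizontal/vertical with integer anchors deliberately: along
a limb the analytic field is linear in the coordinates, so bilinear
interpolation of the rasterized grid reproduces the closed-form profile
exactly and the only residual is count quantization (±0.005 °C); the
phantom-vs-truth profile tolerance is 0.01 °C. The canonical profile
polyline runs canthus → thorax → hip → 2 px short of the toe tip (stopping
short keeps the endpoint clear of the rounded end cap).

What the phantom does **not** emulate: 3-D posture and self-occlusion,
physiological heat diffusion (no bioheat equation), vignetting and optics,
fixed-pattern sensor noise, motion, clothing edges, or photorealistic
color. Passing tests therefore demonstrate the correctness of the
measurement chain — conversion, registration, sampling, statistics — not
detector robustness on clinical imagery.

**Board phantom.** The checkerboard is rendered analytically under a
board→IR homography with 4× supersampled anti-aliasing; the IR rendering
maps the pattern to apparent temperatures (warm paper ~30 °C, aluminium
~16 °C, ambient surround) with polarity inverted relative to the print.
True inner-corner coordinates are returned for both frames, consistent
with the ground-truth transform by construction.

**Cohort simulator.** Latent standard normals (z_c, z_l) are drawn with
Pearson correlation 2·sin(π·ρ_s/6), the bivariate-normal copula value
whose Spearman correlation is exactly ρ_s; θ_c is the uniform quantile
transform of z_c over the configured range (default 32–35 °C) and θ_l is
normal with mean mid(range) − 3.19 °C and sd 3.0 °C. Both maps are
strictly increasing, so the rank correlation is inherited from the latent
pair exactly; ρ_s = 1 yields a comonotone cohort with sample Spearman
exactly 1. The defaults target the observed cohort scale: core–extremity
rank correlation 0.66, median gradient ≈ 3.2 °C with spread comparable to
the observed −1.1…+6 °C range, and a clinical reference temperature
rank-coupled to θ_c at ρ = 0.40 (normal, 37.0 ± 0.6 °C rectal-equivalent;
axillary records store the raw reading so the pipeline's +0.5 °C
adjustment reconstructs it). Clinical flags are Bernoulli with
paper-scale prevalences (vasodilator 7/36, vasoconstrictor 3/36) and an
optional additive gradient shift; the default shift is zero, as no group
difference was observed. Exclusions (distortion, calibration error, limbs
not visible) are assigned to a seeded random subset on request.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  spec + seed gives bit-identical frames, records and CSV outputs.
- Homography recovery on exact points is asserted to 1e−6 relative error;
  the DLT is cross-checked against an independent least-squares solver.
- Degenerate inputs raise typed exceptions (`DomainError`, `BoundsError`,
  `DegenerateGeometryError`, `UndefinedCorrelationError`, ...) rather than
  propagating NaNs.
- Arc-length sample positions are computed by cumulative segment lengths
  and `searchsorted`; interval membership for artefact masks uses closed
  intervals, and flagged-run boundaries are reported at sample positions
  (accurate to one sample spacing by construction).
- Test problem sizes are desk-scale by design: 120×160 IR / 480×640 color
  frames, 7×9 boards, 100-transform recovery sweeps, 500-vector Spearman
  oracle sweeps, and n = 500 cohorts for stochastic recovery (rank
  correlation within ±0.08, group shifts within ±0.3 °C). The full suite
  runs in well under a minute.

## Known limitations

- The corner detector targets rendered boards; real imagery needs the
  field calibration tooling the rig shipped with.
- The 0.01 K/count resolution is inferred from the sensor's documented
  worked value; sensors in other gain states need the resolution set
  explicitly.
- The cohort simulator controls the rank correlation and marginals but not
  the joint tail behaviour of real hemodynamics; it validates statistical
  machinery, not physiology.
- Registration assumes a planar scene; out-of-plane anatomy introduces
  parallax that no single homography can capture.
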
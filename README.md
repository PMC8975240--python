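# thermograd

Optical-thermography analysis of core–limb skin-temperature gradients in
critically ill children.

Skin temperature is a direct readout of cutaneous blood flow: under
peripheral vasoconstriction the body centralizes perfusion and the
extremities cool relative to the core, while vasodilation can invert that
pattern. `thermograd` implements the full analysis chain for a bedside
setup that pairs a low-resolution radiometric long-wave infrared sensor
(160×120 px, thermal sensitivity < 50 mK) with a high-resolution color
camera:

1. **Radiometry** — TLinear radiometric counts to temperature,
   `T[K] = ρ·c` with ρ = 0.01 K/count (a pixel value of 30000 is 300.00 K
   = 26.85 °C), then Kelvin → Celsius.
2. **Registration** — a 3×3 planar homography `H` mapping IR pixels onto
   the color frame, estimated from the inner corners of a dual-emissivity
   checkerboard (aluminium squares appear cold to the IR sensor) by a
   Hartley-normalized direct linear transform, with reprojection RMSE as
   the quality metric and optional robust (consensus) fitting.
3. **Profiles** — core (inner canthus, or thorax when the eyes are
   obstructed) and extremity (finger/toe) temperatures θ_c and θ_l sampled
   with configurable windows; the gradient **Δθ = θ_c − θ_l**, the ratio
   **r = θ_l / θ_c** (Celsius scale, r > 1 ⇔ Δθ < 0); temperature profiles
   along a core-to-extremity polyline, artefact flagging by plausibility
   thresholds (default 28–38 °C), and the limb's OLS temperature slope.
4. **Cohort statistics** — the +0.5 °C axillary-to-rectal equivalence
   adjustment, median [IQR] summaries (type-7 quantiles), fixed-width
   histograms, Spearman rank correlation ρ (average-rank ties; exact
   permutation p for n ≤ 8, t-approximation with n − 2 df otherwise), and
   per-clinical-flag group comparisons (mean ± SD, metric-vs-flag rank
   correlation).
5. **Phantoms** — ground-truthed synthetic inputs (body scenes, board
   pairs, rank-coupled cohorts) so the whole pipeline is testable without
   patient data.

## Worked example

The `demo` subcommand generates a body phantom and a calibration board,
calibrates, extracts the gradient, flags artefacts along the
core-to-toe line, and summarizes a simulated 36-patient cohort:

```bash
thermograd demo --seed 1 --out demo/
```

prints

```
theta_c = 34.01 degC, theta_l = 30.02 degC, gradient = 3.99 degC, ratio = 0.8827
calibration RMSE = 0.4121 px; 1 artefact interval(s) flagged
Cohort: 36 records, 36 usable
theta_c: 33.65 degC [33.05-34.16]
theta_l: 29.96 degC [28.95-31.14]
gradient: 3.64 degC [2.57-4.60]
ratio: 0.89 [0.86-0.92]
Spearman theta_c vs theta_l: rho = 0.51, p = 0.0015 (n = 36, t_approximation)
...
```

The phantom's core is injected at 34 °C and its toes at 30 °C, so the
recovered gradient of 3.99 °C reflects the injected 4 °C (the canthus is
read at its hottest window pixel, which rides ~0.07 °C above the mean
under sensor noise); the ratio 0.88 < 1 says the extremities are cooler
than the core. The calibration RMSE of 0.41 px is the corner reprojection
error of the estimated IR→RGB homography at IR scale. The cohort block
shows the median [IQR] summaries and the core-vs-extremity rank
correlation for one simulated 36-subject draw.

The same stages are available individually (`simulate`, `calibrate`,
`warp`, `extract`, `profile`, `cohort`) and as library functions:

```python
from thermograd import phantom, radiometry, profile

spec = phantom.PhantomSpec(theta_core=33.88, theta_limb_end=30.21, noise_sd_k=0.0)
rgb, frame, truth = phantom.generate_body_phantom(spec)
field = radiometry.frame_to_celsius(frame)
canthus = profile.sample_point_temperature(field, truth.landmarks_ir["inner_canthus"],
                                           "inner_canthus")
toe = profile.sample_point_temperature(field, truth.landmarks_ir["toe_right"], "toe")
result = profile.GradientResult.from_temperatures(canthus.temperature, toe.temperature)
# result.gradient == 3.67, result.ratio == 0.8917 (to count quantization)
```

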
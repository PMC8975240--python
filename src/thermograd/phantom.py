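"""Synthetic ground-truthed phantoms: body scenes, calibration boards, cohorts.

No patient imagery is distributed with studies of this kind, so every other
module is exercised against phantoms with analytically known answers:

* a 2-D body silhouette (circle head, ellipse torso, capsule limbs) over a
  PICU-ambient background, with a warm core, limb temperatures declining
  linearly toward the extremities, optional cold artefact patches
  (bandage/diaper), Gaussian sensor noise at the sensor's thermal
  sensitivity, and TLinear count quantization — paired with a
  higher-resolution color rendering of the same scene through a known
  planar transform;
* a dual-emissivity checkerboard pair (printed pattern for the color
  camera, contrast-inverted apparent-temperature pattern for the IR
  sensor) with exact inner-corner coordinates in both frames;
* a patient cohort whose core/limb temperatures are rank-coupled through a
  Gaussian copula to hit a target Spearman correlation in expectation.

The body model is deliberately 2-D: the pipeline needs plausible planar
thermal structure, not a physiological render.  Limb axes are axis-aligned
with integer ramp anchors so that bilinear interpolation along a limb
reproduces the closed-form profile exactly (up to count quantization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import PatientRecord
from .errors import DomainError, GeometryError
from .radiometry import ThermalFrame, celsius_to_frame
from .registration import PlanarTransform

#: IR sensor geometry: 160 x 120 pixels, thermal sensitivity < 50 mK.
DEFAULT_IR_SHAPE = (120, 160)
#: Color frame at 4:1 linear scale vs IR (the full-sensor 4096 x 3072 regime
#: is preserved in miniature; the scale is configurable).
DEFAULT_RGB_SHAPE = (480, 640)
DEFAULT_NOISE_SD_K = 0.05
#: PICU rooms are held at a constant 21-22 degC.
DEFAULT_AMBIENT_C = 21.5


def default_transform_truth() -> PlanarTransform:
    """IR -> RGB ground-truth homography: ~4x scale, offset, mild perspective."""
    matrix = np.array([
        [4.0, 0.02, 8.0],
        [0.015, 4.0, 6.0],
        [1.0e-5, -8.0e-6, 1.0],
    ])
    return PlanarTransform(matrix, src_space="ir", dst_space="rgb")


@dataclass(frozen=True)
class Limb:
    """A capsule limb: temperature declines linearly along its axis.

    ``start``/``end`` are the axis endpoints in IR pixel coordinates
    (proximal first); within ``anchor_s`` pixels of the start the limb stays
    at the proximal temperature, beyond it the temperature ramps linearly to
    the distal value at the axis end (clamped past the end caps).
    """

    label: str
    start: tuple[float, float]
    end: tuple[float, float]
    radius: float
    anchor_s: float

    @property
    def length(self) -> float:
        return math.dist(self.start, self.end)

    def axis_temperature(self, s, proximal_c: float, distal_c: float):
        """Closed-form temperature at arc position s along the axis."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        t = np.clip((s - self.anchor_s) / (self.length - self.anchor_s), 0.0, 1.0)
        out = proximal_c + (distal_c - proximal_c) * t
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ArtefactPatch:
    """A uniform-temperature patch (bandage, diaper) overwriting skin.

    ``kind`` is ``disc`` with params (cx, cy, r) or ``rect`` with params
    (x0, y0, x1, y1), in IR pixel coordinates.  ``temperature_c`` of None
    defaults to ambient + 3 degC at generation time.
    """

    kind: str
    params: tuple
    temperature_c: float | None = None

    def contains(self, x, y):
        if self.kind == "disc":
            cx, cy, r = self.params
            return (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2 <= r ** 2
        if self.kind == "rect":
            x0, y0, x1, y1 = self.params
            x = np.asarray(x)
            y = np.asarray(y)
            return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        raise GeometryError(f"unknown patch kind {self.kind!r}")


def _default_limbs() -> tuple[Limb, ...]:
    # Axis-aligned capsules with integer ramp anchors (see module docstring);
    # proximal ends sit inside the torso ellipse so the body is connected.
    return (
        Limb("leg_right", (96.0, 74.0), (150.0, 74.0), 5.0, anchor_s=6.0),
        Limb("leg_left", (96.0, 46.0), (150.0, 46.0), 5.0, anchor_s=6.0),
        Limb("arm_right", (60.0, 80.0), (60.0, 112.0), 4.0, anchor_s=5.0),
        Limb("arm_left", (60.0, 40.0), (60.0, 8.0), 4.0, anchor_s=5.0),
    )


@dataclass
class PhantomSpec:
    """Full description of a synthetic body scene.

    Geometry is expressed in IR pixel coordinates of the default 120 x 160
    frame.  ``theta_core`` is the core (inner-canthus/torso) skin
    temperature; each limb declines to ``theta_limb_end`` at its tip.
    """

    frame_shape_ir: tuple[int, int] = DEFAULT_IR_SHAPE
    frame_shape_rgb: tuple[int, int] = DEFAULT_RGB_SHAPE
    theta_core: float = 34.0
    theta_limb_end: float = 30.0
    ambient: float = DEFAULT_AMBIENT_C
    head_center: tuple[float, float] = (28.0, 60.0)
    head_radius: float = 13.0
    torso_center: tuple[float, float] = (72.0, 60.0)
    torso_axes: tuple[float, float] = (35.0, 26.0)
    limbs: tuple[Limb, ...] = field(default_factory=_default_limbs)
    artefact_patches: tuple[ArtefactPatch, ...] = ()
    noise_sd_k: float = DEFAULT_NOISE_SD_K
    transform_truth: PlanarTransform = field(default_factory=default_transform_truth)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_core <= self.ambient:
            raise DomainError("theta_core must exceed ambient")
        if self.noise_sd_k < 0:
            raise DomainError("noise_sd_k must be non-negative")
        if min(self.frame_shape_ir) <= 0 or min(self.frame_shape_rgb) <= 0:
            raise DomainError("frame shapes must be positive")


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated body phantom."""

    temperature_field: np.ndarray  # noiseless Celsius grid at IR resolution
    landmarks_ir: dict  # label -> (x, y) in IR pixels
    landmarks_rgb: dict  # label -> (x, y) in RGB pixels (exact via transform)
    profile_polyline: np.ndarray  # canonical core -> toe polyline, IR pixels
    profile_truth: object  # callable s -> Celsius along that polyline
    artefact_extents: list  # [s_lo, s_hi] intervals on the polyline
    spec: PhantomSpec


def _body_temperature(spec: PhantomSpec, x, y) -> np.ndarray:
    """Analytic scene temperature at IR coordinates (x, y), patches included.

    Overlapping components resolve to the warmest value, which keeps the
    field continuous where limbs emerge from the torso at core temperature.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    temp = np.full(np.broadcast(x, y).shape, spec.ambient)
    body = np.zeros_like(temp, dtype=bool)

    hx, hy = spec.head_center
    in_head = (x - hx) ** 2 + (y - hy) ** 2 <= spec.head_radius ** 2
    tx, ty = spec.torso_center
    ta, tb = spec.torso_axes
    in_torso = ((x - tx) / ta) ** 2 + ((y - ty) / tb) ** 2 <= 1.0
    core = in_head | in_torso
    temp[core] = spec.theta_core
    body |= core

    for limb in spec.limbs:
        p0 = np.asarray(limb.start)
        d = np.asarray(limb.end) - p0
        length = limb.length
        # projection of each point onto the axis, clamped to the segment
        s = ((x - p0[0]) * d[0] + (y - p0[1]) * d[1]) / length
        s_cl = np.clip(s, 0.0, length)
        px = p0[0] + s_cl * d[0] / length
        py = p0[1] + s_cl * d[1] / length
        in_limb = (x - px) ** 2 + (y - py) ** 2 <= limb.radius ** 2
        limb_t = limb.axis_temperature(s_cl, spec.theta_core, spec.theta_limb_end)
        temp[in_limb] = np.maximum(temp[in_limb], np.asarray(limb_t)[in_limb]
                                   if np.ndim(limb_t) else limb_t)
        body |= in_limb

    for patch in spec.artefact_patches:
        t_patch = (patch.temperature_c if patch.temperature_c is not None
                   else spec.ambient + 3.0)
        inside = patch.contains(x, y) & body
        if not inside.any():
            raise GeometryError(
                f"artefact patch {patch.kind}{patch.params} lies outside the body")
        temp[inside] = t_patch
    return temp


def _landmarks_ir(spec: PhantomSpec) -> dict:
    marks = {
        "inner_canthus": (25.0, 56.0),
        "thorax": (float(spec.torso_center[0]), float(spec.torso_center[1])),
    }
    for limb in spec.limbs:
        kind = "toe" if limb.label.startswith("leg") else "finger"
        marks[f"{kind}_{limb.label.split('_', 1)[1]}"] = (float(limb.end[0]),
                                                          float(limb.end[1]))
    return marks


def default_profile_polyline(spec: PhantomSpec) -> np.ndarray:
    """Canonical core-to-toe polyline: canthus -> thorax -> hip -> toe tip."""
    leg = spec.limbs[0]
    return np.array([
        list(_landmarks_ir(spec)["inner_canthus"]),
        list(spec.torso_center),
        list(leg.start),
        [leg.end[0] - 2.0, leg.end[1]],  # stop short of the end cap
    ])


def _profile_truth_fn(spec: PhantomSpec):
    """Closed-form temperature vs arc length along the canonical polyline."""
    poly = default_profile_polyline(spec)
    seg = np.diff(poly, axis=0)
    seg_len = np.sqrt((seg ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    leg = spec.limbs[0]
    s_leg_start = cum[2]  # polyline reaches the limb axis start here

    def truth(s):
        s = np.asarray(s, dtype=float)
        on_leg = np.clip(s - s_leg_start, 0.0, leg.length)
        base = leg.axis_temperature(on_leg, spec.theta_core, spec.theta_limb_end)
        base = np.where(s < s_leg_start, spec.theta_core, base)
        if spec.artefact_patches:
            # patch membership evaluated at the exact polyline position
            idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0,
                          len(seg_len) - 1)
            frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
            pts = poly[idx] + frac[..., None] * seg[idx]
            for patch in spec.artefact_patches:
                t_patch = (patch.temperature_c if patch.temperature_c is not None
                           else spec.ambient + 3.0)
                base = np.where(patch.contains(pts[..., 0], pts[..., 1]),
                                t_patch, base)
        return base if base.ndim else float(base)

    return truth, poly


def _artefact_extents(spec: PhantomSpec, poly: np.ndarray,
                      step: float = 0.02) -> list:
    """Arc-length intervals of the polyline covered by artefact patches."""
    seg = np.diff(poly, axis=0)
    seg_len = np.sqrt((seg ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0.0, cum[-1] + step, step)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    pts = poly[idx] + frac[:, None] * seg[idx]
    covered = np.zeros(len(s), dtype=bool)
    for patch in spec.artefact_patches:
        covered |= np.asarray(patch.contains(pts[:, 0], pts[:, 1]))
    extents = []
    start = None
    for i, c in enumerate(covered):
        if c and start is None:
            start = i
        elif not c and start is not None:
            extents.append((float(s[start]), float(s[i - 1])))
            start = None
    if start is not None:
        extents.append((float(s[start]), float(s[-1])))
    return extents


def generate_body_phantom(spec: PhantomSpec
                          ) -> tuple[np.ndarray, ThermalFrame, PhantomTruth]:
    """Render the body scene: (rgb_frame, ir_thermal_frame, truth).

    The IR frame is the analytic temperature field sampled at pixel centers,
    plus i.i.d. Gaussian sensor noise (sd ``noise_sd_k``), quantized to
    TLinear counts.  The RGB frame renders the same geometry at color
    resolution through ``transform_truth``.  Identical spec + seed gives
    bit-identical output.
    """
    h, w = spec.frame_shape_ir
    yy, xx = np.mgrid[0:h, 0:w]
    truth_field = _body_temperature(spec, xx.astype(float), yy.astype(float))

    rng = np.random.default_rng(spec.seed)
    noisy = truth_field + rng.normal(0.0, spec.noise_sd_k, truth_field.shape) \
        if spec.noise_sd_k > 0 else truth_field
    ir_frame = celsius_to_frame(noisy, frame_id=f"phantom-body-{spec.seed}")

    rgb = _render_rgb_scene(spec)

    marks_ir = _landmarks_ir(spec)
    marks_rgb = {k: tuple(spec.transform_truth.apply([v])[0])
                 for k, v in marks_ir.items()}
    truth_fn, poly = _profile_truth_fn(spec)
    truth = PhantomTruth(
        temperature_field=truth_field,
        landmarks_ir=marks_ir,
        landmarks_rgb=marks_rgb,
        profile_polyline=poly,
        profile_truth=truth_fn,
        artefact_extents=_artefact_extents(spec, poly),
        spec=spec,
    )
    return rgb, ir_frame, truth


def _render_rgb_scene(spec: PhantomSpec) -> np.ndarray:
    """Color rendering: skin silhouette and bright artefact patches.

    Each RGB pixel center is mapped back into IR coordinates through the
    inverse of ``transform_truth`` and classified against the same analytic
    geometry, so the two frames are exactly consistent with the transform.
    """
    hh, ww = spec.frame_shape_rgb
    yy, xx = np.mgrid[0:hh, 0:ww]
    inv = np.linalg.inv(spec.transform_truth.matrix)
    pts = inv @ np.stack([xx.ravel(), yy.ravel(), np.ones(xx.size)])
    ix = (pts[0] / pts[2]).reshape(hh, ww)
    iy = (pts[1] / pts[2]).reshape(hh, ww)
    temp = _body_temperature(spec, ix, iy)
    body = temp != spec.ambient
    rgb = np.empty((hh, ww, 3))
    rgb[...] = (0.24, 0.25, 0.30)  # bed sheet / background
    rgb[body] = (0.85, 0.65, 0.55)  # skin
    for patch in spec.artefact_patches:
        rgb[patch.contains(ix, iy) & body] = (0.95, 0.95, 0.92)  # dressing
    return np.round(rgb * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dual-emissivity checkerboard pair

@dataclass
class BoardPair:
    """Rendered calibration pair plus exact inner-corner coordinates."""

    rgb: np.ndarray
    ir_frame: ThermalFrame
    corners_ir: np.ndarray  # (rows*cols, 2), row-major
    corners_rgb: np.ndarray
    inner_grid: tuple[int, int]
    transform_truth: PlanarTransform


def default_board_pose(square_px_ir: float = 12.0,
                       offset: tuple[float, float] = (22.0, 14.0),
                       angle_deg: float = 3.0) -> np.ndarray:
    """Board-plane -> IR homography: rotation + offset + mild perspective."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([
        [c, -s, offset[0]],
        [s, c, offset[1]],
        [2.0e-5, -1.5e-5, 1.0],
    ])


def _render_board(shape: tuple[int, int], h_board2img: np.ndarray,
                  inner_grid: tuple[int, int], square_px: float,
                  dark: float, light: float, background: float,
                  supersample: int = 4) -> np.ndarray:
    """Anti-aliased parity rendering of a checkerboard under a homography.

    Board coordinates put inner corner (i, j) at (j, i) * square_px; the
    squares extend one square beyond the inner grid on every side.
    """
    rows, cols = inner_grid
    h, w = shape
    ss = supersample
    yy, xx = np.mgrid[0:h * ss, 0:w * ss]
    xs = (xx + 0.5) / ss - 0.5
    ys = (yy + 0.5) / ss - 0.5
    inv = np.linalg.inv(h_board2img)
    pts = inv @ np.stack([xs.ravel(), ys.ravel(), np.ones(xs.size)])
    u = (pts[0] / pts[2]) / square_px
    v = (pts[1] / pts[2]) / square_px
    inside = (u >= -1) & (u <= cols) & (v >= -1) & (v <= rows)
    parity = (np.floor(u) + np.floor(v)) % 2 == 0
    img = np.full(xs.size, background)
    img[inside] = np.where(parity[inside], dark, light)
    return img.reshape(h, ss, w, ss).mean(axis=(1, 3))


def _true_corners(h_board2img: np.ndarray, inner_grid: tuple[int, int],
                  square_px: float) -> np.ndarray:
    rows, cols = inner_grid
    grid = np.array([[j * square_px, i * square_px]
                     for i in range(rows) for j in range(cols)], dtype=float)
    hp = h_board2img @ np.vstack([grid.T, np.ones(len(grid))])
    return (hp[:2] / hp[2]).T


def generate_checkerboard_pair(
    inner_grid: tuple[int, int] = (7, 9),
    square_px_ir: float = 12.0,
    board_to_ir: np.ndarray | None = None,
    transform_truth: PlanarTransform | None = None,
    ir_shape: tuple[int, int] = DEFAULT_IR_SHAPE,
    rgb_shape: tuple[int, int] = DEFAULT_RGB_SHAPE,
    noise_sd_k: float = 0.0,
    seed: int = 0,
) -> BoardPair:
    """Render a dual-emissivity board in both frames with exact corners.

    The color frame shows the printed pattern (dark squares on a light
    board); the IR frame shows the aluminium squares as apparently cold
    regions on a warm board — a contrast-inverted thermal rendering of the
    same pose.  Corner lists are row-major and mutually consistent with
    ``transform_truth``.
    """
    if transform_truth is None:
        transform_truth = default_transform_truth()
    if board_to_ir is None:
        board_to_ir = default_board_pose(square_px_ir)
    rows, cols = inner_grid

    corners_ir = _true_corners(board_to_ir, inner_grid, square_px_ir)
    h_ir, w_ir = ir_shape
    if (corners_ir.min() < 1 or corners_ir[:, 0].max() > w_ir - 2
            or corners_ir[:, 1].max() > h_ir - 2):
        raise GeometryError("board exceeds the IR frame")
    corners_rgb = transform_truth.apply(corners_ir)
    h_rgb, w_rgb = rgb_shape
    if (corners_rgb.min() < 1 or corners_rgb[:, 0].max() > w_rgb - 2
            or corners_rgb[:, 1].max() > h_rgb - 2):
        raise GeometryError("board exceeds the RGB frame")

    # IR: warm paper ~30 degC, low-emissivity aluminium apparently ~16 degC,
    # room background at ambient.  Pattern polarity inverted vs the print.
    ir_celsius = _render_board(ir_shape, board_to_ir, inner_grid, square_px_ir,
                               dark=30.0, light=16.0, background=DEFAULT_AMBIENT_C)
    if noise_sd_k > 0:
        rng = np.random.default_rng(seed)
        ir_celsius = ir_celsius + rng.normal(0.0, noise_sd_k, ir_celsius.shape)
    ir_frame = celsius_to_frame(ir_celsius, frame_id=f"phantom-board-{seed}")

    h_board2rgb = transform_truth.matrix @ board_to_ir
    rgb_gray = _render_board(rgb_shape, h_board2rgb, inner_grid, square_px_ir,
                             dark=0.08, light=0.92, background=0.5)
    rgb = np.round(np.repeat(rgb_gray[..., None], 3, axis=2) * 255).astype(np.uint8)

    return BoardPair(rgb=rgb, ir_frame=ir_frame, corners_ir=corners_ir,
                     corners_rgb=corners_rgb, inner_grid=inner_grid,
                     transform_truth=transform_truth)


# ---------------------------------------------------------------------------
# Cohort simulator

@dataclass
class CohortTruth:
    """Generating parameters of a synthetic cohort, for recovery tests."""

    rho_target: float
    rho_latent_pearson: float
    theta_c_range: tuple[float, float]
    gradient_mean: float
    theta_l_sd: float
    flag_effects: dict
    rho_reference_target: float


def generate_cohort(
    n: int,
    rho_target: float = 0.66,
    theta_c_range: tuple[float, float] = (32.0, 35.0),
    gradient_mean: float = 3.19,
    theta_l_sd: float = 3.0,
    flag_effects: dict | None = None,
    rho_reference_target: float = 0.40,
    axillary_fraction: float = 0.5,
    exclusions: dict | None = None,
    seed: int = 0,
) -> tuple[list[PatientRecord], CohortTruth]:
    """Simulate a PICU cohort with a target core-limb rank correlation.

    Latent standard normals (z_c, z_l) are drawn with Pearson correlation
    ``2 sin(pi * rho_target / 6)``, which yields Spearman correlation
    ``rho_target`` in expectation for the bivariate normal copula.  theta_c
    is the uniform quantile transform of z_c over ``theta_c_range``; theta_l
    is normal with mean ``mid(theta_c_range) - gradient_mean`` and sd
    ``theta_l_sd``.  Both maps are strictly increasing, so ranks — and hence
    the Spearman coefficient — are inherited from the latent pair exactly;
    ``rho_target = 1`` gives a comonotone cohort with sample Spearman
    exactly 1.

    ``flag_effects`` maps a clinical flag name to ``(prevalence,
    gradient_shift_c)``: flagged subjects have their limb temperature
    lowered by the shift (raising the gradient).  The clinical reference
    temperature is rank-coupled to theta_c with target Spearman
    ``rho_reference_target``; axillary sites store the raw (pre-increment)
    reading.  ``exclusions`` maps exclusion reasons to counts of records
    marked unusable.
    """
    if n < 3:
        raise DomainError("cohort needs n >= 3")
    if not -1.0 <= rho_target <= 1.0:
        raise DomainError("|rho_target| must be <= 1")
    lo, hi = theta_c_range
    if not lo < hi or lo <= 0:
        raise DomainError("theta_c_range must be an increasing positive interval")
    if flag_effects is None:
        # Paper-scale prevalences; no gradient effect by default (the study
        # found none between vasoactive groups).
        flag_effects = {"vasodilator": (7 / 36, 0.0),
                        "vasoconstrictor": (3 / 36, 0.0)}

    from scipy import stats

    rng = np.random.default_rng(seed)
    rho_p = 2.0 * math.sin(math.pi * rho_target / 6.0)
    z_c = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    z_l = rho_p * z_c + math.sqrt(max(0.0, 1.0 - rho_p ** 2)) * eps

    theta_c = lo + (hi - lo) * stats.norm.cdf(z_c)
    mu_l = 0.5 * (lo + hi) - gradient_mean
    theta_l = mu_l + theta_l_sd * z_l

    flags = {}
    for name, (prevalence, shift) in flag_effects.items():
        flagged = rng.random(n) < prevalence
        flags[name] = flagged
        theta_l = theta_l - shift * flagged

    a_ref = 2.0 * math.sin(math.pi * rho_reference_target / 6.0)
    z_ref = a_ref * z_c + math.sqrt(max(0.0, 1.0 - a_ref ** 2)) \
        * rng.standard_normal(n)
    t_ref_core = 37.0 + 0.6 * z_ref  # rectal-equivalent reading
    axillary = rng.random(n) < axillary_fraction

    reasons = []
    if exclusions:
        for reason, count in exclusions.items():
            reasons.extend([reason] * count)
        if len(reasons) > n:
            raise DomainError("more exclusions than records")
    excluded_idx = rng.choice(n, size=len(reasons), replace=False) \
        if reasons else np.array([], dtype=int)
    reason_by_idx = dict(zip(excluded_idx.tolist(), reasons))

    records = []
    for i in range(n):
        site = "axillary" if axillary[i] else "rectal"
        ref = t_ref_core[i] - (0.5 if site == "axillary" else 0.0)
        reason = reason_by_idx.get(i, "none")
        records.append(PatientRecord(
            patient_id=f"P{i + 1:04d}",
            theta_c=float(theta_c[i]),
            theta_l=float(theta_l[i]),
            clinical_reference_temp=float(ref),
            reference_site=site,
            clinical_flags={name: bool(v[i]) for name, v in flags.items()},
            usable=reason == "none",
            exclusion_reason=reason,
        ))
    truth = CohortTruth(rho_target=rho_target, rho_latent_pearson=rho_p,
                        theta_c_range=theta_c_range, gradient_mean=gradient_mean,
                        theta_l_sd=theta_l_sd, flag_effects=dict(flag_effects),
                        rho_reference_target=rho_reference_target)
    return records, truth
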
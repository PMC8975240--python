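"""Core and extremity temperature sampling, gradients and line profiles.

Under peripheral vasoconstriction blood flow is centralized, so the skin of
the extremities cools relative to the core.  Two scalar summaries capture
this: the core-limb gradient ``theta_c - theta_l`` (positive when the core
is warmer) and the ratio ``theta_l / theta_c`` on the Celsius scale (> 1
when the extremities are warmer).  A richer view is a temperature profile
sampled along a polyline drawn from the core down a limb: troughs flag cold
artefacts (bandage, diaper) and the limb section's slope quantifies the
continuous gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import BoundsError, DomainError, GeometryError, InsufficientDataError
from .radiometry import TemperatureField

REGION_LABELS = ("inner_canthus", "thorax", "finger", "toe")

#: Plausible skin-temperature band for artefact flagging, degC.  Healthy skin
#: sits at 33-36 degC; the band is widened for critically ill children.
DEFAULT_PLAUSIBLE_RANGE_C = (28.0, 38.0)


@dataclass
class RegionSample:
    """A temperature sampled at a labeled anatomical point."""

    point: tuple[float, float]
    label: str
    temperature: float
    window: int = 1

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise DomainError(f"label must be one of {REGION_LABELS}")
        if not (-273.15 <= self.temperature <= 100.0):
            raise DomainError("temperature outside [-273.15, 100] degC")


@dataclass
class GradientResult:
    """Core/limb temperatures with their gradient and ratio."""

    theta_c: float
    theta_l: float
    gradient: float
    ratio: float

    @classmethod
    def from_temperatures(cls, theta_c: float, theta_l: float) -> "GradientResult":
        return cls(theta_c=theta_c, theta_l=theta_l,
                   gradient=core_limb_gradient(theta_c, theta_l),
                   ratio=core_limb_ratio(theta_c, theta_l))


@dataclass
class ThermalProfile:
    """Equally spaced (arc-length, temperature) samples along a polyline.

    ``arc_lengths`` are strictly increasing and start at 0; ``xy`` carries
    the sampled pixel coordinates for traceability.
    """

    polyline: np.ndarray
    arc_lengths: np.ndarray
    temperatures: np.ndarray
    xy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.polyline = np.atleast_2d(np.asarray(self.polyline, dtype=float))
        self.arc_lengths = np.asarray(self.arc_lengths, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.arc_lengths.shape != self.temperatures.shape:
            raise DomainError("arc_lengths and temperatures must align")
        if len(self.arc_lengths) and (
                self.arc_lengths[0] != 0.0
                or np.any(np.diff(self.arc_lengths) <= 0)):
            raise DomainError("arc lengths must start at 0 and strictly increase")

    @property
    def n_samples(self) -> int:
        return len(self.arc_lengths)

    def to_dataframe(self, image_id: str = "") -> pd.DataFrame:
        xy = self.xy if self.xy is not None else np.full((self.n_samples, 2), np.nan)
        return pd.DataFrame({
            "image_id": image_id,
            "sample_index": np.arange(self.n_samples),
            "arc_length_px": self.arc_lengths,
            "x": xy[:, 0], "y": xy[:, 1],
            "temperature_c": self.temperatures,
        })


def core_limb_gradient(theta_c: float, theta_l: float) -> float:
    """Gradient ``theta_c - theta_l``; positive when the core is warmer."""
    if not (math.isfinite(theta_c) and math.isfinite(theta_l)):
        raise DomainError("temperatures must be finite")
    return theta_c - theta_l


def core_limb_ratio(theta_c: float, theta_l: float) -> float:
    """Ratio ``theta_l / theta_c`` on the Celsius scale; > 1 iff gradient < 0."""
    if not (math.isfinite(theta_c) and math.isfinite(theta_l)):
        raise DomainError("temperatures must be finite")
    if theta_c <= 0:
        raise DomainError("ratio undefined for core temperature <= 0 degC")
    return theta_l / theta_c


def sample_point_temperature(field_: TemperatureField, point, label: str,
                             window: int = 3) -> RegionSample:
    """Sample a labeled point as an aggregate over an odd square window.

    The aggregate is the window *median* for skin and limb points (robust to
    isolated artefact pixels) and the window *maximum* for the inner canthus,
    which is a small local hot spot in a low-resolution frame and is read at
    its hottest pixel.  ``window=1`` reproduces single-pixel manual reads.
    """
    if window < 1 or window % 2 == 0:
        raise DomainError("window must be an odd positive integer")
    if label not in REGION_LABELS:
        raise DomainError(f"label must be one of {REGION_LABELS}")
    x, y = float(point[0]), float(point[1])
    half = window // 2
    h, w = field_.shape
    xi, yi = int(round(x)), int(round(y))
    if xi - half < 0 or yi - half < 0 or xi + half >= w or yi + half >= h:
        raise BoundsError(
            f"window {window} at ({x:g}, {y:g}) overlaps the field boundary")
    patch = field_.celsius[yi - half:yi + half + 1, xi - half:xi + half + 1]
    value = float(np.max(patch) if label == "inner_canthus" else np.median(patch))
    return RegionSample(point=(x, y), label=label, temperature=value,
                        window=window)


def extract_line_profile(field_: TemperatureField, polyline, n_samples: int | None = None,
                         interpolation: str = "bilinear") -> ThermalProfile:
    """Sample temperatures equally spaced in arc length along a polyline.

    ``n_samples`` defaults to one sample per pixel of total arc length
    (``ceil(length) + 1``).  Interpolation is bilinear by default, nearest
    optionally.
    """
    poly = np.atleast_2d(np.asarray(polyline, dtype=float))
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 2:
        raise GeometryError("polyline needs at least 2 (x, y) control points")
    h, w = field_.shape
    if (poly[:, 0].min() < 0 or poly[:, 0].max() > w - 1
            or poly[:, 1].min() < 0 or poly[:, 1].max() > h - 1):
        raise BoundsError("polyline control point outside the field extent")
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError("interpolation must be 'nearest' or 'bilinear'")

    seg = np.diff(poly, axis=0)
    seg_len = np.sqrt((seg ** 2).sum(axis=1))
    if seg_len.sum() == 0:
        raise GeometryError("polyline has zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if n_samples is None:
        n_samples = int(math.ceil(total)) + 1
    if n_samples < 2:
        raise DomainError("n_samples must be >= 2")

    s = np.linspace(0.0, total, n_samples)
    # locate each arc-length position on its segment
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    xy = poly[idx] + frac[:, None] * seg[idx]

    order = 1 if interpolation == "bilinear" else 0
    temps = ndimage.map_coordinates(field_.celsius, [xy[:, 1], xy[:, 0]],
                                    order=order, mode="nearest")
    return ThermalProfile(polyline=poly, arc_lengths=s, temperatures=temps, xy=xy)


def flag_artefact_segments(profile: ThermalProfile,
                           min_plausible: float = DEFAULT_PLAUSIBLE_RANGE_C[0],
                           max_plausible: float = DEFAULT_PLAUSIBLE_RANGE_C[1],
                           ) -> list[tuple[float, float]]:
    """Maximal runs of samples outside the plausible band, as arc intervals.

    Temperatures implausible for skin (a cold bandage or diaper, a hot probe)
    betray artefacts; each maximal contiguous run of out-of-band samples is
    returned as a closed ``[s_start, s_end]`` arc-length interval.
    """
    if profile.n_samples == 0:
        raise DomainError("empty profile")
    if not min_plausible < max_plausible:
        raise DomainError("min_plausible must be below max_plausible")
    outside = (profile.temperatures < min_plausible) | \
              (profile.temperatures > max_plausible)
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(outside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((profile.arc_lengths[start],
                              profile.arc_lengths[i - 1]))
            start = None
    if start is not None:
        intervals.append((profile.arc_lengths[start], profile.arc_lengths[-1]))
    return intervals


def artefact_mask(profile: ThermalProfile,
                  artefact_intervals) -> np.ndarray:
    """Boolean mask of samples lying inside any flagged interval."""
    mask = np.zeros(profile.n_samples, dtype=bool)
    for lo, hi in artefact_intervals:
        mask |= (profile.arc_lengths >= lo) & (profile.arc_lengths <= hi)
    return mask


def limb_slope(profile: ThermalProfile,
               segment: tuple[float, float] | None = None,
               artefact_intervals=(),
               mm_per_pixel: float | None = None) -> float:
    """OLS slope of temperature vs arc length over unflagged samples.

    ``segment`` restricts the fit to a closed arc-length interval (default:
    the whole profile); samples inside ``artefact_intervals`` are excluded.
    The slope is degC per pixel, or degC per mm when ``mm_per_pixel`` is given.
    """
    keep = ~artefact_mask(profile, artefact_intervals)
    if segment is not None:
        lo, hi = segment
        keep &= (profile.arc_lengths >= lo) & (profile.arc_lengths <= hi)
    s = profile.arc_lengths[keep]
    t = profile.temperatures[keep]
    if len(s) < 2 or np.ptp(s) == 0:
        raise InsufficientDataError("fewer than 2 usable samples for slope fit")
    slope = float(np.polyfit(s, t, 1)[0])
    if mm_per_pixel is not None:
        if mm_per_pixel <= 0:
            raise DomainError("mm_per_pixel must be positive")
        slope /= mm_per_pixel
    return slope


# ---------------------------------------------------------------------------
# Landmark CSV interface: image_id, label, x, y, window

def extract_landmarks(field_: TemperatureField, landmarks: pd.DataFrame,
                      image_id: str | None = None) -> list[RegionSample]:
    """Sample every landmark row of a landmarks table against a field."""
    required = {"label", "x", "y"}
    missing = required - set(landmarks.columns)
    if missing:
        raise DomainError(f"landmarks table missing columns {sorted(missing)}")
    rows = landmarks
    if image_id is not None and "image_id" in landmarks.columns:
        rows = landmarks[landmarks["image_id"] == image_id]
    samples = []
    for _, row in rows.iterrows():
        window = int(row["window"]) if "window" in rows.columns else 3
        samples.append(sample_point_temperature(
            field_, (float(row["x"]), float(row["y"])), str(row["label"]),
            window=window))
    return samples


def gradient_from_samples(samples: list[RegionSample],
                          core_label: str = "inner_canthus",
                          limb_label: str = "toe") -> GradientResult:
    """Build a GradientResult from labeled samples, recording the core label.

    When the eyes are obstructed the thorax stands in for the core; pass
    ``core_label='thorax'`` in that case.
    """
    by_label = {s.label: s for s in samples}
    if core_label not in by_label or limb_label not in by_label:
        raise DomainError(
            f"need samples labeled {core_label!r} and {limb_label!r}")
    return GradientResult.from_temperatures(by_label[core_label].temperature,
                                            by_label[limb_label].temperature)


def profile_to_csv(profile: ThermalProfile, path: str | Path,
                   image_id: str = "",
                   artefact_intervals=()) -> None:
    df = profile.to_dataframe(image_id)
    df["artefact_flag"] = artefact_mask(profile, artefact_intervals)
    df.to_csv(path, index=False)
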
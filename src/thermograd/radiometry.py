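"""Radiometric count <-> temperature conversion.

A radiometric long-wave IR sensor in TLinear mode encodes absolute scene
temperature linearly in its pixel counts: with the default resolution of
0.01 K per count, a count of 30000 means 300.00 K (26.85 degC).  This module
holds the raw-count container (:class:`ThermalFrame`), the derived Celsius
container (:class:`TemperatureField`), the elementwise conversions between
them, and file I/O for both.

Frames whose TLinear flag is off carry scene *flux* counts, for which no
temperature model is available; every conversion refuses them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError, UnsupportedModeError

ABSOLUTE_ZERO_C = -273.15
#: Kelvin per count in TLinear high-gain mode (30000 counts <-> 300.00 K).
DEFAULT_RESOLUTION_K = 0.01


@dataclass
class ThermalFrame:
    """Raw radiometric sensor frame.

    Parameters
    ----------
    counts
        Non-negative integer grid, height x width.  Stored as uint16:
        TLinear centikelvin values (e.g. 30000 for 300 K) exceed the 14 bits
        of the sensor's flux mode, so the container is 16-bit.
    tlinear_enabled
        True when counts encode temperature linearly; conversions refuse
        frames where this is False.
    resolution_k_per_count
        Kelvin per count; 0.01 K in high-gain TLinear mode, 0.1 K in the
        low-resolution dialect some sensors use.
    frame_id
        Free-form provenance identifier carried into derived products.
    """

    counts: np.ndarray
    tlinear_enabled: bool = True
    resolution_k_per_count: float = DEFAULT_RESOLUTION_K
    frame_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.size == 0:
            raise DomainError("counts must be a non-empty 2-D grid")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise DomainError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if counts.min() < 0:
            raise DomainError("counts must be non-negative")
        if counts.max() > np.iinfo(np.uint16).max:
            raise DomainError("counts exceed the 16-bit container")
        if self.resolution_k_per_count <= 0:
            raise DomainError("resolution_k_per_count must be positive")
        self.counts = counts.astype(np.uint16)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class TemperatureField:
    """Per-pixel Celsius temperatures derived from a :class:`ThermalFrame`."""

    celsius: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        celsius = np.asarray(self.celsius, dtype=float)
        if celsius.ndim != 2 or celsius.size == 0:
            raise DomainError("celsius must be a non-empty 2-D grid")
        if np.nanmin(celsius) < ABSOLUTE_ZERO_C:
            raise DomainError("temperatures below absolute zero")
        self.celsius = celsius

    @property
    def shape(self) -> tuple[int, int]:
        return self.celsius.shape


def tlinear_counts_to_kelvin(counts, resolution: float = DEFAULT_RESOLUTION_K):
    """Convert TLinear counts to Kelvin: ``T = counts * resolution``.

    Exact for integer counts; accepts scalars or arrays.
    """
    counts = np.asarray(counts)
    if resolution <= 0:
        raise DomainError("resolution must be positive")
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative")
    kelvin = counts * resolution
    return float(kelvin) if np.isscalar(kelvin) or kelvin.ndim == 0 else kelvin


def kelvin_to_celsius(t_k):
    """Kelvin -> Celsius (``t_k - 273.15``); refuses negative Kelvin."""
    t_k = np.asarray(t_k, dtype=float)
    if np.any(t_k < 0):
        raise DomainError("Kelvin temperature must be non-negative")
    t_c = t_k + ABSOLUTE_ZERO_C
    return float(t_c) if t_c.ndim == 0 else t_c


def frame_to_celsius(frame: ThermalFrame) -> TemperatureField:
    """Elementwise TLinear count -> Celsius conversion of a whole frame."""
    if not frame.tlinear_enabled:
        raise UnsupportedModeError(
            "frame is not in TLinear mode; flux counts carry no temperature model"
        )
    kelvin = tlinear_counts_to_kelvin(frame.counts.astype(np.int64),
                                      frame.resolution_k_per_count)
    return TemperatureField(kelvin_to_celsius(kelvin), provenance=frame.frame_id)


def celsius_to_tlinear_counts(t_c, resolution: float = DEFAULT_RESOLUTION_K):
    """Inverse conversion: Celsius -> nearest integer TLinear counts.

    Round-trips with :func:`frame_to_celsius` to within ``resolution / 2``.
    """
    t_c = np.asarray(t_c, dtype=float)
    if resolution <= 0:
        raise DomainError("resolution must be positive")
    if np.any(t_c < ABSOLUTE_ZERO_C):
        raise DomainError("temperature below absolute zero")
    counts = np.round((t_c - ABSOLUTE_ZERO_C) / resolution)
    if counts.ndim == 0:
        return int(counts)
    return counts.astype(np.uint16 if counts.max() <= np.iinfo(np.uint16).max
                         else np.int64)


def celsius_to_frame(celsius, resolution: float = DEFAULT_RESOLUTION_K,
                     frame_id: str = "") -> ThermalFrame:
    """Quantize a Celsius grid to a sensor-realistic TLinear frame."""
    counts = celsius_to_tlinear_counts(np.asarray(celsius, dtype=float), resolution)
    return ThermalFrame(counts, tlinear_enabled=True,
                        resolution_k_per_count=resolution, frame_id=frame_id)


# ---------------------------------------------------------------------------
# File I/O: 16-bit single-channel PNG/TIFF with a JSON metadata sidecar.

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_frame(frame: ThermalFrame, path: str | Path) -> None:
    """Write counts as 16-bit PNG or TIFF plus a ``<stem>.json`` sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, frame.counts)
    elif suffix == ".png":
        import imageio.v3 as iio
        iio.imwrite(path, frame.counts)
    else:
        raise ValueError(f"unsupported frame format {suffix!r} (use .png/.tif)")
    meta = {
        "tlinear_enabled": frame.tlinear_enabled,
        "resolution_k_per_count": frame.resolution_k_per_count,
        "frame_id": frame.frame_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def load_frame(path: str | Path) -> ThermalFrame:
    """Read a frame written by :func:`save_frame` (sidecar optional)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        counts = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio
        counts = iio.imread(path)
    else:
        raise ValueError(f"unsupported frame format {suffix!r} (use .png/.tif)")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ThermalFrame(
        np.asarray(counts),
        tlinear_enabled=bool(meta.get("tlinear_enabled", True)),
        resolution_k_per_count=float(
            meta.get("resolution_k_per_count", DEFAULT_RESOLUTION_K)),
        frame_id=str(meta.get("frame_id", path.stem)),
    )


def save_field(field_: TemperatureField, path: str | Path) -> None:
    """Write Celsius grid as CSV (no header) or 32-bit float TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        np.savetxt(path, field_.celsius, delimiter=",", fmt="%.6g")
    elif suffix in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, field_.celsius.astype(np.float32))
    else:
        raise ValueError(f"unsupported field format {suffix!r} (use .csv/.tif)")


def load_field(path: str | Path, provenance: str = "") -> TemperatureField:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        celsius = np.loadtxt(path, delimiter=",", ndmin=2)
    elif suffix in (".tif", ".tiff"):
        import tifffile
        celsius = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported field format {suffix!r} (use .csv/.tif)")
    return TemperatureField(np.asarray(celsius, dtype=float),
                            provenance=provenance or path.stem)
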
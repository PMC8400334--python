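"""Dark-current removal, normalization, and spectral binning.

Three per-pixel normalization schemes are provided, all applied to
dark-corrected spectra ``r' = r − D``:

* ``per_norm``   — min–max scale each pixel spectrum to [0, 100]:
  ``Pn = (r'_n − r'_min) / (r'_max − r'_min) × 100``.
* ``max_norm``   — divide by the pixel's maximum:
  ``Mn = r'_n / r'_max × 100``.
* ``reflectance_norm`` — divide band-wise by the white reference:
  ``Rn = (r_n − D) / (Wref − D)``.

Per-Norm and Max-Norm are invariant to per-pixel multiplicative gain
applied after dark removal, which is what collapses the large
pixel-to-pixel offsets seen on a glossy, unevenly lit seaweed surface.

Spectral binning here is decimation (keep every n-th band), matching
in-camera 1/n binning: 224 bands → 112 (n=2) → 56 (n=4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hypercube_io import HyperCube, IntegrityError, ReferenceFrame

__all__ = [
    "CalibratedCube",
    "subtract_dark",
    "per_norm",
    "max_norm",
    "reflectance_norm",
    "spectral_bin",
    "METHODS",
]

METHODS = ("per_norm", "max_norm", "reflectance_norm")


@dataclass
class CalibratedCube:
    """Normalized cube: same geometry as the source, float values.

    ``binning`` records the decimation factor already applied (1 = none).
    """

    data: np.ndarray
    method: str
    wavelengths: np.ndarray
    binning: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown calibration method {self.method!r}")
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


def _dark_grid(cube: HyperCube, dark: ReferenceFrame) -> np.ndarray:
    return dark.as_grid(cube.n_samples, cube.n_bands)


def subtract_dark(cube: HyperCube, dark: ReferenceFrame) -> HyperCube:
    """Remove fixed-pattern camera noise: ``DN → max(DN − D, 0)``.

    Sensor counts cannot be negative, so the difference is clamped at 0.
    """
    d = _dark_grid(cube, dark)
    out = np.maximum(cube.data.astype(float) - d[None, :, :], 0.0)
    return HyperCube(data=out, wavelengths=cube.wavelengths, meta=dict(cube.meta))


def _dark_removed(cube: HyperCube, dark: ReferenceFrame) -> np.ndarray:
    """Unclamped dark-corrected spectra (normalizations handle sign)."""
    d = _dark_grid(cube, dark)
    return cube.data.astype(float) - d[None, :, :]


def _warn_degenerate(n: int) -> None:
    warnings.warn(
        f"{n} pixel(s) with a constant dark-corrected spectrum; set to 0",
        stacklevel=3,
    )


def per_norm(cube: HyperCube, dark: ReferenceFrame) -> CalibratedCube:
    """Per-pixel percentage normalization to [0, 100].

    Each pixel's dark-corrected spectrum is min–max scaled so its
    minimum band maps to 0 and its maximum to 100.  Pixels with a
    constant spectrum are degenerate: flagged with a warning, set to 0.
    """
    r = _dark_removed(cube, dark)
    rmin = r.min(axis=2, keepdims=True)
    rmax = r.max(axis=2, keepdims=True)
    span = rmax - rmin
    degenerate = span[..., 0] == 0
    out = (r - rmin) / np.where(span == 0, 1.0, span) * 100.0
    if degenerate.any():
        _warn_degenerate(int(degenerate.sum()))
        out[degenerate] = 0.0
    return CalibratedCube(out, "per_norm", cube.wavelengths, meta=dict(cube.meta))


def max_norm(cube: HyperCube, dark: ReferenceFrame) -> CalibratedCube:
    """Divide each pixel's spectrum by its maximum, times 100."""
    r = _dark_removed(cube, dark)
    rmax = r.max(axis=2, keepdims=True)
    degenerate = rmax[..., 0] <= 0
    out = r / np.where(rmax <= 0, 1.0, rmax) * 100.0
    if degenerate.any():
        _warn_degenerate(int(degenerate.sum()))
        out[degenerate] = 0.0
    return CalibratedCube(out, "max_norm", cube.wavelengths, meta=dict(cube.meta))


def reflectance_norm(
    cube: HyperCube, dark: ReferenceFrame, white: ReferenceFrame
) -> CalibratedCube:
    """Band-wise reflectance: ``(r − D) / (Wref − D)``.

    A pixel identical to the white frame maps to 1.0 everywhere, the
    dark frame to 0.0.  Raises if the white reference does not exceed
    the dark current at every (sample, band).
    """
    d = _dark_grid(cube, dark)
    w = white.as_grid(cube.n_samples, cube.n_bands)
    denom = w - d
    if np.any(denom <= 0):
        bad = np.unique(np.nonzero(np.any(denom <= 0, axis=0))[0]) + 1
        raise IntegrityError(
            f"white reference <= dark current at band(s) {bad.tolist()} (1-based)"
        )
    out = (cube.data.astype(float) - d[None]) / denom[None]
    return CalibratedCube(out, "reflectance_norm", cube.wavelengths, meta=dict(cube.meta))


def spectral_bin(cube, n: int, phase: int = 0):
    """1/n spectral binning by decimation: keep every n-th band.

    Starts at band ``phase`` (default 0, i.e. the first band of each
    group is kept), subsetting the wavelength grid identically.  The
    band count must be divisible by ``n`` — no partial bins.  Works on
    raw and calibrated cubes alike, returning the same type.
    """
    if n not in (1, 2, 4):
        raise ValueError(f"binning factor must be 1, 2 or 4, got {n}")
    if not 0 <= phase < n:
        raise ValueError(f"phase must lie in [0, {n}), got {phase}")
    n_bands = cube.data.shape[2]
    if n_bands % n:
        raise ValueError(f"band count {n_bands} not divisible by binning factor {n}")
    if n == 1:
        return cube
    data = cube.data[:, :, phase::n]
    wl = np.asarray(cube.wavelengths)[phase::n]
    if isinstance(cube, CalibratedCube):
        return CalibratedCube(data, cube.method, wl, binning=cube.binning * n, meta=dict(cube.meta))
    return HyperCube(data=data, wavelengths=wl, meta=dict(cube.meta))
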
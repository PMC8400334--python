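"""ENVI hypercube I/O and the raster data model.

A push-broom VNIR camera captures one spatial line times all spectral
bands per frame; stacking frames along the transport direction yields a
hypercube with axes ``(line, sample, band)``.  Values are raw digital
numbers (DN): dimensionless, non-negative sensor counts.

Cubes are exchanged in the ENVI format: a flat binary raster plus a
plain-text ``.hdr`` sidecar recording dimensions, data type, interleave
and the per-band centre wavelengths.  All three standard interleaves
(BIL, BIP, BSQ) are read; BIL is the write default because it is the
native frame order of a line-scan camera.

Internally everything is 0-based ``(line, sample, band)``.  Band numbers
in user-facing configuration are 1-based (matching the field convention
of speaking of "the 26th band"); the conversion happens exactly once, at
config parse time in :mod:`kelpscan.reference_model`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "HyperCube",
    "ReferenceFrame",
    "FormatError",
    "IntegrityError",
    "read_envi",
    "write_envi",
    "write_envi_array",
    "read_reference",
    "write_reference",
    "MAX_BANDS",
    "MAX_SAMPLES",
]

#: Sensor limits of the camera class this pipeline targets.
MAX_BANDS = 224
MAX_SAMPLES = 1024


class FormatError(ValueError):
    """Raised when an ENVI header or raster cannot be parsed."""


class IntegrityError(ValueError):
    """Raised when parsed or constructed data violates a cube invariant."""


# ENVI "data type" codes <-> numpy dtypes (the commonly used subset).
_ENVI_DTYPES = {
    1: np.dtype("u1"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
    13: np.dtype("<u4"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """Raw hypercube: DN raster plus per-band centre wavelengths.

    Parameters
    ----------
    data
        3-D array of digital numbers, axes ``(line, sample, band)``.
    wavelengths
        Strictly increasing band-centre wavelengths in nm; length equals
        the band-axis extent.
    meta
        Free-form acquisition descriptors (frame rate, bit depth, ...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.validate()

    # -- shape helpers -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def line(self, i: int) -> np.ndarray:
        """Single acquisition line as a ``(samples, bands)`` view."""
        return self.data[i]

    def lines(self) -> Iterator[np.ndarray]:
        """Iterate lines in acquisition order (the streaming contract)."""
        for i in range(self.n_lines):
            yield self.data[i]

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise IntegrityError(f"cube data must be 3-D, got {self.data.ndim}-D")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.n_bands:
            raise IntegrityError(
                f"wavelength count {len(self.wavelengths)} != band count {self.n_bands}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise IntegrityError("wavelengths must be strictly increasing")
        if self.n_bands > MAX_BANDS:
            raise IntegrityError(f"band count {self.n_bands} exceeds sensor limit {MAX_BANDS}")
        if self.n_samples > MAX_SAMPLES:
            raise IntegrityError(
                f"samples per line {self.n_samples} exceeds sensor limit {MAX_SAMPLES}"
            )
        if self.data.size and self.data.min() < 0:
            raise IntegrityError("DN values must be non-negative")


@dataclass
class ReferenceFrame:
    """Dark-current or white-reference frame.

    ``values`` is either a per-``(sample, band)`` array or a per-band
    vector when the reference is spatially constant.
    """

    kind: str  # "dark_current" | "white_reference"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("dark_current", "white_reference"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise IntegrityError("reference values must be 1-D (per band) or 2-D (sample, band)")

    def as_grid(self, n_samples: int, n_bands: int) -> np.ndarray:
        """Broadcast to a full ``(samples, bands)`` grid."""
        v = self.values
        if v.ndim == 1:
            if len(v) != n_bands:
                raise IntegrityError(f"per-band reference length {len(v)} != {n_bands} bands")
            return np.broadcast_to(v, (n_samples, n_bands))
        if v.shape != (n_samples, n_bands):
            raise IntegrityError(f"reference shape {v.shape} != ({n_samples}, {n_bands})")
        return v


# ---------------------------------------------------------------------------
# ENVI parsing


def _header_path(path: Path) -> Path:
    if path.suffix == ".hdr":
        return path
    cand = path.with_suffix(path.suffix + ".hdr")
    if cand.exists():
        return cand
    return path.with_suffix(".hdr")


def _raster_path(hdr: Path) -> Path:
    base = hdr.with_suffix("")  # strip .hdr
    for cand in (base, base.with_suffix(".raw"), base.with_suffix(".img"), base.with_suffix(".dat")):
        if cand.exists() and cand != hdr:
            return cand
    raise FormatError(f"no raster file found next to header {hdr}")


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic)")
    # Collapse brace-delimited multi-line values, then parse key = value.
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", body, re.M | re.S):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def read_envi(path: str | Path) -> HyperCube:
    """Read an ENVI raster + header pair into a :class:`HyperCube`.

    ``path`` may point at either the header or the raster file.
    """
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise FormatError(f"ENVI header not found for {path}")
    fields = _parse_header(hdr.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bil").lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field {exc}") from exc
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")

    wl_field = fields.get("wavelength")
    if wl_field is None:
        raise FormatError("ENVI header has no wavelength block")
    wavelengths = np.array(
        [float(tok) for tok in wl_field.strip("{} \n").replace("\n", ",").split(",") if tok.strip()]
    )
    if len(wavelengths) != bands:
        raise IntegrityError(
            f"header lists {len(wavelengths)} wavelengths for {bands} bands"
        )

    dtype = _ENVI_DTYPES[code]
    raster = path if (path.exists() and path != hdr) else _raster_path(hdr)
    raw = np.fromfile(raster, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise IntegrityError(
            f"raster holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:  # bsq
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    meta = {k: v for k, v in fields.items() if k.startswith("kelpscan ")}
    return HyperCube(data=np.ascontiguousarray(data), wavelengths=wavelengths, meta=meta)


def write_envi(
    cube: HyperCube,
    path: str | Path,
    interleave: str = "bil",
    dtype: np.dtype | str | None = None,
) -> Path:
    """Write a cube as ENVI raster + ``.hdr``; round-trips bit-exactly.

    Returns the raster path.  DN rasters default to unsigned 16-bit;
    float cubes keep their own dtype.
    """
    cube.validate()
    return write_envi_array(cube.data, cube.wavelengths, path, interleave, dtype, cube.meta)


def write_envi_array(
    data: np.ndarray,
    wavelengths: np.ndarray,
    path: str | Path,
    interleave: str = "bil",
    dtype: np.dtype | str | None = None,
    meta: dict | None = None,
) -> Path:
    """Low-level ENVI writer for any ``(line, sample, band)`` array.

    Unlike :func:`write_envi` this skips the DN invariants, so it also
    serves calibrated cubes (which may hold negative floats).
    """
    data = np.asarray(data)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if data.ndim != 3 or len(wavelengths) != data.shape[2]:
        raise IntegrityError("need 3-D (line, sample, band) data with one wavelength per band")
    if np.any(np.diff(wavelengths) <= 0):
        raise IntegrityError("wavelengths must be strictly increasing")
    n_lines, n_samples, n_bands = data.shape
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype is None:
        dtype = data.dtype if data.dtype.kind == "f" else np.dtype("<u2")
    dtype = np.dtype(dtype).newbyteorder("<")
    if dtype not in _DTYPE_CODES:
        raise FormatError(f"dtype {dtype} has no ENVI data-type code")

    path = Path(path)
    raster = path.with_suffix(".raw") if path.suffix == ".hdr" else path
    hdr = raster.with_suffix(raster.suffix + ".hdr") if raster.suffix else raster.with_suffix(".hdr")

    arr = np.ascontiguousarray(data, dtype=dtype)
    if interleave == "bil":
        out = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        out = arr
    else:
        out = arr.transpose(2, 0, 1)

    wl = ",\n ".join(repr(float(w)) for w in wavelengths)
    meta = meta or {}
    meta_lines = "".join(f"{k} = {v}\n" for k, v in meta.items() if isinstance(v, (str, int, float)))
    hdr.write_text(
        "ENVI\n"
        f"samples = {n_samples}\n"
        f"lines = {n_lines}\n"
        f"bands = {n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"{meta_lines}"
        "wavelength units = Nanometers\n"
        f"wavelength = {{\n {wl}\n}}\n"
    )
    np.ascontiguousarray(out).tofile(raster)
    return raster


def write_reference(
    frame: ReferenceFrame, wavelengths: np.ndarray, path: str | Path
) -> Path:
    """Store a dark/white reference as a single-line ENVI raster."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = frame.values
    if values.ndim == 1:
        values = values[None, :]
    cube = HyperCube(
        data=values[None, :, :],
        wavelengths=wavelengths,
        meta={"kelpscan reference kind": frame.kind},
    )
    return write_envi(cube, path, dtype=np.float32)


def read_reference(path: str | Path, kind: str | None = None) -> ReferenceFrame:
    """Read a single-line ENVI raster back into a :class:`ReferenceFrame`."""
    cube = read_envi(path)
    if cube.n_lines != 1:
        raise IntegrityError(f"reference raster must have exactly 1 line, got {cube.n_lines}")
    if kind is None:
        kind = cube.meta.get("kelpscan reference kind", "dark_current")
    return ReferenceFrame(kind=kind, values=cube.data[0].astype(float))
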
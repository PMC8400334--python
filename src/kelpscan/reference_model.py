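"""Per-class spectral reference statistics and subtraction-band selection.

A :class:`ReferenceProfile` summarizes a labeled set of Per-Norm pixel
spectra for one material class (seaweed or conveyor belt): per-band mean
and population standard deviation, plus the standardized envelope — the
band-wise min/max of the reference pixels after z-scoring.  The envelope
(not ±k·σ) is what the stage-2 inspection widens by a margin.

:func:`select_band_pair` is the exhaustive search for the two-band
subtraction feature: within one wavelength range it scores every ordered
band pair (i < j) by the separation between the two classes' mean
subtraction values and returns the argmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ReferenceProfile",
    "SubtractionConfig",
    "build_profile",
    "standardize",
    "select_band_pair",
    "derive_intervals",
    "default_subtraction_config",
    "load_subtraction_config",
    "save_profiles",
    "load_profiles",
]


@dataclass
class ReferenceProfile:
    """Per-band reference statistics for one material class.

    ``mean``/``std`` are in Per-Norm units; ``env_low``/``env_high`` are
    dimensionless z units.  The std is the population std: with ~10,000
    reference pixels the sample/population distinction is negligible,
    and population keeps tiny test fixtures deterministic.
    """

    class_name: str
    mean: np.ndarray
    std: np.ndarray
    env_low: np.ndarray
    env_high: np.ndarray
    n_pixels: int
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("mean", "std", "env_low", "env_high"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.std <= 0):
            bad = (np.nonzero(self.std <= 0)[0] + 1).tolist()
            raise ValueError(f"non-positive std at band(s) {bad} (1-based)")
        if np.any(self.env_low > 0) or np.any(self.env_high < 0):
            raise ValueError("envelope must bracket 0 (the mean pixel) at every band")

    @property
    def n_bands(self) -> int:
        return len(self.mean)


def build_profile(pixels: np.ndarray, class_name: str) -> ReferenceProfile:
    """Build a :class:`ReferenceProfile` from Per-Norm reference pixels.

    ``pixels`` is ``(n_pixels, n_bands)`` with n >= 2.  Bands where the
    reference set has zero spread are rejected by name, since they make
    standardization undefined.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[0] < 2:
        raise ValueError("need a 2-D (n_pixels, n_bands) array with at least 2 pixels")
    mean = pixels.mean(axis=0)
    std = pixels.std(axis=0)  # population
    if np.any(std == 0):
        bad = (np.nonzero(std == 0)[0] + 1).tolist()
        raise ValueError(f"zero standard deviation at band(s) {bad} (1-based)")
    z = (pixels - mean) / std
    return ReferenceProfile(
        class_name=class_name,
        mean=mean,
        std=std,
        env_low=z.min(axis=0),
        env_high=z.max(axis=0),
        n_pixels=pixels.shape[0],
    )


def standardize(x: np.ndarray, profile: ReferenceProfile) -> np.ndarray:
    """z-score spectra against a class profile: ``(x − μ) / σ`` band-wise.

    Accepts a single spectrum or any leading batch shape ``(..., bands)``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != profile.n_bands:
        raise ValueError(f"spectrum has {x.shape[-1]} bands, profile has {profile.n_bands}")
    return (x - profile.mean) / profile.std


def select_band_pair(
    profile_a: ReferenceProfile,
    profile_b: ReferenceProfile,
    range_nm: tuple[float, float],
    wavelengths: np.ndarray,
) -> tuple[int, int, float]:
    """Exhaustive two-band search for maximal class separation.

    Scores every ordered pair ``(i < j)`` of bands inside ``range_nm``
    by ``|(μa_j − μa_i) − (μb_j − μb_i)|`` and returns the 1-based
    ``(band_lo, band_hi, separation)`` argmax.  Ties break toward the
    smaller i, then the smaller j.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    lo, hi = range_nm
    idx = np.nonzero((wavelengths >= lo) & (wavelengths <= hi))[0]
    if len(idx) < 2:
        raise ValueError(f"fewer than 2 bands inside {range_nm} nm")
    # Separation of pair (i, j) reduces to |d_j − d_i| with d = μa − μb.
    d = profile_a.mean[idx] - profile_b.mean[idx]
    sep = np.abs(d[None, :] - d[:, None])
    iu, ju = np.triu_indices(len(idx), k=1)
    scores = sep[iu, ju]
    best = scores.max()
    # np.argmax over the row-major upper triangle is the lexicographic
    # first (smallest i, then j) among exact ties.
    k = int(np.argmax(scores == best))
    return int(idx[iu[k]]) + 1, int(idx[ju[k]]) + 1, float(best)


@dataclass
class SubtractionConfig:
    """Stage-1 operating point: two band pairs plus class intervals.

    Band numbers are 1-based indices into the binned cube.  Intervals
    are in Per-Norm difference units, closed on both ends.
    """

    visible_pair: tuple[int, int]
    nir_pair: tuple[int, int]
    visible_intervals: dict[str, tuple[float, float]]
    nir_intervals: dict[str, tuple[float, float]]
    visible_range_nm: tuple[float, float] = (400.0, 750.0)
    nir_range_nm: tuple[float, float] = (750.0, 1000.0)

    def __post_init__(self) -> None:
        self.visible_pair = tuple(int(b) for b in self.visible_pair)
        self.nir_pair = tuple(int(b) for b in self.nir_pair)
        self.visible_intervals = {k: tuple(map(float, v)) for k, v in self.visible_intervals.items()}
        self.nir_intervals = {k: tuple(map(float, v)) for k, v in self.nir_intervals.items()}
        for name, ivals in (("visible", self.visible_intervals), ("nir", self.nir_intervals)):
            _check_disjoint(ivals, name)

    def validate_against(self, wavelengths: np.ndarray) -> None:
        """Check that the configured bands exist and lie in their nm range."""
        wavelengths = np.asarray(wavelengths, dtype=float)
        for pair, (lo, hi), name in (
            (self.visible_pair, self.visible_range_nm, "visible"),
            (self.nir_pair, self.nir_range_nm, "nir"),
        ):
            for b in pair:
                if not 1 <= b <= len(wavelengths):
                    raise ValueError(f"{name} band {b} outside 1..{len(wavelengths)}")
                if not lo <= wavelengths[b - 1] <= hi:
                    raise ValueError(
                        f"{name} band {b} at {wavelengths[b - 1]:.1f} nm outside [{lo}, {hi}] nm"
                    )


def _check_disjoint(intervals: dict, range_name: str) -> None:
    items = sorted(intervals.items(), key=lambda kv: kv[1][0])
    for (ka, (_, ahi)), (kb, (blo, _)) in zip(items, items[1:]):
        if blo <= ahi:
            raise ValueError(
                f"{range_name} intervals of {ka!r} and {kb!r} overlap — classes not separable"
            )


def default_subtraction_config() -> SubtractionConfig:
    """The bundled operating point for 112-band (1/2-binned) cubes."""
    with resources.files("kelpscan.data").joinpath("default_subtraction.yaml").open() as fh:
        return _config_from_dict(yaml.safe_load(fh))


def load_subtraction_config(path: str | Path) -> SubtractionConfig:
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def _config_from_dict(d: dict) -> SubtractionConfig:
    return SubtractionConfig(
        visible_pair=tuple(d["visible_pair"]),
        nir_pair=tuple(d["nir_pair"]),
        visible_intervals={k: tuple(v) for k, v in d["visible_intervals"].items()},
        nir_intervals={k: tuple(v) for k, v in d["nir_intervals"].items()},
        visible_range_nm=tuple(d.get("visible_range_nm", (400.0, 750.0))),
        nir_range_nm=tuple(d.get("nir_range_nm", (750.0, 1000.0))),
    )


def derive_intervals(
    pixel_sets: dict[str, np.ndarray],
    config: SubtractionConfig,
    slack: float = 0.0,
) -> SubtractionConfig:
    """Derive class acceptance intervals from labeled reference pixels.

    For each class, the interval is the observed [min, max] of the
    subtraction value over its reference pixels at the configured band
    pairs, padded by ``slack`` on each side (default 0: the shipped
    operating point uses fixed intervals, not a derivation rule).
    """
    from .detector import subtraction_features  # local: avoid import cycle

    vis: dict[str, tuple[float, float]] = {}
    nir: dict[str, tuple[float, float]] = {}
    for cls, pixels in pixel_sets.items():
        pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
        if pixels.shape[0] == 1:
            warnings.warn(f"class {cls!r} has a single reference pixel: zero-width interval")
        sv, sn = subtraction_features(pixels, config)
        vis[cls] = (float(sv.min()) - slack, float(sv.max()) + slack)
        nir[cls] = (float(sn.min()) - slack, float(sn.max()) + slack)
    return replace(config, visible_intervals=vis, nir_intervals=nir)


# ---------------------------------------------------------------------------
# Profile serialization: versioned plain-text table so a detection run is
# reproducible without the training pixels.

_PROFILE_VERSION = "kelpscan-profiles v1"


def save_profiles(profiles: dict[str, ReferenceProfile], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {_PROFILE_VERSION}\n")
        for name, p in profiles.items():
            fh.write(f"# class={name} n_pixels={p.n_pixels}\n")
        fh.write("class\tband\twavelength\tmean\tstd\tenv_low\tenv_high\n")
        for name, p in profiles.items():
            wl = p.wavelengths if p.wavelengths is not None else [float("nan")] * p.n_bands
            for b in range(p.n_bands):
                vals = (wl[b], p.mean[b], p.std[b], p.env_low[b], p.env_high[b])
                fh.write(f"{name}\t{b + 1}\t" + "\t".join(repr(float(v)) for v in vals) + "\n")
    return path


def load_profiles(path: str | Path) -> dict[str, ReferenceProfile]:
    path = Path(path)
    n_pixels: dict[str, int] = {}
    rows: dict[str, list] = {}
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"# {_PROFILE_VERSION}":
            raise ValueError(f"{path} is not a {_PROFILE_VERSION} table")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = dict(tok.split("=") for tok in line[1:].split() if "=" in tok)
                if "class" in parts:
                    n_pixels[parts["class"]] = int(parts.get("n_pixels", 0))
                continue
            if line.startswith("class\t"):
                continue
            cls, band, wl, mean, std, lo, hi = line.split("\t")
            rows.setdefault(cls, []).append((int(band), *(float(v) for v in (wl, mean, std, lo, hi))))
    out: dict[str, ReferenceProfile] = {}
    for cls, rr in rows.items():
        rr.sort()
        arr = np.array([r[1:] for r in rr], dtype=float)
        wl = arr[:, 0]
        out[cls] = ReferenceProfile(
            class_name=cls,
            mean=arr[:, 1],
            std=arr[:, 2],
            env_low=arr[:, 3],
            env_high=arr[:, 4],
            n_pixels=n_pixels.get(cls, 0),
            wavelengths=None if np.isnan(wl).all() else wl,
        )
    return out
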
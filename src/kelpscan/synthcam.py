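"""Synthetic push-broom line-scan camera for seaweed sheets on a belt.

The generator's purpose is to reproduce the *decision structure* of the
inspection problem — interval membership of the two-band subtraction
features, envelope excursions under standardization, diffuse-reflection
brightness events — not radiometrically accurate reflectance.  Each
material is a piecewise-linear Per-Norm-space profile (control points in
[0, 100] over 400–1000 nm) mapped to DN as

    DN = dark + gain_pixel * shape / 100 + diffuse_boost + noise,

with a per-pixel multiplicative gain jitter (the large pixel-to-pixel
offset of a glossy, unevenly lit surface, which Per-Norm is designed to
cancel), an additive brightness boost confined to 500–680 nm occurring
with some probability (diffuse reflection off the greasy sheet surface),
and additive Gaussian sensor noise.  DN values are quantized to uint16.

Material design constraints (verified at library construction):

* seaweed:      per-normed SV in [60, 80], SN in [−30, −5];
* belt:         SV in [20, 45], SN in [5, 25];
* plastic:      inside the stage-1 seaweed intervals but far outside
                both class envelopes at several bands (a black plastic
                bag — only the standardization inspection catches it);
* shrimp_shell: SV in the gap between the class intervals — caught at
                stage 1; likewise insect (SV below both intervals) and
                thread (SV above both).

The default grid is 112 uniform bands over 400–1000 nm, the 1/2-binned
operating point, on which 1-based bands 26/63/68/93 sit at
535.1/735.1/762.2/897.3 nm.  All randomness flows from a single seed:
a fixed seed yields a byte-identical cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube_io import HyperCube, ReferenceFrame
from .reference_model import SubtractionConfig, default_subtraction_config

__all__ = [
    "BAND_COUNT",
    "default_wavelengths",
    "MaterialSpectrum",
    "ForeignObject",
    "SceneSpec",
    "Scene",
    "make_materials",
    "draw_dn_pixels",
    "render_scene",
    "make_benchmark",
    "MATERIAL_CODES",
]

BAND_COUNT = 112

#: Ground-truth mask codes; >= 2 means a foreign material.
MATERIAL_CODES = {"belt": 0, "seaweed": 1, "shrimp_shell": 2, "plastic": 3, "insect": 4, "thread": 5}


def default_wavelengths(n_bands: int = BAND_COUNT) -> np.ndarray:
    """Uniform band grid over 400–1000 nm (VNIR)."""
    return np.linspace(400.0, 1000.0, n_bands)


# The four decision wavelengths on the 112-band grid (1-based 26/63/68/93).
_WL = default_wavelengths()
_L26, _L63, _L68, _L93 = _WL[25], _WL[62], _WL[67], _WL[92]


@dataclass
class MaterialSpectrum:
    """Piecewise-linear material model in Per-Norm shape units.

    ``control_values`` are the shape at ``control_wavelengths``;
    ``jitter`` gives the uniform half-width applied per control point
    per pixel (bounded spread, so reference envelopes cover fresh
    draws).  ``diffuse_boost`` is ``(probability, lo, hi)`` for the
    additive 500–680 nm brightness event, in shape units scaled by the
    base gain; ``None`` disables it.
    """

    name: str
    control_wavelengths: np.ndarray
    control_values: np.ndarray
    jitter: np.ndarray
    gain_base: float
    gain_jitter: float = 0.1
    diffuse_boost: tuple[float, float, float] | None = None
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        self.control_wavelengths = np.asarray(self.control_wavelengths, dtype=float)
        self.control_values = np.asarray(self.control_values, dtype=float)
        self.jitter = np.asarray(self.jitter, dtype=float)
        if np.any(self.control_values < 0):
            raise ValueError("base profile must be non-negative")
        if np.any(self.jitter < 0) or self.gain_jitter < 0 or self.noise_sd < 0:
            raise ValueError("spread parameters must be non-negative")

    def interp(self, wavelengths: np.ndarray, values: np.ndarray | None = None) -> np.ndarray:
        """Evaluate the (possibly jittered) profile on a band grid.

        ``values`` may be a ``(n_pixels, n_control)`` batch; returns
        ``(n_pixels, n_bands)`` then.
        """
        if values is None:
            return np.interp(wavelengths, self.control_wavelengths, self.control_values)
        seg = np.clip(
            np.searchsorted(self.control_wavelengths, wavelengths, side="right") - 1,
            0,
            len(self.control_wavelengths) - 2,
        )
        w0 = self.control_wavelengths[seg]
        w1 = self.control_wavelengths[seg + 1]
        t = np.clip((wavelengths - w0) / (w1 - w0), 0.0, 1.0)
        return values[:, seg] * (1 - t) + values[:, seg + 1] * t


def _boost_taper(wavelengths: np.ndarray) -> np.ndarray:
    """Unit taper of the diffuse-reflection boost: ramps 500→520 nm,
    plateau to 660 nm, ramps down to 680 nm."""
    w = np.asarray(wavelengths, dtype=float)
    up = np.clip((w - 500.0) / 20.0, 0.0, 1.0)
    down = np.clip((680.0 - w) / 20.0, 0.0, 1.0)
    return np.minimum(up, down)


def _hat_basis(material: MaterialSpectrum, k: int, wavelengths: np.ndarray) -> np.ndarray:
    """Influence of control point ``k`` on each band: the piecewise-linear
    hat function that is 1 at that control wavelength, 0 at its neighbors."""
    unit = np.zeros(len(material.control_values))
    unit[k] = 1.0
    return np.interp(wavelengths, material.control_wavelengths, unit)


def sample_shapes(
    material: MaterialSpectrum, n: int, rng: np.random.Generator, wavelengths: np.ndarray
) -> np.ndarray:
    """Draw ``n`` per-pixel shape spectra (Per-Norm units, pre-gain).

    Interpolation is linear in the control values, so per-pixel jitter
    reduces to rank-1 hat-basis updates on the base spectrum — one per
    jittered control point.
    """
    shapes = np.tile(material.interp(wavelengths), (n, 1))
    for k in np.nonzero(material.jitter)[0]:
        u = rng.uniform(-material.jitter[k], material.jitter[k], size=n)
        shapes += np.outer(u, _hat_basis(material, int(k), wavelengths))
    if material.diffuse_boost is not None:
        p, lo, hi = material.diffuse_boost
        hit = rng.random(n) < p
        amp = np.where(hit, rng.uniform(lo, hi, size=n), 0.0)
        shapes = shapes + amp[:, None] * _boost_taper(wavelengths)[None, :]
    return shapes


def draw_dn_pixels(
    material: MaterialSpectrum,
    n: int,
    rng: np.random.Generator,
    wavelengths: np.ndarray,
    dark: np.ndarray,
) -> np.ndarray:
    """Draw ``n`` DN spectra, quantized to whole counts.

    ``dark`` is a per-band vector or an ``(n, bands)`` per-pixel grid.
    The diffuse boost is additive in DN (amplitude scaled by the base
    gain, not the jittered pixel gain), so heavily-lit pixels do not
    get proportionally larger boosts.
    """
    boost = material.diffuse_boost
    mat_plain = MaterialSpectrum(
        name=material.name,
        control_wavelengths=material.control_wavelengths,
        control_values=material.control_values,
        jitter=material.jitter,
        gain_base=material.gain_base,
        gain_jitter=material.gain_jitter,
        diffuse_boost=None,
        noise_sd=material.noise_sd,
    )
    shapes = sample_shapes(mat_plain, n, rng, wavelengths)
    gain = material.gain_base * rng.uniform(
        1.0 - material.gain_jitter, 1.0 + material.gain_jitter, size=n
    )
    dn = np.asarray(dark, dtype=float) + shapes / 100.0 * gain[:, None]
    if boost is not None:
        p, lo, hi = boost
        hit = rng.random(n) < p
        amp = np.where(hit, rng.uniform(lo, hi, size=n), 0.0)
        dn = dn + (amp[:, None] * _boost_taper(wavelengths)[None, :]) / 100.0 * material.gain_base
    dn += rng.normal(0.0, material.noise_sd, size=dn.shape)
    np.rint(dn, out=dn)
    np.clip(dn, 0, 65535, out=dn)
    return dn.astype(np.uint16)


def make_materials(
    config: SubtractionConfig | None = None,
    wavelengths: np.ndarray | None = None,
) -> dict[str, MaterialSpectrum]:
    """Build the default material library, constructed so the shipped
    stage-1 intervals hold by design.

    Raises if the base profiles (worst-case over jitter, boost and
    gain spread) violate the configured intervals.
    """
    if config is None:
        config = default_subtraction_config()
    if wavelengths is None:
        wavelengths = default_wavelengths()

    def mat(name, pts, jit, gain, gj=0.1, boost=None, noise=3.0):
        wl = np.array([p[0] for p in pts], dtype=float)
        val = np.array([p[1] for p in pts], dtype=float)
        j = np.zeros(len(pts))
        for k, hw in jit.items():
            j[k] = hw
        return MaterialSpectrum(
            name=name,
            control_wavelengths=wl,
            control_values=val,
            jitter=j,
            gain_base=gain,
            gain_jitter=gj,
            diffuse_boost=boost,
            noise_sd=noise,
        )

    # Every profile starts with a 0-plateau (400–410 nm) and carries a
    # 100-plateau at its brightest region: Per-Norm pins a pixel's min
    # band to exactly 0 and its max to exactly 100, so which band is
    # extremal must vary from pixel to pixel or those bands would have
    # zero reference spread and standardization would be undefined.
    # The inspected classes (seaweed, belt) also jitter their plateau
    # control points: real material varies at EVERY band, and the
    # envelope inspection presumes the per-band reference spread
    # reflects that variation rather than bare sensor noise (whose
    # one-sided tail at a pinned band the envelope would understate).
    # Per-pixel plateau shifts cancel out of the subtraction features
    # up to a small scale distortion, which the feasibility check
    # bounds below.
    lib = {
        # Vegetation-like: chlorophyll-dark visible, steep red edge,
        # NIR plateau sagging toward 900 nm (SN < 0).
        "seaweed": mat(
            "seaweed",
            [(400, 0), (410, 0), (450, 4), (500, 7), (_L26, 10), (600, 16), (680, 28),
             (710, 55), (_L63, 82), (752, 100), (768, 100), (800, 97), (850, 92),
             (_L93, 86), (950, 83), (1000, 80)],
            {0: 1.0, 1: 1.0, 5: 2.0, 6: 3.0, 8: 3.0, 9: 1.0, 10: 1.0, 13: 4.0},
            gain=2400.0,
            boost=(0.35, 3.0, 6.0),
        ),
        # Grey belt: gently rising, brightest in the NIR (SN > 0).
        "belt": mat(
            "belt",
            [(400, 0), (410, 0), (500, 25), (_L26, 40), (600, 52), (680, 60), (_L63, 72),
             (760, 74), (800, 78), (_L93, 89), (950, 95), (980, 100), (1000, 100)],
            {0: 1.0, 1: 1.0, 3: 2.0, 6: 2.0, 9: 3.0, 11: 1.0, 12: 1.0},
            gain=1200.0,
            gj=0.08,
        ),
        # Stage-1-detectable: SV lands in the gap between the class
        # intervals.
        "shrimp_shell": mat(
            "shrimp_shell",
            [(400, 0), (410, 0), (_L26, 30), (600, 50), (_L63, 82), (752, 100), (768, 100),
             (_L93, 88), (1000, 84)],
            {2: 2.0, 4: 2.0},
            gain=2000.0,
        ),
        # Black plastic bag: mimics seaweed at the four decision bands,
        # but bulges at 560–650 nm and dips near 780 nm — only the
        # envelope inspection sees it.
        "plastic": mat(
            "plastic",
            [(400, 0), (410, 0), (500, 8), (_L26, 10), (560, 30), (600, 52), (650, 55),
             (680, 30), (710, 55), (_L63, 82), (752, 100), (768, 100), (780, 86), (820, 90),
             (_L93, 86), (1000, 80)],
            {9: 2.0, 14: 2.0},
            gain=900.0,
        ),
        # Dark flat bug: SV below both intervals.
        "insect": mat(
            "insect",
            [(400, 0), (410, 0), (_L26, 58), (600, 62), (_L63, 68), (760, 70), (_L93, 70),
             (950, 80), (980, 100), (1000, 100)],
            {2: 2.0, 4: 2.0},
            gain=700.0,
        ),
        # Bright fibre: SV above both intervals.
        "thread": mat(
            "thread",
            [(400, 0), (410, 0), (_L26, 5), (600, 40), (_L63, 95), (752, 100), (768, 100),
             (_L93, 90), (1000, 85)],
            {2: 2.0, 4: 2.0},
            gain=2600.0,
        ),
    }
    _check_feasible(lib, config, wavelengths)
    return lib


def _worst_case_features(m: MaterialSpectrum, wavelengths: np.ndarray):
    """Interval bounds of (SV, SN) over jitter, boost and gain spread.

    Enumerates jitter sign corners at the four decision wavelengths.
    A per-pixel shift of the extremal plateaus cancels out of a band
    difference but distorts the Per-Norm scale by up to
    ``100 / (span -+ plateau jitters)``, which is folded in here.
    Sensor noise is not included (kept small relative to the interval
    slack).
    """
    base = {}
    for lam in (_L26, _L63, _L68, _L93):
        corners = np.array(
            np.meshgrid(*[(-h, h) if h else (0.0,) for h in m.jitter])
        ).reshape(len(m.jitter), -1).T
        vals = m.interp(np.array([lam]), m.control_values[None, :] + corners)[:, 0]
        lo, hi = float(vals.min()), float(vals.max())
        if m.diffuse_boost is not None:
            _, blo, bhi = m.diffuse_boost
            t = float(_boost_taper(np.array([lam]))[0])
            # Boost amplitude in per-norm units spans amp/(1 ± gain_jitter).
            hi += bhi * t / (1.0 - m.gain_jitter)
        base[lam] = (lo, hi)
    top = m.control_values.max()
    j_min = float(m.jitter[m.control_values == m.control_values.min()].max(initial=0.0))
    j_max = float(m.jitter[m.control_values == top].max(initial=0.0))
    span = top - m.control_values.min()
    scales = (100.0 / (span + j_min + j_max), 100.0 / (span - j_min - j_max))

    def diff_range(hi_band, lo_band):
        lo = base[hi_band][0] - base[lo_band][1]
        hi = base[hi_band][1] - base[lo_band][0]
        cand = [lo * s / (100.0 / span) for s in scales] + [hi * s / (100.0 / span) for s in scales]
        return min(cand), max(cand)

    return diff_range(_L63, _L26), diff_range(_L93, _L68)


def _check_feasible(
    lib: dict[str, MaterialSpectrum], config: SubtractionConfig, wavelengths: np.ndarray
) -> None:
    def inside(rng, ival):
        return ival[0] <= rng[0] and rng[1] <= ival[1]

    def outside_all(rng, ivals):
        return all(rng[1] < lo or rng[0] > hi for lo, hi in ivals)

    vis = config.visible_intervals
    nir = config.nir_intervals
    for cls in ("seaweed", "belt"):
        sv, sn = _worst_case_features(lib[cls], wavelengths)
        if not (inside(sv, vis[cls]) and inside(sn, nir[cls])):
            raise ValueError(f"{cls} profile violates its stage-1 intervals: SV={sv}, SN={sn}")
    sv, sn = _worst_case_features(lib["plastic"], wavelengths)
    if not (inside(sv, vis["seaweed"]) and inside(sn, nir["seaweed"])):
        raise ValueError(f"plastic must hide inside the seaweed stage-1 intervals: SV={sv}, SN={sn}")
    for name in ("shrimp_shell", "insect", "thread"):
        sv, _ = _worst_case_features(lib[name], wavelengths)
        if not outside_all(sv, vis.values()):
            raise ValueError(f"{name} SV range {sv} not outside both visible intervals")


# ---------------------------------------------------------------------------
# Scene rendering


@dataclass
class ForeignObject:
    """Rectangular contaminant patch, positioned relative to the sheet
    origin (line offset, sample offset), sized in pixels."""

    material: str
    line: int
    sample: int
    height: int = 3
    width: int = 3


@dataclass
class SceneSpec:
    """One conveyor pass: a single sheet plus belt margins.

    Sheet sizes follow the two commercial formats: rectangular
    26 cm x 20 cm (length along travel) and square 20 cm x 20 cm.  The
    along-track extent in lines is ``length / belt_speed * line_rate``
    (26 cm at 30 cm/s and 300 lines/s spans 260 lines); across-track,
    ``200 mm / pixel_pitch_mm`` samples.
    """

    sheet_shape: str = "rectangular"  # or "square"
    samples_per_line: int = 1024
    pixel_pitch_mm: float = 0.25
    belt_speed_cm_s: float = 30.0
    line_rate_hz: float = 300.0
    margin_lines: int = 15
    foreign_objects: list[ForeignObject] = field(default_factory=list)
    seed: int = 0
    n_bands: int = BAND_COUNT

    @property
    def sheet_length_cm(self) -> float:
        return 26.0 if self.sheet_shape == "rectangular" else 20.0

    @property
    def sheet_lines(self) -> int:
        return round(self.sheet_length_cm / self.belt_speed_cm_s * self.line_rate_hz)

    @property
    def sheet_samples(self) -> int:
        return round(200.0 / self.pixel_pitch_mm)

    @property
    def total_lines(self) -> int:
        return self.sheet_lines + 2 * self.margin_lines

    @property
    def contaminated(self) -> bool:
        return bool(self.foreign_objects)


@dataclass
class Scene:
    """Rendered scene: cube, ground truth and calibration references."""

    cube: HyperCube
    mask: np.ndarray  # (lines, samples) of MATERIAL_CODES
    dark: ReferenceFrame
    white: ReferenceFrame
    spec: SceneSpec


def _dark_grid(n_samples: int, n_bands: int) -> np.ndarray:
    """Deterministic smooth fixed-pattern dark current, ~40 DN."""
    s = np.sin(np.linspace(0.0, np.pi, n_samples))[:, None]
    b = np.linspace(0.0, 1.0, n_bands)[None, :]
    return 40.0 + 8.0 * s + 4.0 * b


def _white_grid(n_samples: int, n_bands: int) -> np.ndarray:
    """White reference: dark plus a bright, gently vignetted field."""
    dark = _dark_grid(n_samples, n_bands)
    vignette = 0.96 + 0.04 * np.sin(np.linspace(0.0, np.pi, n_samples))[:, None]
    return dark + 3200.0 * vignette


def render_scene(spec: SceneSpec, materials: dict[str, MaterialSpectrum]) -> Scene:
    """Render one push-broom pass line-by-line into a DN cube.

    The ground-truth mask labels every pixel's material; the dark and
    white frames are the exact references the calibration should use.
    Deterministic for a fixed ``spec.seed``.
    """
    wl = default_wavelengths(spec.n_bands)
    n_lines, n_samples = spec.total_lines, spec.samples_per_line
    if spec.sheet_samples > n_samples:
        raise ValueError(
            f"sheet needs {spec.sheet_samples} samples but the line has {n_samples}"
        )
    mask = np.zeros((n_lines, n_samples), dtype=np.int8)
    l0 = spec.margin_lines
    s0 = (n_samples - spec.sheet_samples) // 2
    mask[l0 : l0 + spec.sheet_lines, s0 : s0 + spec.sheet_samples] = MATERIAL_CODES["seaweed"]
    for obj in spec.foreign_objects:
        if obj.material not in materials:
            raise ValueError(f"unknown material {obj.material!r}")
        top, left = l0 + obj.line, s0 + obj.sample
        if not (
            l0 <= top and top + obj.height <= l0 + spec.sheet_lines
            and s0 <= left and left + obj.width <= s0 + spec.sheet_samples
        ):
            raise ValueError(f"foreign object {obj} overflows the sheet extent")
        mask[top : top + obj.height, left : left + obj.width] = MATERIAL_CODES[obj.material]

    dark = _dark_grid(n_samples, spec.n_bands)
    rng = np.random.default_rng(spec.seed)
    data = np.zeros((n_lines, n_samples, spec.n_bands), dtype=np.uint16)
    code_to_name = {v: k for k, v in MATERIAL_CODES.items()}
    for code in sorted(np.unique(mask)):
        name = code_to_name[int(code)]
        rows, cols = np.nonzero(mask == code)
        data[rows, cols] = draw_dn_pixels(
            materials[name], len(rows), rng, wl, dark=dark[cols]
        )
    cube = HyperCube(data=data, wavelengths=wl, meta={"kelpscan scene seed": spec.seed})
    return Scene(
        cube=cube,
        mask=mask,
        dark=ReferenceFrame("dark_current", dark),
        white=ReferenceFrame("white_reference", _white_grid(n_samples, spec.n_bands)),
        spec=spec,
    )


_CONTAMINANTS = ("shrimp_shell", "plastic", "insect", "thread")


def make_benchmark(
    n_clean: int,
    n_contaminated: int,
    seed: int,
    samples_per_line: int = 1024,
    pixel_pitch_mm: float = 0.25,
) -> list[SceneSpec]:
    """Benchmark manifest: alternating rectangular/square sheets.

    Contaminated sheets carry 1–3 rectangular foreign objects of mixed
    materials, each at least 1 mm (>= 1 sample and >= 1 line) across,
    placed uniformly inside the sheet.  Scene seeds derive from
    ``seed``, so the whole benchmark is reproducible.
    """
    if n_clean < 0 or n_contaminated < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    specs: list[SceneSpec] = []
    flags = [False] * n_clean + [True] * n_contaminated
    for i, contaminated in enumerate(flags):
        spec = SceneSpec(
            sheet_shape="rectangular" if i % 2 == 0 else "square",
            samples_per_line=samples_per_line,
            pixel_pitch_mm=pixel_pitch_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if contaminated:
            objs = []
            for _ in range(int(rng.integers(1, 4))):
                material = _CONTAMINANTS[int(rng.integers(len(_CONTAMINANTS)))]
                h = int(rng.integers(2, 7))
                w = int(rng.integers(2, 7))
                objs.append(
                    ForeignObject(
                        material=material,
                        line=int(rng.integers(2, spec.sheet_lines - h - 2)),
                        sample=int(rng.integers(2, spec.sheet_samples - w - 2)),
                        height=h,
                        width=w,
                    )
                )
            spec.foreign_objects = objs
        specs.append(spec)
    return specs
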
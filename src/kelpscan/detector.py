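"""Two-stage foreign-object detector for sheet food on a conveyor.

Stage 1 (subtraction segmentation) computes, per pixel, the difference
between two Per-Norm band values in the visible range (SV) and two in
the near-infrared range (SN).  Each class (seaweed, belt) owns a closed
acceptance interval for SV and for SN.  A pixel whose SV falls in
neither class's visible interval — or whose SN falls in neither NIR
interval — is foreign; otherwise the visible-range membership decides
seaweed vs belt (when the two ranges disagree about the class, the
visible range wins; such pixels are counted and logged).

Stage 2 (standardization inspection) z-scores each remaining pixel
against its class's reference profile and flags it foreign when ANY
band leaves the reference envelope widened by a margin (default 3 z
units).  Belt pixels outside the bounding box of the detected sheet can
be skipped entirely (the "ignored zone"), since foreign objects on bare
belt need not be found.

Both stages are per-line computations, so the detector can run
streaming on a push-broom feed; :func:`detect_stream` is bit-identical
to whole-cube :func:`detect_sheet` when the ignored zone is off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibratedCube
from .reference_model import ReferenceProfile, SubtractionConfig

__all__ = [
    "BELT",
    "SEAWEED",
    "FOREIGN",
    "LABEL_NAMES",
    "ClassMap",
    "DetectorParams",
    "SheetVerdict",
    "subtraction_features",
    "stage1_classify",
    "ignored_zone",
    "stage2_inspect",
    "detect_sheet",
    "detect_stream",
    "render_classmap",
]

log = logging.getLogger(__name__)

BELT, SEAWEED, FOREIGN = 0, 1, 2
LABEL_NAMES = {BELT: "belt", SEAWEED: "seaweed", FOREIGN: "foreign"}

# 4-connectivity for foreign-region components (conservative).
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class DetectorParams:
    subtraction: SubtractionConfig
    margin: float = 3.0  # z units added to each envelope bound
    min_foreign_pixels: int = 1
    ignored_zone_mode: str = "outside_sheet_bbox"  # or "none"
    streaming_window: int = 64  # trailing lines used for the bbox in streaming mode

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.min_foreign_pixels < 1:
            raise ValueError("min_foreign_pixels must be >= 1")
        if self.ignored_zone_mode not in ("none", "outside_sheet_bbox"):
            raise ValueError(f"unknown ignored_zone_mode {self.ignored_zone_mode!r}")


@dataclass
class ClassMap:
    """Per-pixel result: labels plus bookkeeping masks.

    ``stage1_foreign`` marks pixels flagged by the subtraction stage;
    ``stage2_foreign`` those flagged only by the envelope inspection.
    ``ignored`` pixels were never inspected at stage 2 and are never
    labeled foreign by it.
    """

    labels: np.ndarray
    ignored: np.ndarray
    stage1_foreign: np.ndarray
    stage2_foreign: np.ndarray

    @property
    def foreign(self) -> np.ndarray:
        return self.labels == FOREIGN


@dataclass
class SheetVerdict:
    decision: str  # "accept" | "reject"
    foreign_pixel_count: int
    foreign_components: int


def subtraction_features(
    pernorm: np.ndarray, config: SubtractionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel subtraction values ``SV = P_hi,vis − P_lo,vis`` and
    ``SN = P_hi,nir − P_lo,nir``.

    ``pernorm`` is any ``(..., bands)`` array of Per-Norm values; the
    configured band numbers are 1-based.
    """
    pernorm = np.asarray(pernorm, dtype=float)
    n_bands = pernorm.shape[-1]
    for b in (*config.visible_pair, *config.nir_pair):
        if not 1 <= b <= n_bands:
            raise ValueError(f"configured band {b} outside 1..{n_bands}")
    v_lo, v_hi = config.visible_pair
    n_lo, n_hi = config.nir_pair
    sv = pernorm[..., v_hi - 1] - pernorm[..., v_lo - 1]
    sn = pernorm[..., n_hi - 1] - pernorm[..., n_lo - 1]
    return sv, sn


def _in(x: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    lo, hi = interval
    return (x >= lo) & (x <= hi)


def stage1_classify(
    sv: np.ndarray, sn: np.ndarray, config: SubtractionConfig
) -> np.ndarray:
    """Interval-membership segmentation into {belt, seaweed, foreign}.

    Foreign wins if either range recognizes no class; otherwise the
    visible range decides.  Range disagreements (visible says one
    class, NIR the other) are logged at DEBUG and follow the visible
    range.
    """
    vis_sea = _in(sv, config.visible_intervals["seaweed"])
    vis_belt = _in(sv, config.visible_intervals["belt"])
    nir_sea = _in(sn, config.nir_intervals["seaweed"])
    nir_belt = _in(sn, config.nir_intervals["belt"])
    foreign = ~(vis_sea | vis_belt) | ~(nir_sea | nir_belt)
    labels = np.where(foreign, FOREIGN, np.where(vis_sea, SEAWEED, BELT)).astype(np.int8)
    disagree = ~foreign & ((vis_sea & nir_belt) | (vis_belt & nir_sea))
    n_disagree = int(np.count_nonzero(disagree))
    if n_disagree:
        log.debug("stage 1: %d pixel(s) with visible/NIR class disagreement", n_disagree)
    return labels


def ignored_zone(labels: np.ndarray, mode: str = "outside_sheet_bbox") -> np.ndarray:
    """Mask of pixels exempt from the stage-2 inspection.

    ``outside_sheet_bbox``: belt pixels outside the bounding box of all
    seaweed-labeled pixels are ignored; belt pixels inside the box stay
    inspected (an object lying on the sheet edge may segment as belt).
    If no seaweed was found, everything is ignored, with a warning.
    """
    labels = np.asarray(labels)
    if mode == "none":
        return np.zeros(labels.shape, dtype=bool)
    if mode != "outside_sheet_bbox":
        raise ValueError(f"unknown ignored-zone mode {mode!r}")
    sheet = labels == SEAWEED
    if not sheet.any():
        warnings.warn("no seaweed pixels found: entire raster ignored at stage 2")
        return np.ones(labels.shape, dtype=bool)
    rows = np.nonzero(sheet.any(axis=1))[0]
    cols = np.nonzero(sheet.any(axis=0))[0]
    inside = np.zeros(labels.shape, dtype=bool)
    inside[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1] = True
    return (labels == BELT) & ~inside


def stage2_inspect(
    pixels: np.ndarray,
    profile: ReferenceProfile,
    margin: float = 3.0,
) -> np.ndarray:
    """Envelope inspection: foreign iff any band's z-value leaves
    ``[env_low − margin, env_high + margin]``.

    ``pixels`` is ``(..., bands)`` of Per-Norm values already segmented
    into ``profile``'s class; returns a boolean array of the leading
    shape.
    """
    pixels = np.asarray(pixels, dtype=float)
    z = (pixels - profile.mean) / profile.std
    out_low = z < (profile.env_low - margin)
    out_high = z > (profile.env_high + margin)
    return (out_low | out_high).any(axis=-1)


def _stage2_pass(
    pernorm: np.ndarray,
    labels: np.ndarray,
    ignored: np.ndarray,
    profiles: dict[str, ReferenceProfile],
    margin: float,
) -> np.ndarray:
    """Run stage 2 on all non-ignored seaweed/belt pixels of one raster."""
    stage2 = np.zeros(labels.shape, dtype=bool)
    for code in (SEAWEED, BELT):
        name = LABEL_NAMES[code]
        if name not in profiles:
            raise ValueError(f"no reference profile for class {name!r}")
        sel = (labels == code) & ~ignored
        if sel.any():
            stage2[sel] = stage2_inspect(pernorm[sel], profiles[name], margin)
    return stage2


def _verdict(foreign: np.ndarray, min_foreign_pixels: int) -> SheetVerdict:
    count = int(np.count_nonzero(foreign))
    _, n_comp = ndimage.label(foreign, structure=_CROSS)
    return SheetVerdict(
        decision="reject" if count >= min_foreign_pixels else "accept",
        foreign_pixel_count=count,
        foreign_components=int(n_comp),
    )


def detect_sheet(
    cube: CalibratedCube,
    params: DetectorParams,
    profiles: dict[str, ReferenceProfile],
) -> tuple[ClassMap, SheetVerdict]:
    """Full two-stage detection on a whole Per-Norm cube.

    Stage-1 foreign pixels are excluded from stage 2; stage-2 runs on
    the remaining non-ignored seaweed/belt pixels against their own
    class profile; the verdict rejects when the merged foreign-pixel
    count reaches ``min_foreign_pixels``.
    """
    if cube.method != "per_norm":
        raise ValueError(f"detector expects a per_norm cube, got {cube.method!r}")
    for p in profiles.values():
        if p.n_bands != cube.n_bands:
            raise ValueError(
                f"profile {p.class_name!r} has {p.n_bands} bands, cube has {cube.n_bands}"
            )
    sv, sn = subtraction_features(cube.data, params.subtraction)
    labels = stage1_classify(sv, sn, params.subtraction)
    stage1_foreign = labels == FOREIGN
    ignored = ignored_zone(labels, params.ignored_zone_mode)
    stage2 = _stage2_pass(cube.data, labels, ignored, profiles, params.margin)
    final = np.where(stage2, FOREIGN, labels).astype(np.int8)
    cmap = ClassMap(labels=final, ignored=ignored, stage1_foreign=stage1_foreign, stage2_foreign=stage2)
    return cmap, _verdict(cmap.foreign, params.min_foreign_pixels)


def detect_stream(
    lines,
    params: DetectorParams,
    profiles: dict[str, ReferenceProfile],
) -> tuple[ClassMap, SheetVerdict]:
    """Line-by-line detection over an iterable of ``(samples, bands)``
    Per-Norm lines, honoring the push-broom streaming contract.

    With ``ignored_zone_mode="none"`` the result is bit-identical to
    :func:`detect_sheet`.  With ``outside_sheet_bbox`` the sheet extent
    is unknowable per line, so the bbox is approximated over a trailing
    window of ``streaming_window`` lines — a documented divergence from
    batch mode.
    """
    label_rows, ignored_rows, s1_rows, s2_rows = [], [], [], []
    window: list[np.ndarray] = []
    for line in lines:
        line = np.asarray(line, dtype=float)
        sv, sn = subtraction_features(line, params.subtraction)
        labels = stage1_classify(sv, sn, params.subtraction)
        if params.ignored_zone_mode == "none":
            ignored = np.zeros(labels.shape, dtype=bool)
        else:
            window.append(labels == SEAWEED)
            if len(window) > params.streaming_window:
                window.pop(0)
            cols = np.nonzero(np.any(window, axis=0))[0]
            ignored = labels == BELT
            if len(cols):
                inside = np.zeros(labels.shape, dtype=bool)
                inside[cols[0] : cols[-1] + 1] = True
                ignored &= ~inside
        stage2 = _stage2_pass(line, labels, ignored, profiles, params.margin)
        label_rows.append(np.where(stage2, FOREIGN, labels).astype(np.int8))
        ignored_rows.append(ignored)
        s1_rows.append(labels == FOREIGN)
        s2_rows.append(stage2)
    cmap = ClassMap(
        labels=np.array(label_rows),
        ignored=np.array(ignored_rows),
        stage1_foreign=np.array(s1_rows),
        stage2_foreign=np.array(s2_rows),
    )
    return cmap, _verdict(cmap.foreign, params.min_foreign_pixels)


_PALETTE = {
    SEAWEED: (0, 0, 0),  # black
    BELT: (255, 255, 255),  # white
    FOREIGN: (255, 0, 0),  # red
}


def render_classmap(cmap: ClassMap) -> np.ndarray:
    """Black/white/red rendering: seaweed black, belt (and ignored
    pixels) white, foreign red.  Returns a ``(lines, samples, 3)``
    uint8 image."""
    rgb = np.empty((*cmap.labels.shape, 3), dtype=np.uint8)
    for code, color in _PALETTE.items():
        rgb[cmap.labels == code] = color
    rgb[cmap.ignored & (cmap.labels != FOREIGN)] = _PALETTE[BELT]
    return rgb
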
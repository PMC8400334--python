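"""Spectral-angle-mapper (SAM) baseline classifier.

The comparison method: classify each 112-band Per-Norm pixel by its
spectral angle to labeled training pixels,

    theta(x, y) = arccos( <x, y> / (||x|| ||y||) ),

either by nearest angle (default — the transparent reading of
"classify through this angle") or with a one-vs-one SVM over the
precomputed kernel K(x, y) = exp(−theta(x, y)).  The exp(−theta)
transform is an implementation choice for a well-behaved kernel matrix,
not a claim about the original multi-class SVM's internals, which are
not specified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibratedCube
from .detector import FOREIGN, LABEL_NAMES, ClassMap, SheetVerdict, _verdict

__all__ = ["SamTrainingSet", "sam_angle", "sam_angles", "sam_classify", "sam_detect_sheet"]

_NAME_TO_CODE = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class SamTrainingSet:
    """Labeled Per-Norm training spectra for the 3-class SAM baseline."""

    pixels: np.ndarray  # (n, bands)
    labels: np.ndarray  # (n,) of {"seaweed", "belt", "foreign"}

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=float))
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.pixels.shape[0]:
            raise ValueError("one label per training pixel required")
        if np.any(np.linalg.norm(self.pixels, axis=1) == 0):
            raise ValueError("training set contains a zero-norm spectrum")
        for name in _NAME_TO_CODE:
            if name not in self.labels:
                raise ValueError(f"training set has no {name!r} pixels")


def sam_angle(x: np.ndarray, y: np.ndarray) -> float:
    """Spectral angle between two spectra, in radians in [0, pi].

    Symmetric and invariant to positive scaling of either argument.
    """
    return float(sam_angles(np.atleast_2d(x), np.atleast_2d(y))[0, 0])


def sam_angles(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise spectral angles, shape ``(len(X), len(Y))``."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    nx = np.linalg.norm(X, axis=1)
    ny = np.linalg.norm(Y, axis=1)
    if np.any(nx == 0) or np.any(ny == 0):
        raise ValueError("zero-norm spectrum has no spectral angle")
    cos = (X @ Y.T) / np.outer(nx, ny)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def _fit_svm(train: SamTrainingSet):
    from sklearn.svm import SVC

    K = np.exp(-sam_angles(train.pixels, train.pixels))
    clf = SVC(kernel="precomputed")  # sklearn SVC is one-vs-one for multi-class
    clf.fit(K, train.labels)
    return clf


def sam_classify(
    pixels: np.ndarray, train: SamTrainingSet, mode: str = "nearest_angle"
) -> np.ndarray:
    """Classify spectra against the training set.

    ``nearest_angle``: label of the training pixel minimizing theta
    (ties go to the smallest training index).  ``svm_precomputed``:
    one-vs-one SVM on K = exp(−theta).  Accepts one spectrum or a
    ``(n, bands)`` batch; returns labels of matching shape.
    """
    single = np.asarray(pixels).ndim == 1
    X = np.atleast_2d(np.asarray(pixels, dtype=float))
    if mode == "nearest_angle":
        theta = sam_angles(X, train.pixels)
        out = train.labels[np.argmin(theta, axis=1)]
    elif mode == "svm_precomputed":
        clf = _fit_svm(train)
        out = clf.predict(np.exp(-sam_angles(X, train.pixels)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out[0] if single else out


def sam_detect_sheet(
    cube: CalibratedCube,
    train: SamTrainingSet,
    mode: str = "nearest_angle",
    min_foreign_pixels: int = 1,
) -> tuple[ClassMap, SheetVerdict]:
    """Per-pixel SAM classification of a whole cube plus the sheet
    verdict under the same at-least-``min_foreign_pixels`` rule as the
    two-stage detector."""
    flat = cube.data.reshape(-1, cube.n_bands)
    # Guard Per-Norm's degenerate all-zero pixels (flagged upstream).
    norms = np.linalg.norm(flat, axis=1)
    ok = norms > 0
    train_codes = np.array([_NAME_TO_CODE[str(l)] for l in train.labels], dtype=np.int8)
    codes = np.full(flat.shape[0], _NAME_TO_CODE["belt"], dtype=np.int8)
    if mode == "svm_precomputed":
        clf = _fit_svm(train)
        pred = clf.predict(np.exp(-sam_angles(flat[ok], train.pixels)))
        codes[ok] = [_NAME_TO_CODE[str(l)] for l in pred]
    elif mode == "nearest_angle":
        theta = sam_angles(flat[ok], train.pixels)
        codes[ok] = train_codes[np.argmin(theta, axis=1)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels = codes.reshape(cube.n_lines, cube.n_samples)
    foreign = labels == FOREIGN
    shape_false = np.zeros(labels.shape, dtype=bool)
    cmap = ClassMap(labels=labels, ignored=shape_false, stage1_foreign=foreign, stage2_foreign=shape_false.copy())
    return cmap, _verdict(foreign, min_foreign_pixels)
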
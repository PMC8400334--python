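"""Sheet-level confusion metrics and the data-rate calculator.

The positive class is "contains a foreign object": TP = contaminated
sheet rejected, FN = contaminated accepted, FP = clean rejected,
TN = clean accepted.  This is the convention under which the published
sheet-level recall/precision/accuracy figures are internally
consistent.  Displayed metrics round half-up to 2 decimals; raw values
are always retained.

The throughput side is plain stream arithmetic: a full-band, full-width
VNIR line is samples x bands x bytes-per-sample bytes, and a belt
moving v cm/s inspected at r mm per line needs 10 v / r lines per
second.  1/n spectral binning drops (1 - 1/n) of the stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ConfusionCounts",
    "StreamSpec",
    "score_benchmark",
    "required_line_rate",
    "data_rate",
    "binning_savings",
    "round_metric",
]


def round_metric(value: float, places: int = 2) -> float:
    """Half-up rounding for display (0.9090... -> 0.91)."""
    return float(Decimal(repr(value)).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    def metrics(self, rounded: bool = True) -> dict:
        out = {}
        for name in ("recall", "precision", "accuracy"):
            v = getattr(self, name)
            if v is None:
                out[name] = "n/a"
            else:
                out[name] = round_metric(v) if rounded else v
        return out


def score_benchmark(verdicts) -> ConfusionCounts:
    """Tally sheet verdicts against ground truth.

    ``verdicts`` is an iterable of ``(verdict, contaminated)`` pairs,
    where ``verdict`` is a SheetVerdict or a decision string.
    """
    counts = ConfusionCounts()
    n = 0
    for verdict, contaminated in verdicts:
        decision = getattr(verdict, "decision", verdict)
        rejected = decision == "reject"
        if contaminated:
            if rejected:
                counts.tp += 1
            else:
                counts.fn += 1
        else:
            if rejected:
                counts.fp += 1
            else:
                counts.tn += 1
        n += 1
    if n == 0:
        raise ValueError("no verdicts to score")
    return counts


@dataclass
class StreamSpec:
    samples_per_line: int = 1024
    bands: int = 224
    bytes_per_sample: int = 1
    line_rate_hz: float = 300.0

    def __post_init__(self) -> None:
        if min(self.samples_per_line, self.bands, self.bytes_per_sample) <= 0 or self.line_rate_hz <= 0:
            raise ValueError("stream parameters must be positive")


def required_line_rate(belt_speed_cm_s: float, resolution_mm: float) -> float:
    """Line rate needed for a given along-track resolution:
    ``10 * belt_speed / resolution`` (30 cm/s at 1 mm -> 300 lines/s)."""
    if belt_speed_cm_s <= 0 or resolution_mm <= 0:
        raise ValueError("belt speed and resolution must be positive")
    return belt_speed_cm_s * 10.0 / resolution_mm


def data_rate(spec: StreamSpec) -> tuple[int, float]:
    """(bytes per line, bytes per second) of the raw stream."""
    per_line = spec.samples_per_line * spec.bands * spec.bytes_per_sample
    return per_line, per_line * spec.line_rate_hz


def binning_savings(spec: StreamSpec, n: int) -> float:
    """Bytes/s removed from the stream by 1/n spectral binning."""
    if n not in (2, 4):
        raise ValueError("binning factor must be 2 or 4")
    _, per_second = data_rate(spec)
    return per_second * (1.0 - 1.0 / n)
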
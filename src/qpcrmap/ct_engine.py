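"""Threshold-cycle (Ct) calling and detection-intensity classification.

The Ct of a well is the (fractional) cycle at which fluorescence first
reaches the user-supplied threshold. The crossing is located by two-point
linear interpolation between the last sub-threshold and first at-or-above-
threshold readings — deterministic and equivalent to a local linear fit
through the flanking cycles. No baseline subtraction is applied: the
per-well threshold is taken against raw readings (see
:func:`ct_from_curve`'s ``baseline_corrector`` hook).

Detections are binned into ordinal intensity levels by Ct. The defaults
mirror common eDNA practice: positives require Ct < 40, and lower Ct
(earlier amplification, more target DNA) means stronger intensity:
very strong [0, 10), strong [10, 20), moderate [20, 30), weak [30, 40),
none detected at Ct >= 40 or no crossing.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .core import NO_CROSSING
from .platform_io import FluorescenceCurve, MergedRecord

NONE_DETECTED = "none detected"

#: Fixed hex values for the named default palette.
DEFAULT_COLORS: dict[str, str] = {
    NONE_DETECTED: "#90EE90",  # light green
    "weak": "#FFFFE0",         # light yellow
    "moderate": "#007BA7",     # cerulean
    "strong": "#FF66B3",       # light magenta-pink
    "very strong": "#CD5700",  # tawny
}

#: Fallback palette for custom schemes with a non-default number of bins.
_FALLBACK_PALETTE = (
    "#CD5700", "#FF66B3", "#007BA7", "#FFFFE0",
    "#8C6BB1", "#41AB5D", "#4292C6", "#EF6548",
)


@dataclass(frozen=True)
class IntensityScheme:
    """Ct cutoff, bin lower bounds, ordered labels, and label colors.

    ``bin_lower_bounds`` are ascending bin starts; bin *i* spans
    ``[bounds[i], bounds[i+1])`` and the last bin runs to ``cutoff``.
    ``labels[i]`` names bin *i*, so labels run from strongest (lowest Ct)
    to weakest.
    """

    cutoff: float = 40.0
    bin_lower_bounds: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0)
    labels: tuple[str, ...] = ("very strong", "strong", "moderate", "weak")
    colors: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def __post_init__(self):
        if not math.isfinite(self.cutoff) or self.cutoff <= 0:
            raise ValueError("cutoff must be a positive finite Ct value")
        if len(self.labels) != len(self.bin_lower_bounds):
            raise ValueError("need exactly one label per bin lower bound")
        if any(
            b <= a for a, b in zip(self.bin_lower_bounds, self.bin_lower_bounds[1:])
        ):
            raise ValueError("bin lower bounds must be strictly ascending")
        if self.bin_lower_bounds and self.bin_lower_bounds[-1] >= self.cutoff:
            raise ValueError("all bin lower bounds must be below the cutoff")
        if NONE_DETECTED in self.labels:
            raise ValueError(f"{NONE_DETECTED!r} is reserved for Ct >= cutoff")

    def color_of(self, label: str) -> str:
        return self.colors.get(label, "#808080")

    @classmethod
    def with_bounds(
        cls, cutoff: float, bin_lower_bounds: Sequence[float]
    ) -> "IntensityScheme":
        """Scheme for custom bounds; default labels when 4 bins, generic otherwise."""
        bounds = tuple(float(b) for b in bin_lower_bounds)
        if len(bounds) == 4:
            return cls(cutoff=cutoff, bin_lower_bounds=bounds)
        labels = tuple(f"level {i + 1}" for i in range(len(bounds)))
        colors = {NONE_DETECTED: DEFAULT_COLORS[NONE_DETECTED]}
        for i, lab in enumerate(labels):
            colors[lab] = _FALLBACK_PALETTE[i % len(_FALLBACK_PALETTE)]
        return cls(cutoff=cutoff, bin_lower_bounds=bounds, labels=labels, colors=colors)


@dataclass(frozen=True)
class DetectionClass:
    """Intensity label assigned to one Ct value."""

    label: str
    ct: float | object  # float or NO_CROSSING


def ct_from_curve(
    curve: FluorescenceCurve,
    threshold: float,
    baseline_corrector: Callable[[FluorescenceCurve], FluorescenceCurve] | None = None,
) -> float | object:
    """First threshold crossing of a curve, or ``NO_CROSSING``.

    If the very first reading is already at/above threshold the first cycle
    is returned; with non-monotone noise the first crossing wins.
    ``baseline_corrector`` is an optional pre-processing hook (identity by
    default — raw readings are compared to the raw threshold).
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if baseline_corrector is not None:
        curve = baseline_corrector(curve)
    for j, reading in enumerate(curve.readings):
        if reading >= threshold:
            if j == 0:
                return float(curve.cycles[0])
            c0, c1 = curve.cycles[j - 1], curve.cycles[j]
            r0, r1 = curve.readings[j - 1], curve.readings[j]
            return c0 + (c1 - c0) * (threshold - r0) / (r1 - r0)
    return NO_CROSSING


def classify(ct: float | object, scheme: IntensityScheme) -> DetectionClass:
    """Bin one Ct into its intensity level (half-open bins, top-exclusive)."""
    if ct is NO_CROSSING:
        return DetectionClass(NONE_DETECTED, NO_CROSSING)
    ct = float(ct)
    if not math.isfinite(ct) or ct < 0:
        raise ValueError(f"ct must be a finite non-negative cycle value, got {ct}")
    if ct >= scheme.cutoff:
        return DetectionClass(NONE_DETECTED, ct)
    i = bisect_right(scheme.bin_lower_bounds, ct) - 1
    if i < 0:
        i = 0  # a ct below the first bound falls in the strongest bin
    return DetectionClass(scheme.labels[i], ct)


def classify_table(
    records: Sequence[MergedRecord], scheme: IntensityScheme
) -> list[DetectionClass]:
    """Elementwise :func:`classify` over merged records (order preserved)."""
    return [classify(r.ct, scheme) for r in records]
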
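"""Acceptability bands and traffic-light colors for Guttman error levels.

Mokken's qualitative cutoffs for Loevinger coefficients (poor < 0.3;
weak 0.3 to < 0.4; moderate 0.4 to < 0.5; strong >= 0.5), inverted to
the error scale e = 1 - h and expressed in percent, give four bands:
<= 50% no problems, (50, 60]% admissible with reservation, (60, 70]%
borderline, > 70% problematic. The color gradient runs green through
yellow to deep red along those bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import LinearSegmentedColormap, to_rgb

__all__ = ["BandScheme", "DEFAULT_SCHEME", "error_band", "error_color",
           "classify_h", "H_CATEGORIES"]

BAND_LABELS = (
    "no-problems",
    "admissible-with-reservation",
    "borderline",
    "problematic",
)
H_CATEGORIES = ("poor", "weak", "moderate", "strong")

# 7-stop green -> greenish-yellow -> yellow -> orange -> deep red gradient,
# anchored so the band boundaries (50/60/70%) fall on distinct hues. The
# published palette's exact RGBs are not recoverable; this is a documented
# approximation and is user-replaceable.
DEFAULT_STOPS = (
    (0.0, "#1a9850"),    # pure green
    (25.0, "#66bd63"),
    (50.0, "#d9ef8b"),   # greenish yellow: top of "no problems"
    (60.0, "#fee08b"),   # yellow: top of "admissible with reservation"
    (70.0, "#fdae61"),   # orange: top of "borderline"
    (85.0, "#f46d43"),
    (100.0, "#d73027"),  # deep red; values above 100 clamp here
)


@dataclass(frozen=True)
class BandScheme:
    """Band boundaries (percent) with labels and gradient color stops."""

    boundaries: tuple[float, float, float] = (50.0, 60.0, 70.0)
    labels: tuple[str, str, str, str] = BAND_LABELS
    stops: tuple[tuple[float, str], ...] = DEFAULT_STOPS

    def __post_init__(self) -> None:
        anchors = [a for a, _ in self.stops]
        if anchors != sorted(anchors) or len(anchors) < 2:
            raise ValueError("color stops must be sorted by anchor value")

    def position(self, e: float) -> float:
        """Monotone position of an error level along the stop sequence, 0..1."""
        anchors = np.array([a for a, _ in self.stops])
        lo, hi = anchors[0], anchors[-1]
        return float((np.clip(e, lo, hi) - lo) / (hi - lo))

    def colormap(self) -> LinearSegmentedColormap:
        """Matplotlib colormap over the stop anchor range, NaN drawn white."""
        anchors = np.array([a for a, _ in self.stops])
        pos = (anchors - anchors[0]) / (anchors[-1] - anchors[0])
        cmap = LinearSegmentedColormap.from_list(
            "guttmap", list(zip(pos, [c for _, c in self.stops]))
        )
        cmap.set_bad("white")
        return cmap


DEFAULT_SCHEME = BandScheme()


def error_band(e: float, scheme: BandScheme = DEFAULT_SCHEME) -> str:
    """Classify an error percentage into its acceptability band.

    Intervals are half-open on the left: <= b1, (b1, b2], (b2, b3], > b3.
    Values above 100% remain "problematic".
    """
    if not np.isfinite(e) or e < 0:
        raise ValueError(f"error percentage must be finite and >= 0, got {e}")
    b1, b2, b3 = scheme.boundaries
    if e <= b1:
        return scheme.labels[0]
    if e <= b2:
        return scheme.labels[1]
    if e <= b3:
        return scheme.labels[2]
    return scheme.labels[3]


def error_color(e: float, scheme: BandScheme = DEFAULT_SCHEME) -> tuple[float, float, float]:
    """RGB color for an error percentage via piecewise-linear interpolation.

    Values at or above the last stop anchor (100%) clamp to the deepest
    red; negative values are invalid.
    """
    if not np.isfinite(e) or e < 0:
        raise ValueError(f"error percentage must be finite and >= 0, got {e}")
    anchors = np.array([a for a, _ in scheme.stops])
    rgbs = np.array([to_rgb(c) for _, c in scheme.stops])
    e = float(np.clip(e, anchors[0], anchors[-1]))
    i = int(np.searchsorted(anchors, e, side="right")) - 1
    i = min(i, len(anchors) - 2)
    t = (e - anchors[i]) / (anchors[i + 1] - anchors[i])
    rgb = (1 - t) * rgbs[i] + t * rgbs[i + 1]
    return tuple(float(c) for c in rgb)


def classify_h(h: float) -> str:
    """Mokken's qualitative category for a Loevinger coefficient.

    poor < 0.3; weak [0.3, 0.4); moderate [0.4, 0.5); strong >= 0.5
    (the printed cutoffs leave 0.5 itself unstated; it is assigned to
    "strong").
    """
    if h > 1 + 1e-12:
        raise ValueError(f"Loevinger coefficients cannot exceed 1, got {h}")
    if h < 0.3:
        return "poor"
    if h < 0.4:
        return "weak"
    if h < 0.5:
        return "moderate"
    return "strong"
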
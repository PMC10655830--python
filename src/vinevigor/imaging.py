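"""Foliage cover and exposed leaf area from row-facing RGB images.

A vertical-shoot-positioned canopy photographed against a distinguishable
(blue) background is segmented into green / non-green pixels.  The fraction
of green pixels in the analysed window is the foliage cover FC, and the
exposed leaf area per plant follows Carbonneau's geometric formula

    ELA = D * FC * S,        S = W + 1.25 * H,

with D the along-row plant spacing (m), W the canopy width (m) and H the
canopy height (m); S = 2.05 for a 0.3 m x 1.40 m canopy in full sun.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

#: default HSV green band: hue in degrees, saturation / value floors
DEFAULT_HUE_BAND = (70.0, 170.0)
DEFAULT_SAT_MIN = 0.2
DEFAULT_VAL_MIN = 0.1


def shape_constant(W: float, H: float) -> float:
    """Canopy shape constant S = W + 1.25 H (full-sun vertical canopy)."""
    if W <= 0 or H <= 0:
        raise ValueError("canopy width and height must be positive")
    return W + 1.25 * H


@dataclass
class ElaGeometry:
    """Training-system geometry entering the ELA formula."""

    D: float = 1.40  # plant spacing, m
    W: float = 0.30  # canopy width, m
    H: float = 1.40  # canopy height, m

    def __post_init__(self) -> None:
        if self.D <= 0 or self.W <= 0 or self.H <= 0:
            raise ValueError("all geometry parameters must be positive")

    @property
    def S(self) -> float:
        return shape_constant(self.W, self.H)


@dataclass
class FoliageCover:
    green_pixels: int
    analyzed_pixels: int

    def __post_init__(self) -> None:
        if self.analyzed_pixels <= 0:
            raise ValueError("analysis window must contain pixels")
        if not 0 <= self.green_pixels <= self.analyzed_pixels:
            raise ValueError("green pixel count out of range")

    @property
    def FC(self) -> float:
        return self.green_pixels / self.analyzed_pixels


def segment_green(
    image: np.ndarray,
    hue_band: tuple[float, float] = DEFAULT_HUE_BAND,
    sat_min: float = DEFAULT_SAT_MIN,
    val_min: float = DEFAULT_VAL_MIN,
) -> np.ndarray:
    """Boolean foliage mask: hue within the green band, saturation and value
    above their floors.  Requires an (h, w, 3) RGB image."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (h, w, 3)")
    hsv = rgb2hsv(image)
    hue_deg = hsv[..., 0] * 360.0
    return ((hue_deg >= hue_band[0]) & (hue_deg <= hue_band[1])
            & (hsv[..., 1] >= sat_min) & (hsv[..., 2] >= val_min))


def foliage_cover(
    mask: np.ndarray,
    analysis_window: tuple[int, int, int, int] | None = None,
) -> FoliageCover:
    """FC over a (row0, row1, col0, col1) half-open window (whole mask if None)."""
    mask = np.asarray(mask, dtype=bool)
    if analysis_window is not None:
        r0, r1, c0, c1 = analysis_window
        if not (0 <= r0 < r1 <= mask.shape[0] and 0 <= c0 < c1 <= mask.shape[1]):
            raise ValueError("analysis window empty or outside the image")
        mask = mask[r0:r1, c0:c1]
    return FoliageCover(int(mask.sum()), int(mask.size))


def exposed_leaf_area(fc, geom: ElaGeometry = ElaGeometry()) -> float:
    """ELA = D * FC * S in m² per plant."""
    value = fc.FC if isinstance(fc, FoliageCover) else float(fc)
    if not 0.0 <= value <= 1.0:
        raise ValueError("FC must lie in [0, 1]")
    return geom.D * value * geom.S
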
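"""Colour-model transforms for plot windows.

The colour indicator channels are the four colour models (RGB, HSV,
CIE 1976 L*a*b*, NTSC YIQ) applied to the reflectance-scaled visible bands,
plus the per-pixel colour ratios r = R/(R+G+B) (and g, b alike) that measure
excess red/green/blue.  Digital numbers are first mapped to reflectance by
``min(dn/scale, 1)`` so every transform sees bounded [0,1] input.

Conventions (configurable only by swapping functions, documented here):

* HSV: hexcone model, H normalised to [0,1) rather than degrees,
  S = 0 where V = 0 (scikit-image convention).
* L*a*b*: sRGB primaries with gamma linearization, D65 white point,
  CIE 1976; L* in [0,100] (scikit-image ``rgb2lab``).
* YIQ: linear NTSC transform with the matrix :data:`YIQ_MATRIX`;
  Y = 0.299 R + 0.587 G + 0.114 B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .raster import PlotPixels

#: NTSC RGB -> YIQ matrix (rows: Y, I, Q).
YIQ_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.59590059, -0.27455667, -0.32134392],
        [0.21153661, -0.52273617, 0.31119955],
    ]
)


def dn_to_reflectance(dn: np.ndarray, scale: float = 10000.0) -> np.ndarray:
    """Digital numbers to reflectance: ``min(dn/scale, 1.0)``."""
    return np.minimum(np.asarray(dn, dtype=float) / scale, 1.0)


def colour_ratios(R: np.ndarray, G: np.ndarray, B: np.ndarray):
    """Per-pixel band fractions r, g, b and the degenerate-pixel flag mask.

    Where R+G+B = 0 all three ratios are set to 0 and the pixel is flagged.
    At every other pixel the three ratios sum to exactly 1.
    """
    total = R + G + B
    degenerate = total <= 0
    safe = np.where(degenerate, 1.0, total)
    r = np.where(degenerate, 0.0, R / safe)
    g = np.where(degenerate, 0.0, G / safe)
    b = np.where(degenerate, 0.0, B / safe)
    return r, g, b, degenerate


def _stack(R, G, B) -> np.ndarray:
    return np.stack([R, G, B], axis=-1).astype(float)


def rgb_to_hsv(R: np.ndarray, G: np.ndarray, B: np.ndarray):
    """Hexcone HSV; H in [0,1), S,V in [0,1]; S = 0 where V = 0."""
    hsv = skcolor.rgb2hsv(_stack(R, G, B))
    return hsv[..., 0], hsv[..., 1], hsv[..., 2]


def rgb_to_lab(R: np.ndarray, G: np.ndarray, B: np.ndarray):
    """CIE 1976 L*a*b* (sRGB gamma linearization, D65 white)."""
    lab = skcolor.rgb2lab(_stack(R, G, B))
    return lab[..., 0], lab[..., 1], lab[..., 2]


def rgb_to_yiq(R: np.ndarray, G: np.ndarray, B: np.ndarray):
    """Linear NTSC YIQ via :data:`YIQ_MATRIX`."""
    rgb = _stack(R, G, B)
    yiq = rgb @ YIQ_MATRIX.T
    return yiq[..., 0], yiq[..., 1], yiq[..., 2]


def yiq_to_rgb(Y: np.ndarray, I: np.ndarray, Q: np.ndarray):
    """Inverse of :func:`rgb_to_yiq` (exact matrix inverse)."""
    inv = np.linalg.inv(YIQ_MATRIX)
    rgb = np.stack([Y, I, Q], axis=-1) @ inv.T
    return rgb[..., 0], rgb[..., 1], rgb[..., 2]


@dataclass
class ColourPlanes:
    """All colour channels of one plot window, on a common grid.

    ``planes`` maps plane keys to 2-D arrays: reflectance ``r g b nir``,
    HSV ``h s v``, L*a*b* ``l a bb``, YIQ ``y i q`` and the colour ratios
    ``ratio_r ratio_g ratio_b``.  ``ratio_degenerate`` flags pixels with
    R+G+B = 0.
    """

    planes: dict[str, np.ndarray]
    ratio_degenerate: np.ndarray

    @classmethod
    def from_plot(cls, plot: PlotPixels, dn_scale: float = 10000.0) -> "ColourPlanes":
        R = dn_to_reflectance(plot.red, dn_scale)
        G = dn_to_reflectance(plot.green, dn_scale)
        B = dn_to_reflectance(plot.blue, dn_scale)
        NIR = dn_to_reflectance(plot.nir, dn_scale)
        h, s, v = rgb_to_hsv(R, G, B)
        l, a, bb = rgb_to_lab(R, G, B)
        y, i, q = rgb_to_yiq(R, G, B)
        rr, rg, rb, degenerate = colour_ratios(R, G, B)
        planes = dict(
            r=R, g=G, b=B, nir=NIR, h=h, s=s, v=v, l=l, a=a, bb=bb,
            y=y, i=i, q=q, ratio_r=rr, ratio_g=rg, ratio_b=rb,
        )
        return cls(planes=planes, ratio_degenerate=degenerate)
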
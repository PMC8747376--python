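"""Vegetation indicator channels: SAVI and the LAI derived from it.

SAVI = (1 + L)(NIR - RED) / (L + NIR + RED) with soil factor L (default
0.5, which keeps the denominator positive for reflectance input).  LAI
follows the empirical logarithmic relation

    LAI = -ln((0.69 - SAVI) / 0.59) / 0.91

valid for SAVI < 0.69; at or beyond that saturation point the canopy signal
carries no more LAI information and the pixel is assigned a configurable
cap (default 6.0, a typical maximum for a closed maize canopy) and flagged.
SAVI below 0.10 yields negative LAI; those values are kept by default
(``clip_negative`` clips them to 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SAVI_SATURATION = 0.69
_SCALE = 0.59
_RATE = 0.91


@dataclass
class VegetationPlanes:
    """SAVI and LAI planes plus per-pixel domain flags."""

    savi: np.ndarray
    lai: np.ndarray
    savi_flags: np.ndarray  # non-positive denominator
    lai_flags: np.ndarray   # SAVI at/above saturation, LAI capped


def savi(nir: np.ndarray, red: np.ndarray, L: float = 0.5):
    """Per-pixel SAVI; returns (plane, flag mask for zero denominators)."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = L + nir + red
    flags = denom <= 0
    safe = np.where(flags, 1.0, denom)
    values = np.where(flags, 0.0, (1.0 + L) * (nir - red) / safe)
    return values, flags


def lai(savi_plane: np.ndarray, cap: float = 6.0, clip_negative: bool = False):
    """Per-pixel LAI from SAVI; returns (plane, flag mask for capped pixels)."""
    s = np.asarray(savi_plane, dtype=float)
    flags = s >= SAVI_SATURATION
    safe = np.where(flags, SAVI_SATURATION - _SCALE, s)  # arg -> 1, ln -> 0
    values = -np.log((SAVI_SATURATION - safe) / _SCALE) / _RATE
    values = np.where(flags, cap, values)
    if clip_negative:
        values = np.maximum(values, 0.0)
    return values, flags


def savi_from_lai(lai_plane: np.ndarray) -> np.ndarray:
    """Inverse relation SAVI = 0.69 - 0.59 exp(-0.91 LAI) (for round-trips)."""
    return SAVI_SATURATION - _SCALE * np.exp(-_RATE * np.asarray(lai_plane, float))


def vegetation_planes(nir, red, L: float = 0.5, cap: float = 6.0,
                      clip_negative: bool = False) -> VegetationPlanes:
    s, sf = savi(nir, red, L)
    v, vf = lai(s, cap=cap, clip_negative=clip_negative)
    return VegetationPlanes(savi=s, lai=v, savi_flags=sf, lai_flags=vf)
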
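"""Synthetic labelled maize scenes.

The field campaign this package models — weekly monitoring of maize plots
over one agricultural cycle, matched to 4-band satellite composites — is
emulated here by a generator that places rectangular plots on a bare-soil
background and fills each with a per-stage reflectance profile plus
spatially autocorrelated Gaussian noise.  Spatial autocorrelation is what
makes the texture indicators (local Moran's I, LBP) informative, so the
noise field is white noise convolved with an isotropic Gaussian kernel of
configurable range and re-normalised to unit marginal standard deviation
(the convolution would otherwise shrink the requested ``noise_sd``).

Defaults mirror the study conditions the pipeline was designed around:
an 804 x 1498-pixel composite, 148 plots of 14 x 14 pixels (~2 ha at
10 m/pixel), six phenological stages from emergence to end of senescence,
and the Sentinel-2 L2A digital-number convention (reflectance x 10000,
uint16).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError
from .raster import BandComposite, Window, write_composite, write_plot_table

#: per-stage mean surface reflectance (blue B02, green B03, red B04, NIR B08).
#: Greenness and NIR rise from emergence (1) to ear maturation (4) and fall
#: through senescence (5, 6); red does the opposite (chlorophyll absorption).
_DEFAULT_PROFILES: dict[int, tuple[float, float, float, float]] = {
    1: (0.055, 0.090, 0.110, 0.250),  # emergence: mostly soil signal
    2: (0.045, 0.100, 0.070, 0.380),  # development: canopy closing
    3: (0.040, 0.105, 0.055, 0.460),  # tassels and ears
    4: (0.035, 0.110, 0.045, 0.500),  # ear formation/maturation: peak canopy
    5: (0.052, 0.098, 0.105, 0.360),  # beginning of senescence
    6: (0.065, 0.095, 0.130, 0.280),  # end of senescence: 50-100% dry
}

#: bare-soil background reflectance (blue, green, red, NIR)
SOIL_PROFILE: tuple[float, float, float, float] = (0.060, 0.090, 0.120, 0.220)

#: per-stage multiplier on the noise amplitude.  Within-plot variability is
#: highest where soil and canopy mix (emergence, late senescence) and lowest
#: under a closed uniform canopy (ear maturation).
_DEFAULT_NOISE_SCALE: dict[int, float] = {
    1: 1.4, 2: 1.1, 3: 0.9, 4: 0.7, 5: 1.0, 6: 1.3,
}

#: per-stage autocorrelation range (Gaussian sigma, pixels).  The spatial
#: grain coarsens as the canopy closes and breaks up again at dry-down;
#: this is what gives the texture indicators (LISA, LBP) class signal.
_DEFAULT_STAGE_RANGE: dict[int, float] = {
    1: 1.0, 2: 1.5, 3: 2.0, 4: 2.5, 5: 2.0, 6: 1.2,
}


def default_stage_noise_scales() -> dict[int, float]:
    """Per-stage noise-amplitude multipliers (dimensionless)."""
    return dict(_DEFAULT_NOISE_SCALE)


def default_stage_autocorrelation() -> dict[int, float]:
    """Per-stage noise autocorrelation ranges (pixels)."""
    return dict(_DEFAULT_STAGE_RANGE)


def default_phenology_profiles() -> dict[int, tuple[float, float, float, float]]:
    """Per-stage band-mean reflectance (B02, B03, B04, B08), stages 1-6."""
    return dict(_DEFAULT_PROFILES)


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic labelled scene.

    ``noise_sd`` is the marginal standard deviation of the additive
    reflectance noise; ``autocorrelation_range`` is the Gaussian smoothing
    scale (sigma, in pixels) of the noise field, 0 for white noise.
    """

    grid_height: int = 804
    grid_width: int = 1498
    n_plots: int = 148
    plot_height: int = 14
    plot_width: int = 14
    stage_labels: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    stage_profiles: Mapping[int, tuple[float, float, float, float]] = field(
        default_factory=default_phenology_profiles
    )
    noise_sd: float = 0.015
    autocorrelation_range: float = 2.0
    stage_noise_scale: Mapping[int, float] = field(
        default_factory=default_stage_noise_scales
    )
    stage_autocorrelation: Mapping[int, float] = field(
        default_factory=default_stage_autocorrelation
    )
    dn_scale: float = 10000.0
    seed: int = 0
    date: str = "20190601"
    margin: int = 2  # gap between plots and to the border, pixels

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.dn_scale <= 0:
            raise ConfigurationError("dn_scale must be > 0")
        if not self.stage_labels or not set(self.stage_labels) <= set(range(1, 7)):
            raise ConfigurationError("stage_labels must be a subset of 1..6")
        for s in self.stage_labels:
            if s not in self.stage_profiles:
                raise ConfigurationError(f"no profile for stage {s}")
            if not all(0.0 <= v <= 1.0 for v in self.stage_profiles[s]):
                raise ConfigurationError(f"profile of stage {s} outside [0,1]")
            if self.stage_noise_scale.get(s, 1.0) < 0:
                raise ConfigurationError(f"negative noise scale for stage {s}")


@dataclass(frozen=True)
class PlotRecord:
    """One plot's footprint and label inside a generated scene."""

    plot_id: str
    footprint: Window
    date: str
    stage: int


@dataclass
class LabeledScene:
    """A generated composite plus the plot records that label it."""

    composite: BandComposite
    plots: list[PlotRecord]
    config: SceneConfig


def _plot_layout(config: SceneConfig) -> list[Window]:
    """Row-major non-overlapping placement of equal-size plots with margins."""
    m = config.margin
    step_r = config.plot_height + m
    step_c = config.plot_width + m
    rows = (config.grid_height - m) // step_r
    cols = (config.grid_width - m) // step_c
    if rows * cols < config.n_plots:
        raise ConfigurationError(
            f"{config.n_plots} plots of {config.plot_height}x{config.plot_width}"
            f" do not fit a {config.grid_height}x{config.grid_width} grid"
        )
    wins: list[Window] = []
    for i in range(config.n_plots):
        r, c = divmod(i, cols)
        r0 = m + r * step_r
        c0 = m + c * step_c
        wins.append((r0, r0 + config.plot_height, c0, c0 + config.plot_width))
    return wins


def _unit_smooth(white: np.ndarray, rng_px: float) -> np.ndarray:
    """Smooth a white field and rescale to unit marginal standard deviation."""
    if rng_px <= 0:
        return white
    smooth = gaussian_filter(white, sigma=rng_px, mode="reflect")
    # normalise by the kernel's l2 norm so the marginal sd stays 1
    impulse = np.zeros((int(8 * rng_px) + 9,) * 2)
    impulse[impulse.shape[0] // 2, impulse.shape[1] // 2] = 1.0
    norm = float(np.sqrt((gaussian_filter(impulse, sigma=rng_px) ** 2).sum()))
    return smooth / norm


def generate_scene(config: SceneConfig) -> LabeledScene:
    """Generate a labelled scene; bit-identical for a fixed config and seed.

    Each plot's per-band reflectance is its stage-profile mean plus a
    spatially smoothed Gaussian noise field whose amplitude and
    autocorrelation range follow the plot's stage (``stage_noise_scale``,
    ``stage_autocorrelation``); the background carries the bare-soil
    profile plus noise at the base amplitude and range.  Values are clipped
    to [0,1], scaled by ``dn_scale`` and rounded half-up to uint16.
    """
    config.validate()
    windows = _plot_layout(config)
    rng = np.random.default_rng(config.seed)
    labels = [config.stage_labels[i % len(config.stage_labels)]
              for i in range(config.n_plots)]

    stage_range = {
        s: config.stage_autocorrelation.get(s, config.autocorrelation_range)
        for s in config.stage_labels
    }
    stage_sd = {
        s: config.noise_sd * config.stage_noise_scale.get(s, 1.0)
        for s in config.stage_labels
    }

    bands_dn: list[np.ndarray] = []
    shape = (config.grid_height, config.grid_width)
    for b in range(4):
        mean = np.full(shape, SOIL_PROFILE[b])
        for (r0, r1, c0, c1), stage in zip(windows, labels):
            mean[r0:r1, c0:c1] = config.stage_profiles[stage][b]
        if config.noise_sd > 0:
            white = rng.standard_normal(shape)
            # one unit-variance smoothed field per distinct range
            ranges = {config.autocorrelation_range, *stage_range.values()}
            fields = {r: _unit_smooth(white, r) for r in sorted(ranges)}
            noise = config.noise_sd * fields[config.autocorrelation_range]
            for (r0, r1, c0, c1), stage in zip(windows, labels):
                noise[r0:r1, c0:c1] = (
                    stage_sd[stage] * fields[stage_range[stage]][r0:r1, c0:c1]
                )
            refl = mean + noise
        else:
            refl = mean
        np.clip(refl, 0.0, 1.0, out=refl)
        dn = np.floor(refl * config.dn_scale + 0.5)  # round half-up
        bands_dn.append(np.clip(dn, 0, 65535).astype(np.uint16))

    composite = BandComposite(*bands_dn)
    plots = [
        PlotRecord(plot_id=str(i + 1), footprint=w, date=config.date, stage=s)
        for i, (w, s) in enumerate(zip(windows, labels))
    ]
    return LabeledScene(composite=composite, plots=plots, config=config)


def write_scene(scene: LabeledScene, out_dir: str | Path) -> None:
    """Persist a scene as ``composite.tif`` (4-band uint16) + ``plots.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_composite(out / "composite.tif", scene.composite)
    write_plot_table(out / "plots.csv", scene.plots)


def scene_for_seed(config: SceneConfig, seed: int, date: str | None = None) -> LabeledScene:
    """Convenience: regenerate the configured scene under a different seed."""
    cfg = replace(config, seed=seed, **({"date": date} if date else {}))
    return generate_scene(cfg)
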
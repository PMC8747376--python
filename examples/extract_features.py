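"""Extract the 86-feature vector of one plot sample.

Each sample is converted to 43 indicator channels (13 colour planes, 13
local-Moran texture planes, 13 LBP planes, 3 colour ratios, LAI) and each
channel contributes its mean (``m``) and variance (``v``) over the plot's
masked pixels.
"""

from maizephen import (
    SceneConfig,
    compute_channels,
    extract_features,
    extract_plot,
    generate_scene,
)

scene = generate_scene(SceneConfig(
    grid_height=60, grid_width=120, n_plots=12, plot_height=10, plot_width=10,
    seed=7,
))
rec = scene.plots[3]
plot = extract_plot(scene.composite, rec.footprint, rec.plot_id,
                    rec.date, rec.stage)
print(f"sample {plot.plot_id} ({plot.date}), stage {plot.stage}, "
      f"{plot.n_pixels} pixels")

channels = compute_channels(plot)
print(f"indicator channels: {channels.channel_count} "
      "(13 colour + 13 LISA + 13 LBP + 3 ratio + 1 LAI)")

vec = extract_features(plot)
print(f"feature vector length: {len(vec)}")
for name in ("red_m", "nir_m", "lai_m", "lisa_nirm", "lbp_nirm", "Ratio_gm"):
    print(f"  {name:10s} = {vec.values[name]: .4f}")
# red_m/nir_m are band reflectances; lai_m the leaf-area index estimate;
# lisa_nirm the mean spatial autocorrelation of NIR (positive = smooth
# texture); lbp_nirm the mean 8-bit local-binary-pattern code; Ratio_gm the
# green fraction of R+G+B (rises as the canopy greens up).
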
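"""Greedy forward feature selection seeded with the RGB colour features.

Starting from the six RGB colour-model features, each candidate feature is
added once, in canonical schema order, and kept only if the cross-validated
overall precision does not drop.
"""

from maizephen import ClassifierSpec, SceneConfig, generate_scene, greedy_selection
from maizephen.features import scene_feature_table

scene = generate_scene(SceneConfig(
    grid_height=100, grid_width=180, n_plots=48, plot_height=10, plot_width=10,
    seed=21,
))
table = scene_feature_table(scene)

candidates = ["nir_m", "nir_v", "l*_m", "a*_m", "b*_m", "q*_m",
              "lisa_nirm", "lisa_nirv", "lbp_nirm", "lbp_nirv",
              "Ratio_gm", "Ratio_rm", "lai_m", "lai_v", "h_m", "s_m"]
schema = greedy_selection(table, ClassifierSpec("lda"), cv_folds=5, seed=0,
                          candidate_names=candidates)

print(f"candidates offered: {len(candidates)} (plus the 6 RGB start features)")
print(f"selected schema size: {len(schema)}")
print("kept:", ", ".join(schema.names))
# Features whose addition lowered the CV precision were discarded; the
# survivors are the 'representative' subset for this table.
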
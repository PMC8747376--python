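"""End-to-end convenience drivers: synthetic scenes -> feature tables -> CV.

These tie the generator, the indicator extraction and the evaluation
together so experiments (and the examples) stay one-liners.  All
randomness descends from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, kfold_cv
from .features import ChannelConfig, FeatureSchema, scene_feature_table
from .scene import SceneConfig, generate_scene


def synthetic_feature_table(
    scene_config: SceneConfig = SceneConfig(),
    channel_config: ChannelConfig = ChannelConfig(),
    n_scenes: int = 1,
    seed: int = 0,
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Generate ``n_scenes`` labelled scenes (distinct dates, derived seeds)
    and extract one pooled feature table."""
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(n_scenes):
        cfg = replace(
            scene_config,
            seed=int(rng.integers(0, 2**31 - 1)),
            date=f"201906{(i % 28) + 1:02d}",
        )
        scene = generate_scene(cfg)
        tbl = scene_feature_table(scene, channel_config, schema)
        # keep sample ids unique across scenes sharing a nominal date
        tbl["sample_id"] = tbl["sample_id"] + f"s{i}"
        tables.append(tbl)
    return pd.concat(tables, ignore_index=True)


def noise_degradation_curve(
    noise_levels,
    scene_config: SceneConfig = SceneConfig(),
    channel_config: ChannelConfig = ChannelConfig(),
    spec: ClassifierSpec | None = None,
    n_seeds: int = 20,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean CV accuracy per noise level, averaged over ``n_seeds`` replicates.

    Returns a frame with columns ``noise_sd`` and ``mean_accuracy`` (plus the
    per-seed accuracies), used to check that accuracy degrades on average as
    the within-plot noise grows.
    """
    if spec is None:
        spec = ClassifierSpec("svm_quadratic")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    rows = []
    for sd in noise_levels:
        accs = []
        for s in seeds:
            cfg = replace(scene_config, noise_sd=float(sd), seed=int(s))
            table = scene_feature_table(generate_scene(cfg), channel_config)
            report = kfold_cv(table, spec, k=k, seed=int(s) % (2**31 - 1))
            accs.append(report.overall)
        rows.append({"noise_sd": float(sd),
                     "mean_accuracy": float(np.mean(accs)),
                     "accuracies": accs})
    return pd.DataFrame(rows)
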
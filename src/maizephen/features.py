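"""Feature schemas, per-plot channel computation and aggregation.

One plot sample produces 43 indicator channels:

* 13 colour planes — reflectance R, G, B, NIR; HSV; L*a*b*; YIQ;
* 13 local-Moran (LISA) planes, one per colour plane;
* 13 LBP planes, one per colour plane;
* 3 colour-ratio planes and 1 LAI plane.

The mean (``m``) and variance (``v``) of each channel over the plot's
masked pixels give the canonical 86-feature vector, partitioned
26 colour / 52 texture / 8 vegetation.  The 45-feature "main
characteristics" schema is the empirically selected subset (all LISA and
LBP features on RGB/NIR, LISA on L*a*b*, LBP on Q, the RGB/NIR and L*a*b*
colour features, the Q chroma features, the colour ratios and LAI); six
ablation subsets each drop one indicator group from it.

Feature name grammar (matching the published main-characteristics table):
plain planes use ``{prefix}_{plane}{m|v}`` (``lisa_rv``, ``lbp_nirm``,
``red_m``, ``nir_v``); starred planes (l*, a*, b*, q*) use
``{prefix}{plane}*_{m|v}`` with prefix ``lmor`` for LISA and ``lbp`` for
LBP (``lmorl*_v``, ``lbpq*_m``) or no prefix for colour (``l*_m``,
``q*_v``); ratios are ``Ratio_{r|g|b}{m|v}`` and LAI ``lai_{m|v}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .colour import ColourPlanes
from .exceptions import DegenerateInputError, SchemaError
from .raster import PlotPixels, sample_filename
from .scene import LabeledScene
from .texture import WeightScheme, build_neighbor_graph, lbp, local_moran
from .vegetation import vegetation_planes

#: canonical plane order; keys as in ColourPlanes.planes ('bb' = L*a*b* b*)
PLANE_ORDER = ("r", "g", "b", "nir", "h", "s", "v", "l", "a", "bb", "y", "i", "q")

#: starred planes use the compact "{prefix}{letter}*_{stat}" name style
_STAR = {"l": "l", "a": "a", "bb": "b", "q": "q"}
_COLOUR_NAME = {
    "r": "red", "g": "green", "b": "blue", "nir": "nir",
    "h": "h", "s": "s", "v": "v", "y": "y", "i": "i",
}
_PLANE_INDICATOR = {
    "r": "RGB_NIR", "g": "RGB_NIR", "b": "RGB_NIR", "nir": "RGB_NIR",
    "h": "HSV", "s": "HSV", "v": "HSV",
    "l": "LAB", "a": "LAB", "bb": "LAB",
    "y": "YIQ", "i": "YIQ", "q": "YIQ",
}

#: published per-stage sample counts, six phenological stages (4015 total)
STAGE_SAMPLE_COUNTS_SIX = {1: 715, 2: 1214, 3: 227, 4: 963, 5: 511, 6: 385}
#: counts after stage-3 removal and expert relabeling, five stages (3764 total)
STAGE_SAMPLE_COUNTS_FIVE = {1: 828, 2: 1085, 4: 903, 5: 520, 6: 428}


@dataclass(frozen=True)
class Feature:
    """One named feature: (indicator, plane, statistic) with its group tag."""

    name: str
    group: str       # colour | texture | vegetation
    indicator: str   # RGB_NIR | HSV | LAB | YIQ | LISA | LBP | RATIO | LAI
    plane: str
    statistic: str   # m | v


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, unique feature names with group/indicator/statistic tags."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def group_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.group] = out.get(f.group, 0) + 1
        return out

    def indicator_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.indicator] = out.get(f.indicator, 0) + 1
        return out

    def without_indicator(self, indicator: str) -> "FeatureSchema":
        return FeatureSchema(
            tuple(f for f in self.features if f.indicator != indicator)
        )

    def select(self, names: Iterable[str]) -> "FeatureSchema":
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise SchemaError(f"unknown feature names: {sorted(missing)}")
        return FeatureSchema(tuple(f for f in self.features if f.name in wanted))


def _colour_feature_name(plane: str, stat: str) -> str:
    if plane in _STAR:
        return f"{_STAR[plane]}*_{stat}"
    return f"{_COLOUR_NAME[plane]}_{stat}"


def _texture_feature_name(method: str, plane: str, stat: str) -> str:
    if plane in _STAR:
        prefix = "lmor" if method == "LISA" else "lbp"
        return f"{prefix}{_STAR[plane]}*_{stat}"
    prefix = "lisa" if method == "LISA" else "lbp"
    return f"{prefix}_{plane}{stat}"


def full_schema() -> FeatureSchema:
    """The canonical 86-feature schema (26 colour, 52 texture, 8 vegetation)."""
    feats: list[Feature] = []
    for plane in PLANE_ORDER:
        for stat in ("m", "v"):
            feats.append(Feature(
                name=_colour_feature_name(plane, stat), group="colour",
                indicator=_PLANE_INDICATOR[plane], plane=plane, statistic=stat,
            ))
    for method in ("LISA", "LBP"):
        for plane in PLANE_ORDER:
            for stat in ("m", "v"):
                feats.append(Feature(
                    name=_texture_feature_name(method, plane, stat),
                    group="texture", indicator=method, plane=plane,
                    statistic=stat,
                ))
    for plane in ("r", "g", "b"):
        for stat in ("m", "v"):
            feats.append(Feature(
                name=f"Ratio_{plane}{stat}", group="vegetation",
                indicator="RATIO", plane=plane, statistic=stat,
            ))
    for stat in ("m", "v"):
        feats.append(Feature(
            name=f"lai_{stat}", group="vegetation", indicator="LAI",
            plane="lai", statistic=stat,
        ))
    return FeatureSchema(tuple(feats))


#: the published 45 "main characteristics", in table order
REPRESENTATIVE_NAMES = (
    # texture: LISA on r,g,b (variance), NIR (both), L*a*b* (both) -> 11
    "lisa_rv", "lisa_gv", "lisa_bv", "lisa_nirm", "lisa_nirv",
    "lmorl*_m", "lmorl*_v", "lmora*_m", "lmora*_v", "lmorb*_m", "lmorb*_v",
    # texture: LBP on r,g,b,NIR (both) and q* (both) -> 10
    "lbp_rm", "lbp_rv", "lbp_gm", "lbp_gv", "lbp_bm", "lbp_bv",
    "lbp_nirm", "lbp_nirv", "lbpq*_m", "lbpq*_v",
    # colour: RGB and NIR -> 8
    "red_m", "red_v", "green_m", "green_v", "blue_m", "blue_v",
    "nir_m", "nir_v",
    # colour: L*a*b* -> 6
    "l*_m", "l*_v", "a*_m", "a*_v", "b*_m", "b*_v",
    # colour: YIQ chroma Q -> 2
    "q*_m", "q*_v",
    # vegetation: colour ratios -> 6
    "Ratio_rm", "Ratio_rv", "Ratio_gm", "Ratio_gv", "Ratio_bm", "Ratio_bv",
    # vegetation: LAI -> 2
    "lai_m", "lai_v",
)


def representative_schema() -> FeatureSchema:
    """The 45-feature main-characteristics schema, in published order."""
    by_name = {f.name: f for f in full_schema()}
    return FeatureSchema(tuple(by_name[n] for n in REPRESENTATIVE_NAMES))


#: indicator groups removed in the ablation experiment, in published row order
ABLATION_GROUPS = ("LISA", "LBP", "LAI", "RATIO", "RGB_NIR", "LAB")


def ablation_sets() -> dict[str, FeatureSchema]:
    """Six subsets of the 45-feature schema, each dropping one indicator."""
    base = representative_schema()
    return {group: base.without_indicator(group) for group in ABLATION_GROUPS}


# -- channel computation -----------------------------------------------------

@dataclass(frozen=True)
class ChannelConfig:
    """Indicator configuration shared by every plot of an analysis run."""

    dn_scale: float = 10000.0
    weight_scheme: WeightScheme = "W"
    lbp_radius: int = 1
    savi_L: float = 0.5
    lai_cap: float = 6.0
    lai_clip_negative: bool = False


@dataclass
class Channels:
    """Named per-pixel channel planes of one plot, plus degenerate flags.

    ``colour``, ``lisa`` and ``lbp`` map plane keys (see
    :data:`PLANE_ORDER`) to 2-D arrays; LBP planes use NaN at pixels
    without a full masked neighbourhood.  ``flags`` holds channel keys
    (e.g. ``"lisa:r"``) whose input was degenerate (constant plane).
    """

    colour: dict[str, np.ndarray]
    lisa: dict[str, np.ndarray]
    lbp: dict[str, np.ndarray]
    ratio: dict[str, np.ndarray]
    lai: np.ndarray
    mask: np.ndarray
    flags: set[str]

    @property
    def channel_count(self) -> int:
        return len(self.colour) + len(self.lisa) + len(self.lbp) + len(self.ratio) + 1


def compute_channels(plot: PlotPixels, config: ChannelConfig = ChannelConfig()) -> Channels:
    """All 43 indicator channels of one plot sample."""
    cp = ColourPlanes.from_plot(plot, dn_scale=config.dn_scale)
    mask = plot.mask
    colour = {k: cp.planes[k] for k in PLANE_ORDER}
    flags: set[str] = set()

    graph = build_neighbor_graph(mask)
    lisa_planes: dict[str, np.ndarray] = {}
    for key in PLANE_ORDER:
        try:
            lisa_planes[key] = local_moran(
                colour[key], mask, scheme=config.weight_scheme, graph=graph
            ).values
        except DegenerateInputError:
            zero = np.full(mask.shape, np.nan)
            zero[mask] = 0.0
            lisa_planes[key] = zero
            flags.add(f"lisa:{key}")

    lbp_planes: dict[str, np.ndarray] = {}
    for key in PLANE_ORDER:
        try:
            res = lbp(colour[key], mask, P=8, R=config.lbp_radius)
            plane = np.where(res.valid, res.codes.astype(float), np.nan)
            if not res.valid.any():
                flags.add(f"lbp:{key}")
        except DegenerateInputError:  # window smaller than the neighbourhood
            plane = np.full(mask.shape, np.nan)
            flags.add(f"lbp:{key}")
        lbp_planes[key] = plane

    # degenerate ratio pixels (R+G+B = 0) are excluded from aggregation
    ratio = {
        k: np.where(cp.ratio_degenerate, np.nan, cp.planes[f"ratio_{k}"])
        for k in ("r", "g", "b")
    }
    veg = vegetation_planes(
        cp.planes["nir"], cp.planes["r"], L=config.savi_L,
        cap=config.lai_cap, clip_negative=config.lai_clip_negative,
    )
    return Channels(
        colour=colour, lisa=lisa_planes, lbp=lbp_planes, ratio=ratio,
        lai=veg.lai, mask=mask, flags=flags,
    )


def mean_variance(values: np.ndarray) -> tuple[float, float, bool]:
    """Mean and sample variance (n-1 denominator) of the finite values.

    Returns ``(mean, variance, flagged)``; channels with fewer than two
    valid pixels get variance 0 and are flagged.
    """
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return 0.0, 0.0, True
    mean = float(finite.mean())
    if finite.size < 2:
        return mean, 0.0, True
    if np.ptp(finite) == 0.0:
        # constant channels get an exact 0 (summation noise would otherwise
        # leave a ~1e-34 residue)
        return float(finite[0]), 0.0, False
    return mean, float(finite.var(ddof=1)), False


@dataclass
class FeatureVector:
    """One sample's named feature values with degenerate-feature flags."""

    sample_id: str
    date: str
    plot_id: str
    stage: int
    values: dict[str, float]
    flags: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.values)


def aggregate(
    channels: Channels,
    plot: PlotPixels,
    schema: FeatureSchema | None = None,
) -> FeatureVector:
    """Mean/variance of every channel over the masked pixels -> FeatureVector.

    Degenerate channels (constant-plane LISA, channels with fewer than two
    valid pixels) contribute 0 and are recorded in ``flags``.
    """
    if schema is None:
        schema = full_schema()
    mask = channels.mask
    stats: dict[str, tuple[float, float, bool]] = {}
    for key in PLANE_ORDER:
        stats[f"colour:{key}"] = mean_variance(channels.colour[key][mask])
        lv = channels.lisa[key][mask]
        m, v, flagged = mean_variance(lv)
        if f"lisa:{key}" in channels.flags:
            m, v, flagged = 0.0, 0.0, True
        stats[f"lisa:{key}"] = (m, v, flagged)
        stats[f"lbp:{key}"] = mean_variance(channels.lbp[key][mask])
    for key in ("r", "g", "b"):
        stats[f"ratio:{key}"] = mean_variance(channels.ratio[key][mask])
    stats["lai"] = mean_variance(channels.lai[mask])

    values: dict[str, float] = {}
    flags: set[str] = set()
    for f in schema:
        if f.indicator in ("LISA", "LBP"):
            key = f"{f.indicator.lower()}:{f.plane}"
        elif f.indicator == "RATIO":
            key = f"ratio:{f.plane}"
        elif f.indicator == "LAI":
            key = "lai"
        else:
            key = f"colour:{f.plane}"
        m, v, flagged = stats[key]
        values[f.name] = m if f.statistic == "m" else v
        if flagged:
            flags.add(f.name)
    return FeatureVector(
        sample_id=sample_filename(plot), date=plot.date, plot_id=plot.plot_id,
        stage=plot.stage, values=values, flags=flags,
    )


def extract_features(
    plot: PlotPixels,
    config: ChannelConfig = ChannelConfig(),
    schema: FeatureSchema | None = None,
) -> FeatureVector:
    """Compute channels and aggregate them for one plot sample."""
    return aggregate(compute_channels(plot, config), plot, schema)


#: metadata columns preceding the feature columns in a feature table
META_COLUMNS = ("sample_id", "date", "plot_id", "stage")


def feature_table(
    vectors: Sequence[FeatureVector],
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Assemble feature vectors into a rectangular labelled table."""
    if schema is None:
        schema = full_schema()
    rows = []
    for v in vectors:
        row = dict(sample_id=v.sample_id, date=v.date, plot_id=v.plot_id,
                   stage=v.stage)
        row.update({n: v.values[n] for n in schema.names})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(schema.names))


def scene_feature_table(
    scene: LabeledScene,
    config: ChannelConfig = ChannelConfig(),
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Extract every plot of a labelled scene into one feature table."""
    from .raster import extract_plot  # local import to avoid cycle at module load

    vectors = []
    for rec in scene.plots:
        plot = extract_plot(scene.composite, rec.footprint, rec.plot_id,
                            rec.date, rec.stage)
        vectors.append(extract_features(plot, config, schema))
    return feature_table(vectors, schema)


def table_schema_names(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table (everything after the metadata columns)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def debug_stage_filter(table: pd.DataFrame, drop_stage: int = 3) -> pd.DataFrame:
    """Remove the rows of one phenological stage (the tassels-and-ears
    debugging step); remaining rows are untouched."""
    return table[table["stage"] != drop_stage].reset_index(drop=True)


def greedy_selection(
    table: pd.DataFrame,
    classifier_spec=None,
    cv_folds: int = 10,
    seed: int = 0,
    candidate_names: Sequence[str] | None = None,
) -> FeatureSchema:
    """Greedy forward pass over the schema, seeded with the RGB colour features.

    Starting from the six RGB colour-model features, every remaining feature
    is tried once in canonical schema order and kept iff adding it does not
    decrease the cross-validated overall precision.  Deterministic for a
    fixed seed (the same fold split is reused for every evaluation).
    """
    from .classify import ClassifierSpec, kfold_cv  # deferred: avoid cycle
    from .exceptions import SelectionError

    if table["stage"].nunique() < 2:
        raise SelectionError("greedy selection needs >= 2 classes")
    if classifier_spec is None:
        classifier_spec = ClassifierSpec("lda")
    schema = full_schema()
    available = set(table_schema_names(table))
    start = [n for n in ("red_m", "red_v", "green_m", "green_v",
                         "blue_m", "blue_v") if n in available]
    if candidate_names is None:
        candidate_names = [n for n in schema.names
                           if n in available and n not in start]
    selected = list(start)

    def score(names: list[str]) -> float:
        report = kfold_cv(table, classifier_spec, k=cv_folds, seed=seed,
                          feature_names=names)
        return report.overall

    best = score(selected)
    for name in candidate_names:
        trial = score(selected + [name])
        if trial >= best:
            selected.append(name)
            best = trial
    return schema.select(selected)
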
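"""Synthetic study areas with known ground truth.

Every downstream stage of the framework (occurrence submodel, traffic
submodels, collision GLM) is exercised against scenes generated here:
spatially autocorrelated covariate rasters, a road network of six
classes, presence/background points whose sampling probability is a
known logistic function of the covariates, log-normal daily traffic
driven by road class and proximity covariates, class-dependent posted
speeds, and binary collision outcomes drawn from the Poisson encounter
model with known coefficients.

Only the *statistical* structure of the source datasets is emulated
(autocorrelation, class mixes, log-normal volumes, rare binary
outcomes), not any real geography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

from ._rng import substream
from .raster import CovariateRaster
from .spatial import CollisionRecord, GridSpec, RoadSegment, split_roads_by_grid
from .risk import RiskCoefficients, collision_rate

__all__ = [
    "ROAD_CLASSES",
    "ROAD_CLASS_RANK",
    "SceneConfig",
    "TruthParameters",
    "SyntheticScene",
    "generate_covariate_rasters",
    "generate_road_network",
    "generate_species_data",
    "simulate_collisions",
    "draw_collision_records",
    "generate_scene",
]

# Six road classes ordered by design intensity; the rank is the ordered
# integer encoding used wherever road class enters a model as a predictor.
ROAD_CLASSES = ("freeway", "highway", "arterial", "subarterial", "collector", "local")
ROAD_CLASS_RANK = {c: r for c, r in zip(ROAD_CLASSES, (6, 5, 4, 3, 2, 1))}

_DEFAULT_COVARIATES = ("ELEV", "GREEN", "LIGHT", "MNTEMPWQ", "PRECDM", "SLOPE", "TREEDENS")
_DEFAULT_CLASS_MIX = {
    "freeway": 0.05,
    "highway": 0.08,
    "arterial": 0.15,
    "subarterial": 0.17,
    "collector": 0.25,
    "local": 0.30,
}
# Typical road length as a fraction of the scene diagonal, by class.
_CLASS_LENGTH_FRAC = {
    "freeway": 0.9,
    "highway": 0.7,
    "arterial": 0.5,
    "subarterial": 0.35,
    "collector": 0.25,
    "local": 0.15,
}


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and size of a synthetic study area.

    The default 1000 m cell matches the one-square-kilometre analysis
    grid of the framework.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 40_000.0, 40_000.0)
    cell_size: float = 1000.0
    covariate_names: tuple[str, ...] = _DEFAULT_COVARIATES
    smoothing_scale: float = 5.0  # autocorrelation length in cells
    n_roads: int = 120
    road_class_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CLASS_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must enclose a strictly positive area")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.smoothing_scale < 0:
            raise ValueError("smoothing_scale must be non-negative")
        unknown = set(self.road_class_mix) - set(ROAD_CLASSES)
        if unknown:
            raise ValueError(f"unknown road classes in mix: {sorted(unknown)}")
        total = sum(self.road_class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError(f"road_class_mix must sum to 1, got {total}")

    @property
    def n_cols(self) -> int:
        return int(math.ceil((self.extent[2] - self.extent[0]) / self.cell_size))

    @property
    def n_rows(self) -> int:
        return int(math.ceil((self.extent[3] - self.extent[1]) / self.cell_size))

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            origin=(self.extent[0], self.extent[1]),
            cell_size=self.cell_size,
            n_cols=self.n_cols,
            n_rows=self.n_rows,
        )


@dataclass(frozen=True)
class TruthParameters:
    """Known generating parameters of a synthetic scene.

    ``risk_coefs`` are the coefficients of the log-linear collision-rate
    model; with beta1 = beta2 = beta3 = 1 the simulated rate is exactly
    a * O * V * S with a = exp(beta0).
    """

    occ_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "ELEV": -0.8,
            "GREEN": 0.7,
            "LIGHT": -0.6,
            "MNTEMPWQ": 0.4,
            "PRECDM": 0.9,
            "SLOPE": -0.3,
            "TREEDENS": 0.5,
        }
    )
    occ_intercept: float = -1.0
    vol_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "RDCLASS": 0.55,
            "KMTODEV": -0.06,
            "KMTOHWY": -0.03,
            "POPDENS": 0.0004,
            "RDDENS": 0.05,
        }
    )
    vol_intercept: float = 5.3
    vol_sigma: float = 0.45
    speed_by_class: dict[str, float] = field(
        default_factory=lambda: {
            "freeway": 102.0,
            "highway": 94.0,
            "arterial": 82.0,
            "subarterial": 71.0,
            "collector": 60.0,
            "local": 51.0,
        }
    )
    speed_rddens_coef: float = -1.5
    speed_sigma: float = 3.0
    risk_coefs: RiskCoefficients = field(
        default_factory=lambda: RiskCoefficients(-14.5, 0.66, 0.27, 2.7)
    )

    def __post_init__(self) -> None:
        if self.vol_sigma < 0:
            raise ValueError("vol_sigma must be non-negative")
        if any(v <= 0 for v in self.speed_by_class.values()):
            raise ValueError("all class speed means must be positive")

    @property
    def a(self) -> float:
        """Constant of proportionality of the multiplicative risk model."""
        return math.exp(self.risk_coefs.beta0)


@dataclass
class SyntheticScene:
    """A complete generated study area with its ground truth."""

    config: SceneConfig
    truth: TruthParameters
    rasters: dict[str, CovariateRaster]
    network: list[tuple[str, str, LineString]]
    segments: list[RoadSegment]
    segment_table: pd.DataFrame  # per-segment predictors, truth O/V/S, p, Y
    presences: pd.DataFrame  # columns x, y
    background: pd.DataFrame
    traffic_obs: pd.DataFrame  # observed AADT/SPEEDLMT on a subset
    collision_records: list[CollisionRecord]


def generate_covariate_rasters(config: SceneConfig) -> dict[str, CovariateRaster]:
    """Spatially autocorrelated, standardised covariate layers.

    Each layer is Gaussian white noise smoothed with a Gaussian kernel of
    sigma ``smoothing_scale`` cells and re-standardised to mean 0, sd 1.
    A scale of 0 leaves the noise unsmoothed.
    """
    rasters: dict[str, CovariateRaster] = {}
    for name in config.covariate_names:
        rng = substream(config.seed, f"raster:{name}")
        field_ = rng.standard_normal((config.n_rows, config.n_cols))
        if config.smoothing_scale > 0:
            field_ = ndimage.gaussian_filter(field_, sigma=config.smoothing_scale, mode="wrap")
        field_ = (field_ - field_.mean()) / field_.std()
        rasters[name] = CovariateRaster(
            name=name,
            values=field_,
            origin=(config.extent[0], config.extent[1]),
            cell_size=config.cell_size,
        )
    return rasters


def generate_road_network(config: SceneConfig) -> list[tuple[str, str, LineString]]:
    """Random planar polylines with one of the six road classes each.

    Roads are gently meandering walks: class drawn from the configured
    mix, start point uniform, heading perturbed at each of a handful of
    vertices, coordinates clamped to the extent.  Higher-intensity
    classes are longer on average.
    """
    if config.n_roads < 1:
        raise ValueError("n_roads must be at least 1")
    rng = substream(config.seed, "roads")
    xmin, ymin, xmax, ymax = config.extent
    diag = math.hypot(xmax - xmin, ymax - ymin)
    classes = [c for c in ROAD_CLASSES if config.road_class_mix.get(c, 0) > 0]
    probs = np.array([config.road_class_mix[c] for c in classes])
    probs = probs / probs.sum()
    network: list[tuple[str, str, LineString]] = []
    for i in range(config.n_roads):
        cls = classes[rng.choice(len(classes), p=probs)]
        length = _CLASS_LENGTH_FRAC[cls] * diag * rng.uniform(0.4, 0.9)
        n_steps = 8
        step = length / n_steps
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        heading = rng.uniform(0, 2 * math.pi)
        pts = [(x, y)]
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.15)
            x = min(max(x + step * math.cos(heading), xmin), xmax)
            y = min(max(y + step * math.sin(heading), ymin), ymax)
            pts.append((x, y))
        line = LineString(pts)
        if line.length == 0:  # fully clamped into a corner; retry straight inward
            line = LineString([(xmin + 1.0, ymin + 1.0), (xmin + 1.0 + step, ymin + 1.0)])
        network.append((f"road-{i:04d}", cls, line))
    return network


def _true_occurrence(rasters, truth: TruthParameters, xs, ys) -> np.ndarray:
    eta = np.full(np.shape(xs), truth.occ_intercept, dtype=float)
    for name, coef in truth.occ_coefs.items():
        if name not in rasters:
            raise KeyError(f"occ_coefs references missing raster '{name}'")
        eta = eta + coef * rasters[name].sample_points(xs, ys)
    return 1.0 / (1.0 + np.exp(-eta))


def generate_species_data(
    rasters: dict[str, CovariateRaster],
    truth: TruthParameters,
    n_presence: int,
    n_background: int,
    seed: int,
    road_bias: tuple[list, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence and background point sets over the raster extent.

    Background points are uniform.  Presence points are rejection-sampled
    with acceptance probability logistic(occ_intercept + occ_coefs . x),
    i.e. proportional to the true occurrence surface.  ``road_bias``
    optionally biases presences toward roads: a pair
    ``(road_geometries, decay_metres)`` multiplies the acceptance weight
    by exp(-d_road / decay), emulating survey records concentrated near
    roads and towns.
    """
    some = next(iter(rasters.values()))
    xmin, ymin, xmax, ymax = some.bounds
    rng = substream(seed, "species")
    bg_x = rng.uniform(xmin, np.nextafter(xmax, xmin), size=n_background)
    bg_y = rng.uniform(ymin, np.nextafter(ymax, ymin), size=n_background)
    background = pd.DataFrame({"x": bg_x, "y": bg_y})

    tree = None
    if road_bias is not None:
        geoms, decay = road_bias
        tree = STRtree(np.array(geoms, dtype=object))

    xs: list[float] = []
    ys: list[float] = []
    while len(xs) < n_presence:
        m = max(4 * (n_presence - len(xs)), 256)
        cx = rng.uniform(xmin, np.nextafter(xmax, xmin), size=m)
        cy = rng.uniform(ymin, np.nextafter(ymax, ymin), size=m)
        w = _true_occurrence(rasters, truth, cx, cy)
        if tree is not None:
            pts = np.array([Point(a, b) for a, b in zip(cx, cy)], dtype=object)
            _, dists = tree.query_nearest(pts, return_distance=True, all_matches=False)
            w = w * np.exp(-dists / road_bias[1])
        accept = rng.uniform(size=m) < w
        xs.extend(cx[accept])
        ys.extend(cy[accept])
    presences = pd.DataFrame({"x": xs[:n_presence], "y": ys[:n_presence]})
    return presences, background


def simulate_collisions(
    segment_table: pd.DataFrame,
    risk_coefs: RiskCoefficients,
    seed: int,
) -> pd.DataFrame:
    """Draw binary collision outcomes from the Poisson encounter model.

    For each segment with exposure ``O`` in (0,1] and hazard components
    ``V``, ``S`` > 0, the rate is C = exp(b0 + b1 ln O + b2 ln V +
    b3 ln S); the segment records a collision (Y=1) with probability
    p = 1 - exp(-C).

    Returns a copy of the table with columns ``rate``, ``p`` and ``Y``.
    """
    out = segment_table.copy()
    for col in ("O", "V", "S"):
        vals = np.asarray(out[col], dtype=float)
        bad = np.flatnonzero(~(vals > 0))
        if bad.size:
            sid = out.iloc[bad[0]].get("segment_id", bad[0])
            raise ValueError(
                f"non-positive {col} on segment {sid!r} "
                f"({bad.size} offending segment(s)); rates need positive inputs"
            )
    rate = collision_rate(out["O"].to_numpy(), out["V"].to_numpy(), out["S"].to_numpy(), risk_coefs)
    p = -np.expm1(-rate)
    rng = substream(seed, "collisions")
    y = (rng.uniform(size=len(out)) < p).astype(int)
    out["rate"] = rate
    out["p"] = p
    out["Y"] = y
    return out


def draw_collision_records(
    segments: list[RoadSegment],
    outcomes: pd.DataFrame,
    seed: int,
    jitter_sd: float = 50.0,
    accuracy_shape: float = 2.0,
    accuracy_scale: float = 75.0,
) -> list[CollisionRecord]:
    """Reported collision points for collision-coded segments.

    Each segment with Y=1 yields one report: a point drawn uniformly
    along the segment, jittered by isotropic Gaussian noise of sd
    ``jitter_sd`` metres, with a gamma-distributed positional-accuracy
    attribute (default mean 150 m, so a share of records exceeds the
    usual 300 m screening threshold and is filtered out downstream).
    """
    rng = substream(seed, "collision-records")
    by_id = {s.segment_id: s for s in segments}
    records: list[CollisionRecord] = []
    hits = outcomes.loc[outcomes["Y"] == 1, "segment_id"]
    for sid in hits:
        seg = by_id[sid]
        pt = seg.geometry.interpolate(rng.uniform(), normalized=True)
        records.append(
            CollisionRecord(
                x=pt.x + rng.normal(0.0, jitter_sd),
                y=pt.y + rng.normal(0.0, jitter_sd),
                accuracy=float(rng.gamma(accuracy_shape, accuracy_scale)),
                timestamp="",
                source_id=f"report:{sid}",
            )
        )
    return records


def _segment_predictors(
    segments: list[RoadSegment],
    config: SceneConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Traffic-model predictors for every segment.

    KMTODEV is distance (km) from the segment midpoint to the nearest of
    a few random development centres; KMTOHWY the distance (km) to the
    nearest freeway/highway segment; POPDENS a noisy decaying function of
    KMTODEV (people per km^2); RDDENS total road length (km) within the
    segment's grid cell; RDCLASS the ordered intensity rank.
    """
    xmin, ymin, xmax, ymax = config.extent
    n_dev = 3
    dev_pts = np.column_stack(
        [rng.uniform(xmin, xmax, size=n_dev), rng.uniform(ymin, ymax, size=n_dev)]
    )
    mids = np.array([s.midpoint for s in segments])
    d_dev = np.min(
        np.hypot(mids[:, None, 0] - dev_pts[None, :, 0], mids[:, None, 1] - dev_pts[None, :, 1]),
        axis=1,
    )
    major = [s.geometry for s in segments if s.road_class in ("freeway", "highway")]
    if major:
        tree = STRtree(np.array(major, dtype=object))
        pts = np.array([Point(m) for m in mids], dtype=object)
        _, d_hwy = tree.query_nearest(pts, return_distance=True, all_matches=False)
    else:
        d_hwy = np.full(len(segments), math.hypot(xmax - xmin, ymax - ymin))

    rddens_m: dict[int, float] = {}
    for s in segments:
        rddens_m[s.cell_id] = rddens_m.get(s.cell_id, 0.0) + s.length
    df = pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "road_id": [s.road_id for s in segments],
            "road_class": [s.road_class for s in segments],
            "cell_id": [s.cell_id for s in segments],
            "length": [s.length for s in segments],
            "mid_x": mids[:, 0],
            "mid_y": mids[:, 1],
            "RDCLASS": [ROAD_CLASS_RANK[s.road_class] for s in segments],
            "KMTODEV": d_dev / 1000.0,
            "KMTOHWY": d_hwy / 1000.0,
            "RDDENS": [rddens_m[s.cell_id] / 1000.0 for s in segments],
        }
    )
    df["POPDENS"] = 1500.0 * np.exp(-df["KMTODEV"] / 4.0) * rng.lognormal(0.0, 0.2, size=len(df))
    return df


def generate_scene(
    config: SceneConfig,
    truth: TruthParameters | None = None,
    n_presence: int = 900,
    n_background: int = 10_000,
    traffic_obs_fraction: float = 0.3,
) -> SyntheticScene:
    """Generate a full synthetic study area.

    The scene is a pure function of (config, truth): every stochastic
    element draws from a named substream of ``config.seed``, so repeated
    calls are bit-identical and changing e.g. ``n_roads`` does not
    perturb the rasters.
    """
    truth = truth or TruthParameters()
    rasters = generate_covariate_rasters(config)
    network = generate_road_network(config)
    segments = split_roads_by_grid(network, config.grid)

    pred_rng = substream(config.seed, "segment-predictors")
    table = _segment_predictors(segments, config, pred_rng)

    # ground-truth exposure and hazard per segment
    table["O"] = np.clip(
        _true_occurrence(rasters, truth, table["mid_x"].to_numpy(), table["mid_y"].to_numpy()),
        1e-6,
        1.0,
    )
    traffic_rng = substream(config.seed, "traffic")
    eta_v = truth.vol_intercept + sum(
        coef * table[name].to_numpy() for name, coef in truth.vol_coefs.items()
    )
    table["V"] = np.exp(eta_v + traffic_rng.normal(0.0, truth.vol_sigma, size=len(table)))
    base_speed = table["road_class"].map(truth.speed_by_class).to_numpy(dtype=float)
    speed = (
        base_speed
        + truth.speed_rddens_coef * table["RDDENS"].to_numpy()
        + traffic_rng.normal(0.0, truth.speed_sigma, size=len(table))
    )
    table["S"] = np.clip(np.round(speed / 10.0) * 10.0, 40.0, 110.0)

    # observed traffic on a subset of segments (AADT counters and posted
    # speed records exist only for part of the network)
    obs_rng = substream(config.seed, "traffic-obs")
    n_obs = max(int(round(traffic_obs_fraction * len(table))), 2)
    obs_idx = np.sort(obs_rng.choice(len(table), size=n_obs, replace=False))
    traffic_obs = table.iloc[obs_idx][
        ["segment_id", "KMTODEV", "KMTOHWY", "POPDENS", "RDCLASS", "RDDENS"]
    ].copy()
    traffic_obs["AADT"] = table.iloc[obs_idx]["V"].to_numpy()
    traffic_obs["SPEEDLMT"] = table.iloc[obs_idx]["S"].to_numpy()

    presences, background = generate_species_data(
        rasters, truth, n_presence, n_background, config.seed
    )

    table = simulate_collisions(table, truth.risk_coefs, config.seed)
    records = draw_collision_records(segments, table, config.seed)

    return SyntheticScene(
        config=config,
        truth=truth,
        rasters=rasters,
        network=network,
        segments=segments,
        segment_table=table,
        presences=presences,
        background=background,
        traffic_obs=traffic_obs,
        collision_records=records,
    )
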
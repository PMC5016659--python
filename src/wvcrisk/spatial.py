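"""Geoprocessing: grid overlay, road segmentation, record-segment matching.

Roads are planar polylines in one projected CRS (metres).  The analysis
grid tiles the study area with half-open square cells
``[x, x+w) x [y, y+h)``, so every point belongs to exactly one cell.
Splitting the network at cell boundaries produces the road *segments*
that are the modelling units of the collision model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

__all__ = [
    "GridSpec",
    "RoadSegment",
    "CollisionRecord",
    "GridCoverageError",
    "split_roads_by_grid",
    "sample_raster_at_point",
    "filter_records_by_accuracy",
    "assign_records_to_segments",
    "draw_background_segments",
]

# Clipped pieces shorter than this (metres) are merged into a neighbouring
# piece instead of becoming their own segment.
SLIVER_TOLERANCE = 1e-3


class GridCoverageError(ValueError):
    """Roads fall outside the analysis grid."""


@dataclass(frozen=True)
class GridSpec:
    """A regular square analysis grid in projected metres."""

    origin: tuple[float, float]
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    def cell_of(self, x: float, y: float) -> int:
        """Row-major id of the half-open cell containing the point.

        Points exactly on the top/right outer boundary are assigned to the
        last row/column so a network touching the outer edge still grids.
        """
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y - y0) / self.cell_size))
        col = min(max(col, 0), self.n_cols - 1)
        row = min(max(row, 0), self.n_rows - 1)
        return row * self.n_cols + col

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        row, col = divmod(cell_id, self.n_cols)
        x0, y0 = self.origin
        return (
            x0 + col * self.cell_size,
            y0 + row * self.cell_size,
            x0 + (col + 1) * self.cell_size,
            y0 + (row + 1) * self.cell_size,
        )


@dataclass
class RoadSegment:
    """A piece of road clipped to a single grid cell."""

    segment_id: str
    road_id: str
    road_class: str
    geometry: LineString
    cell_id: int

    @property
    def length(self) -> float:
        return self.geometry.length

    @property
    def midpoint(self) -> tuple[float, float]:
        p = self.geometry.interpolate(0.5, normalized=True)
        return (p.x, p.y)


@dataclass
class CollisionRecord:
    """A reported collision with positional uncertainty in metres."""

    x: float
    y: float
    accuracy: float
    timestamp: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.accuracy < 0:
            raise ValueError("positional accuracy must be non-negative")


def _grid_crossings(a: float, b: float, origin: float, step: float) -> np.ndarray:
    """Parameters t in (0,1) where a + t*(b-a) crosses origin + k*step."""
    d = b - a
    if d == 0:
        return np.empty(0)
    k_lo = int(np.ceil((min(a, b) - origin) / step))
    k_hi = int(np.floor((max(a, b) - origin) / step))
    if k_hi < k_lo:
        return np.empty(0)
    lines = origin + step * np.arange(k_lo, k_hi + 1)
    t = (lines - a) / d
    return t[(t > 0.0) & (t < 1.0)]


def split_roads_by_grid(
    network: Sequence[tuple[str, str, LineString]] | Sequence,
    grid: GridSpec,
) -> list[RoadSegment]:
    """Partition each road polyline at grid-cell boundaries.

    Parameters
    ----------
    network : sequence
        Items are ``(road_id, road_class, LineString)`` triples, or objects
        with attributes ``road_id``, ``road_class`` and ``geometry``.
    grid : GridSpec

    Returns
    -------
    list of RoadSegment
        One segment per maximal within-cell run of each polyline; total
        length is conserved and sub-millimetre slivers are merged into a
        neighbouring segment.
    """
    roads = []
    for item in network:
        if isinstance(item, tuple):
            roads.append(item)
        else:
            roads.append((item.road_id, item.road_class, item.geometry))
    if not roads:
        raise ValueError("network is empty")

    xmin, ymin, xmax, ymax = grid.bounds
    outside = [
        rid
        for rid, _, geom in roads
        if not (
            geom.bounds[0] >= xmin
            and geom.bounds[1] >= ymin
            and geom.bounds[2] <= xmax
            and geom.bounds[3] <= ymax
        )
    ]
    if outside:
        raise GridCoverageError(f"roads outside grid extent: {outside}")

    x0, y0 = grid.origin
    segments: list[RoadSegment] = []

    for road_id, road_class, geom in roads:
        coords = np.asarray(geom.coords, dtype=float)
        # (cell_id, [coords]) runs of the polyline
        runs: list[tuple[int, list[tuple[float, float]]]] = []
        for (ax, ay), (bx, by) in zip(coords[:-1], coords[1:]):
            ts = np.concatenate(
                [
                    [0.0, 1.0],
                    _grid_crossings(ax, bx, x0, grid.cell_size),
                    _grid_crossings(ay, by, y0, grid.cell_size),
                ]
            )
            ts = np.unique(ts)
            for ta, tb in zip(ts[:-1], ts[1:]):
                if tb <= ta:
                    continue
                pa = (ax + ta * (bx - ax), ay + ta * (by - ay))
                pb = (ax + tb * (bx - ax), ay + tb * (by - ay))
                tm = 0.5 * (ta + tb)
                cell = grid.cell_of(ax + tm * (bx - ax), ay + tm * (by - ay))
                if runs and runs[-1][0] == cell:
                    runs[-1][1].append(pb)
                else:
                    runs.append((cell, [pa, pb]))

        # merge slivers into the previous (or next) run
        merged: list[tuple[int, list[tuple[float, float]]]] = []
        for cell, pts in runs:
            if merged and LineString(pts).length < SLIVER_TOLERANCE:
                merged[-1][1].extend(pts[1:])
            else:
                merged.append((cell, pts))
        if len(merged) > 1 and LineString(merged[0][1]).length < SLIVER_TOLERANCE:
            head = merged.pop(0)
            merged[0] = (merged[0][0], head[1][:-1] + merged[0][1])

        for k, (cell, pts) in enumerate(merged):
            line = LineString(pts)
            if line.length == 0:
                continue
            segments.append(
                RoadSegment(
                    segment_id=f"{road_id}-{k:03d}",
                    road_id=road_id,
                    road_class=road_class,
                    geometry=line,
                    cell_id=cell,
                )
            )
    return segments


def sample_raster_at_point(raster, point) -> float:
    """Value of the raster cell containing the point (no interpolation)."""
    if isinstance(point, Point):
        x, y = point.x, point.y
    else:
        x, y = point
    return raster.sample(x, y)


def filter_records_by_accuracy(
    records: Iterable[CollisionRecord], max_accuracy: float = 300.0
) -> list[CollisionRecord]:
    """Keep records whose positional accuracy does not exceed the threshold.

    A record at exactly the threshold is retained; ``max_accuracy``
    defaults to 300 m.
    """
    if max_accuracy <= 0:
        raise ValueError("max_accuracy must be positive")
    return [r for r in records if r.accuracy <= max_accuracy]


def assign_records_to_segments(
    records: Sequence[CollisionRecord],
    segments: Sequence[RoadSegment],
) -> tuple[list[str], list[str]]:
    """Match each record to the nearest road segment.

    Returns
    -------
    (assignments, collision_ids)
        ``assignments[i]`` is the segment_id nearest record *i* (distance
        ties broken by lowest segment_id); ``collision_ids`` is the sorted,
        de-duplicated set of segment ids hit by at least one record.
    """
    if not segments:
        raise ValueError("at least one segment is required")
    if not records:
        return [], []
    geoms = np.array([s.geometry for s in segments], dtype=object)
    tree = STRtree(geoms)
    points = np.array([Point(r.x, r.y) for r in records], dtype=object)
    pairs = tree.query_nearest(points, all_matches=True)
    assignments: list[str] = [""] * len(records)
    best: dict[int, str] = {}
    for rec_idx, seg_idx in pairs.T:
        sid = segments[seg_idx].segment_id
        if rec_idx not in best or sid < best[rec_idx]:
            best[rec_idx] = sid
    for i in range(len(records)):
        assignments[i] = best[i]
    collision_ids = sorted(set(assignments))
    return assignments, collision_ids


def draw_background_segments(
    segments: Sequence[RoadSegment] | Sequence[str],
    collision_ids: Iterable[str],
    ratio: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Sample non-collision segments to serve as zeros in the GLM.

    A uniform sample without replacement, disjoint from ``collision_ids``,
    of size ``round(ratio * n_collisions)``.  The default ratio of 2
    follows the convention of drawing roughly twice as many background
    segments as collision-coded ones.
    """
    ids = [s if isinstance(s, str) else s.segment_id for s in segments]
    collision_set = set(collision_ids)
    candidates = sorted(set(ids) - collision_set)
    k = int(round(ratio * len(collision_set)))
    if k == 0:
        return []
    if k > len(candidates):
        raise ValueError(
            f"need {k} background segments but only {len(candidates)} "
            f"non-collision candidates (shortfall {k - len(candidates)})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(chosen)]
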
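"""Reading and writing the package's on-disk formats.

Vector data travel as GeoJSON FeatureCollections (built with
``shapely.geometry.mapping``/``shape``), rasters as ESRI ASCII grids,
tables as CSV, and run/scene manifests as JSON.  All coordinates are in
one projected CRS (metres) declared in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .raster import write_ascii_grid
from .spatial import RoadSegment
from .synthetic import SyntheticScene

__all__ = [
    "network_to_geojson",
    "network_from_geojson",
    "segments_to_geojson",
    "segments_from_geojson",
    "points_to_geojson",
    "write_scene",
]


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def _collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def network_to_geojson(network, path: str | Path) -> None:
    feats = [
        _feature(geom, {"road_id": rid, "road_class": cls}) for rid, cls, geom in network
    ]
    Path(path).write_text(json.dumps(_collection(feats)))


def network_from_geojson(path: str | Path) -> list[tuple[str, str, object]]:
    data = json.loads(Path(path).read_text())
    return [
        (f["properties"]["road_id"], f["properties"]["road_class"], shape(f["geometry"]))
        for f in data["features"]
    ]


def segments_to_geojson(segments: list[RoadSegment], path: str | Path, extra=None) -> None:
    """Write segments as LineString features; *extra* maps segment_id to
    additional properties (e.g. predictions)."""
    extra = extra or {}
    feats = []
    for s in segments:
        props = {
            "segment_id": s.segment_id,
            "road_id": s.road_id,
            "road_class": s.road_class,
            "cell_id": s.cell_id,
            "length": s.length,
        }
        props.update(extra.get(s.segment_id, {}))
        feats.append(_feature(s.geometry, props))
    Path(path).write_text(json.dumps(_collection(feats)))


def segments_from_geojson(path: str | Path) -> tuple[list[RoadSegment], pd.DataFrame]:
    """Read segments; returns the geometry objects and a properties table."""
    data = json.loads(Path(path).read_text())
    segs, rows = [], []
    for f in data["features"]:
        p = f["properties"]
        segs.append(
            RoadSegment(
                segment_id=p["segment_id"],
                road_id=p["road_id"],
                road_class=p["road_class"],
                geometry=shape(f["geometry"]),
                cell_id=int(p["cell_id"]),
            )
        )
        rows.append(p)
    return segs, pd.DataFrame(rows)


def points_to_geojson(df: pd.DataFrame, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
            "properties": {},
        }
        for row in df.itertuples()
    ]
    Path(path).write_text(json.dumps(_collection(feats)))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def write_scene(scene: SyntheticScene, directory: str | Path) -> dict:
    """Write a scene to a directory; returns the manifest dict.

    Layout: one ``.asc`` per covariate raster, ``network.geojson``,
    ``segments.geojson``, per-segment ``segments.csv`` (predictors,
    ground-truth O/V/S, rate, p, Y), presence/background point CSVs,
    ``traffic_obs.csv``, ``collision_records.csv`` and a
    ``manifest.json`` echoing config, truth and seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for name, raster in scene.rasters.items():
        fn = f"{name}.asc"
        write_ascii_grid(raster, directory / fn)
        files.append(fn)
    network_to_geojson(scene.network, directory / "network.geojson")
    segments_to_geojson(scene.segments, directory / "segments.geojson")
    scene.segment_table.to_csv(directory / "segments.csv", index=False)
    scene.presences.to_csv(directory / "presences.csv", index=False)
    scene.background.to_csv(directory / "background.csv", index=False)
    scene.traffic_obs.to_csv(directory / "traffic_obs.csv", index=False)
    pd.DataFrame(
        [
            {"x": r.x, "y": r.y, "accuracy": r.accuracy, "timestamp": r.timestamp,
             "source_id": r.source_id}
            for r in scene.collision_records
        ]
    ).to_csv(directory / "collision_records.csv", index=False)
    files += [
        "network.geojson",
        "segments.geojson",
        "segments.csv",
        "presences.csv",
        "background.csv",
        "traffic_obs.csv",
        "collision_records.csv",
    ]
    manifest = {
        "crs": "projected-metres (synthetic)",
        "config": _jsonable(scene.config),
        "truth": _jsonable(scene.truth),
        "seed": scene.config.seed,
        "files": files,
    }
    write_json(manifest, directory / "manifest.json")
    return manifest
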
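"""File formats, run configuration and the pipeline driver.

Formats: floes as GeoJSON FeatureCollections (Polygon geometry, planar scene
metres, no CRS member) or flat CSV; rasters as single-band GeoTIFF with
ModelPixelScale/ModelTiepoint georeferencing tags (north-up, origin at the
top-left corner); colonies as CSV points; fitted models and run manifests as
JSON.  Writers are deterministic: stable key order, 6-significant-digit
floats in CSV, 3-decimal GeoJSON coordinates (mm at scene scale).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping

from . import features as feat
from . import synth
from .segmented import SegmentedNegativeBinomial, SegmentedNBResults

logger = logging.getLogger("floeseal")

__all__ = [
    "read_floes",
    "write_floes_geojson",
    "write_floes_csv",
    "read_raster",
    "write_raster",
    "read_colonies",
    "write_colonies",
    "model_to_json",
    "model_from_json",
    "RunConfig",
    "run_pipeline",
]

_CSV_FLOAT = "%.6g"
_REQUIRED_CSV = ("area",)


# --------------------------------------------------------------------------
# floes
# --------------------------------------------------------------------------

def write_floes_geojson(floes: pd.DataFrame, path) -> None:
    feats = []
    for _, row in floes.iterrows():
        geom = row.get("geometry")
        if geom is None:
            r = float(np.sqrt(row["area"] / np.pi))
            geom = shapely.Point(row["x"], row["y"]).buffer(r, quad_segs=32)
        gj = shapely_mapping(shapely.set_precision(geom, 0.001))
        props = {k: (v.item() if isinstance(v, np.generic) else v)
                 for k, v in row.items() if k != "geometry" and pd.notna(v)}
        props["area_m2"] = props.pop("area", None)
        props["perimeter_m"] = props.pop("perimeter", None)
        feats.append({"type": "Feature", "geometry": gj, "properties": props})
    doc = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(doc, sort_keys=True, allow_nan=False))


def write_floes_csv(floes: pd.DataFrame, path) -> None:
    floes.drop(columns=["geometry"], errors="ignore").to_csv(
        path, index=False, float_format=_CSV_FLOAT)


def read_floes(path) -> pd.DataFrame:
    """Read a floe table from GeoJSON or CSV.

    GeoJSON must be a FeatureCollection of Polygons; missing area/perimeter
    properties are recomputed from the geometry.  CSV needs at least the
    columns ``area, x, y``.  Internal floe ids are 0-based.
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        df = pd.read_csv(path)
        missing = [c for c in _REQUIRED_CSV if c not in df.columns]
        if missing:
            raise ValueError(f"floe CSV {path} lacks required columns: {missing}")
        if "floe_id" not in df.columns:
            df.insert(0, "floe_id", np.arange(len(df)))
        return df
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed GeoJSON in {path}: line {exc.lineno} "
                         f"col {exc.colno}: {exc.msg}") from exc
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    for i, featr in enumerate(doc.get("features", [])):
        geom = shapely_shape(featr["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(
                f"{path}: feature {i} has geometry {geom.geom_type}; "
                "only Polygon floes are supported")
        props = dict(featr.get("properties") or {})
        row = {"floe_id": i,
               "scene_id": props.pop("scene_id", 0),
               "area": props.pop("area_m2", None) or geom.area,
               "perimeter": props.pop("perimeter_m", None) or geom.length,
               "x": geom.centroid.x, "y": geom.centroid.y,
               "geometry": geom}
        props.pop("floe_id", None)
        props.pop("x", None), props.pop("y", None)
        row.update(props)
        rows.append(row)
    return pd.DataFrame(rows) if rows else synth._empty_floe_table()


# --------------------------------------------------------------------------
# rasters and colonies
# --------------------------------------------------------------------------

_TAG_SCALE = 33550   # GeoTIFF ModelPixelScaleTag
_TAG_TIEPOINT = 33922  # GeoTIFF ModelTiepointTag


def write_raster(grid: np.ndarray, path, pixel_size: float,
                 origin=(0.0, 0.0)) -> None:
    """Single-band GeoTIFF, north-up affine, origin at the top-left corner."""
    extratags = [
        (_TAG_SCALE, "d", 3, (float(pixel_size), float(pixel_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)),
    ]
    data = grid.astype(np.float32) if grid.dtype != bool else grid.astype(np.uint8)
    tifffile.imwrite(path, data, extratags=extratags)


def read_raster(path):
    """Returns ``(grid, pixel_size, origin)`` from a single-band GeoTIFF."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        grid = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    scale = tags.get(_TAG_SCALE, (1.0, 1.0, 0.0))
    tie = tags.get(_TAG_TIEPOINT, (0.0,) * 6)
    return grid, float(scale[0]), (float(tie[3]), float(tie[4]))


def read_colonies(path) -> feat.ColonySet:
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"colony CSV {path} lacks columns: {missing}")
    return feat.ColonySet(df[["x", "y"]].to_numpy(dtype=float))


def write_colonies(points: np.ndarray, path) -> None:
    pd.DataFrame(np.atleast_2d(points), columns=["x", "y"]).to_csv(
        path, index=False, float_format=_CSV_FLOAT)


# --------------------------------------------------------------------------
# model serialization
# --------------------------------------------------------------------------

def model_to_json(res: SegmentedNBResults, path=None) -> dict:
    doc = {
        "model": "segmented_nb2",
        "coefficients": {k: float(v) for k, v in res.params.items()},
        "se": {k: float(v) for k, v in res.bse.items()},
        "breakpoints": [float(p) for p in res.psi],
        "breakpoint_se": [float(s) for s in res.psi_se],
        "segment_slopes": [float(s) for s in res.segment_slopes] if len(res.psi) else
                          [float(res.params[res.seg_name])],
        "exog_names": list(res.exog_names),
        "theta": float(res.theta),
        "theta_se": float(res.theta_se),
        "loglik": float(res.llf),
        "aic": float(res.aic),
        "seg_name": res.seg_name,
        "convergence": {"converged": bool(res.converged),
                        "n_iter": int(res.n_iter),
                        "n_starts": int(res.n_starts),
                        "trace": res.trace},
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))
    return doc


def model_from_json(path) -> SegmentedNBResults:
    doc = json.loads(Path(path).read_text())
    names = doc.get("exog_names", sorted(doc["coefficients"]))
    coef = pd.Series(doc["coefficients"]).reindex(names)
    return SegmentedNBResults(
        params=coef, bse=pd.Series(doc["se"]).reindex(names),
        theta=doc["theta"], theta_se=doc["theta_se"], llf=doc["loglik"],
        aic=doc["aic"], converged=doc["convergence"]["converged"],
        n_iter=doc["convergence"]["n_iter"], exog_names=names,
        psi=np.asarray(doc["breakpoints"], dtype=float),
        psi_se=np.asarray(doc["breakpoint_se"], dtype=float),
        seg_name=doc.get("seg_name", "area"))


# --------------------------------------------------------------------------
# run configuration and pipeline
# --------------------------------------------------------------------------

_CONFIG_SECTIONS = ("scene", "model", "features", "fit", "predict")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through YAML."""

    scene: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    predict: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "floeseal_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(_CONFIG_SECTIONS) | {"seed", "out_dir", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for sec in _CONFIG_SECTIONS:
            if not isinstance(raw.get(sec, {}), dict):
                raise ValueError(f"config section {sec!r} must be a mapping")
        cfg = cls(**raw)
        for sec, allowed in (("scene", synth.SceneSpec.__dataclass_fields__),
                             ("model", synth.SegmentedModelSpec.__dataclass_fields__)):
            bad = set(getattr(cfg, sec)) - set(allowed)
            if bad:
                raise ValueError(f"unknown keys in config section {sec!r}: {sorted(bad)}")
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> features -> fit -> predict, with a manifest of artifacts.

    Each stage logs on entry and persists its outputs before the next starts,
    so a failure leaves prior artifacts on disk; the manifest records the
    package version, seeds and SHA-256 digests of every file written.
    """
    from . import __version__
    from .prediction import predict_counts, scene_summary

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("simulate")
        spec = synth.SceneSpec(**{"seed": config.seed, **config.scene})
        model = synth.SegmentedModelSpec(**config.model)
        floes, mask = synth.gen_floe_field(spec)
        bathy = synth.gen_bathymetry(spec, shape=mask.shape)
        colonies = synth.gen_colonies(spec)
        write_floes_geojson(floes, out / "floes.geojson")
        write_raster(mask, out / "ice_mask.tif", spec.pixel_size)
        write_raster(bathy, out / "bathymetry.tif", spec.pixel_size)
        write_colonies(colonies, out / "colonies.csv")
        artifacts.update({k: out / v for k, v in
                          [("floes", "floes.geojson"), ("ice_mask", "ice_mask.tif"),
                           ("bathymetry", "bathymetry.tif"), ("colonies", "colonies.csv")]})

        stage("features")
        rasters = feat.SceneRasters(mask, bathy, spec.pixel_size)
        buf = config.features.get("edge_buffer", 1000.0)
        kept, report = feat.edge_filter(floes, rasters.bounds, buffer=buf)
        logger.info("edge filter removed %d floes", report["n_excluded"])
        table = feat.build_feature_table(kept, rasters, feat.ColonySet(colonies))
        table = synth.sample_counts(table, model, config.seed)
        write_floes_csv(table, out / "features.csv")
        artifacts["features"] = out / "features.csv"

        stage("fit")
        n_bp = config.fit.get("n_breakpoints", 2)
        exog_cols = config.fit.get(
            "covariates", ["rough_1000", "sic_750", "colony_dist"])
        exog = np.column_stack([np.ones(len(table))] +
                               [table[c].to_numpy(dtype=float) for c in exog_cols])
        seg = table["area"].to_numpy(dtype=float)
        res = SegmentedNegativeBinomial(
            table["seal_count"].to_numpy(), exog, seg, n_breakpoints=n_bp,
            exog_names=["const"] + exog_cols).fit(
                init=config.fit.get("init", "quantile"))
        model_to_json(res, out / "model.json")
        artifacts["model"] = out / "model.json"

        stage("predict")
        mu = predict_counts(res, table)
        preds = table.drop(columns=["geometry"], errors="ignore").copy()
        preds["mu_hat"] = mu
        preds.to_csv(out / "preds.csv", index=False, float_format=_CSV_FLOAT)
        summary = scene_summary(table, mu)
        summary.to_csv(out / "report.csv", index=False, float_format=_CSV_FLOAT)
        artifacts["preds"] = out / "preds.csv"
        artifacts["report"] = out / "report.csv"
    except Exception:
        logger.exception("pipeline halted; artifacts so far: %s",
                         {k: str(v) for k, v in artifacts.items()})
        raise

    manifest = {
        "package": "floeseal", "version": __version__, "seed": config.seed,
        "config": asdict(config),
        "artifacts": {k: {"path": str(v), "sha256": _digest(v)}
                      for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
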
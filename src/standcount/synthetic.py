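"""Synthetic rapeseed plot scenes with exact per-leaf ground truth.

Real stand-count studies work from UAV orthomosaics of seedling plots in
which every canopy leaf has been hand-outlined. This module emulates that
data: rosette plants whose leaf number and leaf size follow the crop's
leaf-development staging (driven by days after planting, DAP), heavy canopy
overlap at late stages, small green weed blobs, and a textured bare-soil
background. Because the scene is rendered from the ground truth, every leaf
outline, plant center and plant count is exact — which is what lets every
downstream stage (labeling, CNN detection, overcounting calibration,
leaf-to-plant regression) be verified quantitatively.

Colors are drawn so that the vegetation-index rules used for class labeling
hold by construction: leaf and weed pixels satisfy ExG−ExR > 0, soil pixels
satisfy NGRDI < 0.

Coordinates are 0-based, row-major, pixel-center, with half-open image
bounds. Polygons are (n, 2) float arrays of (row, col) vertices, closed
implicitly (last vertex connects to first).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

__all__ = [
    "GrowthStageSpec",
    "LeafAnnotation",
    "PlotScene",
    "SimConfig",
    "PlacementError",
    "generate_scene",
    "generate_observation_series",
    "save_scene",
    "load_scene",
]


class PlacementError(ValueError):
    """Raised when the requested plant count cannot fit in the plot."""


@dataclass(frozen=True)
class GrowthStageSpec:
    """Leaf-development stage parameters for one observation date.

    The staging follows the crop's leaf-unfolding calendar: one- to
    three-leaf before 40 DAP, three- to four-leaf from 40 to 50 DAP,
    four- to six-leaf from 50 to 60 DAP, seven leaves and beyond after
    60 DAP. Leaf size grows with DAP; overlap intensity (0 = isolated
    rosettes, 1 = closed canopy) rises with it.
    """

    dap: int
    leaves_per_plant_range: tuple[int, int]
    leaf_major_axis: tuple[float, float]  # (mean, sd) in cm
    leaf_aspect: float = 0.65  # minor/major axis ratio
    overlap_intensity: float = 0.5

    def __post_init__(self) -> None:
        kmin, kmax = self.leaves_per_plant_range
        if kmin < 1 or kmax < kmin:
            raise ValueError("leaves_per_plant_range must satisfy 1 <= min <= max")
        if self.leaf_major_axis[0] <= 0:
            raise ValueError("leaf_major_axis mean must be positive")
        if not 0.0 <= self.overlap_intensity <= 1.0:
            raise ValueError("overlap_intensity must lie in [0, 1]")

    @classmethod
    def from_dap(cls, dap: int) -> "GrowthStageSpec":
        """Default staging for a given observation date (days after planting)."""
        if dap < 40:
            k = (1, 3)
        elif dap < 50:
            k = (3, 4)
        elif dap < 60:
            k = (4, 6)
        else:
            k = (7, 9)
        # Leaf blades elongate roughly linearly over the observed window;
        # the late-stage mean gives individual leaf areas of a few tens of
        # cm^2, matching field-scale rosette leaves.
        mean_cm = max(1.0, 0.14 * dap - 0.8)
        overlap = float(np.clip((dap - 30.0) / 45.0, 0.0, 1.0))
        return cls(
            dap=dap,
            leaves_per_plant_range=k,
            leaf_major_axis=(mean_cm, 0.12 * mean_cm),
            overlap_intensity=overlap,
        )


@dataclass
class LeafAnnotation:
    """One ground-truth leaf outline (or weed blob outline)."""

    vertices: np.ndarray  # (n, 2) float, (row, col)
    plant_id: int | None = None
    leaf_id: int = 0


@dataclass
class PlotScene:
    """One observation of one plot: raster, metadata and exact ground truth."""

    image: np.ndarray  # H x W x 3 uint8
    resolution: float  # cm per pixel
    dap: int
    plot_id: str
    role: str  # "train" | "test"
    leaf_polygons: list[LeafAnnotation]
    plant_count: int
    plant_centers: list[tuple[float, float]]
    weed_polygons: list[LeafAnnotation] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass(frozen=True)
class SimConfig:
    """Scene-generation parameters.

    The desk-scale default (2 m x 1 m at 0.25 cm/px, 800 x 400 px) runs the
    full pipeline in seconds; the field-scale geometry of the emulated study
    (9.5 m x 2 m plots at 0.18 cm/px, 20 cm row spacing) is available by
    overriding ``plot_size``/``resolution``.
    """

    plot_size: tuple[float, float] = (2.0, 1.0)  # (height m, width m)
    resolution: float = 0.25  # cm per pixel
    rows: int = 4
    row_spacing: float = 20.0  # cm
    plants_per_plot: int = 42
    weed_density: float = 12.0  # blobs per m^2 (no weed control in the field)
    stage: GrowthStageSpec = field(default_factory=lambda: GrowthStageSpec.from_dap(53))
    seed: int = 0
    plot_id: str = "plot-0"
    role: str = "train"

    def __post_init__(self) -> None:
        if self.plot_size[0] <= 0 or self.plot_size[1] <= 0:
            raise ValueError("plot_size must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.rows < 1 or self.row_spacing <= 0:
            raise ValueError("rows/row_spacing must be positive")
        if self.plants_per_plot < 0:
            raise ValueError("plants_per_plot must be >= 0")
        if self.weed_density < 0:
            raise ValueError("weed_density must be >= 0")

    @property
    def image_shape(self) -> tuple[int, int]:
        h = int(round(self.plot_size[0] * 100.0 / self.resolution))
        w = int(round(self.plot_size[1] * 100.0 / self.resolution))
        return h, w


# -- internal layout ---------------------------------------------------------

_MAX_LEAVES = 12
_GOLDEN_ANGLE = np.deg2rad(137.508)


@dataclass
class _PlantLayout:
    """Per-plant random state reused across observation dates of a series."""

    centers: np.ndarray  # (P, 2) float (row, col)
    leaf_u: np.ndarray  # (P,) uniform draws deciding leaf count within range
    base_angle: np.ndarray  # (P,)
    angle_jitter: np.ndarray  # (P, MAX) radians
    size_factor: np.ndarray  # (P, MAX) lognormal-ish per-leaf size multipliers
    green: np.ndarray  # (P, MAX, 3) base leaf color
    radial_frac: np.ndarray  # (P, MAX) leaf-center offset fraction


def _build_layout(config: SimConfig) -> _PlantLayout:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    h, w = config.image_shape
    p = config.plants_per_plot

    # Rows run along the image height, spaced across the width.
    spacing_px = config.row_spacing / config.resolution
    row_cols = (np.arange(config.rows) - (config.rows - 1) / 2.0) * spacing_px + w / 2.0
    if p > 0 and (row_cols.min() < 0 or row_cols.max() >= w):
        raise PlacementError("row layout does not fit in the plot width")

    # Mature-leaf reach decides the margin needed to keep polygons in bounds.
    reach_px = 1.6 * config.stage.leaf_major_axis[0] / config.resolution
    margin = min(reach_px, h / 4.0)

    per_row = np.full(config.rows, p // config.rows, dtype=int)
    per_row[: p % config.rows] += 1
    usable = h - 2.0 * margin
    min_spacing = 3.0
    if p > 0 and (usable <= 0 or per_row.max() * min_spacing > usable):
        raise PlacementError(
            f"cannot place {p} plants in a "
            f"{config.plot_size[0]:g}x{config.plot_size[1]:g} m plot"
        )

    centers = []
    for r in range(config.rows):
        n = per_row[r]
        if n == 0:
            continue
        base = margin + (np.arange(n) + 0.5) * usable / n
        rows_px = base + rng.normal(0.0, 0.15 * usable / max(n, 1), size=n)
        cols_px = row_cols[r] + rng.normal(0.0, 0.12 * spacing_px, size=n)
        rows_px = np.clip(rows_px, margin, h - 1 - margin)
        cols_px = np.clip(cols_px, margin, w - 1 - margin)
        centers.append(np.column_stack([rows_px, cols_px]))
    centers_arr = np.concatenate(centers) if centers else np.empty((0, 2))

    return _PlantLayout(
        centers=centers_arr,
        leaf_u=rng.uniform(0.0, 1.0, size=p),
        base_angle=rng.uniform(0.0, 2 * np.pi, size=p),
        angle_jitter=rng.normal(0.0, 0.25, size=(p, _MAX_LEAVES)),
        size_factor=np.exp(rng.normal(0.0, 0.18, size=(p, _MAX_LEAVES))),
        green=_leaf_green(rng, (p, _MAX_LEAVES)),
        radial_frac=rng.uniform(0.85, 1.15, size=(p, _MAX_LEAVES)),
    )


def _leaf_green(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    g = rng.uniform(105.0, 155.0, size=shape)
    r = g * rng.uniform(0.35, 0.55, size=shape)
    b = g * rng.uniform(0.25, 0.45, size=shape)
    return np.stack([r, g, b], axis=-1)


def _leaf_count(u: float, stage: GrowthStageSpec) -> int:
    kmin, kmax = stage.leaves_per_plant_range
    span = kmax - kmin + 1
    return int(kmin + min(span - 1, int(u * span)))


def _ellipse_polygon(
    center: np.ndarray,
    angle: float,
    major_px: float,
    aspect: float,
    bounds: tuple[int, int],
    n_vertices: int = 28,
) -> np.ndarray:
    """Leaf outline: an ellipse whose near end sits at the plant center side."""
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    a = major_px / 2.0
    b = a * aspect
    x = a * np.cos(t)
    y = b * np.sin(t)
    # Slight teardrop: narrow the end pointing back toward the plant center.
    pinch = 1.0 - 0.25 * np.clip(-np.cos(t), 0.0, 1.0)
    y = y * pinch
    rr = center[0] + x * np.sin(angle) + y * np.cos(angle)
    cc = center[1] + x * np.cos(angle) - y * np.sin(angle)
    rr = np.clip(rr, 0.0, bounds[0] - 1.0)
    cc = np.clip(cc, 0.0, bounds[1] - 1.0)
    return np.column_stack([rr, cc])


def _paint_polygon(
    image: np.ndarray,
    poly: np.ndarray,
    color: np.ndarray,
    rng: np.random.Generator,
    shade_center: np.ndarray | None = None,
) -> None:
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=image.shape[:2])
    if rr.size == 0:
        return
    px = np.broadcast_to(color, (rr.size, 3)).astype(np.float64).copy()
    if shade_center is not None:
        d = np.hypot(rr - shade_center[0], cc - shade_center[1])
        dmax = max(d.max(), 1.0)
        # Brighter toward the blade center, darker at the margin.
        px *= (1.0 + 0.22 * (1.0 - d / dmax))[:, None]
    px += rng.normal(0.0, 4.0, size=px.shape)
    image[rr, cc] = np.clip(px, 0.0, 255.0)


def _soil_background(
    shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    base = np.array([142.0, 120.0, 92.0])
    lowfreq = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=8.0)
    lowfreq /= max(np.abs(lowfreq).max(), 1e-9)
    img = base[None, None, :] * (1.0 + 0.10 * lowfreq[:, :, None])
    img += rng.normal(0.0, 5.0, size=(h, w, 1)) * np.array([1.0, 0.9, 0.8])
    return img


def _render_scene(
    config: SimConfig, layout: _PlantLayout, stage: GrowthStageSpec
) -> PlotScene:
    h, w = config.image_shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, stage.dap, 202]))

    img = _soil_background((h, w), rng)

    mean_major_px = stage.leaf_major_axis[0] / config.resolution
    sd_frac = stage.leaf_major_axis[1] / stage.leaf_major_axis[0]

    # Weeds first so leaves overpaint them where they overlap.
    weed_polys: list[LeafAnnotation] = []
    area_m2 = config.plot_size[0] * config.plot_size[1]
    n_weeds = int(rng.poisson(config.weed_density * area_m2))
    for j in range(n_weeds):
        center = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
        # Weed blobs stay below 40% of the stage's mean leaf area
        # (major axis <= sqrt(0.4) of the mean), a deliberate size cue.
        major = rng.uniform(0.30, 0.63) * mean_major_px
        poly = _ellipse_polygon(
            center, rng.uniform(0, 2 * np.pi), major, rng.uniform(0.5, 0.9), (h, w), 16
        )
        g = rng.uniform(110.0, 150.0)
        color = np.array([g * rng.uniform(0.60, 0.75), g, g * rng.uniform(0.20, 0.32)])
        _paint_polygon(img, poly, color, rng)
        weed_polys.append(LeafAnnotation(vertices=poly, plant_id=None, leaf_id=j))

    leaf_polys: list[LeafAnnotation] = []
    leaf_id = 0
    for p_idx in range(layout.centers.shape[0]):
        center = layout.centers[p_idx]
        k = _leaf_count(layout.leaf_u[p_idx], stage)
        for j in range(k):
            angle = (
                layout.base_angle[p_idx]
                + j * _GOLDEN_ANGLE
                + layout.angle_jitter[p_idx, j]
            )
            major = mean_major_px * layout.size_factor[p_idx, j]
            major *= 1.0 + sd_frac * 0.0  # sd folded into size_factor
            # Offset of the leaf-blade center from the plant center: petiole
            # length shrinks as the canopy closes (overlap_intensity -> 1).
            offset = (0.62 - 0.22 * stage.overlap_intensity) * major
            offset *= layout.radial_frac[p_idx, j]
            leaf_center = center + offset * np.array([np.sin(angle), np.cos(angle)])
            leaf_center = np.clip(leaf_center, 0.0, [h - 1.0, w - 1.0])
            poly = _ellipse_polygon(
                leaf_center, angle, major, stage.leaf_aspect, (h, w)
            )
            _paint_polygon(
                img, poly, layout.green[p_idx, j], rng, shade_center=leaf_center
            )
            leaf_polys.append(
                LeafAnnotation(vertices=poly, plant_id=p_idx, leaf_id=leaf_id)
            )
            leaf_id += 1

    img += rng.normal(0.0, 2.5, size=img.shape)
    image = np.clip(img, 0.0, 255.0).astype(np.uint8)

    return PlotScene(
        image=image,
        resolution=config.resolution,
        dap=stage.dap,
        plot_id=config.plot_id,
        role=config.role,
        leaf_polygons=leaf_polys,
        plant_count=layout.centers.shape[0],
        plant_centers=[tuple(c) for c in layout.centers],
        weed_polygons=weed_polys,
    )


def generate_scene(config: SimConfig) -> PlotScene:
    """Render one plot scene. The seed fully determines the output raster
    and ground-truth polygons (bit-identical across calls)."""
    layout = _build_layout(config)
    return _render_scene(config, layout, config.stage)


def generate_observation_series(
    base: SimConfig, daps: list[int]
) -> list[PlotScene]:
    """Render the same plot at several observation dates.

    Plant positions are identical across dates; per-plant leaf counts and
    leaf sizes are non-decreasing with DAP (plants only grow); the plant
    count is constant. Weeds and soil texture are redrawn per date.
    """
    if list(daps) != sorted(daps):
        raise ValueError("daps must be sorted ascending")
    layout = _build_layout(base)
    scenes = []
    for dap in daps:
        stage = GrowthStageSpec.from_dap(dap)
        scenes.append(_render_scene(base, layout, stage))
    return scenes


# -- plain-text scene I/O ----------------------------------------------------


def _polygons_to_geojson(annotations: list[LeafAnnotation]) -> dict:
    features = []
    for ann in annotations:
        ring = [[float(c), float(r)] for r, c in ann.vertices]  # (x, y) = (col, row)
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"plant_id": ann.plant_id, "leaf_id": ann.leaf_id},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def _geojson_to_polygons(doc: dict) -> list[LeafAnnotation]:
    out = []
    for feat in doc["features"]:
        ring = feat["geometry"]["coordinates"][0]
        verts = np.array([[y, x] for x, y in ring[:-1]], dtype=float)
        props = feat.get("properties") or {}
        out.append(
            LeafAnnotation(
                vertices=verts,
                plant_id=props.get("plant_id"),
                leaf_id=props.get("leaf_id", 0),
            )
        )
    return out


def save_scene(scene: PlotScene, out_dir: str | Path) -> Path:
    """Write a scene as PNG + leaf/weed GeoJSON + JSON sidecar; returns the dir."""
    out = Path(out_dir) / f"{scene.plot_id}_dap{scene.dap}"
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(scene.image).save(out / "image.png")
    (out / "leaves.geojson").write_text(
        json.dumps(_polygons_to_geojson(scene.leaf_polygons))
    )
    (out / "weeds.geojson").write_text(
        json.dumps(_polygons_to_geojson(scene.weed_polygons))
    )
    sidecar = {
        "plot_id": scene.plot_id,
        "dap": scene.dap,
        "resolution_cm": scene.resolution,
        "plant_count": scene.plant_count,
        "role": scene.role,
        "plant_centers": [[float(r), float(c)] for r, c in scene.plant_centers],
    }
    (out / "meta.json").write_text(json.dumps(sidecar, indent=1))
    return out


def load_scene(scene_dir: str | Path) -> PlotScene:
    d = Path(scene_dir)
    meta = json.loads((d / "meta.json").read_text())
    image = np.asarray(Image.open(d / "image.png").convert("RGB"))
    leaves = _geojson_to_polygons(json.loads((d / "leaves.geojson").read_text()))
    weeds_path = d / "weeds.geojson"
    weeds = (
        _geojson_to_polygons(json.loads(weeds_path.read_text()))
        if weeds_path.exists()
        else []
    )
    return PlotScene(
        image=image,
        resolution=meta["resolution_cm"],
        dap=meta["dap"],
        plot_id=meta["plot_id"],
        role=meta.get("role", "train"),
        leaf_polygons=leaves,
        plant_count=meta["plant_count"],
        plant_centers=[tuple(c) for c in meta.get("plant_centers", [])],
        weed_polygons=weeds,
    )


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
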
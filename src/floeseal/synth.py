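"""Synthetic pack-ice scenes and seal counts.

Real surveys of pack-ice seals work from very-high-resolution satellite
imagery that cannot be redistributed, so this module builds stand-in scenes
with the same statistical skeleton: a heavily right-skewed floe-size
distribution (floes >= 1 m^2), non-overlapping floes rasterised into an ice
mask, a smooth random bathymetry surface, penguin-colony point locations, and
per-floe seal counts drawn from an NB2 model whose log-mean is piecewise
linear in floe area (slope changes at two breakpoints) with additive effects
of bathymetric roughness, local sea-ice concentration and colony distance.

Everything is a pure function of (spec, seed): a master seed is split into
independent per-component streams with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "SceneSpec",
    "SegmentedModelSpec",
    "gen_floe_field",
    "gen_bathymetry",
    "gen_colonies",
    "sample_covariates",
    "sample_counts",
    "simulate_scene",
    "simulate_survey_table",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Geometry and stochastic parameters of one synthetic scene.

    Distances in metres.  The floe-size law is log-normal by default
    (``size_law="lognormal"``, parameters ``size_meanlog``/``size_sdlog`` on
    log-area), with a Pareto option (``size_meanlog`` ignored,
    ``size_sdlog`` reinterpreted as the tail index); areas are truncated to
    [min_area, max_area].
    """

    width: float = 6000.0
    height: float = 6000.0
    pixel_size: float = 2.0
    n_floes: int = 500
    size_law: str = "lognormal"
    size_meanlog: float = math.log(10.0)
    size_sdlog: float = 2.0
    min_area: float = 1.0
    max_area: float = 5000.0
    bathy_mean: float = -450.0
    bathy_amplitude: float = 60.0
    bathy_corr_length: float = 800.0
    n_colonies: int = 3
    colony_extent: float = 8.0e5
    floe_shape: str = "circle"
    seed: int = 0

    def __post_init__(self):
        if min(self.width, self.height) <= 2000.0:
            raise ValueError("scene must exceed 2000 m in each dimension "
                             "(the 1000 m edge buffer must leave an interior)")
        if self.min_area < 1.0:
            raise ValueError("min_area must be >= 1 m^2")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.size_law not in ("lognormal", "pareto"):
            raise ValueError(f"unknown size law {self.size_law!r}")
        if self.floe_shape not in ("circle", "polygon"):
            raise ValueError(f"unknown floe shape {self.floe_shape!r}")


@dataclass
class SegmentedModelSpec:
    """Generative (or fitted) segmented NB2 occupancy model.

    log mu = beta0 + beta_area1 * a + beta_area2_inc * h(a, psi1)
             + beta_area3_inc * h(a, psi2) + beta_rough * rough_1000
             + beta_sic * sic_750 + beta_colony * colony_dist

    with h(a, psi) = max(0, a - psi) and counts NB2:
    Var = mu + mu^2 / theta.  The hinge coefficients are slope *increments*,
    so log-mean is continuous in area by construction and the per-segment
    slopes are cumulative sums of (beta_area1, beta_area2_inc,
    beta_area3_inc).  Units: areas m^2, SIC a fraction in [0, 1], roughness
    metres, colony distance metres.
    """

    beta0: float = -7.53
    beta_area1: float = 0.139
    beta_area2_inc: float = -0.136
    beta_area3_inc: float = -0.003
    psi1: float = 49.84
    psi2: float = 481.32
    beta_rough: float = 0.042
    beta_sic: float = -0.72
    beta_colony: float = 6.19e-7
    theta: float = 0.5

    def __post_init__(self):
        if not self.psi1 < self.psi2:
            raise ValueError("breakpoints must satisfy psi1 < psi2")
        if self.theta <= 0:
            raise ValueError("NB dispersion theta must be positive")

    @classmethod
    def default(cls) -> "SegmentedModelSpec":
        """The reference Western-Antarctic-Peninsula haul-out model.

        First-segment area slope 0.139 per m^2 up to ~50 m^2, a slope of
        0.003 between the breakpoints, and a plateau past ~481 m^2; denser
        surrounding ice depresses haul-out (SIC coefficient -0.72) while
        rougher bathymetry raises it.  The dispersion is a package default
        (strong overdispersion); see docs/methods.md.
        """
        return cls()

    @property
    def segment_slopes(self) -> np.ndarray:
        return np.cumsum([self.beta_area1, self.beta_area2_inc, self.beta_area3_inc])

    def linear_predictor(self, floes: pd.DataFrame) -> np.ndarray:
        a = floes["area"].to_numpy(dtype=float)
        lp = (self.beta0
              + self.beta_area1 * a
              + self.beta_area2_inc * np.maximum(0.0, a - self.psi1)
              + self.beta_area3_inc * np.maximum(0.0, a - self.psi2)
              + self.beta_rough * floes["rough_1000"].to_numpy(dtype=float)
              + self.beta_sic * floes["sic_750"].to_numpy(dtype=float)
              + self.beta_colony * floes["colony_dist"].to_numpy(dtype=float))
        return lp

    def mu(self, floes: pd.DataFrame) -> np.ndarray:
        return np.exp(self.linear_predictor(floes))

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# floe field
# --------------------------------------------------------------------------

def _draw_areas(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Truncated right-skewed areas, by rejection from the parent law."""
    out = np.empty(0)
    while out.size < spec.n_floes:
        m = max(4 * (spec.n_floes - out.size), 256)
        if spec.size_law == "lognormal":
            draw = np.exp(rng.normal(spec.size_meanlog, spec.size_sdlog, size=m))
        else:  # pareto with tail index size_sdlog, scale min_area
            draw = spec.min_area * (1.0 + rng.pareto(spec.size_sdlog, size=m))
        draw = draw[(draw >= spec.min_area) & (draw <= spec.max_area)]
        out = np.concatenate([out, draw])
    return out[: spec.n_floes]


def _convex_floe(center, area, rng: np.random.Generator) -> Polygon:
    """Random convex polygon scaled to the requested area."""
    k = rng.integers(6, 12)
    ang = np.sort(rng.uniform(0, 2 * np.pi, size=k))
    rad = rng.uniform(0.6, 1.0, size=k)
    pts = np.c_[np.cos(ang) * rad, np.sin(ang) * rad]
    poly = Polygon(pts).convex_hull
    scale = math.sqrt(area / poly.area)
    coords = np.asarray(poly.exterior.coords) * scale + np.asarray(center)
    return Polygon(coords)


def gen_floe_field(spec: SceneSpec, max_retries: int = 200):
    """Place non-overlapping floes and rasterise the ice mask.

    Returns ``(floes, ice_mask)``: a DataFrame with one row per floe
    (floe_id, area, perimeter, centroid, geometry; covariates and counts
    unset) and a boolean ice-mask grid at ``spec.pixel_size``.  Floes are
    placed largest-first by rejection sampling; if a floe cannot be placed in
    ``max_retries`` attempts a RuntimeError reports the ice fraction
    achieved so far.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    ny = int(round(spec.height / spec.pixel_size))
    nx = int(round(spec.width / spec.pixel_size))
    mask = np.zeros((ny, nx), dtype=bool)
    if spec.n_floes == 0:
        return _empty_floe_table(), mask

    areas = np.sort(_draw_areas(spec, rng))[::-1]
    radii = np.sqrt(areas / math.pi)
    # coarse occupancy grid for overlap rejection
    cell = max(2.0 * radii.max(), spec.pixel_size)
    gx = int(math.ceil(spec.width / cell))
    gy = int(math.ceil(spec.height / cell))
    buckets: dict[tuple[int, int], list[int]] = {}
    xs = np.empty(spec.n_floes)
    ys = np.empty(spec.n_floes)
    placed = 0
    for i, r in enumerate(radii):
        ok = False
        for _ in range(max_retries):
            x = rng.uniform(r, spec.width - r)
            y = rng.uniform(r, spec.height - r)
            bx, by = int(x / cell), int(y / cell)
            clash = False
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for j in buckets.get((bx + dx, by + dy), ()):
                        if (x - xs[j]) ** 2 + (y - ys[j]) ** 2 < (r + radii[j] + spec.pixel_size) ** 2:
                            clash = True
                            break
                    if clash:
                        break
                if clash:
                    break
            if not clash:
                xs[i], ys[i] = x, y
                buckets.setdefault((bx, by), []).append(i)
                ok = True
                placed += 1
                break
        if not ok:
            achieved = areas[:placed].sum() / (spec.width * spec.height)
            raise RuntimeError(
                f"could not place floe of area {areas[i]:.1f} m^2 after "
                f"{max_retries} tries; achieved ice fraction {achieved:.3f} — "
                "requested ice cover appears unattainable for this scene")

    records = []
    for i in range(spec.n_floes):
        c = (xs[i], ys[i])
        if spec.floe_shape == "circle":
            geom = Point(c).buffer(radii[i], quad_segs=32)
            perim = 2.0 * math.pi * radii[i]
        else:
            geom = _convex_floe(c, areas[i], rng)
            perim = geom.length
        records.append({"floe_id": i, "scene_id": 0, "area": areas[i],
                        "perimeter": perim, "x": c[0], "y": c[1],
                        "geometry": geom})
        _rasterize_circle(mask, c, radii[i], spec.pixel_size) \
            if spec.floe_shape == "circle" else _rasterize_poly(mask, geom, spec.pixel_size)
    floes = pd.DataFrame.from_records(records)
    return floes, mask


def _empty_floe_table() -> pd.DataFrame:
    return pd.DataFrame({
        "floe_id": pd.Series(dtype=int), "scene_id": pd.Series(dtype=int),
        "area": pd.Series(dtype=float), "perimeter": pd.Series(dtype=float),
        "x": pd.Series(dtype=float), "y": pd.Series(dtype=float),
        "geometry": pd.Series(dtype=object)})


def _rasterize_circle(mask, center, radius, px):
    x0, y0 = center
    j0 = max(int((x0 - radius) / px), 0)
    j1 = min(int((x0 + radius) / px) + 1, mask.shape[1])
    i0 = max(int((y0 - radius) / px), 0)
    i1 = min(int((y0 + radius) / px) + 1, mask.shape[0])
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    cx = (jj + 0.5) * px
    cy = (ii + 0.5) * px
    inside = (cx - x0) ** 2 + (cy - y0) ** 2 <= radius ** 2
    mask[i0:i1, j0:j1] |= inside


def _rasterize_poly(mask, geom, px):
    minx, miny, maxx, maxy = geom.bounds
    j0 = max(int(minx / px), 0)
    j1 = min(int(maxx / px) + 1, mask.shape[1])
    i0 = max(int(miny / px), 0)
    i1 = min(int(maxy / px) + 1, mask.shape[0])
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    pts = shapely.points(np.c_[(jj.ravel() + 0.5) * px, (ii.ravel() + 0.5) * px])
    inside = shapely.covers(geom, pts).reshape(jj.shape)
    mask[i0:i1, j0:j1] |= inside


# --------------------------------------------------------------------------
# bathymetry
# --------------------------------------------------------------------------

def gen_bathymetry(spec: SceneSpec, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Spectrally synthesised smooth depth surface.

    Gaussian random field built by filtering white noise in Fourier space
    with a Gaussian kernel of length scale ``bathy_corr_length``; rescaled so
    the realised field has standard deviation ``bathy_amplitude`` about
    ``bathy_mean`` (a zero amplitude yields a constant grid).
    """
    if spec.bathy_corr_length <= 0:
        raise ValueError("bathymetry correlation length must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    if shape is None:
        shape = (int(round(spec.height / spec.pixel_size)),
                 int(round(spec.width / spec.pixel_size)))
    ny, nx = shape
    if spec.bathy_amplitude == 0:
        return np.full(shape, spec.bathy_mean)
    noise = rng.standard_normal(shape)
    ky = np.fft.fftfreq(ny, d=spec.pixel_size)
    kx = np.fft.fftfreq(nx, d=spec.pixel_size)
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    filt = np.exp(-2.0 * np.pi ** 2 * k2 * spec.bathy_corr_length ** 2)
    field = np.real(np.fft.ifft2(np.fft.fft2(noise) * filt))
    sd = field.std()
    if sd < 1e-12:
        return np.full(shape, spec.bathy_mean)
    return spec.bathy_mean + spec.bathy_amplitude * (field - field.mean()) / sd


def gen_colonies(spec: SceneSpec) -> np.ndarray:
    """Penguin-colony point locations, uniform in a frame around the scene.

    Colonies sit within ``colony_extent`` metres of the scene origin (real
    colonies are tens to hundreds of km from the pack ice), never inside the
    scene itself.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    pts = []
    while len(pts) < spec.n_colonies:
        x = rng.uniform(-spec.colony_extent, spec.colony_extent)
        y = rng.uniform(-spec.colony_extent, spec.colony_extent)
        if 0 <= x <= spec.width and 0 <= y <= spec.height:
            continue
        pts.append((x, y))
    return np.asarray(pts, dtype=float)


# --------------------------------------------------------------------------
# covariates and counts
# --------------------------------------------------------------------------

#: Parametric per-floe covariate distributions used when floes are simulated
#: directly, without a raster scene.  Chosen to emulate pack-ice conditions
#: along the western Antarctic Peninsula: high surrounding ice concentration
#: (Beta(5, 2), mean 0.71), seafloor roughness on the order of tens of metres
#: (log-normal, mean ~21 m), colonies 20-800 km away.
COVARIATE_LAWS = {
    "sic_750": ("beta", 5.0, 2.0),
    "rough_1000": ("lognormal", 2.95, 0.4),
    "colony_dist": ("uniform", 2.0e4, 8.0e5),
}


def sample_covariates(n: int, seed: int) -> pd.DataFrame:
    """Draw per-floe covariates from the package's parametric laws.

    Also fills the companion covariates (SIC at the other radii, slope and
    TRI at 1000 m) as noisy monotone transforms of the primary ones so that
    selection procedures see realistically correlated candidates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    sic = rng.beta(*COVARIATE_LAWS["sic_750"][1:], size=n)
    rough = np.exp(rng.normal(*COVARIATE_LAWS["rough_1000"][1:], size=n))
    dist = rng.uniform(*COVARIATE_LAWS["colony_dist"][1:], size=n)
    df = pd.DataFrame({"sic_750": sic, "rough_1000": rough, "colony_dist": dist})
    for r in (150, 250, 500, 1000):
        df[f"sic_{r}"] = np.clip(sic + rng.normal(0, 0.05, size=n), 0.0, 1.0)
    df["slope_1000"] = rough * 0.002 + rng.normal(0, 0.005, size=n)
    df["tri_1000"] = rough * 0.35 + rng.normal(0, 1.0, size=n)
    return df


def sample_counts(floes: pd.DataFrame, model: SegmentedModelSpec, seed: int,
                  lp_max: float = 50.0) -> pd.DataFrame:
    """Draw NB2 seal counts for each floe from the occupancy model.

    Returns a copy of ``floes`` with ``seal_count`` filled.  A linear
    predictor above ``lp_max`` aborts with the offending floe named — that
    always indicates mis-scaled covariates rather than a plausible scene.
    """
    required = ["area", "rough_1000", "sic_750", "colony_dist"]
    missing = [c for c in required if c not in floes.columns]
    if missing:
        raise ValueError(f"floes table lacks model covariates: {missing}")
    lp = model.linear_predictor(floes)
    if np.any(lp > lp_max):
        i = int(np.argmax(lp))
        fid = floes["floe_id"].iloc[i] if "floe_id" in floes else i
        raise ValueError(
            f"linear predictor {lp[i]:.1f} > {lp_max} for floe {fid} "
            f"(area {floes['area'].iloc[i]:.1f} m^2); covariates look mis-scaled")
    mu = np.exp(lp)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    p = model.theta / (model.theta + mu)
    out = floes.copy()
    out["seal_count"] = rng.negative_binomial(model.theta, p)
    return out


# --------------------------------------------------------------------------
# convenience drivers
# --------------------------------------------------------------------------

def simulate_scene(spec: SceneSpec, model: SegmentedModelSpec | None = None):
    """Full scene: floes + ice mask + bathymetry + colonies (+ counts).

    Covariates here come from the raster via the ``features`` module, so this
    returns raw geometry products; use :func:`floeseal.features.build_feature_table`
    then :func:`sample_counts` to finish, or `floeseal.io.run_pipeline`.
    """
    floes, mask = gen_floe_field(spec)
    bathy = gen_bathymetry(spec, shape=mask.shape)
    colonies = gen_colonies(spec)
    return floes, mask, bathy, colonies


def simulate_survey_table(n_floes: int, model: SegmentedModelSpec, seed: int,
                          spec: SceneSpec | None = None) -> pd.DataFrame:
    """Floe-level survey table without rasters: areas + covariates + counts.

    The fast path for simulation studies: draws areas from the scene spec's
    floe-size law and covariates from :data:`COVARIATE_LAWS`, then samples
    NB2 counts from ``model``.
    """
    spec = spec or SceneSpec(n_floes=n_floes, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    areas = _draw_areas(
        SceneSpec(**{**asdict(spec), "n_floes": n_floes, "seed": seed}), rng)
    df = sample_covariates(n_floes, seed)
    df.insert(0, "area", areas)
    # circle-equivalent perimeter with mild shape irregularity
    df["perimeter"] = 2.0 * np.sqrt(np.pi * areas) * rng.uniform(1.0, 1.3, n_floes)
    df.insert(0, "scene_id", 0)
    df.insert(0, "floe_id", np.arange(n_floes))
    return sample_counts(df, model, seed)
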
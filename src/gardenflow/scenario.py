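"""Seeded synthetic city scenarios.

A scenario emulates the inputs of a socio-ecological connectivity study of an
urban community-garden network: a classified land-cover raster (canopy,
grass/shrub, bare soil, water, buildings, roads/railroads, other paved), a
census-block-group tessellation carrying six correlated sociodemographic
covariates with garden presence planted through a known logistic model,
garden point patterns (clustered or dispersed), and Poisson amenity layers
(schools, parks, places of worship, ...) that later reduce resistance inside
their buffers.

Everything is generated from a single integer seed; a fixed seed reproduces
every output bit-for-bit.  The planted logistic coefficients are recorded on
the block-group table so variable-selection recovery can be tested against
ground truth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .errors import ConfigurationError, GenerationError
from .grid import GridTransform, RasterGrid, rectangle

# Sociodemographic covariates carried by every scenario (block-group scale).
COVARIATE_NAMES = (
    "avg_household_size",
    "median_age",
    "prop_black",
    "prop_hispanic",
    "prop_renters",
    "prop_vacant",
)

_DEFAULT_MEANS = {
    "avg_household_size": 2.6,
    "median_age": 35.0,
    "prop_black": 0.30,
    "prop_hispanic": 0.20,
    "prop_renters": 0.50,
    "prop_vacant": 0.10,
}
_DEFAULT_SDS = {
    "avg_household_size": 0.5,
    "median_age": 8.0,
    "prop_black": 0.20,
    "prop_hispanic": 0.15,
    "prop_renters": 0.20,
    "prop_vacant": 0.08,
}

# Mild, census-plausible correlation among the six covariates (ordered as
# COVARIATE_NAMES): household size falls with median age; renter share rises
# with minority share; vacancy tracks both.
_DEFAULT_CORRELATION = np.array(
    [
        [1.00, -0.25, 0.10, 0.15, 0.20, 0.05],
        [-0.25, 1.00, -0.10, -0.10, -0.30, 0.00],
        [0.10, -0.10, 1.00, -0.20, 0.25, 0.30],
        [0.15, -0.10, -0.20, 1.00, 0.20, 0.05],
        [0.20, -0.30, 0.25, 0.20, 1.00, 0.25],
        [0.05, 0.00, 0.30, 0.05, 0.25, 1.00],
    ]
)

# Planted log-odds of garden presence on standardized covariates:
# intercept then one coefficient per covariate in COVARIATE_NAMES order.
_DEFAULT_BETA = (-1.0, 0.9, -0.7, 0.8, 0.6, -0.6, 0.7)

_DEFAULT_AMENITIES = {
    # name: (points per km^2, buffer metres, surface the reduction targets)
    "public_schools": (1.0, 500.0, "social"),
    "city_parks": (2.0, 250.0, "social"),
    "places_of_worship": (2.0, 500.0, "social"),
    "community_centers": (0.5, 250.0, "social"),
    "libraries": (0.3, 250.0, "social"),
    "conservation_lands": (0.5, 500.0, "biophysical"),
    "wetlands": (0.3, 500.0, "biophysical"),
}

_DEFAULT_CLASS_FRACTIONS = {
    "water": 0.03,
    "canopy": 0.18,
    "grass_shrub": 0.27,
    "bare_soil": 0.05,
    "other_paved": 0.27,
    "building": 0.20,
}


class LandClass(enum.IntEnum):
    """Integer land-cover codes used in the classified raster."""

    CANOPY = 1
    GRASS_SHRUB = 2
    BARE_SOIL = 3
    WATER = 4
    BUILDING = 5
    ROAD_RAIL = 6
    OTHER_PAVED = 7


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic city scenario.

    Attributes
    ----------
    grid_shape : (rows, cols)
        Land-cover raster dimensions.
    cell_size : float
        Metres per raster cell.
    n_blockgroups : int
        Number of census-block-group polygons tiling the extent.
    covariate_means, covariate_sds : dict
        Location/scale of the six named covariates.
    covariate_correlation : (6, 6) array
        Correlation among the named covariates; must be positive
        semi-definite.
    planted_beta : sequence of 7 floats
        Logistic intercept + per-covariate log-odds driving garden presence
        (on standardized covariates); recorded as recoverable truth.
    n_decoys : int
        Extra independent standard-normal covariates with zero true effect,
        so variable selection is non-trivial.
    garden_mode : {"clustered", "dispersed"}
        Point-pattern family for garden nodes.
    n_gardens : int
        Node count (>= 2; pairwise flow needs at least two nodes).
    cluster_sigma_m, n_parents : float, int
        Parent-offspring (Thomas-like) dispersion scale and parent count for
        clustered mode.
    min_spacing_m : float
        Hard-core minimum pairwise distance for dispersed mode.
    amenity_rates : dict name -> points per km^2
        Homogeneous Poisson intensity per amenity layer.
    amenity_buffers_m, amenity_targets : dict
        Buffer radius (metres) and target surface ("social"/"biophysical")
        per layer.
    amenity_reduction : float
        Fractional resistance reduction inside each buffer (default 0.10).
    class_fractions : dict
        Target land-cover mixing proportions over non-road cells.
    road_spacing_cells, smooth_sigma_cells : int, float
        Road-lattice period and Gaussian smoothing scale of the neutral
        land-cover field.
    seed : int
        Master seed; every stage derives its stream from it.
    """

    grid_shape: tuple[int, int] = (200, 200)
    cell_size: float = 10.0
    n_blockgroups: int = 200
    covariate_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    covariate_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    covariate_correlation: np.ndarray = field(
        default_factory=lambda: _DEFAULT_CORRELATION.copy()
    )
    planted_beta: Sequence[float] = _DEFAULT_BETA
    n_decoys: int = 2
    garden_mode: str = "clustered"
    n_gardens: int = 43
    cluster_sigma_m: float = 150.0
    n_parents: int = 6
    min_spacing_m: float = 120.0
    amenity_rates: dict = field(
        default_factory=lambda: {k: v[0] for k, v in _DEFAULT_AMENITIES.items()}
    )
    amenity_buffers_m: dict = field(
        default_factory=lambda: {k: v[1] for k, v in _DEFAULT_AMENITIES.items()}
    )
    amenity_targets: dict = field(
        default_factory=lambda: {k: v[2] for k, v in _DEFAULT_AMENITIES.items()}
    )
    amenity_reduction: float = 0.10
    class_fractions: dict = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_FRACTIONS)
    )
    road_spacing_cells: int = 25
    smooth_sigma_cells: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ConfigurationError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")
        if self.n_blockgroups < 1:
            raise ConfigurationError("n_blockgroups must be >= 1")
        if self.n_gardens < 2:
            raise ConfigurationError("n_gardens must be >= 2 (pairwise flow)")
        if self.garden_mode not in ("clustered", "dispersed"):
            raise ConfigurationError(f"unknown garden_mode {self.garden_mode!r}")
        corr = np.asarray(self.covariate_correlation, dtype=float)
        k = len(COVARIATE_NAMES)
        if corr.shape != (k, k):
            raise ConfigurationError(f"covariate_correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T):
            raise ConfigurationError("covariate_correlation must be symmetric")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("covariate_correlation must be positive semi-definite")
        if len(self.planted_beta) != k + 1:
            raise ConfigurationError(
                f"planted_beta needs intercept + {k} coefficients"
            )
        if not 0 < self.amenity_reduction < 1:
            raise ConfigurationError("amenity_reduction must lie in (0, 1)")
        for name, rate in self.amenity_rates.items():
            if rate < 0:
                raise ConfigurationError(f"amenity rate for {name!r} is negative")
        frac = sum(self.class_fractions.values())
        if not np.isclose(frac, 1.0, atol=1e-6):
            raise ConfigurationError("class_fractions must sum to 1")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ConfigurationError("class_fractions must be non-negative")

    # -- geometry helpers -------------------------------------------------
    @property
    def transform(self) -> GridTransform:
        return GridTransform(0.0, 0.0, self.cell_size)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        rows, cols = self.grid_shape
        return (0.0, 0.0, cols * self.cell_size, rows * self.cell_size)

    @property
    def boundary(self):
        return rectangle(*self.extent)

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream for one generation stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class AmenityLayer:
    """A named Poisson point layer whose buffer reduces resistance."""

    name: str
    points: np.ndarray  # (n, 2) map coordinates
    buffer_m: float
    reduction: float = 0.10
    target: str = "social"

    def buffer_union(self):
        if len(self.points) == 0:
            return shapely.Polygon()
        return shapely.union_all(
            [shapely.Point(p).buffer(self.buffer_m) for p in self.points]
        )


# ---------------------------------------------------------------------------
# land cover


def generate_landcover(config: ScenarioConfig) -> RasterGrid:
    """Generate a classified land-cover raster.

    A Gaussian-smoothed noise field is sliced at the quantiles of the target
    mixing proportions (a neutral-landscape construction), producing
    contiguous water bodies, green patches and built-up blocks; a road
    lattice is then drawn on top at ``road_spacing_cells`` period.  The class
    histogram of non-road cells therefore matches ``class_fractions`` to
    within quantile rounding.
    """
    config.validate()
    rows, cols = config.grid_shape
    rng = config.rng(stage=1)
    fld = ndimage.gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=config.smooth_sigma_cells
    )

    road = np.zeros((rows, cols), dtype=bool)
    sp = config.road_spacing_cells
    if sp > 0:
        road[::sp, :] = True
        road[:, ::sp] = True

    # Quantile thresholds over non-road cells: ordered from wettest/greenest
    # to most built as the field increases.
    order = ["water", "canopy", "grass_shrub", "bare_soil", "other_paved", "building"]
    codes = {
        "water": LandClass.WATER,
        "canopy": LandClass.CANOPY,
        "grass_shrub": LandClass.GRASS_SHRUB,
        "bare_soil": LandClass.BARE_SOIL,
        "other_paved": LandClass.OTHER_PAVED,
        "building": LandClass.BUILDING,
    }
    fracs = np.array([config.class_fractions.get(k, 0.0) for k in order])
    cum = np.cumsum(fracs) / fracs.sum()
    offroad = fld[~road]
    cuts = np.quantile(offroad, cum[:-1])

    classes = np.full((rows, cols), int(LandClass.BUILDING), dtype=np.int16)
    bins = np.digitize(fld, cuts, right=True)
    for i, key in enumerate(order):
        classes[bins == i] = int(codes[key])
    # zero-fraction classes must not appear even at quantile boundaries
    for i, key in enumerate(order):
        if fracs[i] == 0:
            classes[classes == int(codes[key])] = int(LandClass.GRASS_SHRUB)
    classes[road] = int(LandClass.ROAD_RAIL)
    return RasterGrid(classes, config.transform)


# ---------------------------------------------------------------------------
# block groups


def _tessellate(config: ScenarioConfig) -> list:
    """Exact n-polygon rectangular tessellation of the extent (row bands
    split into varying column counts so the requested count is met exactly)."""
    xmin, ymin, xmax, ymax = config.extent
    n = config.n_blockgroups
    nrows = max(1, int(round(np.sqrt(n))))
    base, extra = divmod(n, nrows)
    per_row = [base + (1 if i < extra else 0) for i in range(nrows)]
    per_row = [c for c in per_row if c > 0]
    nrows = len(per_row)
    polys = []
    dy = (ymax - ymin) / nrows
    for i, ncol in enumerate(per_row):
        y0 = ymax - (i + 1) * dy
        dx = (xmax - xmin) / ncol
        for j in range(ncol):
            polys.append(rectangle(xmin + j * dx, y0, xmin + (j + 1) * dx, y0 + dy))
    return polys


def generate_blockgroups(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the block-group table: tessellated polygons, six correlated
    covariates (plus independent decoys), and garden presence sampled from
    the planted logistic model on standardized covariates.

    Returns a DataFrame with one row per block group, a shapely ``geometry``
    column, and the planted truth recorded in ``df.attrs["planted_beta"]``.
    """
    config.validate()
    rng = config.rng(stage=2)
    n = config.n_blockgroups
    k = len(COVARIATE_NAMES)
    corr = np.asarray(config.covariate_correlation, dtype=float)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((n, k)) @ chol.T

    data = {"blockgroup": [f"bg{i:05d}" for i in range(n)]}
    for j, name in enumerate(COVARIATE_NAMES):
        data[name] = config.covariate_means[name] + config.covariate_sds[name] * z[:, j]
    decoy_names = [f"decoy_{i + 1}" for i in range(config.n_decoys)]
    for name in decoy_names:
        data[name] = rng.standard_normal(n)

    beta = np.asarray(config.planted_beta, dtype=float)
    eta = beta[0] + z @ beta[1:]
    p = 1.0 / (1.0 + np.exp(-eta))
    data["garden_present"] = (rng.random(n) < p).astype(int)
    data["p_garden"] = p

    df = pd.DataFrame(data)
    df["geometry"] = _tessellate(config)
    df.attrs["planted_beta"] = {
        "intercept": beta[0],
        **{name: beta[j + 1] for j, name in enumerate(COVARIATE_NAMES)},
        **{name: 0.0 for name in decoy_names},
    }
    df.attrs["covariate_names"] = list(COVARIATE_NAMES) + decoy_names
    df.attrs["extent"] = config.extent
    df.attrs["seed"] = config.seed
    return df


# ---------------------------------------------------------------------------
# garden nodes


def place_gardens(blockgroups: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Place garden nodes inside the extent.

    Clustered mode draws a parent-offspring (Thomas-like) pattern: parents
    are sampled from block groups in proportion to their planted garden
    probability, offspring scatter around parents with Gaussian dispersion.
    Dispersed mode draws a hard-core pattern with a minimum pairwise spacing,
    weighting candidate block groups the same way.

    Returns a DataFrame with columns id, x, y, parent_blockgroup.
    """
    config.validate()
    rng = config.rng(stage=3)
    xmin, ymin, xmax, ymax = config.extent
    probs = blockgroups["p_garden"].to_numpy()
    weights = probs / probs.sum()
    centroids = np.array(
        [[g.centroid.x, g.centroid.y] for g in blockgroups["geometry"]]
    )

    pts = np.empty((config.n_gardens, 2))
    if config.garden_mode == "clustered":
        n_par = min(config.n_parents, len(blockgroups))
        parents = centroids[
            rng.choice(len(blockgroups), size=n_par, replace=False, p=weights)
        ]
        for i in range(config.n_gardens):
            par = parents[rng.integers(n_par)]
            for _ in range(1000):
                cand = par + rng.normal(scale=config.cluster_sigma_m, size=2)
                if xmin <= cand[0] < xmax and ymin <= cand[1] < ymax:
                    pts[i] = cand
                    break
            else:
                raise GenerationError("could not place clustered garden inside extent")
    else:
        placed = 0
        for _ in range(10000 * config.n_gardens):
            bg = rng.choice(len(blockgroups), p=weights)
            gxmin, gymin, gxmax, gymax = blockgroups["geometry"].iloc[bg].bounds
            cand = np.array(
                [rng.uniform(gxmin, gxmax), rng.uniform(gymin, gymax)]
            )
            if placed and (
                np.hypot(*(pts[:placed] - cand).T).min() < config.min_spacing_m
            ):
                continue
            pts[placed] = cand
            placed += 1
            if placed == config.n_gardens:
                break
        else:
            raise GenerationError(
                f"extent too small for {config.n_gardens} gardens at "
                f"{config.min_spacing_m} m minimum spacing"
            )

    row, col = config.transform.locate(
        pts[:, 0], pts[:, 1], config.grid_shape[0], config.grid_shape[1]
    )
    # parent block group by point-in-polygon
    parent = []
    tree = shapely.STRtree(list(blockgroups["geometry"]))
    for x, y in pts:
        hits = tree.query(shapely.Point(x, y), predicate="intersects")
        parent.append(blockgroups["blockgroup"].iloc[hits[0]] if len(hits) else "")
    return pd.DataFrame(
        {
            "id": [f"garden{i:04d}" for i in range(config.n_gardens)],
            "x": pts[:, 0],
            "y": pts[:, 1],
            "parent_blockgroup": parent,
        }
    )


# ---------------------------------------------------------------------------
# amenities


def generate_amenities(config: ScenarioConfig) -> list[AmenityLayer]:
    """Homogeneous Poisson point layers, one per configured amenity."""
    config.validate()
    xmin, ymin, xmax, ymax = config.extent
    area_km2 = (xmax - xmin) * (ymax - ymin) / 1e6
    layers = []
    for i, (name, rate) in enumerate(sorted(config.amenity_rates.items())):
        rng = config.rng(stage=100 + i)
        count = rng.poisson(rate * area_km2)
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, count), rng.uniform(ymin, ymax, count)]
        )
        layers.append(
            AmenityLayer(
                name=name,
                points=pts,
                buffer_m=float(config.amenity_buffers_m.get(name, 250.0)),
                reduction=config.amenity_reduction,
                target=config.amenity_targets.get(name, "social"),
            )
        )
    return layers
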
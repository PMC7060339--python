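"""Biophysical and social resistance landscapes.

The biophysical surface maps land-cover classes to movement resistance on a
1-180 scale (1 = tree canopy, most permeable; 180 = buildings, least).  The
social surface is built from block-group sociodemographics in four steps:

1. screen covariate pairs with Spearman |rho| above a cutoff (default 0.60),
   dropping the member with the weaker univariate association with garden
   presence;
2. fit binary logistic regressions of garden presence on standardized
   covariates and enumerate every covariate subset (an all-subsets "dredge"),
   scoring each by AIC and Akaike weight;
3. model-average within the smallest set of top models whose weights sum to
   a cutoff (default 0.97), yielding per-variable importance weights and
   averaged standardized coefficients;
4. split each selected variable into tertiles (three equal-count groups) and
   score them 10/20/30, directed by the coefficient sign, so that with six
   selected variables the per-block-group sum spans 60-180, comparable to
   the biophysical scale.

Amenity layers (schools, parks, conservation lands, ...) reduce resistance
by a fixed fraction (default 10%) inside their buffers; overlapping buffers
stack multiplicatively and resistance is floored at 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateInputError,
    SchemaError,
)
from .grid import GridTransform, RasterGrid
from .scenario import AmenityLayer, LandClass

RESISTANCE_MIN = 1.0
RESISTANCE_MAX = 180.0

# Per-class biophysical resistance.  The scale's endpoints (canopy 1,
# building 180) anchor the range; intermediate classes are graded by
# permeability to mobile service providers.  Water is removed from the
# circuit (None -> nodata) rather than scored.  Fully configurable.
DEFAULT_BIOPHYSICAL_RESISTANCE: dict[int, float | None] = {
    int(LandClass.CANOPY): 1.0,
    int(LandClass.GRASS_SHRUB): 5.0,
    int(LandClass.BARE_SOIL): 20.0,
    int(LandClass.WATER): None,
    int(LandClass.OTHER_PAVED): 120.0,
    int(LandClass.ROAD_RAIL): 150.0,
    int(LandClass.BUILDING): 180.0,
}

TERTILE_SCORES = (10.0, 20.0, 30.0)


class ResistanceSurface(RasterGrid):
    """A positive per-cell resistance grid with nodata mask.

    ``provenance`` records which landscape the surface describes
    ("biophysical" or "social"); ``pad`` counts boundary-extension cells on
    each side, which downstream statistics must exclude.
    """

    def __init__(self, values, transform, mask=None, provenance="biophysical", pad=0):
        super().__init__(np.asarray(values, dtype=float), transform, mask)
        self.provenance = provenance
        self.pad = int(pad)
        v = self.values[self.mask]
        if v.size and (not np.all(np.isfinite(v)) or v.min() < RESISTANCE_MIN):
            raise SchemaError("resistance values must be finite and >= 1")

    def core_mask(self) -> np.ndarray:
        """Validity mask with boundary-extension padding excluded."""
        m = self.mask.copy()
        if self.pad:
            inner = np.zeros_like(m)
            inner[self.pad : -self.pad, self.pad : -self.pad] = True
            m &= inner
        return m


# ---------------------------------------------------------------------------
# biophysical surface


def base_from_landcover(
    raster: RasterGrid, mapping: dict[int, float | None] | None = None
) -> ResistanceSurface:
    """Look up per-cell resistance from the land-cover class mapping.

    Classes mapped to ``None`` (water by default) become nodata and are
    excluded from the circuit graph.  Mapped values must lie in [1, 180].
    """
    if mapping is None:
        mapping = DEFAULT_BIOPHYSICAL_RESISTANCE
    classes = raster.values.astype(int)
    present = set(np.unique(classes[raster.mask]).tolist())
    missing = present - set(mapping)
    if missing:
        raise SchemaError(f"land-cover classes without resistance mapping: {sorted(missing)}")
    for code, val in mapping.items():
        if val is not None and not (RESISTANCE_MIN <= val <= RESISTANCE_MAX):
            raise ConfigurationError(
                f"resistance for class {code} is {val}, outside "
                f"[{RESISTANCE_MIN:g}, {RESISTANCE_MAX:g}]"
            )
    values = np.full(classes.shape, RESISTANCE_MIN, dtype=float)
    mask = raster.mask.copy()
    for code, val in mapping.items():
        sel = classes == code
        if val is None:
            mask[sel] = False
        else:
            values[sel] = val
    return ResistanceSurface(values, raster.transform, mask, provenance="biophysical")


def apply_reductions(
    surface: ResistanceSurface, layers: list[AmenityLayer]
) -> ResistanceSurface:
    """Reduce resistance inside amenity buffers.

    Each covering layer multiplies the cell by (1 - reduction); overlapping
    layers stack multiplicatively (order-independent).  The result is floored
    at 1 so the surface stays on the 1-180 scale.
    """
    factor = np.ones(surface.shape)
    xs, ys = surface.cell_centers()
    for layer in layers:
        if not 0 < layer.reduction < 1:
            raise ConfigurationError(
                f"reduction for layer {layer.name!r} must be in (0, 1)"
            )
        union = layer.buffer_union()
        if union.is_empty:
            continue
        covered = shapely.contains_xy(union, xs.ravel(), ys.ravel()).reshape(surface.shape)
        factor[covered] *= 1.0 - layer.reduction
    values = np.maximum(surface.values * factor, RESISTANCE_MIN)
    return ResistanceSurface(
        values, surface.transform, surface.mask.copy(), surface.provenance, surface.pad
    )


def extend_boundary(surface: ResistanceSurface, distance: float) -> ResistanceSurface:
    """Pad the grid outward by ``distance`` metres of edge-replicated
    resistance (an edge-effect buffer around the city boundary).  Padded
    cells are flagged via ``surface.pad`` so statistics can exclude them."""
    if distance < 0:
        raise ConfigurationError("boundary distance must be >= 0")
    pad = int(np.ceil(distance / surface.transform.cell))
    if pad == 0:
        return surface
    values = np.pad(surface.values, pad, mode="edge")
    mask = np.pad(surface.mask, pad, mode="edge")
    t = surface.transform
    transform = GridTransform(t.xll - pad * t.cell, t.yll - pad * t.cell, t.cell)
    return ResistanceSurface(
        values, transform, mask, surface.provenance, surface.pad + pad
    )


# ---------------------------------------------------------------------------
# collinearity screening


@dataclass
class ScreeningReport:
    """Outcome of pairwise Spearman screening."""

    pairs: pd.DataFrame  # columns var_a, var_b, rho
    dropped: list[str]
    retained: list[str]
    threshold: float


def screen_collinear(
    table: pd.DataFrame,
    variables: list[str],
    threshold: float = 0.60,
    outcome: str = "garden_present",
) -> ScreeningReport:
    """Drop one member of every covariate pair with Spearman |rho| above the
    threshold.

    The dropped member is the one with the weaker univariate (Spearman)
    association with the outcome; ties break lexicographically.  Constant
    covariates have undefined rank correlation and are dropped with a
    warning.  The retained set has no remaining pair above the threshold.
    """
    if len(variables) < 2:
        raise ConfigurationError("screening needs at least two variables")
    if len(table) < 3:
        raise ConfigurationError("screening needs at least three block groups")
    dropped: list[str] = []
    work = list(variables)
    for v in variables:
        if table[v].nunique() <= 1:
            warnings.warn(f"covariate {v!r} is constant; dropped from screening")
            dropped.append(v)
            work.remove(v)

    strength = {
        v: abs(stats.spearmanr(table[v], table[outcome]).statistic) for v in work
    }
    rows = []
    for a, b in itertools.combinations(work, 2):
        rho = stats.spearmanr(table[a], table[b]).statistic
        rows.append((a, b, rho))
    pairs = pd.DataFrame(rows, columns=["var_a", "var_b", "rho"])

    flagged = pairs[pairs["rho"].abs() > threshold].sort_values(
        "rho", key=abs, ascending=False
    )
    for _, row in flagged.iterrows():
        a, b = row["var_a"], row["var_b"]
        if a in dropped or b in dropped:
            continue
        sa, sb = strength[a], strength[b]
        if sa < sb:
            loser = a
        elif sb < sa:
            loser = b
        else:
            loser = max(a, b)  # lexicographic tie-break: later name loses
        dropped.append(loser)
    retained = [v for v in variables if v not in dropped]
    return ScreeningReport(pairs, dropped, retained, threshold)


# ---------------------------------------------------------------------------
# logistic fits and all-subsets model selection


@dataclass
class FittedLogistic:
    """A maximum-likelihood logistic fit on standardized covariates."""

    variables: tuple[str, ...]
    params: pd.Series  # intercept ("const") + standardized coefficients
    loglik: float
    aic: float
    n: int


def _standardize(table: pd.DataFrame, variables: list[str]) -> np.ndarray:
    x = table[list(variables)].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise DegenerateInputError(f"constant covariates cannot be standardized: {bad}")
    return (x - x.mean(axis=0)) / sd


def fit_logistic(
    table: pd.DataFrame,
    variables: list[str],
    outcome: str = "garden_present",
) -> FittedLogistic:
    """Fit garden presence on z-scored covariates by maximum likelihood.

    Raises ConvergenceError on complete separation instead of returning a
    silently divergent fit, and DegenerateInputError when the outcome has a
    single class.
    """
    y = table[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome must contain both presences and absences")
    if variables:
        x = sm.add_constant(_standardize(table, list(variables)), has_constant="add")
    else:
        x = np.ones((len(y), 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError or overflow
        raise ConvergenceError(f"logistic fit failed for {tuple(variables)}: {exc}") from exc
    if not res.mle_retvals.get("converged", True) or not np.all(np.isfinite(res.params)):
        raise ConvergenceError(f"logistic fit did not converge for {tuple(variables)}")
    names = ["const"] + list(variables)
    params = pd.Series(res.params, index=names)
    k = len(names)
    return FittedLogistic(
        variables=tuple(variables),
        params=params,
        loglik=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        n=len(y),
    )


@dataclass
class ModelSet:
    """All-subsets logistic models ranked by AIC with Akaike weights.

    ``models`` has one row per subset: variables (tuple), k, loglik, aic,
    delta_aic, weight; sorted by weight descending.  Weights sum to 1.
    """

    models: pd.DataFrame
    variables: list[str]
    table: pd.DataFrame = field(repr=False)
    fits: dict = field(repr=False, default_factory=dict)


def akaike_weights(aic: np.ndarray) -> np.ndarray:
    """exp(-delta/2) normalized over the candidate set."""
    delta = np.asarray(aic, dtype=float) - np.min(aic)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def enumerate_models(
    table: pd.DataFrame,
    variables: list[str],
    outcome: str = "garden_present",
    max_variables: int = 16,
) -> ModelSet:
    """Fit every covariate subset (including intercept-only): the all-subsets
    'dredge'.  Bounded at ``max_variables`` candidates (2^k fits)."""
    if len(variables) > max_variables:
        raise ConfigurationError(
            f"{len(variables)} candidate variables exceed the 2^k enumeration "
            f"bound of {max_variables}; screen for collinearity first"
        )
    rows = []
    fits = {}
    for r in range(len(variables) + 1):
        for subset in itertools.combinations(variables, r):
            fit = fit_logistic(table, list(subset), outcome=outcome)
            fits[subset] = fit
            rows.append(
                {
                    "variables": subset,
                    "k": len(subset) + 1,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                }
            )
    models = pd.DataFrame(rows)
    models["delta_aic"] = models["aic"] - models["aic"].min()
    models["weight"] = akaike_weights(models["aic"].to_numpy())
    models = models.sort_values(
        ["weight", "k"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ModelSet(models=models, variables=list(variables), table=table, fits=fits)


# ---------------------------------------------------------------------------
# model averaging and the variable scorecard


@dataclass
class VariableScorecard:
    """Per-variable importance, averaged coefficient, sign, and tertile
    breakpoints driving the social resistance scoring."""

    table: pd.DataFrame  # index: variable; columns: importance, coefficient,
    #                      sign, tertile_low, tertile_high
    cumulative_weight_cutoff: float
    confidence_set_size: int

    def importance(self, variable: str) -> float:
        return float(self.table.loc[variable, "importance"])


def build_scorecard(
    model_set: ModelSet, cutoff: float = 0.97
) -> VariableScorecard:
    """Model-average within the confidence set of top-weighted models.

    The confidence set is the smallest weight-ordered prefix with cumulative
    Akaike weight >= ``cutoff``; weights are renormalized within it.
    Importance(v) is the renormalized weight-sum of set members containing v;
    the averaged standardized coefficient is the weight-average over those
    members.  Tertile breakpoints (1/3 and 2/3 empirical quantiles) come from
    each variable's block-group distribution.
    """
    models = model_set.models
    if models.empty:
        raise DegenerateInputError("empty model set")
    cum = models["weight"].cumsum()
    n_set = int(np.searchsorted(cum.to_numpy(), cutoff - 1e-12) + 1)
    n_set = min(n_set, len(models))
    subset = models.iloc[:n_set]
    w = subset["weight"].to_numpy()
    w = w / w.sum()

    rows = {}
    for v in model_set.variables:
        contains = np.array([v in vs for vs in subset["variables"]])
        importance = float(w[contains].sum())
        if contains.any():
            coefs = np.array(
                [
                    model_set.fits[vs].params[v]
                    for vs in subset["variables"][contains]
                ]
            )
            coefficient = float(np.sum(w[contains] * coefs) / w[contains].sum())
        else:
            coefficient = 0.0
        vals = model_set.table[v].to_numpy(dtype=float)
        q1, q2 = np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0])
        rows[v] = {
            "importance": importance,
            "coefficient": coefficient,
            "sign": "+" if coefficient >= 0 else "-",
            "tertile_low": q1,
            "tertile_high": q2,
        }
    return VariableScorecard(
        table=pd.DataFrame(rows).T,
        cumulative_weight_cutoff=cutoff,
        confidence_set_size=n_set,
    )


def select_variables(
    scorecard: VariableScorecard, threshold: float = 1.0
) -> list[str]:
    """Variables whose importance reaches the threshold (default: only those
    present in every confidence-set model, importance 1.00)."""
    if not 0 < threshold <= 1:
        raise ConfigurationError("importance threshold must be in (0, 1]")
    imp = scorecard.table["importance"].astype(float)
    chosen = [v for v in scorecard.table.index if imp[v] >= threshold - 1e-9]
    if not chosen:
        warnings.warn(f"no variable reaches importance {threshold}; empty selection")
    return chosen


def tertile_scores(
    table: pd.DataFrame,
    scorecard: VariableScorecard,
    variable: str,
    invert_direction: bool = False,
) -> np.ndarray:
    """Score each block group 10/20/30 by the variable's tertile.

    A positive averaged coefficient means the variable favours garden
    presence, so its top tertile gets the lowest resistance (10) and the
    bottom tertile the highest (30); a negative coefficient reverses the
    order.  Ties exactly at a breakpoint fall in the lower-valued group.
    ``invert_direction`` flips the convention.
    """
    if variable not in scorecard.table.index:
        raise KeyError(f"variable {variable!r} not in scorecard")
    row = scorecard.table.loc[variable]
    q1, q2 = float(row["tertile_low"]), float(row["tertile_high"])
    if q1 == q2:
        raise DegenerateInputError(
            f"variable {variable!r} cannot be split into tertiles (constant?)"
        )
    vals = table[variable].to_numpy(dtype=float)
    tert = np.where(vals <= q1, 0, np.where(vals <= q2, 1, 2))
    positive = row["sign"] == "+"
    if invert_direction:
        positive = not positive
    lo, mid, hi = TERTILE_SCORES
    ladder = (hi, mid, lo) if positive else (lo, mid, hi)
    return np.asarray(ladder)[tert]


def social_surface(
    table: pd.DataFrame,
    scorecard: VariableScorecard,
    transform: GridTransform,
    shape: tuple[int, int],
    variables: list[str] | None = None,
    layers: list[AmenityLayer] | None = None,
    rescale_to_full_range: bool = False,
    invert_direction: bool = False,
) -> ResistanceSurface:
    """Rasterize the summed tertile scores of the selected variables.

    With m selected variables the per-block-group base sum spans
    [10m, 30m] (six variables: 60-180, sharing the biophysical ceiling).
    ``rescale_to_full_range`` optionally maps that span linearly onto
    [1, 180]; off by default.  Amenity reductions are then applied.  Cells
    outside every block group become nodata.
    """
    if variables is None:
        variables = select_variables(scorecard)
    if not variables:
        raise DegenerateInputError("no selected variables for the social surface")
    base = np.zeros(len(table))
    for v in variables:
        base += tertile_scores(table, scorecard, v, invert_direction=invert_direction)
    if rescale_to_full_range:
        m = len(variables)
        lo, hi = TERTILE_SCORES[0] * m, TERTILE_SCORES[-1] * m
        base = RESISTANCE_MIN + (base - lo) * (RESISTANCE_MAX - RESISTANCE_MIN) / (hi - lo)

    nrows, ncols = shape
    grid = RasterGrid(np.zeros(shape), transform)
    xs, ys = grid.cell_centers()
    pts = shapely.points(np.column_stack([xs.ravel(), ys.ravel()]))
    tree = shapely.STRtree(list(table["geometry"]))
    pt_idx, poly_idx = tree.query(pts, predicate="intersects")
    values = np.full(nrows * ncols, np.nan)
    # first hit wins where a center sits exactly on a shared edge
    order = np.argsort(pt_idx, kind="mergesort")
    seen = np.zeros(nrows * ncols, dtype=bool)
    for pi, gi in zip(pt_idx[order], poly_idx[order]):
        if not seen[pi]:
            values[pi] = base[gi]
            seen[pi] = True
    mask = seen.reshape(shape)
    values = np.where(seen, values, RESISTANCE_MIN).reshape(shape)
    surface = ResistanceSurface(values, transform, mask, provenance="social")
    if layers:
        social_layers = [l for l in layers if l.target == "social"]
        surface = apply_reductions(surface, social_layers)
    return surface
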
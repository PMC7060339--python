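"""Comparing biophysical and social connectivity layers.

Current-density maps from the two resistance landscapes are compared on a
common random-point sample: each layer is min-max normalized to [0, 1] over
the sampled values, the two are summed into a combined socio-ecological
score on [0, 2] (square-root transformed for its zero-inflated
distribution), and summarised as median +/- SD per layer.  Cells where both
layers independently exceed their mean + 1 SD mark high-high overlap, and
the slope of log(normalized biophysical) on log(normalized social) against
the m = 1 null line describes which layer dominates.  The slope is
descriptive — no linear relationship between the layers is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .errors import ConfigurationError, DegenerateInputError
from .grid import RasterGrid


@dataclass
class SamplePoints:
    """Random points with current values extracted from both layers."""

    x: np.ndarray
    y: np.ndarray
    biophysical_current: np.ndarray
    social_current: np.ndarray
    valid: np.ndarray  # False where either layer is nodata at the point

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "biophysical_current": self.biophysical_current,
                "social_current": self.social_current,
                "valid": self.valid,
            }
        )


def sample_points(
    boundary, bio_map: RasterGrid, soc_map: RasterGrid, n: int, seed: int
) -> SamplePoints:
    """Draw ``n`` uniform random points inside the boundary polygon and
    extract both layers.  Points landing on nodata in either layer are kept
    but flagged invalid (so the dropped count is reportable)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if boundary.is_empty or boundary.area <= 0:
        raise ConfigurationError("empty sampling boundary")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = boundary.bounds
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    while got < n:
        m = max(2 * (n - got), 100)
        cx = rng.uniform(xmin, xmax, m)
        cy = rng.uniform(ymin, ymax, m)
        inside = shapely.contains_xy(boundary, cx, cy)
        take = min(int(inside.sum()), n - got)
        xs[got : got + take] = cx[inside][:take]
        ys[got : got + take] = cy[inside][:take]
        got += take
    bio, bio_ok = bio_map.sample(xs, ys)
    soc, soc_ok = soc_map.sample(xs, ys)
    return SamplePoints(xs, ys, bio, soc, bio_ok & soc_ok)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    lo, hi = np.min(values), np.max(values)
    if hi == lo:
        raise DegenerateInputError("constant layer: min-max normalization undefined")
    return (values - lo) / (hi - lo)


@dataclass
class ConnectivityProfile:
    """Normalized, combined and transformed connectivity at sample points,
    with the summary statistics and the log-log directionality fit."""

    normalized_bio: np.ndarray
    normalized_soc: np.ndarray
    combined: np.ndarray
    sqrt_combined: np.ndarray
    summary: pd.DataFrame
    n_dropped_invalid: int
    slope: float = np.nan
    intercept: float = np.nan
    n_dropped_zero: int = 0

    def summary_row(self) -> dict:
        s = self.summary
        return {
            "median_social": s.loc["social", "median"],
            "median_biophysical": s.loc["biophysical", "median"],
            "median_total": s.loc["combined", "median"],
            "maximum_total": s.loc["combined", "max"],
        }


def normalize_and_combine(points: SamplePoints) -> ConnectivityProfile:
    """Min-max normalize each layer over valid sampled values, sum them into
    the combined [0, 2] score, square-root transform, and tabulate
    median +/- SD per layer and combined."""
    valid = points.valid
    if valid.sum() < 2:
        raise DegenerateInputError("need at least 2 valid sample points")
    bio = minmax_normalize(points.biophysical_current[valid])
    soc = minmax_normalize(points.social_current[valid])
    combined = bio + soc
    sqrtc = np.sqrt(combined)
    summary = pd.DataFrame(
        {
            "median": [np.median(soc), np.median(bio), np.median(combined),
                       np.median(sqrtc)],
            "sd": [np.std(soc, ddof=1), np.std(bio, ddof=1),
                   np.std(combined, ddof=1), np.std(sqrtc, ddof=1)],
            "max": [np.max(soc), np.max(bio), np.max(combined), np.max(sqrtc)],
        },
        index=["social", "biophysical", "combined", "sqrt_combined"],
    )
    return ConnectivityProfile(
        normalized_bio=bio,
        normalized_soc=soc,
        combined=combined,
        sqrt_combined=sqrtc,
        summary=summary,
        n_dropped_invalid=int((~valid).sum()),
    )


def high_overlap_mask(bio_map: RasterGrid, soc_map: RasterGrid):
    """Cells where each layer independently exceeds its own mean + 1 SD.

    Returns (mask RasterGrid, fraction of valid cells in the overlap)."""
    if bio_map.shape != soc_map.shape:
        raise ConfigurationError("maps are not aligned")
    valid = bio_map.mask & soc_map.mask
    bv = bio_map.values[valid]
    sv = soc_map.values[valid]
    if bv.std() == 0 or sv.std() == 0:
        raise DegenerateInputError("zero-variance map: overlap threshold undefined")
    mask = np.zeros(bio_map.shape, dtype=bool)
    mask[valid] = (bv > bv.mean() + bv.std()) & (sv > sv.mean() + sv.std())
    fraction = float(mask[valid].mean())
    return RasterGrid(mask.astype(float), bio_map.transform, valid), fraction


def directionality_slope(
    profile: ConnectivityProfile, swap_axes: bool = False, min_points: int = 10
) -> ConnectivityProfile:
    """Least-squares slope of log normalized biophysical on log normalized
    social connectivity (points with a zero in either layer are dropped and
    counted).  Slope > 1 means biophysical connectivity dominates; < 1, the
    social layer.  Descriptive only."""
    pos = (profile.normalized_bio > 0) & (profile.normalized_soc > 0)
    if pos.sum() < min_points:
        raise DegenerateInputError(
            f"only {int(pos.sum())} strictly positive pairs; need {min_points}"
        )
    yv = np.log(profile.normalized_bio[pos])
    xv = np.log(profile.normalized_soc[pos])
    if swap_axes:
        xv, yv = yv, xv
    slope, intercept = np.polyfit(xv, yv, 1)
    profile.slope = float(slope)
    profile.intercept = float(intercept)
    profile.n_dropped_zero = int((~pos).sum())
    return profile
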
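"""End-to-end orchestration: scenario -> resistance -> current flow ->
connectivity statistics -> hotspots, as a configured, logged, reproducible
run.

Every stage writes its outputs to files (text rasters, GeoJSON, CSV) so any
stage can be rerun or inspected in isolation, and a run manifest records the
config snapshot, seeds, parameter values and SHA-256 digests of every output
— two runs from the same config produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import __version__
from .circuit import SolverSettings, build_lattice, cumulative_current
from .connectivity import (
    directionality_slope,
    high_overlap_mask,
    normalize_and_combine,
    sample_points,
)
from .errors import ConfigurationError, GardenflowError
from .grid import write_ascii_grid, write_geojson
from .hotspots import classify, fishnet_counts, gi_star, idw_surface
from .resistance import (
    DEFAULT_BIOPHYSICAL_RESISTANCE,
    RESISTANCE_MAX,
    RESISTANCE_MIN,
    apply_reductions,
    base_from_landcover,
    build_scorecard,
    enumerate_models,
    extend_boundary,
    screen_collinear,
    select_variables,
    social_surface,
)
from .scenario import (
    COVARIATE_NAMES,
    LandClass,
    ScenarioConfig,
    generate_amenities,
    generate_blockgroups,
    generate_landcover,
    place_gardens,
)

_CLASS_BY_NAME = {c.name.lower(): int(c) for c in LandClass}


@dataclass
class AnalysisConfig:
    """Parameters of the analysis stages (defaults mirror the method:
    10% buffer reductions, rho 0.60 screening, sum-omega 0.97 averaging,
    importance-1.0 selection, 1 km edge buffer, 500 m fishnet and band)."""

    boundary_buffer_m: float = 1000.0
    resistance_mapping: dict = field(
        default_factory=lambda: dict(DEFAULT_BIOPHYSICAL_RESISTANCE)
    )
    spearman_threshold: float = 0.60
    weight_cutoff: float = 0.97
    importance_threshold: float = 1.0
    rescale_social: bool = False
    neighbourhood: int = 4
    tolerance: float = 1e-6
    max_pairs: int = 500
    n_sample_points: int = 50_000
    fishnet_cell_m: float = 500.0
    band_m: float = 500.0
    idw_power: float = 2.0
    hotspot_threshold: float = 1.0

    def validate(self) -> list[str]:
        issues = []
        if self.boundary_buffer_m < 0:
            issues.append("boundary_buffer_m must be >= 0")
        for code, val in self.resistance_mapping.items():
            if val is not None and not RESISTANCE_MIN <= val <= RESISTANCE_MAX:
                issues.append(
                    f"resistance for class {code} is {val}, outside "
                    f"[{RESISTANCE_MIN:g}, {RESISTANCE_MAX:g}]"
                )
        if not 0 < self.spearman_threshold <= 1:
            issues.append("spearman_threshold must be in (0, 1]")
        if not 0 < self.weight_cutoff <= 1:
            issues.append("weight_cutoff must be in (0, 1]")
        if not 0 < self.importance_threshold <= 1:
            issues.append("importance_threshold must be in (0, 1]")
        if self.neighbourhood not in (4, 8):
            issues.append("neighbourhood must be 4 or 8")
        if self.tolerance <= 0:
            issues.append("tolerance must be > 0")
        if self.n_sample_points < 1:
            issues.append("n_sample_points must be >= 1")
        if self.fishnet_cell_m <= 0:
            issues.append("fishnet_cell_m must be > 0")
        if self.band_m <= 0:
            issues.append("band_m must be > 0")
        if self.idw_power <= 0:
            issues.append("idw_power must be > 0")
        return issues


def _scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    if "grid_shape" in d:
        d["grid_shape"] = tuple(d["grid_shape"])
    if "covariate_correlation" in d:
        d["covariate_correlation"] = np.asarray(d["covariate_correlation"], dtype=float)
    if "planted_beta" in d:
        d["planted_beta"] = tuple(float(b) for b in d["planted_beta"])
    return ScenarioConfig(**d)


def _analysis_from_dict(d: dict) -> AnalysisConfig:
    d = dict(d)
    if "resistance_mapping" in d:
        mapping = {}
        for key, val in d["resistance_mapping"].items():
            code = _CLASS_BY_NAME[key.lower()] if isinstance(key, str) else int(key)
            mapping[code] = None if val is None else float(val)
        d["resistance_mapping"] = mapping
    return AnalysisConfig(**d)


def load_config(path: str | Path) -> tuple[ScenarioConfig, AnalysisConfig]:
    """Parse a YAML config file with optional ``scenario:`` and
    ``analysis:`` sections into validated config objects."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    try:
        scenario = _scenario_from_dict(doc.get("scenario", {}))
        analysis = _analysis_from_dict(doc.get("analysis", {}))
    except TypeError as exc:
        raise ConfigurationError(f"unknown config key: {exc}") from exc
    return scenario, analysis


def validate_config(path: str | Path) -> list[str]:
    """Range/consistency checks; returns a human-readable issue list
    (empty when the config is valid)."""
    try:
        scenario, analysis = load_config(path)
    except (ConfigurationError, yaml.YAMLError) as exc:
        return [str(exc)]
    issues = analysis.validate()
    try:
        scenario.validate()
    except ConfigurationError as exc:
        issues.insert(0, str(exc))
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, parameters actually used,
    output digests, and skip/drop counts."""

    config: dict
    seed: int
    version: str
    parameters: dict
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _config_snapshot(scenario: ScenarioConfig, analysis: AnalysisConfig) -> dict:
    snap = dataclasses.asdict(scenario)
    snap["covariate_correlation"] = np.asarray(
        snap["covariate_correlation"]
    ).tolist()
    snap["planted_beta"] = list(snap["planted_beta"])
    snap["grid_shape"] = list(snap["grid_shape"])
    return {"scenario": snap, "analysis": dataclasses.asdict(analysis)}


def run_scenario(
    scenario: ScenarioConfig,
    analysis: AnalysisConfig,
    outdir: str | Path,
) -> RunManifest:
    """Execute the full pipeline and write every stage output under
    ``outdir``.  Returns the run manifest (also written as manifest.json)."""
    scenario.validate()
    issues = analysis.validate()
    if issues:
        raise ConfigurationError("; ".join(issues))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=_config_snapshot(scenario, analysis),
        seed=scenario.seed,
        version=__version__,
        parameters={
            "amenity_reduction": scenario.amenity_reduction,
            "spearman_threshold": analysis.spearman_threshold,
            "weight_cutoff": analysis.weight_cutoff,
            "importance_threshold": analysis.importance_threshold,
            "tertile_scores": [10, 20, 30],
            "boundary_buffer_m": analysis.boundary_buffer_m,
            "band_m": analysis.band_m,
            "fishnet_cell_m": analysis.fishnet_cell_m,
            "neighbourhood": analysis.neighbourhood,
            "max_pairs": analysis.max_pairs,
        },
    )

    def record(name: str, path: Path) -> None:
        manifest.outputs[name] = _sha256(path)

    # --- stage 1: synthetic scenario ------------------------------------
    landcover = generate_landcover(scenario)
    blockgroups = generate_blockgroups(scenario)
    gardens = place_gardens(blockgroups, scenario)
    amenities = generate_amenities(scenario)

    write_ascii_grid(landcover, outdir / "landcover.asc", fmt="%d")
    record("landcover", outdir / "landcover.asc")
    covar_cols = [c for c in blockgroups.columns if c != "geometry"]
    blockgroups[covar_cols].to_csv(outdir / "blockgroups.csv", index=False)
    record("blockgroups_csv", outdir / "blockgroups.csv")
    write_geojson(
        blockgroups["geometry"],
        outdir / "blockgroups.geojson",
        blockgroups[covar_cols].to_dict("records"),
    )
    record("blockgroups_geojson", outdir / "blockgroups.geojson")
    gardens.to_csv(outdir / "gardens.csv", index=False)
    record("gardens_csv", outdir / "gardens.csv")
    write_geojson(
        [shapely.Point(x, y) for x, y in zip(gardens["x"], gardens["y"])],
        outdir / "gardens.geojson",
        gardens.to_dict("records"),
    )
    record("gardens_geojson", outdir / "gardens.geojson")
    amen_geoms, amen_props = [], []
    for layer in amenities:
        for x, y in layer.points:
            amen_geoms.append(shapely.Point(x, y))
            amen_props.append(
                {"layer": layer.name, "buffer_m": layer.buffer_m,
                 "reduction": layer.reduction, "target": layer.target}
            )
    write_geojson(amen_geoms, outdir / "amenities.geojson", amen_props)
    record("amenities", outdir / "amenities.geojson")

    # --- stage 2: biophysical resistance --------------------------------
    bio = base_from_landcover(landcover, analysis.resistance_mapping)
    bio = apply_reductions(bio, [l for l in amenities if l.target == "biophysical"])
    bio = extend_boundary(bio, analysis.boundary_buffer_m)
    write_ascii_grid(bio, outdir / "resistance_biophysical.asc")
    record("resistance_biophysical", outdir / "resistance_biophysical.asc")

    # --- stage 3: social resistance -------------------------------------
    candidates = list(blockgroups.attrs["covariate_names"])
    report = screen_collinear(blockgroups, candidates, analysis.spearman_threshold)
    model_set = enumerate_models(blockgroups, report.retained)
    scorecard = build_scorecard(model_set, analysis.weight_cutoff)
    selected = select_variables(scorecard, analysis.importance_threshold)
    # Small samples can leave no variable in every confidence-set model; the
    # best-AIC model's variables are the principled fallback (recorded).
    selection_fallback = False
    if not selected:
        selected = list(model_set.models.iloc[0]["variables"])
        selection_fallback = True
    if not selected:
        raise GardenflowError(
            "best model is intercept-only; social surface cannot be built"
        )
    manifest.counts["selection_fallback_best_model"] = selection_fallback
    soc = social_surface(
        blockgroups,
        scorecard,
        scenario.transform,
        scenario.grid_shape,
        variables=selected,
        layers=amenities,
        rescale_to_full_range=analysis.rescale_social,
    )
    soc = extend_boundary(soc, analysis.boundary_buffer_m)
    write_ascii_grid(soc, outdir / "resistance_social.asc")
    record("resistance_social", outdir / "resistance_social.asc")
    scorecard.table.rename_axis("variable").to_csv(outdir / "scorecard.csv")
    record("scorecard", outdir / "scorecard.csv")
    models_out = model_set.models.copy()
    models_out["variables"] = models_out["variables"].map(lambda v: "+".join(v) or "(intercept)")
    models_out.to_csv(outdir / "models.csv", index=False)
    record("models", outdir / "models.csv")
    manifest.counts["screened_out"] = report.dropped
    manifest.counts["selected_variables"] = selected
    manifest.counts["confidence_set_size"] = scorecard.confidence_set_size

    # --- stage 4: circuit flow on both surfaces -------------------------
    settings = SolverSettings(
        neighbourhood=analysis.neighbourhood,
        tolerance=analysis.tolerance,
        max_pairs=analysis.max_pairs,
        seed=scenario.seed,
    )
    maps = {}
    for name, surf in (("biophysical", bio), ("social", soc)):
        graph = build_lattice(surf, settings)
        cd = cumulative_current(graph, gardens, settings)
        maps[name] = cd
        write_ascii_grid(cd, outdir / f"current_{name}.asc")
        record(f"current_{name}", outdir / f"current_{name}.asc")
        cd.pair_log.to_csv(outdir / f"pairs_{name}.csv", index=False)
        record(f"pairs_{name}", outdir / f"pairs_{name}.csv")
        manifest.counts[f"n_pairs_{name}"] = cd.n_pairs
        manifest.counts[f"skipped_pairs_{name}"] = len(cd.skipped_pairs)

    # --- stage 5: connectivity statistics -------------------------------
    pts = sample_points(
        scenario.boundary,
        maps["biophysical"],
        maps["social"],
        analysis.n_sample_points,
        seed=scenario.seed,
    )
    profile = normalize_and_combine(pts)
    profile = directionality_slope(profile)
    pts.to_frame().to_csv(outdir / "sample_points.csv", index=False)
    record("sample_points", outdir / "sample_points.csv")
    profile.summary.rename_axis("layer").to_csv(outdir / "summary.csv")
    record("summary", outdir / "summary.csv")
    overlap, overlap_fraction = high_overlap_mask(maps["biophysical"], maps["social"])
    write_ascii_grid(overlap, outdir / "overlap_mask.asc", fmt="%d")
    record("overlap_mask", outdir / "overlap_mask.asc")
    density = pd.DataFrame({"sqrt_combined": profile.sqrt_combined})
    density.to_csv(outdir / "density_data.csv", index=False)
    record("density_data", outdir / "density_data.csv")
    manifest.counts["n_points_invalid"] = profile.n_dropped_invalid
    manifest.counts["n_points_zero_dropped"] = profile.n_dropped_zero
    manifest.counts["slope"] = profile.slope
    manifest.counts["intercept"] = profile.intercept
    manifest.counts["slope_vs_null"] = (
        "biophysical-dominant" if profile.slope > 1 else "social-dominant"
    )
    manifest.counts["overlap_fraction"] = overlap_fraction
    manifest.counts["summary"] = {
        k: float(v) for k, v in profile.summary_row().items()
    }

    # --- stage 6: hotspots ----------------------------------------------
    grid = fishnet_counts(gardens, scenario.extent, analysis.fishnet_cell_m)
    grid = gi_star(grid, analysis.band_m)
    grid = classify(grid, analysis.hotspot_threshold)
    grid.cells.to_csv(outdir / "fishnet.csv", index=False)
    record("fishnet_csv", outdir / "fishnet.csv")
    write_geojson(
        grid.polygons(), outdir / "fishnet.geojson", grid.cells.to_dict("records")
    )
    record("fishnet_geojson", outdir / "fishnet.geojson")
    idw = idw_surface(grid, scenario.transform, scenario.grid_shape, analysis.idw_power)
    write_ascii_grid(idw, outdir / "hotspot_idw.asc")
    record("hotspot_idw", outdir / "hotspot_idw.asc")
    manifest.counts["n_hot_cells"] = int((grid.cells["hotspot_class"] == "hot").sum())
    manifest.counts["n_cold_cells"] = int((grid.cells["hotspot_class"] == "cold").sum())

    manifest.write(outdir / "manifest.json")
    return manifest


def run_from_config(config_path: str | Path, outdir: str | Path,
                    seed: int | None = None) -> RunManifest:
    scenario, analysis = load_config(config_path)
    if seed is not None:
        scenario.seed = int(seed)
    return run_scenario(scenario, analysis, outdir)
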
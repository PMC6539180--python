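"""End-to-end orchestration: config, run directories, and the in-memory
simulate -> correct -> extract -> model chain the CLI exposes.

A run directory has a fixed layout::

    <out>/rasters/   band stacks and DSMs per timepoint (ASCII grids)
    <out>/tables/    layout GeoJSON, truth CSV, feature table, reports
    <out>/models/    fitted/preset model JSON
    <out>/manifest.json

Identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .features import build_feature_table, correlate
from .geo_io import (BandStack, ElevationGrid, read_plots, read_raster,
                     read_table, write_plots, write_raster, write_table,
                     PlotRecord, TRAIT_SCHEMA)
from .radiometry import panel_correct
from .surface_model import (DEFAULT_CANOPY_THRESHOLD, build_dtm, compute_csm,
                            soil_mask_from_plots)
from .synthetic_field import (AgbmLink, SceneSpec,
                              TrialLayout, default_panel_region,
                              generate_trial_layout, generate_truth,
                              render_scene)
from .trait_models import (PRESETS, fit_lasso_agbm, lodging_scores,
                           predict_entries)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Single-file configuration for every pipeline stage."""

    seed: int = 0
    out_dir: str = "runs/run0"
    # simulation
    n_entries: int = 20
    n_reps: int = 3
    plot_size: tuple[float, float] = (1.5, 5.0)
    alley: float = 0.6
    timepoints: tuple[float, ...] = (365.0, 784.0, 1268.0, 1725.0, 1948.0)
    lodging_fraction: float = 0.15
    agbm_noise_sd: float = 0.1
    gsd: float = 0.05
    noise_sd: float = 0.01
    # extraction
    canopy_threshold: float = DEFAULT_CANOPY_THRESHOLD
    mask_vi: bool = True
    nirv_variant: str = "paper"
    # modelling
    model_add: float = 1268.0
    model_features: tuple[str, ...] = ("GRVI_sum", "NDVI_sum", "NDRE_sum", "CC")
    train_frac: float = 0.85
    cv_folds: int = 5
    grouping: str = "by_entry_mean"
    add_base_temp: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ConfigError(f"train_frac must be in (0, 1), got {self.train_frac}")
        if self.canopy_threshold < 0:
            raise ConfigError(
                f"canopy_threshold must be >= 0, got {self.canopy_threshold}")
        if self.nirv_variant not in ("paper", "badgley"):
            raise ConfigError(f"nirv_variant must be paper|badgley, "
                              f"got {self.nirv_variant!r}")
        self.plot_size = tuple(self.plot_size)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        self.model_features = tuple(self.model_features)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(config: PipelineConfig, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.digest(),
                "seed": config.seed, "peafield_version": __version__}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path


# ---------------------------------------------------------------------------
# In-memory pipeline (also the CLI's engine)
# ---------------------------------------------------------------------------

def simulate_trial(config: PipelineConfig):
    """Layout + truth + per-timepoint rendered scenes, all in memory."""
    layout = generate_trial_layout(
        config.n_entries, config.n_reps, plot_size=config.plot_size,
        alley=config.alley, seed=config.seed)
    truth = generate_truth(
        layout, config.timepoints,
        agbm_link=AgbmLink(noise_sd=config.agbm_noise_sd),
        lodging_fraction=config.lodging_fraction, seed=config.seed)
    spec = SceneSpec(gsd=config.gsd, noise_sd=config.noise_sd, seed=config.seed)
    scenes = {add: render_scene(truth, layout, spec, add)
              for add in config.timepoints}
    return layout, truth, spec, scenes


def extract_features(layout: TrialLayout, scenes: Mapping[float, tuple],
                     config: PipelineConfig,
                     panel_polygon=None) -> pd.DataFrame:
    """Panel-correct each stack, build DTM/CSM, and assemble the feature table.

    The DTM is interpolated from automatically sampled bare-soil pixels
    (everything outside the plot polygons).
    """
    processed: dict[float, tuple[BandStack, ElevationGrid]] = {}
    for add, (stack, dsm) in sorted(scenes.items()):
        if panel_polygon is not None:
            stack = panel_correct(stack, panel_polygon)
        soil = soil_mask_from_plots(dsm, layout.plots)
        dtm = build_dtm(dsm, soil)
        csm = compute_csm(dsm, dtm)
        processed[add] = (stack, csm)
    return build_feature_table(processed, layout.plots,
                               canopy_threshold=config.canopy_threshold,
                               mask_vi=config.mask_vi,
                               nirv_variant=config.nirv_variant)


def run_simulate(config: PipelineConfig) -> Path:
    """Simulate a trial and write rasters, layout, truth and manifest."""
    out = Path(config.out_dir)
    layout, truth, spec, scenes = simulate_trial(config)
    panel = default_panel_region(layout, spec)
    panel_record = PlotRecord(plot_id="panel", entry="panel", replicate=0,
                              polygon=panel, role="panel")
    write_plots(layout.plots + [panel_record], out / "tables" / "plots.geojson")
    write_table(truth.table, out / "tables" / "truth.csv")
    write_table(truth.ground_truth_table(), out / "tables" / "ground_truth.csv")
    for add, (stack, dsm) in scenes.items():
        write_raster(stack, out / "rasters" / f"bands_add{add:g}")
        write_raster(dsm, out / "rasters" / f"dsm_add{add:g}.asc")
    write_manifest(config, out)
    return out


def run_extract(config: PipelineConfig) -> Path:
    """Read a simulated run directory and write the feature table."""
    out = Path(config.out_dir)
    records = read_plots(out / "tables" / "plots.geojson")
    plots = [p for p in records if p.role == "plot"]
    panel = next((p.polygon for p in records if p.role == "panel"), None)
    layout = TrialLayout(plots=plots, field_origin=(0.0, 0.0),
                         plot_size=config.plot_size, alley=config.alley,
                         n_entries=config.n_entries, n_reps=config.n_reps)
    scenes = {}
    for add in config.timepoints:
        stack = read_raster(out / "rasters" / f"bands_add{add:g}", kind="bands")
        dsm = read_raster(out / "rasters" / f"dsm_add{add:g}.asc",
                          kind="elevation", role="DSM")
        scenes[add] = (stack, dsm)
    table = extract_features(layout, scenes, config, panel_polygon=panel)
    return write_table(table, out / "tables" / "features.csv")


def run_traits(config: PipelineConfig) -> dict[str, Path]:
    """Correlation report and lodging scores from an extracted run."""
    out = Path(config.out_dir)
    features = read_table(out / "tables" / "features.csv")
    for c in features.columns:
        if c not in ("plot_id", "entry", "leaf_type", "vi_masked"):
            features[c] = pd.to_numeric(features[c], errors="coerce")
    truth = read_table(out / "tables" / "ground_truth.csv", schema=TRAIT_SCHEMA)
    at_peak = features[features["ADD"] == config.model_add]
    report = correlate(at_peak, truth, grouping=config.grouping)
    paths = {}
    paths["correlation_r"] = write_table(
        report.r.reset_index(names="feature"), out / "tables" / "correlation_r.csv")
    paths["correlation_stars"] = write_table(
        report.stars.reset_index(names="feature"),
        out / "tables" / "correlation_stars.csv")
    adds = sorted(set(features["ADD"]))
    if len(adds) >= 2:
        scores = lodging_scores(features, adds[0], adds[-1], include_cc=True)
        paths["lodging"] = write_table(scores, out / "tables" / "lodging_scores.csv")
    return paths


def run_model(config: PipelineConfig, preset: str | None = None) -> dict[str, Path]:
    """Fit (or load a preset) AGBM model and write entry-level predictions."""
    out = Path(config.out_dir)
    features = read_table(out / "tables" / "features.csv")
    for c in features.columns:
        if c not in ("plot_id", "entry", "leaf_type", "vi_masked"):
            features[c] = pd.to_numeric(features[c], errors="coerce")
    at_add = features[features["ADD"] == config.model_add].copy()
    paths = {}
    if preset:
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
        model = PRESETS[preset]
    else:
        truth = read_table(out / "tables" / "ground_truth.csv", schema=TRAIT_SCHEMA)
        model, validation = fit_lasso_agbm(
            at_add, truth, config.model_features,
            train_frac=config.train_frac, cv_folds=config.cv_folds,
            seed=config.seed)
        (out / "models").mkdir(parents=True, exist_ok=True)
        (out / "models" / "validation.json").write_text(
            json.dumps(validation, indent=1, sort_keys=True))
        paths["validation"] = out / "models" / "validation.json"
    paths["model"] = model.to_json(out / "models" / "agbm_model.json")
    entry_est = predict_entries(model, at_add)
    paths["predictions"] = write_table(entry_est,
                                       out / "tables" / "entry_predictions.csv")
    return paths
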
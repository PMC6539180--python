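"""Synthetic pea-breeding trials with known ground truth.

The simulator produces the three things the analysis pipeline consumes —
a randomized-complete-block plot layout, per-plot ground truth over a set
of imaging timepoints, and rendered five-band reflectance + elevation
rasters — with the statistical structure the method assumes:

* canopy height and cover follow a unimodal (scaled beta-shaped) curve
  over accumulated degree days, rising to a peak near flowering (default
  1268 ADD) and declining toward maturity;
* per-band canopy and soil reflectances contrast so that GRVI is negative
  over bare soil and positive over closed canopy, with canopy spectra
  relaxing back toward soil as plants senesce;
* true above-ground biomass is a linear function of latent vegetation
  features (GRVI/NDVI/NDRE sums and canopy-cover area at the peak
  timepoint) plus Gaussian noise;
* a seeded subset of plots lodges after the growth peak: canopy height
  collapses by the lodging ratio (canopy height / total plant length)
  while cover spreads;
* the normal (Af) leaf type reflects more green light than the
  semi-leafless (af) type, separating the classes on plot-mean green
  reflectance;
* a white reference panel region renders at its nominal reflectance in
  every band, and terrain is a gentle planar gradient (default 1% grade).

Canopy placement within a plot is per-pixel Bernoulli(cover_fraction), so
the canopy-coverage statistic is an unbiased estimator of the true cover
fraction. All randomness derives from one seed via named sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from ._seeds import rng_stream
from .geo_io import BAND_NAMES, BandStack, ElevationGrid, GeoTransform, PlotRecord
from .qc_georef import GCPSet
from .zonal import polygon_pixel_mask


class SyntheticFieldError(ValueError):
    pass


#: Reflectance of bright bare soil per band: green below red, so GRVI < 0.
DEFAULT_SOIL_REFLECTANCE = {"B": 0.10, "G": 0.14, "R": 0.16, "RE": 0.22, "NIR": 0.25}

#: Healthy closed-canopy reflectance at peak greenness: GRVI, NDVI, NDRE > 0.
DEFAULT_CANOPY_REFLECTANCE = {"B": 0.04, "G": 0.12, "R": 0.06, "RE": 0.30, "NIR": 0.50}


# ---------------------------------------------------------------------------
# Trial layout
# ---------------------------------------------------------------------------

@dataclass
class TrialLayout:
    """Randomized-complete-block plot grid in map coordinates."""

    plots: list[PlotRecord]
    field_origin: tuple[float, float]
    plot_size: tuple[float, float]       # width (E-W) x length (N-S), m
    alley: float
    n_entries: int
    n_reps: int

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xs, ys = [], []
        for p in self.plots:
            minx, miny, maxx, maxy = p.polygon.bounds
            xs += [minx, maxx]
            ys += [miny, maxy]
        return min(xs), min(ys), max(xs), max(ys)


def generate_trial_layout(n_entries: int, n_reps: int,
                          plot_size: tuple[float, float] = (1.5, 5.0),
                          alley: float = 0.6,
                          origin: tuple[float, float] = (0.0, 0.0),
                          seed: int = 0) -> TrialLayout:
    """Lay out an RCBD trial: ``n_reps`` blocks stacked northward, entries
    randomized east-west within each block.

    Plot rectangles are ``plot_size`` (width x length) with ``alley``
    spacing; entry order within each block is a seeded random permutation,
    so every (entry, replicate) pair appears exactly once.
    """
    if n_entries < 1:
        raise SyntheticFieldError(f"n_entries must be >= 1, got {n_entries}")
    if n_reps < 1:
        raise SyntheticFieldError(f"n_reps must be >= 1, got {n_reps}")
    width, length = plot_size
    if width <= 0:
        raise SyntheticFieldError(f"plot width must be > 0, got {width}")
    if length <= 0:
        raise SyntheticFieldError(f"plot length must be > 0, got {length}")
    if alley < 0:
        raise SyntheticFieldError(f"alley must be >= 0, got {alley}")
    rng = rng_stream(seed, "layout")
    entries = [f"E{i + 1:02d}" for i in range(n_entries)]
    plots: list[PlotRecord] = []
    ox, oy = origin
    idx = 1
    for rep in range(n_reps):
        order = rng.permutation(n_entries)
        y0 = oy + rep * (length + alley)
        for pos, entry_i in enumerate(order):
            x0 = ox + pos * (width + alley)
            poly = box(x0, y0, x0 + width, y0 + length)
            plots.append(PlotRecord(plot_id=f"P{idx:03d}",
                                    entry=entries[entry_i],
                                    replicate=rep + 1, polygon=poly))
            idx += 1
    return TrialLayout(plots=plots, field_origin=origin, plot_size=plot_size,
                       alley=alley, n_entries=n_entries, n_reps=n_reps)


# ---------------------------------------------------------------------------
# Ground truth over time
# ---------------------------------------------------------------------------

@dataclass
class GrowthParams:
    """Unimodal canopy growth in accumulated degree days.

    The height curve is a beta-shaped kernel ``x^a (1-x)^b`` on
    [0, season_end_add], normalized to 1 at ``peak_add`` (b is solved from
    the peak location). Cover follows the same kernel raised to
    ``cover_exponent`` < 1, so cover saturates earlier than height.
    """

    peak_add: float = 1268.0
    season_end_add: float = 2200.0
    max_height: float = 0.6          # m, vigor-1 entry at the peak
    max_cover: float = 0.9           # fraction, vigor-1 entry at the peak
    shape_a: float = 2.0
    cover_exponent: float = 0.6
    entry_vigor_sd: float = 0.15
    plot_vigor_sd: float = 0.05
    #: Floor on the canopy-greenness modulation so early sparse canopy
    #: keeps a (weak) positive GRVI against bright soil.
    min_greenness: float = 0.4
    lodging_cover_spread: float = 0.6
    #: Thickness (m) of the mat a lodged canopy collapses into; piled vines
    #: stay well off the ground however severe the lodging.
    lodged_mat_height: float = 0.20
    green_leaf_type_shift: float = 0.02   # Af green reflectance offset
    reflectance_jitter_sd: float = 0.005

    def curve(self, add) -> np.ndarray:
        """Normalized growth curve, 1.0 at the peak."""
        add = np.asarray(add, dtype=float)
        t_end, peak, a = self.season_end_add, self.peak_add, self.shape_a
        if not 0 < peak < t_end:
            raise SyntheticFieldError("peak_add must lie inside (0, season_end_add)")
        b = a * (t_end / peak - 1.0)
        x = np.clip(add / t_end, 0.0, 1.0)
        xp = peak / t_end
        with np.errstate(divide="ignore", invalid="ignore"):
            g = (x ** a) * ((1 - x) ** b) / ((xp ** a) * ((1 - xp) ** b))
        return np.where(np.isfinite(g), g, 0.0)


@dataclass
class AgbmLink:
    """Linear map from standardized latent vegetation features to biomass."""

    weights: tuple[float, float, float, float] = (0.5, 0.3, 0.15, 0.05)
    base: float = 6.0        # kg, experiment mean
    scale: float = 1.5       # kg per unit of the weighted latent score
    noise_sd: float = 0.1    # kg


LATENT_FEATURES = ("lat_GRVI_sum", "lat_NDVI_sum", "lat_NDRE_sum", "lat_CC")


@dataclass
class SyntheticTruth:
    """Per-plot (and per-timepoint) ground truth of one simulated trial."""

    table: pd.DataFrame          # one row per (plot_id, ADD)
    plot_truth: pd.DataFrame     # one row per plot
    soil_reflectance: dict[str, float]
    timepoints: tuple[float, ...]
    growth: GrowthParams
    seed: int

    def for_timepoint(self, add: float) -> pd.DataFrame:
        sub = self.table[self.table["ADD"] == add]
        if sub.empty:
            raise SyntheticFieldError(f"timepoint {add} ADD not in truth "
                                      f"(have {sorted(set(self.table['ADD']))})")
        return sub

    def ground_truth_table(self) -> pd.DataFrame:
        """Field-book style trait table (one row per plot)."""
        cols = ["plot_id", "entry", "replicate", "AGBM", "CH_gt",
                "lodging_ratio", "leaf_type", "lodged", "F50", "PM", "FN", "SY"]
        return self.plot_truth.loc[:, cols].copy()


def _vi(a: float, b: float) -> float:
    return (a - b) / (a + b)


def generate_truth(layout: TrialLayout, timepoints: Sequence[float],
                   growth: GrowthParams | None = None,
                   agbm_link: AgbmLink | None = None,
                   lodging_fraction: float = 0.15,
                   soil_reflectance: dict[str, float] | None = None,
                   canopy_reflectance: dict[str, float] | None = None,
                   seed: int = 0) -> SyntheticTruth:
    """Simulate per-plot growth, spectra, lodging, leaf type and biomass.

    ``lodging_fraction`` of the plots (exactly, rounded) lodge at
    timepoints after the growth peak. True AGBM is linear in the
    standardized latent features (GRVI/NDVI/NDRE sums and CC at the peak)
    plus Gaussian noise of ``agbm_link.noise_sd``.
    """
    growth = growth or GrowthParams()
    agbm_link = agbm_link or AgbmLink()
    soil = dict(soil_reflectance or DEFAULT_SOIL_REFLECTANCE)
    canopy0 = dict(canopy_reflectance or DEFAULT_CANOPY_REFLECTANCE)
    timepoints = tuple(float(t) for t in timepoints)
    if not timepoints:
        raise SyntheticFieldError("timepoint list is empty")
    if any(b <= a for a, b in zip(timepoints, timepoints[1:])):
        raise SyntheticFieldError(f"timepoints must be strictly increasing: {timepoints}")
    if not 0 <= lodging_fraction <= 1:
        raise SyntheticFieldError(
            f"lodging_fraction must be in [0, 1], got {lodging_fraction}")

    plots = layout.plots
    n_plots = len(plots)
    entries = sorted({p.entry for p in plots})

    rng_vigor = rng_stream(seed, "truth:vigor")
    rng_lodge = rng_stream(seed, "truth:lodging")
    rng_leaf = rng_stream(seed, "truth:leaftype")
    rng_refl = rng_stream(seed, "truth:reflectance")
    rng_agbm = rng_stream(seed, "truth:agbm")
    rng_traits = rng_stream(seed, "truth:traits")

    entry_vigor = {e: max(0.3, 1.0 + rng_vigor.normal(0.0, growth.entry_vigor_sd))
                   for e in entries}
    # leaf type is an entry-level genetic trait: half the entries (at least
    # one) are normal-leafed Af, the rest semi-leafless af
    shuffled = list(entries)
    rng_leaf.shuffle(shuffled)
    n_af_cap = max(1, len(entries) // 2) if len(entries) > 1 else 1
    leaf_of = {e: ("Af" if i < n_af_cap else "af") for i, e in enumerate(shuffled)}

    n_lodged = int(round(lodging_fraction * n_plots))
    lodged_idx = set(rng_lodge.choice(n_plots, size=n_lodged, replace=False).tolist())

    plot_rows = []
    for i, p in enumerate(plots):
        vigor = max(0.3, entry_vigor[p.entry]
                    + rng_vigor.normal(0.0, growth.plot_vigor_sd))
        lodged = i in lodged_idx
        # moderate lodging severity: a lodged pea canopy is a mat of piled
        # stems that stays well off the ground, so the crop remains above
        # the canopy-segmentation height and its measured cover *increases*
        # on lodging (the behaviour the score is designed to exploit)
        ratio = (rng_lodge.uniform(0.50, 0.80) if lodged
                 else rng_lodge.uniform(0.90, 1.00))
        green_shift = (growth.green_leaf_type_shift
                       if leaf_of[p.entry] == "Af" else 0.0)
        jitter = {b: rng_refl.normal(0.0, growth.reflectance_jitter_sd)
                  for b in BAND_NAMES}
        plot_rows.append({
            "plot_id": p.plot_id, "entry": p.entry, "replicate": p.replicate,
            "vigor": vigor, "lodged": lodged, "lodging_ratio": ratio,
            "leaf_type": leaf_of[p.entry], "green_shift": green_shift,
            **{f"jitter_{b}": jitter[b] for b in BAND_NAMES},
        })
    plot_truth = pd.DataFrame(plot_rows)

    g_peak = 1.0
    peak_cover = np.clip(plot_truth["vigor"] * growth.max_cover
                         * g_peak ** growth.cover_exponent, 0.0, 0.98)
    peak_height = plot_truth["vigor"] * growth.max_height
    plot_area = layout.plot_size[0] * layout.plot_size[1]

    # latent vegetation features at the growth peak: sum-type VI features
    # scale with covered area times the plot's own canopy index value
    # (per-plot spectral jitter keeps the four latents from being collinear)
    def peak_band(b, i):
        v = canopy0[b] + float(plot_truth.loc[i, f"jitter_{b}"])
        if b == "G":
            v += float(plot_truth.loc[i, "green_shift"])
        return v

    lat = pd.DataFrame({
        "lat_GRVI_sum": [peak_cover[i] * plot_area
                         * _vi(peak_band("G", i), peak_band("R", i))
                         for i in range(n_plots)],
        "lat_NDVI_sum": [peak_cover[i] * plot_area
                         * _vi(peak_band("NIR", i), peak_band("R", i))
                         for i in range(n_plots)],
        "lat_NDRE_sum": [peak_cover[i] * plot_area
                         * _vi(peak_band("NIR", i), peak_band("RE", i))
                         for i in range(n_plots)],
        "lat_CC": peak_cover * plot_area,
    })
    z = (lat - lat.mean()) / lat.std(ddof=0) if n_plots > 1 else lat * 0.0
    score = z.to_numpy() @ np.asarray(agbm_link.weights)
    agbm = (agbm_link.base + agbm_link.scale * score
            + rng_agbm.normal(0.0, agbm_link.noise_sd, size=n_plots))
    plot_truth = pd.concat([plot_truth, lat], axis=1)
    plot_truth["AGBM"] = agbm
    plot_truth["CH_gt"] = peak_height
    # correlated agronomic traits: vigorous entries flower earlier, yield more
    plot_truth["F50"] = 62.0 - 8.0 * (plot_truth["vigor"] - 1.0) \
        + rng_traits.normal(0.0, 1.0, n_plots)
    plot_truth["PM"] = plot_truth["F50"] + 38.0 + rng_traits.normal(0.0, 1.5, n_plots)
    plot_truth["FN"] = np.round(14.0 + 6.0 * (plot_truth["F50"] - 62.0) / 8.0
                                + rng_traits.normal(0.0, 0.8, n_plots))
    plot_truth["SY"] = np.maximum(
        0.0, 0.4 * plot_truth["AGBM"] + rng_traits.normal(0.0, 0.15, n_plots))

    g = growth.curve(np.asarray(timepoints))
    rows = []
    for i, p in enumerate(plots):
        pt = plot_truth.iloc[i]
        for j, add in enumerate(timepoints):
            height = float(pt["vigor"] * growth.max_height * g[j])
            cover = float(np.clip(pt["vigor"] * growth.max_cover
                                  * g[j] ** growth.cover_exponent, 0.0, 0.98))
            lodged_now = bool(pt["lodged"]) and add > growth.peak_add
            if lodged_now:
                # collapse by the lodging ratio, but never below the mat
                # thickness (and always strictly below the erect height)
                height = max(height * float(pt["lodging_ratio"]),
                             min(growth.lodged_mat_height, 0.95 * height))
                cover = float(np.clip(
                    cover * (1.0 + growth.lodging_cover_spread
                             * (1.0 - pt["lodging_ratio"])), 0.0, 0.98))
            m = float(np.clip(g[j], growth.min_greenness, 1.0))
            refl = {}
            for b in BAND_NAMES:
                base = canopy0[b] + float(pt[f"jitter_{b}"])
                if b == "G":
                    base += float(pt["green_shift"])
                refl[b] = max(1e-3, soil[b] + (base - soil[b]) * m)
            rows.append({
                "plot_id": p.plot_id, "entry": p.entry,
                "replicate": p.replicate, "ADD": add,
                "true_mean_height": height, "true_cover_fraction": cover,
                "true_agbm": float(pt["AGBM"]), "lodged": lodged_now,
                "lodging_ratio": float(pt["lodging_ratio"]),
                "leaf_type": pt["leaf_type"],
                **{f"canopy_{b}": refl[b] for b in BAND_NAMES},
                **{f"soil_{b}": soil[b] for b in BAND_NAMES},
            })
    table = pd.DataFrame(rows)
    return SyntheticTruth(table=table, plot_truth=plot_truth,
                          soil_reflectance=soil, timepoints=timepoints,
                          growth=growth, seed=seed)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Rendering parameters for one synthetic scene.

    ``gsd`` is the ground sample distance in m/pixel. ``noise_sd`` is the
    additive per-band Gaussian reflectance noise. The white reference panel
    (nominal reflectance 0.99) is placed in the margin south-west of the
    field unless ``panel_region`` is given. Terrain is a plane
    ``base_elevation + slope . (E, N)`` (default 1% east-west grade).
    """

    gsd: float = 0.05
    noise_sd: float = 0.01
    panel_region: Polygon | None = None
    panel_reflectance: float = 0.99
    margin: float = 2.0
    base_elevation: float = 100.0
    slope: tuple[float, float] = (0.01, 0.0)
    elevation_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gsd > 0:
            raise SyntheticFieldError(f"gsd must be > 0, got {self.gsd}")
        if self.noise_sd < 0 or self.elevation_noise_sd < 0:
            raise SyntheticFieldError("noise sd must be >= 0")


def default_panel_region(layout: TrialLayout, spec: SceneSpec) -> Polygon:
    """0.5 m x 0.5 m panel in the south-west margin, clear of all plots."""
    minx, miny, _, _ = layout.bounds
    side = max(0.5, 4 * spec.gsd)
    x0 = minx - spec.margin + 0.25 * spec.margin
    y0 = miny - spec.margin + 0.25 * spec.margin
    return box(x0, y0, x0 + side, y0 + side)


def render_scene(truth: SyntheticTruth, layout: TrialLayout, spec: SceneSpec,
                 timepoint: float) -> tuple[BandStack, ElevationGrid]:
    """Render the five-band reflectance stack and the DSM for one timepoint.

    In-plot pixels are canopy with probability ``true_cover_fraction``
    (seeded per plot); canopy pixels take the plot's canopy reflectance and
    ``terrain + true_mean_height`` elevation, everything else takes soil
    reflectance and bare terrain; the panel region takes the panel
    reflectance in every band. Per-band Gaussian noise is added last.
    """
    sub = truth.for_timepoint(timepoint).set_index("plot_id")
    panel = spec.panel_region or default_panel_region(layout, spec)
    minx, miny, maxx, maxy = layout.bounds
    pminx, pminy, pmaxx, pmaxy = panel.bounds
    minx = min(minx, pminx) - spec.margin
    miny = min(miny, pminy) - spec.margin
    maxx = max(maxx, pmaxx) + spec.margin
    maxy = max(maxy, pmaxy) + spec.margin
    ncols = int(np.ceil((maxx - minx) / spec.gsd))
    nrows = int(np.ceil((maxy - miny) / spec.gsd))
    transform = GeoTransform(origin_easting=minx,
                             origin_northing=miny + nrows * spec.gsd,
                             pixel_size=spec.gsd)
    shape = (nrows, ncols)

    for p in layout.plots:
        if panel.intersects(p.polygon):
            raise SyntheticFieldError(
                f"panel region overlaps plot {p.plot_id!r}")

    cgrid, rgrid = np.meshgrid(np.arange(ncols), np.arange(nrows))
    e, n = transform.pixel_center(rgrid, cgrid)
    terrain = (spec.base_elevation + spec.slope[0] * (e - minx)
               + spec.slope[1] * (n - miny))

    soil = truth.soil_reflectance
    bands = {b: np.full(shape, soil[b], dtype=float) for b in BAND_NAMES}
    dsm = terrain.copy()

    for p in layout.plots:
        row = sub.loc[p.plot_id]
        in_plot = polygon_pixel_mask(p.polygon, transform, shape)
        n_px = int(np.count_nonzero(in_plot))
        if n_px == 0:
            raise SyntheticFieldError(
                f"plot {p.plot_id!r} contains zero pixels at gsd {spec.gsd}")
        rng = rng_stream(spec.seed, f"render:{timepoint}:plot:{p.plot_id}")
        canopy = np.zeros(shape, dtype=bool)
        canopy[in_plot] = rng.random(n_px) < float(row["true_cover_fraction"])
        for b in BAND_NAMES:
            bands[b][canopy] = float(row[f"canopy_{b}"])
        dsm[canopy] = terrain[canopy] + float(row["true_mean_height"])

    panel_mask = polygon_pixel_mask(panel, transform, shape)
    if not panel_mask.any():
        raise SyntheticFieldError("panel region contains zero pixels")
    for b in BAND_NAMES:
        bands[b][panel_mask] = spec.panel_reflectance

    rng_noise = rng_stream(spec.seed, f"render:{timepoint}:noise")
    if spec.noise_sd > 0:
        for b in BAND_NAMES:
            bands[b] = np.maximum(
                0.0, bands[b] + rng_noise.normal(0.0, spec.noise_sd, shape))
    if spec.elevation_noise_sd > 0:
        dsm = dsm + rng_noise.normal(0.0, spec.elevation_noise_sd, shape)

    stack = BandStack(bands=bands, transform=transform)
    elevation = ElevationGrid(values=dsm, transform=transform, role="DSM")
    return stack, elevation


# ---------------------------------------------------------------------------
# GCP displacement
# ---------------------------------------------------------------------------

def generate_gcp_errors(n: int, horizontal_sd: float, vertical_sd: float,
                        seed: int = 0,
                        extent: tuple[float, float] = (30.0, 30.0)) -> GCPSet:
    """True GCP coordinates with seeded Gaussian displacements per axis."""
    if n < 1:
        raise SyntheticFieldError(f"n must be >= 1, got {n}")
    if horizontal_sd < 0 or vertical_sd < 0:
        raise SyntheticFieldError("displacement sd must be >= 0")
    rng = rng_stream(seed, "gcp")
    e = rng.uniform(0.0, extent[0], n)
    nn = rng.uniform(0.0, extent[1], n)
    z = rng.uniform(99.0, 101.0, n)
    true = np.column_stack([e, nn, z])
    disp = np.column_stack([
        rng.normal(0.0, horizontal_sd, n),
        rng.normal(0.0, horizontal_sd, n),
        rng.normal(0.0, vertical_sd, n),
    ])
    return GCPSet(true_coords=true, observed_coords=true + disp)
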
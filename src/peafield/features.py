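"""Plot-level feature extraction: zonal statistics, the multi-timepoint
feature table, accumulated degree days, and trait-feature correlations.

Per plot and imaging timepoint the table carries ten image features: sum
("absolute vigor") and mean ("relative vigor") of GRVI, NDVI and NDRE, the
NIRv sum, and the elevation-derived canopy height CH_uas (m), canopy
coverage CC (m^2) and plot volume PV (m^3). Timepoints are indexed by
accumulated degree days (ADD) above a 0 degC base.

Correlations against ground truth follow two protocols: ``by_entry_mean``
averages replicate plots per entry before correlating (the winter-trial
protocol), ``by_plot`` correlates plot-wise (the spring-trial protocol,
used when replicates are not measured on a common day).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo_io import BandStack, ElevationGrid, PlotRecord
from .radiometry import ValueGrid, compute_nirv, compute_vi
from .surface_model import (CanopyMask, DEFAULT_CANOPY_THRESHOLD,
                            plot_canopy_metrics, segment_canopy)
from .zonal import polygon_pixel_mask

FEATURE_COLUMNS = ("GRVI_sum", "GRVI_mean", "NDVI_sum", "NDVI_mean",
                   "NDRE_sum", "NDRE_mean", "NIRv", "CH_uas", "CC", "PV")

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class FeatureError(ValueError):
    pass


def zonal_stats(grid: ValueGrid | ElevationGrid, plot: PlotRecord,
                mask: CanopyMask | None = None) -> tuple[float, float, int]:
    """(sum, mean, n) of valid grid values over the plot polygon.

    With a canopy mask the statistics are restricted to canopy pixels.
    An empty intersection is not an error: it yields ``(0.0, nan, 0)``.
    """
    in_plot = polygon_pixel_mask(plot.polygon, grid.transform, grid.shape)
    valid = in_plot & ~grid.nodata_mask
    if mask is not None:
        if mask.shape != grid.shape:
            raise FeatureError("canopy mask shape differs from grid shape")
        valid &= mask.values
    n = int(np.count_nonzero(valid))
    if n == 0:
        return 0.0, float("nan"), 0
    vals = grid.values[valid]
    total = float(np.sum(vals))
    return total, total / n, n


def build_feature_table(scenes: Mapping[float, tuple[BandStack, ElevationGrid]],
                        plots: Sequence[PlotRecord],
                        canopy_threshold: float = DEFAULT_CANOPY_THRESHOLD,
                        mask_vi: bool = True,
                        nirv_variant: str = "paper") -> pd.DataFrame:
    """One row per (plot_id, ADD) with the ten image features.

    ``scenes`` maps ADD to an aligned (band stack, CSM) pair sharing the
    plot layer. ``mask_vi`` applies the canopy-segmentation soil mask to
    the VI statistics (the unmasked mode reproduces early-season soil
    contamination of plot means).
    """
    add_values = sorted(scenes)
    if len(set(add_values)) != len(scenes):  # pragma: no cover - dict keys unique
        raise FeatureError("duplicate ADD timepoints")
    plot_only = [p for p in plots if p.role == "plot"]
    rows = []
    for add in add_values:
        stack, csm = scenes[add]
        if csm.role != "CSM":
            raise FeatureError(f"scene at {add} ADD: elevation grid must be a CSM")
        mask = segment_canopy(csm, canopy_threshold)
        vi_mask = mask if mask_vi else None
        grids = {name: compute_vi(stack, name) for name in ("GRVI", "NDVI", "NDRE")}
        grids["NIRv"] = compute_nirv(stack, nirv_variant)
        for plot in plot_only:
            row: dict[str, object] = {"plot_id": plot.plot_id, "entry": plot.entry,
                                      "replicate": plot.replicate, "ADD": add}
            for name in ("GRVI", "NDVI", "NDRE"):
                s, m, _ = zonal_stats(grids[name], plot, vi_mask)
                row[f"{name}_sum"], row[f"{name}_mean"] = s, m
            row["NIRv"], _, _ = zonal_stats(grids["NIRv"], plot, vi_mask)
            metrics = plot_canopy_metrics(csm, mask, plot)
            row["CH_uas"] = metrics.ch_uas
            row["CC"] = metrics.cc
            row["PV"] = metrics.pv
            row["vi_masked"] = mask_vi
            rows.append(row)
    table = pd.DataFrame(rows)
    dup = table.duplicated(subset=["plot_id", "ADD"])
    if dup.any():
        raise FeatureError(f"duplicate (plot_id, ADD) rows: "
                           f"{table.loc[dup, ['plot_id', 'ADD']].values.tolist()}")
    return table


def compute_add(dates: Sequence, daily_mean_temp: Sequence[float],
                start_date, base: float = 0.0) -> pd.DataFrame:
    """Accumulated degree days from ``start_date`` at the given base.

    ADD(d) = sum over days from start through d of max(mean temp - base, 0);
    the start date itself contributes its own term.
    """
    dates = pd.to_datetime(pd.Index(dates))
    temps = np.asarray(daily_mean_temp, dtype=float)
    if len(dates) != len(temps):
        raise FeatureError("dates and temperatures differ in length")
    deltas = dates.to_series().diff().dropna()
    if not (deltas == pd.Timedelta(days=1)).all():
        raise FeatureError("dates must be consecutive daily values")
    start = pd.Timestamp(start_date)
    if start < dates[0] or start > dates[-1]:
        raise FeatureError(f"start_date {start.date()} outside the temperature series")
    keep = dates >= start
    contrib = np.maximum(temps[keep] - base, 0.0)
    return pd.DataFrame({"date": dates[keep], "daily_mean_temp": temps[keep],
                         "ADD": np.cumsum(contrib)})


def stars_for_p(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return ""


@dataclass
class CorrelationReport:
    """Feature x trait Pearson matrix with p-values and significance stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame
    grouping: str


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate(features: pd.DataFrame, truth: pd.DataFrame,
              grouping: str = "by_entry_mean",
              feature_cols: Sequence[str] | None = None,
              trait_cols: Sequence[str] | None = None) -> CorrelationReport:
    """Pearson correlations between image features and ground-truth traits.

    Both tables must carry ``plot_id`` (and ``entry`` for the
    ``by_entry_mean`` protocol). p-values are two-sided via the
    t-distribution with n - 2 df; cells with zero variance are NaN.
    """
    if grouping not in ("by_entry_mean", "by_plot"):
        raise FeatureError(f"unknown grouping {grouping!r}")
    merged = features.merge(truth, on="plot_id", suffixes=("", "_gt"))
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_COLUMNS if c in merged.columns]
    if trait_cols is None:
        trait_cols = [c for c in ("AGBM", "F50", "PM", "FN", "SY", "CH_gt",
                                  "lodging_ratio") if c in merged.columns]
    if grouping == "by_entry_mean":
        if "entry" not in merged.columns:
            raise FeatureError("by_entry_mean grouping requires an 'entry' column")
        merged = (merged.groupby("entry", as_index=False)
                  [list(feature_cols) + list(trait_cols)].mean())
    if len(merged) < 3:
        raise FeatureError(
            f"need >= 3 matched units after grouping, got {len(merged)}")
    r = pd.DataFrame(index=feature_cols, columns=trait_cols, dtype=float)
    p = r.copy()
    n = pd.DataFrame(index=feature_cols, columns=trait_cols, dtype=int)
    stars = pd.DataFrame("", index=feature_cols, columns=trait_cols)
    for f in feature_cols:
        for t in trait_cols:
            pair = merged[[f, t]].dropna()
            n.loc[f, t] = len(pair)
            if len(pair) < 3:
                r.loc[f, t] = np.nan
                p.loc[f, t] = np.nan
                continue
            rv, pv = _pearson(pair[f].to_numpy(float), pair[t].to_numpy(float))
            r.loc[f, t] = rv
            p.loc[f, t] = pv
            if np.isfinite(pv):
                stars.loc[f, t] = stars_for_p(pv)
    return CorrelationReport(r=r, p=p, stars=stars, n=n, grouping=grouping)
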
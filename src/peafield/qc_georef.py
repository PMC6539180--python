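"""Georeferencing quality control.

Horizontal position error is the root-mean-square horizontal offset of
observed ground-control-point coordinates from their RTK-surveyed truth:

    HPE = sqrt( sum_i (EE_i^2 + NE_i^2) / n )

with EE, NE the per-point easting/northing errors (observed - true).
Vertical position error compares elevation roughness along a transect of
n_segments + 1 points between a rectified and a non-rectified surface:
DeltaZ of a series is the sum of absolute adjacent elevation differences,
and VPE = (DeltaZ_rectified - DeltaZ_nonrectified) / n_segments. The
signed form can be negative; the absolute value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class GeorefError(ValueError):
    pass


@dataclass
class GCPSet:
    """Paired true and observed (E, N, Z) coordinates of ground control points."""

    true_coords: np.ndarray      # (n, 3) easting, northing, elevation in m
    observed_coords: np.ndarray  # (n, 3)
    hdop: float | None = None
    vdop: float | None = None

    def __post_init__(self) -> None:
        self.true_coords = np.atleast_2d(np.asarray(self.true_coords, float))
        self.observed_coords = np.atleast_2d(np.asarray(self.observed_coords, float))
        if self.true_coords.shape != self.observed_coords.shape:
            raise GeorefError("true and observed coordinate arrays must match in shape")
        if self.true_coords.ndim != 2 or self.true_coords.shape[1] != 3:
            raise GeorefError("coordinates must be (n, 3) arrays of E, N, Z")
        if self.true_coords.shape[0] < 1:
            raise GeorefError("GCP set is empty")
        if not (np.isfinite(self.true_coords).all()
                and np.isfinite(self.observed_coords).all()):
            raise GeorefError("GCP coordinates must be finite")

    @property
    def n(self) -> int:
        return self.true_coords.shape[0]

    @property
    def errors(self) -> np.ndarray:
        """Per-point (EE, NE, ZE) = observed - true."""
        return self.observed_coords - self.true_coords


def compute_hpe(gcps: GCPSet) -> float:
    """Root-mean-square horizontal position error in meters."""
    err = gcps.errors
    return float(np.sqrt(np.mean(err[:, 0] ** 2 + err[:, 1] ** 2)))


@dataclass
class ElevationTransect:
    """Ordered elevations sampled along one line on two surfaces."""

    rectified: np.ndarray
    non_rectified: np.ndarray
    n_segments: int = 4

    def __post_init__(self) -> None:
        self.rectified = np.asarray(self.rectified, float)
        self.non_rectified = np.asarray(self.non_rectified, float)
        if self.rectified.shape != self.non_rectified.shape:
            raise GeorefError("rectified and non-rectified series must match in length")
        if self.rectified.ndim != 1 or self.rectified.size != self.n_segments + 1:
            raise GeorefError(
                f"each series must hold n_segments + 1 = {self.n_segments + 1} "
                f"points, got {self.rectified.size}")


def delta_z(series: np.ndarray) -> float:
    """Sum of absolute elevation changes between adjacent transect points."""
    series = np.asarray(series, float)
    return float(np.sum(np.abs(np.diff(series))))


def compute_vpe(transect: ElevationTransect) -> dict[str, float]:
    """Signed and absolute vertical position error in meters.

    signed = (DeltaZ_rectified - DeltaZ_nonrectified) / n_segments.
    """
    dz_r = delta_z(transect.rectified)
    dz_nr = delta_z(transect.non_rectified)
    signed = (dz_r - dz_nr) / transect.n_segments
    return {"vpe_signed": signed, "vpe_abs": abs(signed),
            "delta_z_rectified": dz_r, "delta_z_non_rectified": dz_nr}


def validate_heights(ch_gt, ch_uas) -> dict[str, float]:
    """Pearson correlation between field-measured and image-derived canopy height."""
    x = np.asarray(ch_gt, float)
    y = np.asarray(ch_uas, float)
    if x.shape != y.shape or x.ndim != 1:
        raise GeorefError("height series must be paired 1-D arrays")
    if x.size < 3:
        raise GeorefError(f"need >= 3 paired heights, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": int(x.size)}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}
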
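"""Slope-pair reliability metric for spectral SO2 fits.

A fitted SO2 value that is physiologically plausible does not prove that the
underlying OA spectrum actually looks like blood.  This module quantifies the
*trend* of a spectrum by two numbers: the slopes (m1, m2) of straight lines
fitted left and right of the ~800 nm isosbestic point.  Pure blood spectra,
swept from SO2 = 0 to 100%, trace a smooth curve in the (m1, m2) plane — the
*reference line* — and the mapping SO2 -> (m1, m2) is one-to-one.  A cluster
of measured slope pairs that sits on the reference line near the point of its
mean fitted SO2 corroborates the fits; a cluster far from that point exposes
them as untrustworthy regardless of how plausible the SO2 numbers look.

Spectra are mean-normalized (divided by their mean over the measurement
wavelengths) before slope extraction so that the unknown amplitude scaling of
OA signals drops out; the reference line is built with the same normalization
for comparability.

The cluster statistic is the ratio

    ratio = distance / spread

where *distance* is the mean Euclidean distance of the cluster members from
the reference point at the cluster's mean fitted SO2, and *spread* is the mean
Euclidean distance of the members from the cluster centroid.  For an ideal
cluster centered on its reference point the ratio is 1; large values flag
unreliable fits.  No pass/fail threshold is built in — callers may configure
their own; the default behavior is report-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chromophores import (
    DEFAULT_GRID,
    ChromophoreTable,
    Spectrum,
    WavelengthGrid,
    blood_absorption,
    _as_grid,
)
from .errors import DegenerateClusterError, DegenerateSpectrumError, ValidationError

__all__ = [
    "DEFAULT_LEFT_SET",
    "DEFAULT_RIGHT_SET",
    "ClusterStats",
    "MetricPlotData",
    "ReferenceLine",
    "SlopePair",
    "build_reference_line",
    "cluster_stats",
    "metric_plot_data",
    "normalize_spectrum",
    "plot_metric",
    "reference_point_at",
    "slope_pair",
]

#: Wavelength subsets (nm) for the left/right slope fits.  740 nm is excluded:
#: blood spectra are not approximately linear that far below the isosbestic
#: point.  800 nm (the isosbestic point) anchors both subsets.
DEFAULT_LEFT_SET: tuple[float, ...] = (760.0, 780.0, 800.0)
DEFAULT_RIGHT_SET: tuple[float, ...] = (800.0, 830.0, 860.0, 890.0)

_SPREAD_FLOOR = 1e-12


@dataclass(frozen=True)
class SlopePair:
    """Slopes (per nm) of first-order polynomials fitted left (m1) and right
    (m2) of the isosbestic point.  ``normalized`` records whether the spectrum
    was mean-normalized before the fits (required for comparability with the
    reference line)."""

    m1: float
    m2: float
    normalized: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m1) and np.isfinite(self.m2)):
            raise ValidationError("slope pair must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.m1, self.m2])

    def distance_to(self, other: "SlopePair") -> float:
        return float(np.hypot(self.m1 - other.m1, self.m2 - other.m2))


@dataclass(frozen=True)
class ReferenceLine:
    """Slope pairs of mean-normalized pure-blood spectra on an SO2 grid."""

    so2_grid_percent: np.ndarray
    pairs: tuple[SlopePair, ...]
    left_set_nm: tuple[float, ...]
    right_set_nm: tuple[float, ...]

    def __post_init__(self) -> None:
        grid = np.asarray(self.so2_grid_percent, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("SO2 grid must be strictly increasing")
        if len(self.pairs) != grid.size:
            raise ValidationError("one slope pair per SO2 grid point required")
        object.__setattr__(self, "so2_grid_percent", grid)

    def as_array(self) -> np.ndarray:
        """(n, 2) array of (m1, m2) along the SO2 grid."""
        return np.array([[p.m1, p.m2] for p in self.pairs])


@dataclass(frozen=True)
class ClusterStats:
    """Summary of one slope-pair cluster against the reference line."""

    centroid: SlopePair
    spread: float
    mean_so2_percent: float
    reference_point: SlopePair
    distance: float
    ratio: float
    n_members: int

    def to_dict(self) -> dict:
        return {
            "centroid_m1": self.centroid.m1,
            "centroid_m2": self.centroid.m2,
            "spread": self.spread,
            "mean_so2_percent": self.mean_so2_percent,
            "distance": self.distance,
            "ratio": self.ratio,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Divide a spectrum by its mean over the measurement wavelengths.

    The result is dimensionless with mean 1, making spectra of arbitrary
    amplitude comparable.  Raises on (numerically) zero mean.
    """
    m = float(np.mean(spectrum.values))
    if abs(m) <= 1e-300 or abs(m) <= 1e-15 * float(np.max(np.abs(spectrum.values), initial=0.0)):
        raise DegenerateSpectrumError("spectrum mean is zero; cannot normalize")
    return Spectrum(spectrum.wavelengths_nm, spectrum.values / m, spectrum.label)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def slope_pair(
    spectrum: Spectrum,
    left_set_nm: Sequence[float] = DEFAULT_LEFT_SET,
    right_set_nm: Sequence[float] = DEFAULT_RIGHT_SET,
    normalize: bool = True,
) -> SlopePair:
    """Extract the (m1, m2) slope pair of a spectrum.

    m1 and m2 are ordinary least-squares slopes of straight lines through the
    (wavelength, value) points of the left and right subsets.  Each subset
    must be contained in the spectrum's grid and hold at least 2 wavelengths.
    """
    if normalize:
        spectrum = normalize_spectrum(spectrum)
    lam = spectrum.wavelengths_nm
    slopes = []
    for name, subset in (("left", left_set_nm), ("right", right_set_nm)):
        sub = np.asarray(subset, dtype=float)
        if sub.size < 2:
            raise ValidationError(f"{name} subset needs at least 2 wavelengths")
        idx = np.searchsorted(lam, sub)
        if np.any(idx >= lam.size) or np.any(lam[np.clip(idx, 0, lam.size - 1)] != sub):
            raise ValidationError(
                f"{name} subset {sub.tolist()} not contained in the spectrum grid"
            )
        slopes.append(_ols_slope(sub, spectrum.values[idx]))
    return SlopePair(m1=slopes[0], m2=slopes[1], normalized=normalize)


def build_reference_line(
    table: ChromophoreTable,
    grid: "WavelengthGrid | np.ndarray" = DEFAULT_GRID,
    so2_step_percent: float = 1.0,
    left_set_nm: Sequence[float] = DEFAULT_LEFT_SET,
    right_set_nm: Sequence[float] = DEFAULT_RIGHT_SET,
) -> ReferenceLine:
    """Reference line: slope pairs of pure blood for SO2 = 0..100.

    Each blood spectrum is evaluated on the *measurement* grid and normalized
    by its mean over that grid — the same normalization applied to measured
    spectra — before slope extraction.
    """
    if not 0.0 < so2_step_percent <= 100.0:
        raise ValidationError("so2_step_percent must be in (0, 100]")
    g = _as_grid(grid)
    so2_grid = np.arange(0.0, 100.0 + so2_step_percent / 2, so2_step_percent)
    pairs = tuple(
        slope_pair(
            blood_absorption(table, s, g), left_set_nm, right_set_nm, normalize=True
        )
        for s in so2_grid
    )
    return ReferenceLine(so2_grid, pairs, tuple(left_set_nm), tuple(right_set_nm))


def reference_point_at(
    line: ReferenceLine,
    table: ChromophoreTable,
    grid: "WavelengthGrid | np.ndarray",
    so2_percent: float,
) -> SlopePair:
    """Slope pair of pure blood at exactly ``so2_percent``.

    Computed freshly (blood spectrum + normalization + slopes), never
    interpolated from the stored grid, so off-grid SO2 values are exact.
    """
    s = float(np.clip(so2_percent, 0.0, 100.0))
    return slope_pair(
        blood_absorption(table, s, _as_grid(grid)),
        line.left_set_nm,
        line.right_set_nm,
        normalize=True,
    )


def cluster_stats(
    pairs: Sequence[SlopePair],
    fitted_so2: Sequence[float],
    line: ReferenceLine,
    table: ChromophoreTable,
    grid: "WavelengthGrid | np.ndarray" = DEFAULT_GRID,
) -> ClusterStats:
    """Distance / spread statistics of a slope-pair cluster.

    ``fitted_so2`` holds the fitted SO2 of each member; the mean (clamped to
    [0, 100]) selects the reference point.  ``spread`` is the mean distance of
    members from the cluster centroid, ``distance`` the mean distance from the
    reference point; their ratio is ~1 for trustworthy fits.
    """
    if len(pairs) < 2:
        raise ValidationError("cluster_stats requires at least 2 members")
    if len(pairs) != len(fitted_so2):
        raise ValidationError("pairs and fitted_so2 must be aligned")
    pts = np.array([[p.m1, p.m2] for p in pairs])
    so2 = np.asarray(fitted_so2, dtype=float)
    centroid = pts.mean(axis=0)
    spread = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
    if spread < _SPREAD_FLOOR:
        raise DegenerateClusterError(
            "cluster spread is numerically zero; the ratio is undefined"
        )
    mean_so2 = float(np.clip(so2.mean(), 0.0, 100.0))
    ref = reference_point_at(line, table, grid, mean_so2)
    distance = float(np.mean(np.linalg.norm(pts - ref.as_array(), axis=1)))
    return ClusterStats(
        centroid=SlopePair(float(centroid[0]), float(centroid[1])),
        spread=spread,
        mean_so2_percent=mean_so2,
        reference_point=ref,
        distance=distance,
        ratio=distance / spread,
        n_members=len(pairs),
    )


@dataclass(frozen=True)
class MetricPlotData:
    """Plot-ready content of a metric plot.

    ``reference_xy`` / ``reference_so2`` describe the reference polyline with
    its per-point SO2 color values; ``member_xy`` / ``member_so2`` the measured
    slope pairs colored by clamped fitted SO2.  ``stats`` is None for an empty
    member list and for the reduced plot (no reference comparison).
    """

    reference_xy: np.ndarray | None
    reference_so2: np.ndarray | None
    member_xy: np.ndarray
    member_so2: np.ndarray
    stats: ClusterStats | None


def metric_plot_data(
    pairs: Sequence[SlopePair],
    fitted_so2: Sequence[float],
    line: ReferenceLine | None,
    table: ChromophoreTable | None = None,
    grid: "WavelengthGrid | np.ndarray" = DEFAULT_GRID,
) -> MetricPlotData:
    """Assemble the metric plot: reference line, member circles, statistics.

    Pass ``line=None`` for the *reduced* metric plot used on uncorrected
    spectra: members only, no reference line and no distance/ratio annotation
    (trend uniformity is then the only readable quantity).
    """
    member_xy = (
        np.array([[p.m1, p.m2] for p in pairs]) if len(pairs) else np.empty((0, 2))
    )
    member_so2 = np.clip(np.asarray(fitted_so2, dtype=float), 0.0, 100.0)
    stats = None
    if line is not None and len(pairs) >= 2 and table is not None:
        stats = cluster_stats(pairs, fitted_so2, line, table, grid)
    return MetricPlotData(
        reference_xy=line.as_array() if line is not None else None,
        reference_so2=line.so2_grid_percent if line is not None else None,
        member_xy=member_xy,
        member_so2=member_so2,
        stats=stats,
    )


def plot_metric(
    data: MetricPlotData,
    ax=None,
    cmap: str = "coolwarm",
    annotate: bool = True,
):
    """Render a metric plot (thin matplotlib shim over :func:`metric_plot_data`).

    SO2 colors run from the blue end (0%) to the red end (100%) of ``cmap``.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.2))
    if data.reference_xy is not None:
        ax.plot(
            data.reference_xy[:, 0], data.reference_xy[:, 1],
            color="0.6", lw=0.8, zorder=1,
        )
        ax.scatter(
            data.reference_xy[:, 0], data.reference_xy[:, 1],
            c=data.reference_so2, cmap=cmap, vmin=0, vmax=100,
            s=14, marker="o", zorder=2, label="reference line",
        )
    if data.member_xy.size:
        ax.scatter(
            data.member_xy[:, 0], data.member_xy[:, 1],
            c=data.member_so2, cmap=cmap, vmin=0, vmax=100,
            s=28, edgecolors="k", linewidths=0.4,
            zorder=3, label="OA spectra",
        )
    if annotate and data.stats is not None:
        s = data.stats
        ax.set_title(
            f"mean SO2 = {s.mean_so2_percent:.1f}%   "
            f"distance/spread = {s.ratio:.2f}",
            fontsize=9,
        )
    ax.set_xlabel("m1 (per nm)")
    ax.set_ylabel("m2 (per nm)")
    return ax
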
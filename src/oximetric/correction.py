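"""Fluence modeling, spectral correction, and mu_eff estimation.

OA amplitudes are proportional to absorbed energy, i.e. to absorption times
local light fluence.  Because the fluence decays with depth at a
wavelength-dependent rate, raw OA spectra are spectrally distorted; dividing
each spectrum by the modeled fluence spectrum at the vessel position recovers
the shape of the absorption spectrum (up to a scale absorbed by the fit
amplitude).

The fluence model is the isotropic point-source diffusion approximation for a
semi-infinite homogeneous medium,

    Phi(d) = Phi0 * exp(-mu_eff * d) / d,

with d the Euclidean distance from the irradiation spot on the surface to the
evaluation point and mu_eff the effective attenuation coefficient (mm^-1).
This is the simplest form with the exponential mu_eff dependence that drives
the correction; it is a reconstruction of the diffusion-theory fluence, valid
in the far field only (a near-field guard ``d_min`` rejects evaluation points
close to the source).  Extrapolated-boundary / dipole refinements are not
implemented.

mu_eff is estimated per wavelength from the amplitude decay over multiple
irradiation positions: under the model, ln(amplitude * d) is linear in d with
slope -mu_eff, so an ordinary least-squares line through the
(d, ln(amplitude * d)) points yields the estimate, with a confidence
half-width from the slope's standard error.  Each wavelength is estimated
independently (no spectral smoothing by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .chromophores import Spectrum
from .errors import NearFieldError, ValidationError

__all__ = [
    "FluenceModel",
    "MuEffEstimate",
    "correct_spectrum",
    "estimate_mueff",
    "fluence_at",
    "read_mueff_table",
    "write_mueff_table",
]


@dataclass(frozen=True)
class FluenceModel:
    """Per-wavelength fluence decay in a semi-infinite homogeneous medium.

    ``mu_eff_per_mm`` holds one effective attenuation coefficient per
    measurement wavelength; ``source_positions_mm`` the x-coordinates of the
    irradiation spots on the tissue surface (z = 0).  ``d_min`` guards the
    near field where the point-source approximation breaks down.
    """

    mu_eff_per_mm: np.ndarray
    source_positions_mm: np.ndarray
    d_min_mm: float = 0.5
    geometry: str = "semi-infinite-point-source"
    phi0: float = 1.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_eff_per_mm, dtype=float)
        xs = np.asarray(self.source_positions_mm, dtype=float)
        if mu.ndim != 1 or np.any(mu <= 0):
            raise ValidationError("mu_eff must be strictly positive per wavelength")
        if xs.ndim != 1 or np.unique(xs).size != xs.size:
            raise ValidationError("source positions must be distinct")
        object.__setattr__(self, "mu_eff_per_mm", mu)
        object.__setattr__(self, "source_positions_mm", xs)

    @property
    def n_sources(self) -> int:
        return int(self.source_positions_mm.size)

    @property
    def n_wavelengths(self) -> int:
        return int(self.mu_eff_per_mm.size)

    def distance_mm(self, source_index: int, position_mm) -> float:
        x, z = float(position_mm[0]), float(position_mm[1])
        if z <= 0:
            raise ValidationError("evaluation point must lie inside the tissue (z > 0)")
        return float(np.hypot(x - self.source_positions_mm[source_index], z))


def fluence_at(
    model: FluenceModel,
    source_index: int,
    wavelength_index: int,
    position_mm,
) -> float:
    """Fluence Phi = Phi0 * exp(-mu_eff * d) / d at one point (arbitrary units).

    Strictly decreasing in both the source distance d and mu_eff.  Raises
    :class:`NearFieldError` for d <= d_min.
    """
    d = model.distance_mm(source_index, position_mm)
    if d <= model.d_min_mm:
        raise NearFieldError(
            f"distance {d:.3g} mm <= d_min {model.d_min_mm:g} mm: "
            "point-source model invalid near the source"
        )
    mu = model.mu_eff_per_mm[wavelength_index]
    return float(model.phi0 * np.exp(-mu * d) / d)


def fluence_spectrum_at(
    model: FluenceModel, source_index: int, position_mm, wavelengths_nm
) -> Spectrum:
    """Fluence at one point for every modeled wavelength."""
    vals = np.array(
        [fluence_at(model, source_index, j, position_mm) for j in range(model.n_wavelengths)]
    )
    return Spectrum(wavelengths_nm, vals, label="fluence")


def correct_spectrum(
    raw: Spectrum, model: FluenceModel, source_index: int, position_mm
) -> Spectrum:
    """Divide a raw OA spectrum by the modeled fluence spectrum at one point.

    The overall scale of the result is arbitrary (absorbed by the fit
    amplitude A); only the spectral shape is restored.
    """
    if len(raw) != model.n_wavelengths:
        raise ValidationError(
            f"spectrum has {len(raw)} wavelengths, model has {model.n_wavelengths}"
        )
    phi = fluence_spectrum_at(model, source_index, position_mm, raw.wavelengths_nm)
    return Spectrum(raw.wavelengths_nm, raw.values / phi.values, label=raw.label)


@dataclass(frozen=True)
class MuEffEstimate:
    """mu_eff (mm^-1) with a 95% confidence half-width and regression detail."""

    mu_eff_per_mm: float
    ci_half_width: float
    slope_stderr: float
    n_points: int


def estimate_mueff(amplitudes, distances_mm, confidence: float = 0.95) -> MuEffEstimate:
    """Estimate mu_eff from the amplitude decay over source-to-vessel distance.

    Fits ln(amplitude * d) = a - mu_eff * d by ordinary least squares over
    >= 3 (amplitude, distance) pairs; the confidence half-width is the
    slope's standard error scaled by the two-sided Student-t quantile with
    n - 2 degrees of freedom.
    """
    a = np.asarray(amplitudes, dtype=float)
    d = np.asarray(distances_mm, dtype=float)
    if a.shape != d.shape or a.ndim != 1:
        raise ValidationError("amplitudes and distances must be aligned 1-D arrays")
    if a.size < 3:
        raise ValidationError("need at least 3 (amplitude, distance) pairs")
    if np.any(a <= 0):
        raise ValidationError("amplitudes must be strictly positive")
    if np.unique(d).size < 2:
        raise ValidationError("distances must not all be equal")
    y = np.log(a * d)
    res = _st.linregress(d, y)
    half = 0.0
    if a.size > 3 or res.stderr > 0:
        tcrit = float(_st.t.ppf(0.5 + confidence / 2, a.size - 2))
        half = tcrit * float(res.stderr)
    return MuEffEstimate(
        mu_eff_per_mm=-float(res.slope),
        ci_half_width=half,
        slope_stderr=float(res.stderr),
        n_points=int(a.size),
    )


def write_mueff_table(wavelengths_nm, estimates, path) -> pd.DataFrame:
    """Write mu_eff spectra as columnar text: wavelength_nm, mu_eff_per_mm,
    ci_half_width."""
    df = pd.DataFrame(
        {
            "wavelength_nm": np.asarray(wavelengths_nm, dtype=float),
            "mu_eff_per_mm": [e.mu_eff_per_mm for e in estimates],
            "ci_half_width": [e.ci_half_width for e in estimates],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df


def read_mueff_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    required = {"wavelength_nm", "mu_eff_per_mm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    return df
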
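"""Blood absorption spectra from tabulated oxy-/deoxyhemoglobin absorption.

Whole blood in the 700–900 nm window is treated as a two-chromophore medium:
its absorption coefficient at oxygen saturation ``SO2`` (in percent) is the
convex combination

    mu_a(lambda) = mu_a_HbO2(lambda) * SO2/100 + mu_a_Hb(lambda) * (1 - SO2/100)

of the absorption of fully oxygenated and fully deoxygenated blood.  The two
endpoint spectra are shipped as a packaged table at 150 g/L total hemoglobin;
because every downstream fit carries a free amplitude, only the *shape* of the
table matters, not its absolute scale.

The isosbestic point — the wavelength where both hemoglobin forms absorb
equally, near 800 nm — splits the window into a left branch (dominated by the
deoxyhemoglobin peak at 760 nm) and a right branch (oxyhemoglobin rising
toward 890 nm), which is what the slope-pair metric exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import CoverageError, IsosbesticNotFoundError, ValidationError

__all__ = [
    "DEFAULT_GRID",
    "ChromophoreTable",
    "Spectrum",
    "WavelengthGrid",
    "blood_absorption",
    "find_isosbestic",
    "load_default_table",
]

#: Measurement wavelength grid (nm): three wavelengths left and three right of
#: the ~800 nm isosbestic point, plus the isosbestic point itself.
DEFAULT_GRID: np.ndarray = np.array([740.0, 760.0, 780.0, 800.0, 830.0, 860.0, 890.0])

_FIXTURE_NAME = "hb_absorption_150gL.tsv"


def _as_grid(values_nm: "WavelengthGrid | Sequence[float] | np.ndarray") -> np.ndarray:
    if isinstance(values_nm, WavelengthGrid):
        return values_nm.values_nm
    arr = np.asarray(values_nm, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValidationError("wavelength grid must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("wavelength grid contains non-finite values")
    if np.any(np.diff(arr) <= 0):
        raise ValidationError("wavelength grid must be strictly increasing")
    return arr


@dataclass(frozen=True)
class WavelengthGrid:
    """An ordered set of measurement wavelengths in nm (strictly increasing, M >= 3)."""

    values_nm: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values_nm, dtype=float)
        if arr.ndim != 1 or arr.size < 3:
            raise ValidationError("a wavelength grid needs at least 3 wavelengths")
        if np.any(np.diff(arr) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values_nm", arr)

    def __len__(self) -> int:
        return int(self.values_nm.size)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.values_nm, dtype=dtype)


@dataclass(frozen=True)
class Spectrum:
    """One value per wavelength: an OA spectrum, a blood absorption spectrum,
    or a mu_eff spectrum.  Units depend on context (mm^-1 for absorption and
    attenuation spectra, arbitrary for OA amplitudes, dimensionless after
    mean-normalization)."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        lam = _as_grid(self.wavelengths_nm)
        val = np.asarray(self.values, dtype=float)
        if val.shape != lam.shape:
            raise ValidationError(
                f"spectrum has {val.size} values for {lam.size} wavelengths"
            )
        if not np.all(np.isfinite(val)):
            raise ValidationError("spectrum values must be finite")
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "values", val)

    def __len__(self) -> int:
        return int(self.values.size)

    def scaled(self, k: float) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, self.values * float(k), self.label)


@dataclass(frozen=True)
class ChromophoreTable:
    """Tabulated whole-blood absorption (mm^-1) of the two hemoglobin endpoints.

    ``mu_a_hbo2`` is fully oxygenated blood, ``mu_a_hb`` fully deoxygenated;
    both are indexed by ``wavelengths_nm``.  Linear interpolation is used
    between table wavelengths.
    """

    wavelengths_nm: np.ndarray
    mu_a_hbo2: np.ndarray
    mu_a_hb: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        oxy = np.asarray(self.mu_a_hbo2, dtype=float)
        deoxy = np.asarray(self.mu_a_hb, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValidationError("chromophore table needs at least 2 wavelengths")
        if oxy.shape != lam.shape or deoxy.shape != lam.shape:
            raise ValidationError("chromophore table columns have mismatched lengths")
        if np.any(np.diff(lam) <= 0):
            raise ValidationError("table wavelengths must be strictly increasing")
        if np.any(oxy <= 0) or np.any(deoxy <= 0):
            raise ValidationError("absorption coefficients must be strictly positive")
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "mu_a_hbo2", oxy)
        object.__setattr__(self, "mu_a_hb", deoxy)

    @property
    def coverage_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def _check_coverage(self, grid: np.ndarray) -> None:
        lo, hi = self.coverage_nm
        if grid[0] < lo or grid[-1] > hi:
            raise CoverageError(
                f"grid [{grid[0]:g}, {grid[-1]:g}] nm outside table coverage "
                f"[{lo:g}, {hi:g}] nm"
            )

    def interp_hbo2(self, grid) -> np.ndarray:
        g = _as_grid(grid)
        self._check_coverage(g)
        return np.interp(g, self.wavelengths_nm, self.mu_a_hbo2)

    def interp_hb(self, grid) -> np.ndarray:
        g = _as_grid(grid)
        self._check_coverage(g)
        return np.interp(g, self.wavelengths_nm, self.mu_a_hb)


def load_default_table() -> ChromophoreTable:
    """Load the packaged whole-blood absorption table (150 g/L THb)."""
    source = ""
    rows = []
    text = (
        resources.files("oximetric.data").joinpath(_FIXTURE_NAME).read_text("utf-8")
    )
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            source += line.lstrip("# ") + " "
            continue
        parts = line.split("\t")
        rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
    arr = np.array(rows)
    return ChromophoreTable(arr[:, 0], arr[:, 1], arr[:, 2], source.strip())


def blood_absorption(
    table: ChromophoreTable,
    so2_percent: float,
    grid: "WavelengthGrid | Sequence[float] | np.ndarray" = DEFAULT_GRID,
) -> Spectrum:
    """Absorption spectrum of whole blood at saturation ``so2_percent``.

    Linear combination of the two endpoint spectra, interpolated onto ``grid``.
    ``so2_percent`` must lie in [0, 100].
    """
    s = float(so2_percent)
    if not np.isfinite(s):
        raise ValidationError("so2_percent must be finite")
    if not 0.0 <= s <= 100.0:
        raise ValidationError(f"so2_percent={s:g} outside [0, 100]")
    g = _as_grid(grid)
    frac = s / 100.0
    mu = table.interp_hbo2(g) * frac + table.interp_hb(g) * (1.0 - frac)
    return Spectrum(g, mu, label=f"blood SO2={s:g}%")


def find_isosbestic(
    table: ChromophoreTable,
    window_nm: tuple[float, float] = (770.0, 830.0),
    step_nm: float = 0.1,
) -> float:
    """Wavelength (nm) where oxy- and deoxyhemoglobin absorption coincide.

    The difference mu_a_HbO2 - mu_a_Hb is linearly interpolated on a dense grid
    inside ``window_nm``; the wavelength minimizing its absolute value is
    returned (smallest wavelength on ties).  A difference that never touches or
    crosses zero inside the window raises :class:`IsosbesticNotFoundError`.
    """
    lo, hi = float(window_nm[0]), float(window_nm[1])
    if not lo < hi:
        raise ValidationError("window_nm must be an increasing interval")
    table._check_coverage(np.array([lo, hi]))
    dense = np.arange(lo, hi + step_nm / 2, step_nm)
    diff = table.interp_hbo2(dense) - table.interp_hb(dense)
    if np.min(diff) > 0 or np.max(diff) < 0:
        raise IsosbesticNotFoundError(
            f"mu_a_HbO2 - mu_a_Hb does not change sign in [{lo:g}, {hi:g}] nm"
        )
    return float(dense[int(np.argmin(np.abs(diff)))])
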
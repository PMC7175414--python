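"""Least-squares SO2 fit of blood absorption spectra to measured OA spectra.

The fit function is

    y(lambda) = A * [ mu_a_HbO2(lambda) * SO2/100 + mu_a_Hb(lambda) * (1 - SO2/100) ]

with the saturation ``SO2`` (percent) and an amplitude ``A`` as the two free
parameters.  ``A`` absorbs the unknown scaling of OA amplitudes (system
impulse response, vessel orientation, fluence magnitude), so only the spectral
shape informs the SO2.

Although the model is nonlinear in (SO2, A), it spans exactly the linear space
c1 * mu_a_HbO2 + c2 * mu_a_Hb.  The fit is therefore solved globally and
exactly by unconstrained linear least squares in (c1, c2), followed by the
reparametrization A = c1 + c2, SO2 = 100 * c1 / (c1 + c2).

The fit is deliberately UNCONSTRAINED: SO2 may leave [0, 100].  The raw value
is preserved (clamping would hide exactly the unreliability this package is
built to expose) and a clamped copy is provided for display and coloring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chromophores import ChromophoreTable, Spectrum
from .errors import DegenerateFitError, ValidationError

__all__ = ["FitResult", "fit_so2", "fit_so2_batch", "read_spectra_table", "write_fit_table"]

# |c1 + c2| below this (relative to the coefficient norm) has no defined SO2
_DEGENERATE_REL_TOL = 1e-12


@dataclass(frozen=True)
class FitResult:
    """Outcome of a two-parameter blood-spectrum fit.

    ``so2_percent`` is the raw (unconstrained) estimate; ``clamped_so2_percent``
    clips it to [0, 100] for display.  ``negative_scale`` flags a fitted
    amplitude A < 0, which is physically impossible for a real OA signal and
    diagnostic of a spectrum that anticorrelates with every blood spectrum.
    ``error`` is set (and the numeric fields are NaN) for failed entries in a
    batch fit.
    """

    so2_percent: float
    scale_a: float
    residuals: np.ndarray
    chi2: float
    negative_scale: bool = False
    error: str | None = None

    @property
    def clamped_so2_percent(self) -> float:
        return float(np.clip(self.so2_percent, 0.0, 100.0))

    @property
    def ok(self) -> bool:
        return self.error is None


def fit_so2(spectrum: Spectrum, table: ChromophoreTable) -> FitResult:
    """Fit SO2 and amplitude to one spectrum by exact linear least squares."""
    lam = spectrum.wavelengths_nm
    y = spectrum.values
    if lam.size < 3:
        raise ValidationError("need at least 3 wavelengths for a two-parameter fit")
    if not np.any(y != 0.0):
        raise ValidationError("cannot fit an identically zero spectrum")
    basis = np.column_stack([table.interp_hbo2(lam), table.interp_hb(lam)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    c1, c2 = float(coef[0]), float(coef[1])
    total = c1 + c2
    if abs(total) <= _DEGENERATE_REL_TOL * max(abs(c1), abs(c2), 1e-300):
        raise DegenerateFitError(
            "c1 + c2 = 0: the fitted direction has no defined saturation"
        )
    model = basis @ coef
    resid = y - model
    return FitResult(
        so2_percent=100.0 * c1 / total,
        scale_a=total,
        residuals=resid,
        chi2=float(resid @ resid),
        negative_scale=total < 0,
    )


def fit_so2_batch(
    spectra: Sequence[Spectrum], table: ChromophoreTable
) -> list[FitResult]:
    """Fit every spectrum independently; failures are recorded per element.

    Order is preserved; a failed element carries NaN fields and its error
    message instead of aborting the batch.
    """
    if len(spectra) == 0:
        raise ValidationError("fit_so2_batch requires at least one spectrum")
    out: list[FitResult] = []
    for spec in spectra:
        try:
            out.append(fit_so2(spec, table))
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            n = len(spec)
            out.append(
                FitResult(
                    so2_percent=float("nan"),
                    scale_a=float("nan"),
                    residuals=np.full(n, np.nan),
                    chi2=float("nan"),
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return out


def read_spectra_table(path) -> list[Spectrum]:
    """Read columnar text: first column wavelength_nm, one spectrum per
    remaining column.  Lines starting with '#' are comments."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] < 2:
        raise ValidationError(
            f"{path}: expected a wavelength column plus at least one spectrum"
        )
    lam = df.iloc[:, 0].to_numpy(dtype=float)
    return [
        Spectrum(lam, df.iloc[:, k].to_numpy(dtype=float), label=str(df.columns[k]))
        for k in range(1, df.shape[1])
    ]


def write_fit_table(results: Sequence[FitResult], path) -> pd.DataFrame:
    """Write per-spectrum SO2 / A / chi2 as whitespace-delimited text."""
    df = pd.DataFrame(
        {
            "so2_percent": [r.so2_percent for r in results],
            "clamped_so2_percent": [r.clamped_so2_percent for r in results],
            "scale_a": [r.scale_a for r in results],
            "chi2": [r.chi2 for r in results],
            "error": [r.error or "" for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df
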
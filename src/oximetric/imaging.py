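"""From multispectral OA image stacks to per-pixel spectra.

A measurement is a stack of N x M envelope images (N irradiation positions,
M wavelengths).  Vessel positions drift between acquisitions, so the images
are first rigidly re-aligned on manually identified vessel centers.  The
pixels attributed to a vessel — its *support* — are then segmented by a 1/e
threshold relative to the maximum inside a region of interest, and only
pixels that belong to the support at every wavelength enter the spectral
analysis.  Finally, one spectrum per retained pixel is read out across the
wavelength images, optionally divided by the recorded per-wavelength average
pulse energies to remove laser-output variations.

Coordinate convention: row = z (depth, increasing downward from the
transducer/tissue surface), col = x; indices are 0-based; physical positions
in mm are measured from the array origin, ``x = col * dx``, ``z = row * dz``.
Image shifts are integer-pixel (envelope images at this pitch do not justify
sub-pixel resampling, and integer shifts are lossless away from the margins).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .chromophores import Spectrum, _as_grid
from .errors import ConfigError, DegenerateSpectrumError, ValidationError

__all__ = [
    "DEFAULT_PIXEL_PITCH_MM",
    "OAImageStack",
    "Support",
    "align_centers",
    "extract_pixel_spectra",
    "intersect_supports",
    "load_stack",
    "save_stack",
    "segment_support",
    "suggest_center",
]

#: (dx, dz) in mm: lateral and axial pixel pitch of the reconstructed images.
DEFAULT_PIXEL_PITCH_MM: tuple[float, float] = (0.149, 0.077)


@dataclass(frozen=True)
class OAImageStack:
    """N x M stack of 2-D envelope images with acquisition metadata.

    ``images`` has shape (N, M, rows, cols): N irradiation positions by M
    wavelengths.  ``pulse_energy`` (optional, one value per wavelength)
    enables correction of wavelength-dependent laser output.  ``shifts``
    records integer (drow, dcol) applied per image by :func:`align_centers`.
    """

    images: np.ndarray
    grid: np.ndarray
    source_positions_mm: np.ndarray
    pixel_pitch_mm: tuple[float, float] = DEFAULT_PIXEL_PITCH_MM
    pulse_energy: np.ndarray | None = None
    shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.images, dtype=float)
        if img.ndim != 4:
            raise ValidationError("images must be a (N, M, rows, cols) array")
        g = _as_grid(self.grid)
        xs = np.asarray(self.source_positions_mm, dtype=float)
        n, m = img.shape[:2]
        if m != g.size:
            raise ValidationError(f"{m} wavelength images but {g.size} wavelengths")
        if m < 3:
            raise ValidationError("need at least 3 wavelengths")
        if n < 1 or xs.size != n:
            raise ValidationError(f"{n} irradiation images but {xs.size} positions")
        dx, dz = self.pixel_pitch_mm
        if dx <= 0 or dz <= 0:
            raise ValidationError("pixel pitches must be positive")
        if self.pulse_energy is not None:
            pe = np.asarray(self.pulse_energy, dtype=float)
            if pe.size != m or np.any(pe <= 0):
                raise ValidationError("pulse_energy needs one positive value per wavelength")
            object.__setattr__(self, "pulse_energy", pe)
        object.__setattr__(self, "images", img)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "source_positions_mm", xs)

    @property
    def n_positions(self) -> int:
        return int(self.images.shape[0])

    @property
    def n_wavelengths(self) -> int:
        return int(self.images.shape[1])

    @property
    def shape_px(self) -> tuple[int, int]:
        return tuple(self.images.shape[2:])

    def pixel_to_mm(self, row: float, col: float) -> tuple[float, float]:
        dx, dz = self.pixel_pitch_mm
        return (col * dx, row * dz)


@dataclass(frozen=True)
class Support:
    """Pixels attributed to one vessel in one image.

    ``pixel_indices`` is the set of (row, col) pairs inside ``roi`` whose
    intensity is >= ``threshold_value`` (1/e of the ROI maximum, inclusive
    comparison for determinism at ties); ``center_mm`` is the
    intensity-weighted centroid in physical coordinates.
    """

    pixel_indices: frozenset
    roi: tuple[int, int, int, int]
    threshold_value: float
    center_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.pixel_indices:
            raise ValidationError("support must be non-empty")
        r0, r1, c0, c1 = self.roi
        for r, c in self.pixel_indices:
            if not (r0 <= r < r1 and c0 <= c < c1):
                raise ValidationError(f"support pixel ({r}, {c}) outside ROI {self.roi}")

    def __len__(self) -> int:
        return len(self.pixel_indices)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        idx = np.array(sorted(self.pixel_indices))
        m[idx[:, 0], idx[:, 1]] = True
        return m


def _shift_zero_fill(image: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    out = np.zeros_like(image)
    rows, cols = image.shape
    src_r = slice(max(0, -drow), min(rows, rows - drow))
    dst_r = slice(max(0, drow), min(rows, rows + drow))
    src_c = slice(max(0, -dcol), min(cols, cols - dcol))
    dst_c = slice(max(0, dcol), min(cols, cols + dcol))
    out[dst_r, dst_c] = image[src_r, src_c]
    return out


def align_centers(stack: OAImageStack, centers: np.ndarray) -> OAImageStack:
    """Motion correction: shift every image so all vessel centers coincide.

    ``centers`` has shape (N, M, 2) with one manually identified (row, col)
    vessel center per image.  Each image is translated by the integer-pixel
    shift taking its center onto the reference center (the center of the
    first image, rounded); vacated margins are zero-filled and the applied
    shifts are recorded on the returned stack.
    """
    ctr = np.asarray(centers, dtype=float)
    n, m = stack.n_positions, stack.n_wavelengths
    if ctr.shape != (n, m, 2):
        raise ValidationError(f"centers must have shape ({n}, {m}, 2)")
    rows, cols = stack.shape_px
    if np.any(ctr[..., 0] < 0) or np.any(ctr[..., 0] > rows - 1) or np.any(
        ctr[..., 1] < 0
    ) or np.any(ctr[..., 1] > cols - 1):
        raise ValidationError("a vessel center lies outside the image bounds")
    ref = np.round(ctr[0, 0]).astype(int)
    shifts = np.zeros((n, m, 2), dtype=int)
    aligned = np.empty_like(stack.images)
    for i in range(n):
        for j in range(m):
            drow, dcol = (ref - np.round(ctr[i, j]).astype(int)).tolist()
            shifts[i, j] = (drow, dcol)
            aligned[i, j] = _shift_zero_fill(stack.images[i, j], drow, dcol)
    return replace(stack, images=aligned, shifts=shifts)


def segment_support(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    pixel_pitch_mm: tuple[float, float] = DEFAULT_PIXEL_PITCH_MM,
) -> Support:
    """Segment the vessel support by 1/e-of-maximum thresholding in a ROI.

    ``roi`` is a half-open rectangle (row0, row1, col0, col1).  The threshold
    is max(ROI) / e; pixels with intensity >= threshold form the support.
    """
    img = np.asarray(image, dtype=float)
    r0, r1, c0, c1 = (int(v) for v in roi)
    if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
        raise ValidationError(f"ROI {roi} invalid for image of shape {img.shape}")
    sub = img[r0:r1, c0:c1]
    peak = float(sub.max())
    if peak <= 0:
        raise DegenerateSpectrumError("ROI maximum is not positive; nothing to segment")
    thr = peak / np.e
    rr, cc = np.nonzero(sub >= thr)
    rows = rr + r0
    cols = cc + c0
    w = img[rows, cols]
    dx, dz = pixel_pitch_mm
    center_mm = (float((cols * w).sum() / w.sum() * dx), float((rows * w).sum() / w.sum() * dz))
    return Support(
        pixel_indices=frozenset(zip(rows.tolist(), cols.tolist())),
        roi=(r0, r1, c0, c1),
        threshold_value=thr,
        center_mm=center_mm,
    )


def intersect_supports(supports: Sequence[Support]) -> frozenset:
    """Pixels belonging to the support at every wavelength (set intersection).

    An empty intersection is a valid outcome (the vessel was lost at some
    wavelength); it is returned as an empty set with a warning.
    """
    if len(supports) < 1:
        raise ValidationError("need at least one support")
    common = frozenset(supports[0].pixel_indices)
    for s in supports[1:]:
        common &= s.pixel_indices
    if not common:
        warnings.warn("support intersection is empty", stacklevel=2)
    return common


def extract_pixel_spectra(
    stack: OAImageStack,
    pixels: Sequence[tuple[int, int]],
    source_index: int,
    energy_normalize: bool | None = None,
) -> list[Spectrum]:
    """One spectrum per pixel at one irradiation position.

    The value at wavelength j is the envelope intensity of image (i, j) at
    the pixel, divided by the recorded average pulse energy at j when
    energies are available (``energy_normalize=None`` auto-enables this).
    Pixels are processed in sorted order for determinism.
    """
    if energy_normalize is None:
        energy_normalize = stack.pulse_energy is not None
    if energy_normalize and stack.pulse_energy is None:
        raise ConfigError("energy normalization requested but no pulse energies recorded")
    rows, cols = stack.shape_px
    px = sorted(set((int(r), int(c)) for r, c in pixels))
    if not px:
        raise ValidationError("empty pixel set")
    for r, c in px:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValidationError(f"pixel ({r}, {c}) outside image of shape {(rows, cols)}")
    cube = stack.images[source_index]  # (M, rows, cols)
    energies = stack.pulse_energy if energy_normalize else np.ones(stack.n_wavelengths)
    out = []
    for r, c in px:
        vals = cube[:, r, c] / energies
        out.append(Spectrum(stack.grid, vals, label=f"pixel ({r}, {c})"))
    return out


def suggest_center(image: np.ndarray, roi: tuple[int, int, int, int]) -> tuple[float, float]:
    """Suggested vessel center: intensity-weighted centroid of the brightest
    connected region of the 1/e support inside the ROI.

    This is an aid for manual center identification, not an automated
    segmentation claim; returns fractional (row, col).
    """
    from scipy import ndimage

    img = np.asarray(image, dtype=float)
    r0, r1, c0, c1 = (int(v) for v in roi)
    sub = img[r0:r1, c0:c1]
    peak = float(sub.max())
    if peak <= 0:
        raise DegenerateSpectrumError("ROI maximum is not positive")
    labels, nlab = ndimage.label(sub >= peak / np.e)
    sums = ndimage.sum_labels(sub, labels, index=range(1, nlab + 1))
    best = int(np.argmax(sums)) + 1
    mask = labels == best
    w = np.where(mask, sub, 0.0)
    rr, cc = np.mgrid[0:sub.shape[0], 0:sub.shape[1]]
    total = w.sum()
    return (float((rr * w).sum() / total) + r0, float((cc * w).sum() / total) + c0)


def save_stack(stack: OAImageStack, path) -> None:
    """Write a stack to an HDF5 container (images + JSON-encoded metadata)."""
    import h5py

    meta = {
        "grid_nm": np.asarray(stack.grid).tolist(),
        "source_positions_mm": stack.source_positions_mm.tolist(),
        "pixel_pitch_mm": list(stack.pixel_pitch_mm),
        "pulse_energy": None if stack.pulse_energy is None else stack.pulse_energy.tolist(),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=stack.images)
        if stack.shifts is not None:
            f.create_dataset("shifts", data=stack.shifts)
        f.attrs["meta"] = json.dumps(meta)


def load_stack(path) -> OAImageStack:
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        images = f["images"][...]
        shifts = f["shifts"][...] if "shifts" in f else None
    return OAImageStack(
        images=images,
        grid=np.asarray(meta["grid_nm"], dtype=float),
        source_positions_mm=np.asarray(meta["source_positions_mm"], dtype=float),
        pixel_pitch_mm=tuple(meta["pixel_pitch_mm"]),
        pulse_energy=None
        if meta["pulse_energy"] is None
        else np.asarray(meta["pulse_energy"], dtype=float),
        shifts=shifts,
    )
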
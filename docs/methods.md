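# Methods

## Two-chromophore model and fit

Whole blood in the 740–890 nm window is modeled as a convex combination of
fully oxygenated and fully deoxygenated blood:
μa(λ) = μa,HbO₂(λ)·s + μa,Hb(λ)·(1−s), s = SO₂/100. The packaged endpoint
table (`oximetric/data/hb_absorption_150gL.tsv`) is transcribed from the
widely reproduced NIR molar-extinction compilation for human hemoglobin at
10 nm spacing and converted to whole-blood absorption at an assumed total
hemoglobin concentration of 150 g/L (conversion constants in the file
header). The absolute scale is immaterial — the fit amplitude A absorbs any
global factor — so only the spectral shape carries information. Linear
interpolation is used between table wavelengths; the table is dense enough
that higher-order schemes change nothing testable.

The fit y(λ) = A·μa(λ; SO₂) is solved exactly: the model spans the linear
space c₁·μa,HbO₂ + c₂·μa,Hb, so an unconstrained linear least-squares solve
for (c₁, c₂) followed by A = c₁+c₂, SO₂ = 100·c₁/(c₁+c₂) is the global
optimum (verified in the tests against an exhaustive SO₂ grid search with
closed-form per-step amplitude). The fit is deliberately unconstrained: raw
SO₂ may leave [0, 100], and clamping happens only in display copies. Hiding
out-of-range values would mask exactly the unreliability the metric is meant
to expose. A fitted A < 0 is reported with a flag rather than rejected. The
full 7-wavelength grid, including 740 nm, enters the SO₂ fit; c₁+c₂ = 0 is a
degenerate direction with no defined saturation and raises.

## Slope-pair metric

Each spectrum is divided by its mean over the measurement wavelengths, then
two ordinary least-squares lines are fitted through the subsets
{760, 780, 800} nm and {800, 830, 860, 890} nm, giving the pair (m₁, m₂) in
units of per nm. 740 nm is excluded from the slope subsets because blood
spectra stop being approximately linear below ~760 nm. The reference line is
built with the *same* normalization (over the measurement grid, not the full
tabulated range) so that measured and reference pairs are commensurable; it
is stored at 1% SO₂ steps for plotting, but the reference point used in the
cluster statistic is always computed freshly at the exact (clamped) mean
fitted SO₂, never interpolated from the stored grid.

Cluster statistics: centroid (componentwise mean), spread (mean Euclidean
distance of members from the centroid), distance (mean Euclidean distance
from the reference point), ratio = distance/spread. Distances are plain
Euclidean with equally weighted axes — both slopes have the same units after
normalization, and nothing in the construction motivates an axis weighting.
The mean fitted SO₂ is clamped to [0, 100] before evaluating the reference
point because blood spectra are undefined outside that range. A cluster with
numerically zero spread (< 1e-12) raises instead of returning an infinite
ratio: it cannot arise from real noisy data, and an exception is more honest
than a sentinel. No acceptance threshold on the ratio is built in; defining
one would require population statistics the package cannot supply, so the
default is report-only with an optional user-set threshold in `RunConfig`.

The *reduced* metric analysis (CLI flag `--no-reference`) drops the
reference-line comparison and reports spread only. It is the right tool for
uncorrected spectra, where there is no reason to expect blood-like trends:
tight clustering then certifies motion correction and segmentation, nothing
more.

## Fluence model and μ_eff estimation

The fluence is the isotropic point-source diffusion approximation for a
semi-infinite homogeneous medium, Φ(d) = Φ₀·exp(−μ_eff·d)/d, with d the
Euclidean distance from the irradiation spot (on the surface, z = 0) to the
evaluation point. This is the simplest form carrying the exponential μ_eff
dependence that makes fluence errors amplify exponentially with distance in
corrected spectra (a corrected value is multiplied by exp(δ·d) when μ_eff is
off by δ). Extrapolated-boundary/dipole refinements are intentionally not
implemented; a near-field guard (default d_min = 0.5 mm) rejects evaluation
points where the approximation is meaningless. Spectral correction is
pixelwise division of the OA spectrum by the modeled fluence spectrum,
evaluated at the motion-corrected support centroid.

μ_eff is estimated per wavelength independently (no spectral smoothing, so
estimation errors remain visible rather than being painted over) from the
amplitude decay across irradiation positions: under the model,
ln(amplitude·d) is linear in d with slope −μ_eff, estimated by OLS with a
95% Student-t confidence half-width from the slope's standard error. This
linearization is this package's own simplified estimator for
multi-irradiation sensing; it does not segment the tissue into multiple
quasi-homogeneous regions or jointly weight positions.

## Imaging chain

Supports are segmented by thresholding at 1/e of the ROI maximum, with an
inclusive (≥) comparison so exact-equality pixels are handled
deterministically, which also makes segmentation invariant under intensity
scaling. Motion correction shifts each image by an integer pixel count so
that all manually identified vessel centers coincide with the center of the
first image; shifts are lossless away from the zero-filled margins and are
recorded in metadata. Sub-pixel resampling is not used — envelope images at
0.149 × 0.077 mm pitch do not justify it. Vessel centers are an input (an
intensity-weighted-centroid helper offers suggestions; automated centering
is not claimed). Per-pixel spectra are taken only on the intersection of the
supports across all wavelengths — pixels that lose support at any wavelength
carry fewer spectral points than the already-minimal 7 and are excluded.
Pulse-energy normalization divides each spectrum by the recorded
per-wavelength average pulse energy; it applies at spectrum extraction,
which is equivalent to applying it earlier because segmentation is
scale-invariant.

## Synthetic generators

All generators are pure functions of (parameters, seed) and bit-identical on
rerun. Defaults:

- Noise: additive Gaussian, σ = 0.1 relative to the clean-spectrum mean
  (SNR 10), a stand-in for the in-vivo image SNR, which is not known
  precisely. Noise-only spectra sit on a constant offset of 1 so that mean
  normalization is defined.
- Cluster size: 100 spectra, a stand-in for the typical pixel count of one
  vessel support.
- Phantom scene: an artery-like vessel (SO₂ 98%, radius 1.0 mm) at 12 mm
  depth and a vein-like vessel (SO₂ 70%, radius 1.25 mm) at 8 mm, imaged on
  a 180 × 120 raster at the native pitch; 20 irradiation positions stepped
  0.5 mm along the surface; medium μ_eff falling linearly from 0.45 to
  0.28 mm⁻¹ across the grid (inside the 0.1–1 mm⁻¹ range reported for human
  tissue). Vessels are hard disks convolved with a Gaussian point-spread of
  0.5 mm FWHM. Motion is emulated as a shared integer-pixel jitter of ±2 px
  per image; the fluence is evaluated at the nominal vessel center (jitter
  models apparent in-image motion, not a change of illumination geometry).
  Pixel noise std is σ times the peak of that image's noiseless vessel
  contribution, so peak SNR is 1/σ at every wavelength. The default
  background level is 0 — in envelope images the background is
  noise-dominated, and the additive Gaussian noise supplies it; negative
  pixels are kept rather than clipped to preserve noise symmetry.

What the phantom does *not* emulate: acoustic propagation and the system
impulse response (absorbed into a per-vessel intensity scalar), speckle and
the Rician statistics of real envelope noise, depth-dependent resolution
loss, tissue heterogeneity and layered skin optics, and out-of-plane motion.
Passing tests on the phantom therefore demonstrate the correctness and
discrimination behavior of the analysis chain under its own model
assumptions, not in-vivo performance.

## Problem sizes and numerical choices

The standard experiments run at: 100 noisy arterial spectra (fit recovery
and cluster placement), 200 noise spectra (plausibility fraction), 1000
isotropic slope pairs (ideal-ratio limit, which approaches 1 with the
finite-sample excess of order 1/n), 500 Monte-Carlo replicates for μ_eff
bias/coverage, and the full 20-position two-vessel phantom for the
end-to-end discrimination check (true μ_eff versus a ±50% alternating
per-wavelength perturbation — near-ideal ratio versus severalfold
inflation). Tie-breaks: the isosbestic finder returns the smallest
wavelength among minima of |μa,HbO₂ − μa,Hb| on a 0.1 nm interpolated grid,
and requires the difference to touch or cross zero in the window (identical
curves therefore return the left window edge). Empty support intersections
are a valid, warned outcome. An empty spectrum, zero-mean normalization
input, or degenerate fit direction raises a typed exception rather than
propagating NaNs; batch fits record per-element failures and continue.

## Known limitations

The fluence model ignores boundary effects and tissue layering; μ_eff
estimation assumes one quasi-homogeneous segment per vessel; the metric
detects trend mismatch around the isosbestic point but cannot certify
absolute accuracy of SO₂ (a correct trend with a wrong amplitude calibration
is invisible to it); and slope pairs from spectra with near-zero mean are
numerically fragile (guarded by the degenerate-spectrum error).
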
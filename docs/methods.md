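# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic phantoms do and do not show.

## Conventions

Intensities are float64 in [0, 1] from ingest onward (8-bit files are
divided by 255); every equation operates on this scale. Coordinates
are 0-based, row-major (row, col). Binary maps are boolean arrays with
True = vessel / inside-FOV.

## CLAHE

Implemented directly (tile histograms → clip → redistribute → rank map
→ bilinear blend) rather than via a library call, because the package
exposes and tests the equation-level pieces: `clip_histogram` conserves
total mass exactly (the clipped excess is spread evenly over all bins),
the per-tile map is the clipped-histogram CDF and is therefore
monotone, and the output is confined to a configurable range
[i₁, i₂] (default [0, 1]).

Choices the standard description leaves open:

* **Clip limit** β is a fraction of the tile pixel count: each bin is
  clipped at β·m² counts. β = 1 disables clipping and a single tile
  then reduces to classical global histogram equalization (verified in
  tests against a direct rank oracle).
* **Tile geometry.** The conventional parameterization "75 × 75" is
  read as the tile size in pixels (giving an ~8×8 grid on DRIVE-sized
  images); `tile_units="grid"` selects the other reading. An
  8-pixel tile grid would amplify noise far beyond what enhanced
  fundus images show, which is why pixels is the default.
* **Tile blending** is bilinear between tile centers; hard tile
  boundaries produce visible seams that enhanced fundus images do not
  show.
* 256 histogram bins; even-sized smoothing windows are anchored at the
  top-left pixel of the window with symmetric (reflect) padding.

The "adaptive filter" smoothing variant is the local Wiener noise
filter (shrink toward the local mean in proportion to how much the
local variance exceeds the global noise estimate) with a 4×4 window —
the standard meaning of the term in image-processing toolchains.

## Phase congruency

Computed per orientation from quadrature pairs of log-Gabor filters
(radial transfer exp(−ln²(f/f_t)/(2 ln² σ_f)), zero at DC, Gaussian
angular spread, a high-order Butterworth lowpass at 0.45 cycles/pixel
against Nyquist wrap). Defaults are the DRIVE-tuned set (4 scales, 6
orientations, smallest wavelength 3 px, scale multiplier 2.1,
σ_f = 0.55, angular ratio 1.2, k = 2.3, cutOff = 0.5, g = 10);
`PhaseCongParams.stare()` carries the STARE-tuned set (3 scales, 5
orientations, wavelength 2.5, multiplier 2.9, σ_f = 1.5, ratio 1.7,
k = 3, g = 14). Config files accept the conventional camelCase names
verbatim.

Numerical choices:

* **Phase deviation measure.** Δφ defaults to
  cos(φ − φ̄) − |sin(φ − φ̄)|, the sensitive measure; plain cos is
  selectable (`phase_measure="cos"`). On an ideal step edge the
  default localizes the response ~4.7× above the value three pixels
  away; plain cos only ~2.2×.
* **Noise floor.** The smallest-scale amplitude distribution is
  treated as Rayleigh; its scale is estimated from the median
  (τ = median/√ln 4), summed over scales geometrically, and the floor
  is T = τ_total(√(π/2) + k√((4−π)/2)). k = 0 disables suppression.
* ε (final-denominator regularizer) defaults to 1e−4 and is the only
  user-facing regularizer; the per-orientation energy normalization
  uses a fixed 1e−12 guard so that increasing ε strictly decreases PC.
* **Boundaries.** The image is mirrored to twice its size
  (even-symmetric extension) before the FFT, so the periodic extension
  is continuous and no frame-edge response leaks into the map.
* PC is polarity-insensitive; dark vessels and bright vessels produce
  the same map, so no inversion step exists.

## Threshold selection

* **Otsu** maximizes σ_b² over all cuts, smallest maximizing cut on
  ties. Ties are detected with a 1e−12 relative tolerance because runs
  of empty bins make σ_b² mathematically constant while floating-point
  evaluation orders differ. The decomposition σ² = σ_w² + σ_b² is
  exposed (`variance_decomposition`) and holds to 1e−9 on every tested
  histogram.
* **ISODATA** starts at the global mean (configurable), iterates the
  intermeans update with tolerance half a bin width, reuses the
  previous partition mean if a side empties, caps at 500 iterations,
  and returns the iterate whose own update moved less than the
  tolerance — so the returned value is a fixed point by construction.
* **IDM/GLCM.** Co-occurrence matrices are accumulated by explicit
  integer offsets — (0, d), (−d, d), (−d, 0), (−d, −d) for
  0°/45°/90°/135° — counting both ±displacements (symmetric matrix).
  Diagonal distances are lattice steps, i.e. distance 2 at 45° is the
  offset (−2, 2); rounding Euclidean diagonal lengths would collapse
  distances 1 and 2 onto the same offset and destroy the multiscale
  ladder. The map is quantized to 16 levels (configurable) — enough
  texture resolution for a stable 4×4 feature matrix on fundus-sized
  images — with distances (1, 2, 3, 4), the smallest multiscale
  ladder. The IDM denominator defaults to 1 + (i+j)², with the
  classical 1 + (i−j)² form selectable; the threshold rule only
  consumes ranges of F, so both forms run through the same machinery.
  R_Φ is the range of each *column* of F (over distances, per
  orientation; `range_axis="row"` gives the transposed reading), and
  Th = max(R_Φ) + mean(R_Φ) is applied directly to the [0, 1]-rescaled
  average-filtered PC map. Th is capped at 1; a constant image yields
  Th = 0 with a degenerate-threshold warning.

## Postprocessing

8-connectivity everywhere (vessels are thin, frequently diagonal).
The binary median filter is a strict-majority vote; ties in even
windows resolve to background (noise-removal bias). Directional line
structuring elements default to **length 9 px** — comparable to the
2–6 px vessel calibers, long enough that the openings actually remove
blobs; length 1 (which makes every line opening the identity) remains
selectable. Reconstruction is computed as the union of the mask's
8-connected components that touch the marker, which is exactly
geodesic dilation to stability; in the ATC chain the marker is the
directional-filter response and the mask is the MOMF output.

## Pipelines

The CLAHE route thresholds with dark polarity (vessels < t on the
enhanced green channel); the PC route with bright polarity
(vessels > Th on the PC map). Histogram-based thresholds are computed
from FOV-interior pixels only — the black surround would otherwise
dominate the histogram. Binarization is restricted to the FOV eroded
by `fov_margin` (default 6 px): the FOV rim is an artificial step edge
that rings strongly in the PC map. Evaluation covers the full FOV by
default (outside-FOV pixels are trivially correct background and
inflate accuracy; `evaluate_in_fov=False` reproduces the whole-image
convention). A constant working image (no texture at all) yields an
empty vessel map rather than an error.

## Synthetic phantoms

A phantom emulates the green channel of a fundus photograph: 256×256
image, circular FOV of radius 120 px on a dark (0.03) surround,
background level 0.78 plus a random quadratic illumination field of
peak amplitude 0.12, three vessel trees rooted near the rim with three
binary branchings each (width tapering ×0.8 per branching within
2–6 px, branching angles 10–40°, gently curving runs), Gaussian
cross-sectional profiles of depth 0.35 and σ = width/4 — so the
labeled half-width boundary sits at 2σ and the ground-truth width
matches the visually apparent vessel width — optional bright disk
lesions (default 0: healthy retina), and additive Gaussian noise of
σ = 0.05 (contrast-to-noise 7). Ground truth is geometric (within
half a width of a centerline), so rendering noise cannot leak into
labels. The default spec yields vessel densities of 0.12–0.15 of the
FOV across seeds, inside the 0.05–0.18 band typical of fundus images.

What the phantoms do **not** model: the optic disc and fovea, the
central vessel reflex, vessel tortuosity beyond gentle curvature,
crossings/overlaps of independent trees (they do occur geometrically
but carry no special appearance), camera vignetting beyond the smooth
polynomial, and JPEG-like acquisition artifacts. Passing the recovery
tests therefore demonstrates internal correctness of the pipelines
under controlled tubular-structure conditions, not clinical-grade
performance on real retinas.

## Known behaviors and limitations

* **PC accuracy is not monotone in weak noise.** The noise floor
  T = μ + kσ adapts to the image: at very low noise almost nothing is
  suppressed, and because PC is contrast-invariant, faint-but-coherent
  structure (the outer tails of vessel profiles, residual texture)
  scores as high congruency and becomes false positives. Measured on
  the default phantoms, PC+IDM+MO mean accuracy over noise σ
  {0.01, 0.05, 0.1} is 0.90 / 0.96 / 0.96, while the intensity-based
  CLAHE+Gaussian+Otsu+ATC pipeline degrades monotonically
  (0.96 / 0.95 / 0.94). The degradation-monotonicity check therefore
  uses the CLAHE pipeline; the PC behavior is the flip side of its
  noise robustness.
* Global thresholds remain blind to caliber: the thinnest (1–2 px)
  vessels are under-segmented by every route, which is the method
  family's known limitation.
* Problem sizes in the test suite (256² phantoms, 10 seeds for
  recovery runs, 20 for bounds checks) were chosen as the smallest
  sizes at which vessel calibers, filter wavelengths and FOV geometry
  keep their real proportions.
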
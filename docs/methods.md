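# Methods

## Detector model

CR-39 records a heavy charged particle as a latent damage trail that
chemical etching develops into a conical pit. Two etch velocities compete:
the bulk velocity V_b normal to the surface and the faster track velocity
V_t along the trail. Only their ratio is observable; the package therefore
works exclusively with the response S = V_t/V_b − 1, recovered from the
elliptical pit aperture as

S = sqrt(16 B² D_A² / (4B² − D_B²)² + 1) − 1,

where D_A ≥ D_B are the aperture axes and B the bulk removal (default
3.3 μm, uncertainty 0.7 μm, carried as metadata; the response itself is
evaluated at the nominal B). For circular pits (normal incidence) this
reduces algebraically to S = 2d²/(4B² − d²), which the test suite checks to
1e−12 relative error. The formula degenerates when D_B → 2B (the pit mouth
as wide as twice the removal): such over-etched pits are outside the model
and are excluded by default, with a `clamp` option that pins them just
inside the domain; either way they are counted and reported.

A track is revealed only if its dip angle θ (from the detector plane)
exceeds the critical angle, sin θ_c = 1/(S+1). For an isotropic flux
through a plane (angular density 2 sin θ cos θ), the detected fraction is
η = 1 − sin²θ_c = ((S+1)² − 1)/(S+1)², so each observed track enters fluence
sums with weight 1/η. The identity η + sin²θ_c = 1 is property-tested
exactly. Published treatments additionally apply an angular response
correction of the calibration itself; that correction is not reconstructible
from aperture data alone and is absorbed into the 1/η weight here — a known
limitation. Whether per-track weighting or a spectrum-averaged efficiency is
used matters little for narrow spectra; per-track weighting is used because
it is exact for the simulator's geometry.

## Calibration

The S ↔ LET map is a strictly monotone knot curve interpolated log-log
linearly (exact for power laws, stable over two decades of positive
values), valid on 3.5–600 keV/μm in water; 3.5 keV/μm is the material's
registration threshold, so responses below the threshold knot raise an
error while responses above the top are clipped to 600 keV/μm and counted.
Measured batch calibrations are loaded from a two-column CSV. The packaged
default, `synthetic_default_calibration.csv`, is a synthetic stand-in —
S = (L/100 keV μm⁻¹)^{3/2} sampled on 25 geometric knots — chosen to be
near zero at threshold (S ≈ 0.0065) and of order unity at alpha LETs
(S = 1 at 100 keV/μm). Quantitative LET work on real detectors must replace
it with the batch's measured curve; all round-trip and bijectivity tests
are calibration-agnostic.

## Dose accounting

Fluence per LET bin is φ_i = Σ (1/η)/A with A the scored area in cm²;
absorbed dose is D = (1.6×10⁻⁹/ρ) Σ φ_i L_i with ρ = 1.0 g/cm³ by default
and L_i the arithmetic bin midpoint (bins default to 10 keV/μm width over
[3.5, 600]; the representative-L choice matters only for bins wide relative
to spectral structure). Dose maps score L·weight in half-open 10 μm square
cells (a typical cell diameter), density maps count tracks in 50 μm bins;
grid origins snap to the lower corner of the registered tissue bounding
box, points on an upper cell edge belong to the next cell, and out-of-grid
tracks are counted, never dropped. Map building preserves the energy
bookkeeping identity Σ_cells dose·A_cell·ρ/1.6×10⁻⁹ = Σ_tracks L·weight to
1e−9 relative, enforced in tests on every simulated map. Raw counts are
stored beside each dose grid so Poisson uncertainty maps can be derived.

An RBE scalar (default 1) is available in `DosimetryConfig` for quoting
biologically weighted dose; it never scales the physical dose grids.

## Decay-window correction

With instantaneous uptake at injection (t₀ = 0) and decay constant
λ = ln2/half-life (7.2 h for ²¹¹At), the number of decays in [a, b] is
proportional to e^{−λa} − e^{−λb}. Doses scale with decay counts, so the
dose missed before mounting (t₁ = 12 h) relative to the dose observed on
the detector (t₁ to t₂ = 43 h) is

D₀/D = (1 − e^{−λt₁}) / (e^{−λt₁} − e^{−λt₂}) ≈ 2.291,

and total dose = observed × (1 + D₀/D), applied cellwise to maps. The
correction assumes the activity distribution is spatially frozen from
injection onward; redistribution while the animal is alive would make the
pre-window term position-dependent. Limits are tested analytically:
t₁ → 0 gives 0; t₁ = one half-life with t₂ → ∞ gives 1.

## Registration and segmentation

The tissue-to-detector map is a full six-parameter affine fitted by least
squares to ≥ 3 non-collinear marker pairs (collinearity detected via the
design-matrix singular values); the RMS marker residual is reported as QC.
Tracks are carried into the tissue frame with the inverse transform.

Segmentation uses fixed 8-bit thresholds: grayscale is the unweighted RGB
mean rounded half-up (luminance weights configurable); *tissue* is
gray < 138 strictly — stained tissue is darker than the blank detector, and
the threshold side, not given with the published value, is configurable;
*pink* (eosin/necrotic tumour) requires R ∈ [123, 177], G ∈ [42, 84],
B ∈ [94, 139] (closed bands) within tissue; *purple* (viable tissue) is
tissue minus pink, so the two partition tissue by construction. Track
counting is nearest-pixel-centre with half-ties toward the lower index.
Region densities carry 1σ Poisson errors (sqrt(count)/area) and the
concentration efficiency r = ρ_pink/ρ_purple propagates relative errors in
quadrature; the first-order σ_r is validated against a 10⁵-sample
Monte-Carlo Poisson resampling to 5%.

## Synthetic phantom

The phantom emulates a stained liver section with necrotic metastatic foci
on a detector plate. Geometry: one tissue ellipse with tumour sub-ellipses;
fill colours (pink 150/60/120, purple 120/80/160 on white) are verified at
build time to sit strictly inside/outside the segmentation thresholds, so
mask recovery is pixel-exact and the segmentation tests are sharp. The
default field is desk-scale — 2 × 2 mm at 2 μm/pixel — so a full simulation
plus analysis runs in a few seconds; full-slide 12 × 12 mm at 0.28 μm/pixel
is supported by overriding the image size and pixel pitch.

Decays are drawn per region as Poisson counts with mean
activity × area × (1 − e^{−λt₂}) (decays after tissue removal are never
drawn), times from the exponential truncated to [0, t₂], positions uniform
over the rasterised region, dip angles from 2 sin θ cos θ, and LET from a
normal distribution with mean 130 keV/μm and SD 20 truncated to
[3.5, 600] — a stand-in for the slowing-down spectrum of 5.87 MeV alphas
crossing an 8 μm section, pluggable via the config (no stopping-power
transport is modelled, and each decay emits exactly one alpha). A decay is
*registered* iff θ ≥ θ_c of its LET's response. Registered window events are
turned into pit apertures by the exact inverse of the response geometry
(D_B = 2B√((V sinθ−1)/(V sinθ+1)), D_A = (4B²−D_B²)√(V²−1)/(4B), V = S+1),
so the analysis chain recovers S and LET to machine precision and any
spectral distortion in tests is attributable to binning and efficiency
weighting alone.

Activities default to 18 000 decays/mm² (normal, integrated over all time)
with a 6.0 tumour contrast. These are free parameters of the phantom — the
source strengths behind published track densities are not recoverable — and
are sized so a default run registers ≈ 2×10⁴ tracks in the window, giving
percent-level counting statistics on the concentration-efficiency recovery;
they correspond to a higher areal activity than a full-slide specimen at
typical published densities, traded for a 36× smaller field. What passing
phantom tests show is that the chain is self-consistent (geometry inversion,
efficiency correction, decay bookkeeping, registration, segmentation); they
do not validate the synthetic calibration curve or the LET source shape
against real detectors.

All randomness flows from a single seed; bundles embed the config hash and
re-running a seed reproduces every table byte-identically.

## Numerical and interface choices

- Coordinates are micrometres, origin at the top-left pixel centre, y down;
  pixel index = coordinate/pixel-size rounded to nearest with half-ties to
  the lower index.
- Pit tables with swapped axis columns are repaired with a warning rather
  than rejected (digitised tables are often unordered).
- The bundled pit detector (global threshold 138, minimum area 4 px,
  moment-equivalent ellipse axes) is a deliberately simple replacement for
  dedicated pit-fitting software: no deconvolution of overlapping pits, no
  sub-pixel rim fitting. Axis recovery on rendered ellipses is
  regression-tested to 10%.
- The analysis pipeline is deterministic given its inputs; every exclusion
  (degenerate pits, sub-threshold responses, clipped responses, out-of-grid
  or out-of-image tracks) is counted in the report.

## Known limitations

- 2-D source model: no source depth distribution in the section, no
  self-absorption, no energy loss between emission point and detector.
- The efficiency correction ignores the angular dependence of the
  calibration itself (see above).
- The decay correction assumes immediate, permanent binding at injection.
- Segmentation is fixed-threshold; no stain normalisation, so real
  micrographs with different staining or illumination need re-thresholding.
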
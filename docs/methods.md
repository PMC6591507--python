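# Methods

`wmcfit` estimates the absorption coefficient μa and reduced scattering
coefficient μs′ of a small, optically homogeneous tissue volume from a
single time-resolved reflectance curve (TPSF) recorded between two
closely spaced optical fibers.  This note describes the model, the
estimators, the synthetic-data generator, the numerical choices, and the
limits of what the test suite demonstrates.

## Physical model

A semi-infinite homogeneous turbid medium (default: anisotropy g = 0.9,
refractive index n = 1.4, air above) is probed in reflectance by a
source and a detector fiber (50 μm core, NA 0.2) separated by
ρ = 1.25 mm.  Photon packets are launched uniformly over the source spot
into a cone of 11.5° half-angle, measured in the medium (the fiber face
itself is not modeled).  Free paths are exponential with rate μs,
scattering is Henyey–Greenstein sampled by its closed-form inverse CDF,
and the refractive-index step at the boundary is handled with
unpolarized Fresnel coefficients and Snell refraction.  A packet is
detected when it leaves the medium on the detector aperture with an
in-air exit angle satisfying sin θ ≤ NA; detected weight is histogrammed
into 0.3125 ps bins up to 300 ps of time of flight (t = L·n/c), i.e. 960
bins.

Two probe geometries exist:

* **surface contact** (tissue measurements): fiber tips flush with the
  medium boundary;
* **immersed** (liquid-phantom measurements): tips a depth d below the
  liquid–air surface.  The liquid then also fills the layer above the
  tip plane, photons reflect off the liquid–air interface (this
  reflection measurably reshapes the TPSF, which is why it is modeled),
  and collection happens on the tip plane with the acceptance angle
  evaluated in the liquid, sin θ ≤ NA/n.  The liquid index is not part
  of the phantom's tabulated properties; 1.33 (water-like) is assumed
  and recorded in the preset provenance.

## White Monte Carlo and the look-up table

All transport runs are executed at μa = 0 ("white" runs).  Each detected
packet stores its total path length L, so the TPSF at any absorption
level follows analytically from Beer–Lambert reweighting
W = W₀·exp(−μa·L).  The look-up table — peak-normalized TPSFs on a
(μs′, μa) grid, by default 0.6–4.0 mm⁻¹ in steps of 0.1 and 0–0.1 mm⁻¹
in steps of 0.001 — therefore costs one transport run per μs′ value and
nothing per μa value.  μs is derived from the grid's μs′ as
μs = μs′/(1−g) at fixed g.  Records, not just binned curves, are
persisted (HDF5), so new μa values can be added without re-simulation.

## Estimators and variance reduction

Detection through a 50 μm aperture within an NA-0.2 cone at 1.25 mm is
an ~4·10⁻⁴-per-launch event; an analog simulation is far too slow for
desk-scale work.  Three unbiased techniques are layered on top of the
analog walk (each validated against the analog estimator in the tests):

1. **Azimuthal ring detection.**  The problem is cylindrically
   symmetric, so exits are collected over the full annulus ρ ± r_det and
   the spot/annulus area ratio is recorded; peak normalization makes the
   constant irrelevant.

2. **Local (next-event) estimator with splitting and roulette.**  At
   every scattering event within ~6 optical depths of the surface and
   radially inside the collection annulus, the expected weight scattered
   into the in-medium acceptance cone (half-angle asin(NA/n)) *and*
   escaping without further interaction is scored directly:
   w · I_cone(cos α) · exp(−μs z) · T, where I_cone is the
   Henyey–Greenstein mass inside the cone given the pre-scatter
   direction (precomputed table) and T the near-normal Fresnel
   transmission.  Actual boundary transmissions are then booked as
   escape so nothing is double-counted.  At the boundary the packet is
   split deterministically (the reflected fraction always continues);
   weight roulette (threshold 10⁻², survival 0.1) and a depth roulette
   (below 3 mm, survival 0.5 per mm of new maximum depth) terminate
   walkers that can no longer contribute meaningfully, and
   contributions below 10⁻² of the
   maximum are roulette-thinned to keep record arrays compact.  Record
   weights are therefore fractional and variable; statistical quality is
   measured by the effective sample size n_eff = (Σw)²/Σw², which is
   what all size statements below refer to.  Small approximations, each
   far below the Monte Carlo noise at the sizes used: the escape
   attenuation and Fresnel factor are evaluated at the cone axis rather
   than integrated over the cone (≤3% relative on the most attenuated,
   heavily suppressed contributions), and the lateral offset between the
   scatter point and the exit point (≤ z·tan 8.2° ≈ 20 μm) is ignored
   when the exit radius is recorded.

3. **Similarity rescaling.**  A non-absorbing half-space with fixed g
   and indices is exactly self-similar: scaling μs by k⁻¹ scales every
   trajectory length by k.  One white run at the top of the μs′ range,
   collecting exits over a widened radial band, is therefore rescaled to
   *every* μs′ column of the LUT (slice the band at r/k, multiply L and
   depths by k, re-bin the flight times).  The only approximations are
   the fixed source-spot radius and, for the immersed geometry, the
   fixed immersion depth, both nominally scaled by k: the spot (25 μm
   against ρ = 1.25 mm) is negligible; for the phantom LUT the band is
   kept narrow (k ≤ 1.17, immersion depth effectively 0.43–0.5 mm
   instead of 0.5 mm), and the resulting curve differences are below the
   column noise.  Measurement-side runs never use rescaling — each is an
   independent direct run at its own μs.

The analog spot and analog ring estimators remain available
(`ring_detector=False`, `analog_ring=True`) as the reference rungs of
the validation ladder: spot ↔ ring agreement checks the symmetry
argument, ring ↔ local-estimator agreement checks the variance
reduction, and the late-time decay slope is checked against the
closed-form diffusion solution below.

## Fitting

Measured and simulated curves are compared after convolving each LUT
TPSF with the instrument response function (IRF) and peak-normalizing
both curves (convolve first, then normalize).  On top of the peak
normalization, the residual model by default refits a least-squares
amplitude per candidate over the fit range ("free" amplitude), so the
comparison is purely of curve shape and the Monte Carlo noise of the
single peak bin does not set the overall level; the plain
peak-normalized comparison remains available.  The fit range is derived
from the measured curve as the closed bin range between its
leading-edge and falling-edge fraction-of-peak crossings (10%/10% by
default; 40%/40% when a falling-edge IRF artifact such as the
reflection hump must be excluded), evaluated at bin resolution without
sub-bin interpolation so RMSE values are bit-reproducible.  Because a
measured curve carries an arbitrary trigger offset, each candidate is
additionally shifted by up to ±16 bins (±5 ps), and the RMSE

rmse = sqrt(mean over the range of (measured − candidate)²)

is minimized by exhaustive search over all grid cells and shifts.  Exact
ties break toward smaller μa, then smaller μs′, then smaller |shift|.  A
fit is flagged `accepted` when the minimum RMSE is below the threshold
(default 0.025).  No interpolation between grid cells is performed.

## Synthetic data

The generator emulates the measurement side so the whole chain is
testable without hardware:

* **IRF**: Gaussian of FWHM 3.44 ps sampled on the bin grid, unit peak;
  optionally a secondary Gaussian on the falling edge (default delay
  10 ps, relative amplitude 0.2) emulating a streak-camera lens
  reflection.
* **Forward measurement**: white run (fresh or cached) → Beer–Lambert
  absorption → IRF convolution → integer-bin trigger shift → noise →
  peak normalization.  Shot noise scales the curve to a target total
  count (default 10⁶) and draws Poisson variates per bin; a Gaussian
  mode exists for additive noise.  Streak-camera analog artifacts
  (shading, jitter, background) are not modeled.
* **Presets**: the liquid phantom (μa 0.0231 mm⁻¹, μs 15.6 mm⁻¹,
  g 0.836, immersed 0.5 mm) and rat/monkey gray- and white-matter
  values, including the two single-measurement fitting examples
  (μa 0.052/μs′ 1.70 and μa 0.081/μs′ 1.8).

What passing round-trip tests show: the estimator chain inverts its own
forward model within the grid resolution under realistic photon-count
noise.  What they cannot show: agreement with in vivo measurements —
real tissue is layered and the fiber–tissue interface, fiber obstruction
and detector artifacts are outside the model (the immersed-fiber
measurements deeper than ~1 mm are known to be corrupted by
fiber–liquid interface reflections, which this model deliberately does
not include).

## Diffusion oracle and depth analysis

The time-resolved reflectance of a semi-infinite medium in the diffusion
approximation (extrapolated-boundary image solution, D = 1/(3μs′),
source depth 1/μs′, effective internal reflection from a polynomial fit
in the relative index; the variant is recorded in the curve metadata)
serves as an independent closed form.  At ρ = 1.25 mm it fails around
the peak — the reason the forward model is Monte Carlo — but the
late-time (100–250 ps) log-slope of the MC TPSF must and does agree
within 5%.

The depth-contribution analysis histograms Beer–Lambert-weighted
detected weight by each record's maximum depth below the fiber tips,
conditioned on an arrival-time window.  Binning uses the deepest
excursion (not the mean depth) because the question it answers is
whether light reaching below a given depth contributes at all.

## Identifiability, round-trip design, and problem sizes

The (μa, μs′) objective has a nearly degenerate valley: over the 10/10
fit range (≈ 13–51 ps at the rat gray-matter example) one μa grid step
(0.001 mm⁻¹) changes the candidate curve by an RMSE of only ≈ 7·10⁻⁴,
while lowering μa and raising μs′ together leaves the normalized shape
almost unchanged.  Any independent Monte Carlo noise on the two sides
of the comparison therefore slides the argmin along the valley: with
independent measurement and LUT white runs at effective sample sizes
n_eff ≈ 10⁴ per curve, seeded replicates scatter by about ±0.02 mm⁻¹
in μa and ±0.3 mm⁻¹ in μs′ (this mirrors the large spread such fits
show on real tissue data).  The test suite keeps one such
independent-noise round trip with exactly these landscape-derived
bounds, as documentation of the identifiability limit.

The standard round trips instead follow the forward model's contract —
with an impulse IRF and no noise the synthetic measurement reproduces
the LUT TPSF of the same white-run seed family — and draw the
measurement's white run from the same band run as the LUT (rescaled to
the true μs′, which may be off-grid as for the phantom).  What those
round trips verify is the estimation chain itself: Beer–Lambert
rescaling, IRF convolution, trigger-shift registration, range selection
and the grid search, under shot noise at 10⁶ counts.  At that noise
level μa is recovered to within one grid step on the 10/10 range
(a few steps on the shorter 40/40 range) and μs′ exactly; noiseless
self-fits return the exact cell with RMSE < 0.025.  Transport-estimator
correctness is established independently: analog spot ↔ analog ring ↔
local estimator agreement, and the diffusion late-time slope.

Sizes: band runs of 2.5–11·10⁵ records give n_eff ≈ 0.5–1.5·10⁴ per
LUT column; the acceptance script and the test suite state their exact
targets in code.  At these sizes the RMSE floor of an
independent-noise fit is ≈ 0.01, set by Monte Carlo noise rather than
model mismatch; the 0.025 acceptance flag is calibrated for measured
data of full experimental quality and for the same-family round trips,
both of which clear it.

The phantom's true μs′ (15.6 · 0.164 = 2.5584 mm⁻¹) falls between
0.1-step grid lines, and a half-step μs′ quantization error maps onto
≈ 0.003 mm⁻¹ of μa bias along the valley; the phantom LUT therefore
uses a 0.02 mm⁻¹ μs′ step over 2.46–2.66 so the quantization bias
stays below half a μa step.

Other numerical choices: time bins are half-open [kΔt, (k+1)Δt) with
bin = floor(t/Δt); curves are stored on the left-edge time grid; the
all-zero curve is rejected rather than normalized; μa = 0 is a legal
grid point (the raw white run); grid axes are generated with rounding to
avoid floating-point drift; the RNG is a single seeded stream per run
and every artifact records a provenance fingerprint (medium, probe,
run-control, seed), making runs bit-reproducible at fixed thread count
(single-threaded by design).

## Known limitations

* Homogeneous medium only — no layered gray/white models (the known
  systematic when the cortex is thinner than the probed depth is
  inherited from the method itself).
* No fiber-body obstruction, no fiber–medium interface reflections, no
  polarization, no fluorescence, no GPU path.
* The LUT fits by grid search only; parameter uncertainty is limited by
  the grid steps, and no sub-grid refinement is attempted.
* The local estimator's cone-axis approximations (above) introduce
  relative shape errors well below 1% of the curve but are not exactly
  zero; the analog estimators are the arbiter where it matters.
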
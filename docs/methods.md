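# Methods

This note describes the models implemented in `cherenkov_polarimetry`,
the choices made where the design was open, and what the synthetic test
bench does and does not demonstrate.

## Physical background

A charged particle traversing a dielectric of refractive index *n* faster
than the local phase velocity of light (βn > 1) emits Cherenkov light on a
cone of half-angle θ_c around its direction of motion,

    cos θ_c = 1/(βn),

with production threshold

    E_min = m₀c² [(1 − 1/n²)^(−1/2) − 1].

For electrons in water (n = 1.33) the threshold is 264 keV and the cone
opens to at most 41° as β → 1; in polyvinyl toluene (n = 1.58) the
threshold is 149 keV.  The expected photon count per path length over a
wavelength band [λ₁, λ₂] follows the Frank–Tamm spectrum with dispersion
neglected, dN = 2πα sin²θ_c (1/λ₁ − 1/λ₂) ds.  The default band is
400–800 nm; the camera's true spectral window is a free parameter of the
yield only and cancels from every normalized quantity the pipeline
reports.  The emitted light is linearly polarized in the plane spanned by
the particle and photon directions, transverse to the photon, pointing
outward from the cone axis; we compute it as the normalized (û·k̂)k̂ − û.
Electron rest mass is 510.99895 keV; the printed thresholds round
identically with 511 keV.

Because megavoltage beams drive secondary electrons predominantly
forward, the Cherenkov light leaving a water tank is anisotropic, and a
camera viewing the tank from the side samples that anisotropy differently
at every pixel.  The pipeline measures the *polarized* component of the
signal per pixel and removes the anisotropy using simulated angular
distributions, on the premise that the corrected polarized signal is
proportional to the projected dose.

## Malus-law polarimetry

With a rotating linear polarizer at transmission axis α₀, each pixel
follows

    I(α₀) = I_pol cos²(α₀ − α) + I_unpol,

where α is the angle of linear polarization (AoLP).  The degree of linear
polarization is DoLP = I_pol/(I_pol + I_unpol) × 100.  Two conventions
are fixed here:

* **The fitted DC term is the unpolarized contribution.**  An ideal
  polarizer transmits half of any unpolarized intensity; that factor ½ is
  absorbed into I_unpol rather than reported separately, so DoLP is
  defined on the fitted quantities directly.
* **AoLP zero and sign.**  0° is the first polarizer axis, increasing
  counter-clockwise as seen from the camera, reported in (−90°, 90°].
  The reference is configurable by rotating the input angle set.

For the standard angle set {0°, 45°, 90°, 135°} the decomposition is the
closed form of linear Stokes polarimetry: Q = I(0) − I(90),
U = I(45) − I(135), I_pol = √(Q² + U²), α = ½ atan2(U, Q),
I_unpol = (I(0) + I(90) − I_pol)/2.  Noiseless model data round-trip to
float precision.  For any other set of ≥3 distinct angles (mod 180°) a
bounded nonlinear least-squares fit of the same model is used, seeded by
a linear solve in (I, Q, U); non-negativity of I_pol and I_unpol is
enforced as a bound, since shot noise can drive the unconstrained DC
estimate negative.  In the four-angle closed form a negative DC estimate
is clamped to zero and the pixel flagged in a QA mask.

The pair-sum identity I(0) + I(90) = I(45) + I(135) holds exactly for any
signal obeying the model; its per-pixel defect is reported as
`fit_residual` and serves as a model-consistency diagnostic on real
(noisy) data.

Estimator caveat: I_pol = √(Q² + U²) is non-negatively biased under
noise (folded-normal moments), so an unpolarized scene reads a small
positive DoLP.  At ≥10⁴ counts/pixel the bias is below 1 percentage
point, verified by simulation over 20 seeds.

## Frame conditioning

Pipeline order is fixed: temporal median over repeated exposures
(suppresses transient stray-radiation spikes), subtraction of the
averaged background frame (clamped at zero, clamp fraction logged),
division by a cos⁴ vignetting model fitted to a uniform-emitter flat
frame.  Whether flat-fielding preceded background subtraction in
comparable experimental workflows is ambiguous; this order is our
documented choice and is idempotent on clean images.  The vignette model
is A·cos⁴(arctan(r/f)) with a fitted optical center (initial guess: image
center) and scale f in pixels; correction divides by the model normalized
to 1 at the center.  Background frames taken at a different integration
time are scaled by the exposure ratio with a warning.  Pixel scale
(default 0.26 mm/px, the calibrated value for the reference geometry) is
a configuration input; checkerboard calibration itself is out of scope.

## Simplified Monte Carlo

The angular distributions of Cherenkov production are generated by a
deliberately small transport model, not a general-purpose MC:

* **Electrons** — condensed-history stepping, default step 1 mm.  Per
  step: energy loss from the collisional stopping power of water
  (coarse NIST/ESTAR grid, log-log interpolated, bundled as CSV);
  Gaussian multiple scattering with the Highland RMS angle
  (13.6 MeV/βpc)·√(Δs/X₀)·[1 + 0.038 ln(Δs/X₀)], X₀ = 36.08 g/cm²;
  Poisson(Frank–Tamm yield) photons on the instantaneous cone with
  uniform cone azimuth and the analytic polarization vector.  Transport
  stops below the Cherenkov threshold or at the tank wall.  Halving the
  step does not move the shallow-depth polar-histogram mode bin
  (convergence criterion).
* **Photons** — interaction depth sampled from exponential attenuation
  with the tabulated total μ(E) of water; a Compton recoil electron
  sampled from the Klein–Nishina cross-section (rejection sampling in
  the scattered-energy fraction) is handed to the electron transport.
  Single-scatter by default; the scattered photon can be followed
  recursively.  Clinical spectra are approximated by monoenergetic
  effective energies (6 MV → 2 MeV, 18 MV → 5 MeV, roughly one third of
  the accelerating potential); user spectra are accepted as
  (energy, weight) lists.  Bremsstrahlung, pair production, delta rays
  and optical transport are omitted — a known bias, largest for 18 MV,
  acceptable because only *normalized angular shapes* feed the
  correction.

Scoring voxels are 1 cm³ cubes at requested (depth, off-axis) positions
(voxel size configurable; the reference work does not state one).  Polar
angle is measured from the beam axis, azimuth from the camera axis with
φ = 0 toward the camera; bins default to 1° (polar) and 5° (azimuth).
The one-sided collection efficiency of a side-viewing camera is emulated
by an optional filter keeping only photons directed into the camera
hemisphere — our reading of a "θ > 0" scoring convention that is
ambiguous as stated; the azimuth reference offset is likewise exposed as
configuration.

The simulation reproduces the expected qualitative behaviour: polar
distributions peak near 41° at shallow depth for high-energy electrons,
broaden and shift with depth for electron beams, and become mutually
consistent past the build-up region for photon beams; off-axis voxels of
electron beams develop azimuthal asymmetry.

## Geometry and anisotropy correction

Pixels map to tank mid-plane coordinates through the pixel scale and the
optical-axis target (tank center, camera at L = 50 cm by default), giving
viewing angles θ_cam = 90° + arctan((z − z_center)/L) and
φ_cam = arctan(x_lateral/L).  Depths 0–17 cm at 50 cm span roughly
79°–98°.  Parallax along the optical axis is ignored — every pixel gets
its mid-plane angles; perspective is a known residual error source of
the method itself.  Refraction at the tank wall is likewise ignored.

The correction is D(x,y) ∝ C_θ·C_φ·I_pol with C = 1/P evaluated at the
pixel's viewing angle, where P is the normalized angular density
(per-degree, bin-center interpolated) — so the maps are invariant to
histogram rescaling.  Photon beams use the single distribution scored at
the tank center (their post-build-up distributions agree); electron
beams interpolate the polar density linearly in depth between scored
voxels, clamped at the ends.  The azimuthal density interpolates between
scored off-axis positions.  Since only proportionality to dose is
physically claimed, the normalization of the maps is a free convention;
we scale each map to mean 1 over the field, keeping corrected and raw
images directly comparable.  Pixels that hit a vanishing density are
capped (100× the median correction) and flagged rather than diverging.

## Dose metrics

PPDD: lateral sum per depth row (default over the full beam width, the
window is configurable), normalized to 100 at the maximum; d_max is the
argmax position.  Profiles: lateral cut at a depth, averaged over a
0.5 cm window, normalized to 100 on the central axis.  Field size: full
width at the 50% level with linear interpolation at the crossings.
Agreement with a reference curve: mean ± std of (measured − reference)
after linear resampling onto the reference grid, in percentage points;
"central axis" and "penumbra" region masks are defined as the inner 80%
of the FWHM and the 20–80% gradient zone respectively, since no standard
definition is universal.

## Synthetic data: what it emulates and what it does not

The generator renders four-angle stacks from a parametric truth:

* photon depth dose (1 − e^(−bz))·e^(−μz) with b solved so the peak sits
  at the preset d_max (1.2 cm for 6 MV, 3.05 cm for 18 MV; effective
  falloff μ = 0.055 and 0.038 cm⁻¹); electron depth dose
  (1 + s·z)/(1 + e^((z−R50)/w)) with R50 = 2.4/7.5 cm for 6/18 MeV —
  standard clinical magnitudes chosen once as realistic;
* error-function lateral profiles (field 5 cm photon / 6 cm electron,
  penumbra σ = 0.3 cm);
* constant DoLP per preset (42/47/29/33%; 0 for the unpolarized
  scintillator stand-in) and an AoLP field that is 0° on axis and ramps
  linearly across the penumbra to ±35° (endpoints are known,
  the in-between shape is our choice, antisymmetric in the lateral
  coordinate);
* the polarized amplitude is the truth dose divided by the correction
  maps built from the scenario's angular distributions, so the analysis
  correction undoes the weighting exactly (an inverse-crime design that
  isolates the plumbing); the unpolarized term follows from the DoLP
  field; vignetting, constant background, Poisson noise, Gaussian read
  noise and Poisson-rate transient spikes are then applied;
* the default angular distributions are analytic stand-ins (synthetic,
  labelled as such): a polar Gaussian at 41° whose width grows with
  depth for electrons (σ = 14° + 10°/cm·z, capped at 60°) and is fixed
  at 28° for photons, azimuth mildly tilting with off-axis position.
  Distributions scored by the bundled MC can be substituted to break the
  inverse crime.

Default counts put the peak total signal at 3×10⁴ per pixel (camera
counts are not meaningful absolutely; the value keeps relative shot
noise at the sub-percent level typical of long-exposure measurements),
10 frames per polarizer angle, 10 background frames.  Rendered images
default to 150×110 pixels at 1.3 mm/px — a 5×-binned sensor covering the
full tank — so the whole chain runs in seconds; tests use smaller crops.

Passing the synthetic recovery tests shows that the decomposition,
geometry mapping, correction algebra and metrics are mutually consistent
and robust to the modelled noise.  It does *not* validate the transport
model against a full MC, nor the proportionality of polarized signal to
dose in real water — those rest on the physics assumptions above and on
experimental comparison, which requires camera data.

## Numerical choices and degenerate inputs

* Threshold comparisons tolerate 1e-12 roundoff in βn at the cone
  closing; yield returns 0 (not an error) below threshold.
* All-zero or unpolarized pixels: DoLP is defined as 0, AoLP as NaN
  (masked); the general fit masks AoLP when I_pol ≤ 1e-8·max(1, I_unpol).
* DoLP is clipped to [0, 100] against float spill at exactly 100.
* Collinear particle/photon directions make the polarization plane
  undefined and raise.
* Empty scoring voxels produce zero histograms flagged `empty`; empty
  ROIs and non-crossing profiles raise.
* Stopping power and attenuation tables are clamped at their grid ends.

## Known limitations

Single-scatter photon transport and monoenergetic effective spectra bias
18 MV angular shapes; no dispersion (n constant over the band); no
optical propagation, so tank-wall refraction and lens perspective enter
only as the documented approximations; absolute dosimetry is out of
scope — every output is normalized.
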
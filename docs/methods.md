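# Methods

## Scattering model and estimators

A gold nanorod (GNR) at its longitudinal plasmon resonance scatters like
a dipole along its axis **u**: the co-polarized field contribution of rod
*j* is proportional to `u_x²`, the cross-polarized one to `u_x·u_y`, each
phase-modulated by `exp(i·q·z_j)` with backscattering wavenumber
`q = 4πn/λ0`. Independent translational diffusion of `z_j` (coefficient
`DT`, μm²/s) and isotropic rotational diffusion of **u** (coefficient
`DR`, rad²/s) give the normalized field autocorrelations

    g1_HH(τ) = exp(−q²·DT·τ) · [5/9 + 4/9·exp(−6·DR·τ)]
    g1_HV(τ) = exp(−q²·DT·τ) · exp(−6·DR·τ)

The weights 5/9 and 4/9 follow from the second- and fourth-order moments
of an isotropic orientation distribution (`⟨u_x²⟩ = 1/3`,
`⟨u_x⁴⟩ = 1/5`, `⟨u_x²u_y²⟩ = 1/15`); the factor 6·DR is the decay rate
of second-rank orientational correlations.

Estimation proceeds per depth window (ROI):

1. **Autocorrelation.** Complex HH/HV signals are mean-subtracted per
   depth pixel and the biased (divide-by-N) autocovariance is computed by
   FFT, normalized at zero lag; the real part is reported (a magnitude
   mode exists for data with slow phase drift). Because the complex
   field is available, this is the first-order correlation directly — no
   Siegert inversion, which is biased for the non-Gaussian fields of
   small rod ensembles. An intensity route (`siegert_g1`) is provided
   for comparison. The zero lag is never used downstream (it carries
   shot noise). Lags run to N/4 by default to bound estimator variance.
2. **Window averaging.** Per-pixel curves are averaged over depth
   windows of 20 pixels (stationary samples) or 3 pixels (cultures).
3. **Isotropic combination.** `g_ISO = (9/5)·g_HH − (4/5)·g_HV`
   cancels the orientational factor exactly, leaving `exp(−q²·DT·τ)`.
4. **Decay fits.** Unit-amplitude single exponentials are fit by
   nonlinear least squares (on g, not log g, so noisy near-zero samples
   are harmless; initial rate from the 1/e crossing). The fit range ends
   at the first discrete sample below 1/e (isotropic) or 1/e²
   (cross-polarized); the crossing uses no interpolation, matching a
   "first sample below" rule, and a curve that never crosses is censored
   at the last lag. A *dynamic* rule (culture mode) extends 1/e to 1/e²
   when fewer than 4 lags remain; under 4 lags in all cases the ROI is
   rejected. R² is computed over the fitted lags only. Then
   `DT = rate_ISO/q²` and `DR = rate_HV/6`; the latter neglects the
   translational term `q²·DT` in the HV rate, a deliberate approximation
   valid when rotation decays much faster — it overstates DR by
   `q²·DT/6` (≈8% for solvent at 250 kHz). `FitConfig(dt_correction=True)`
   subtracts it when a DT estimate is available.

## ROI validity screening

Each ROI carries named pass/fail flags:

- **surface** — ROIs start 15 pixels (stationary) or 5 pixels (culture)
  below the detected top surface, which shows a strong specular
  reflection. Surface detection thresholds the time-mean HH power
  against a robust noise floor (median + 6×1.4826×MAD of the top 10
  pixels); the robust statistics keep the rule usable even when the
  surface sits inside the noise-estimation band.
- **snr** — mean HH power must exceed 3× the above-surface background
  power (the multiplier is a configurable default; no canonical value
  exists).
- **anisotropy** — `τ_ISO/τ_HV ≥ 1.5`, the signature of rod-dominated
  dynamic scattering; gates both coefficients.
- **iso_range / hv_range** — each decay time must sit inside the dynamic
  range: `τ ≥ 2·dt` and `τ ≤ duration/10` (operationalizing
  "well above the sampling time, well below the acquisition time").
  The isotropic check gates DT only and the cross-polarized check DR
  only: at a 62.5 kHz line rate the solvent HV decay is shorter than the
  sampling period, invalidating DR while DT remains measurable — the
  complementary-validity regime the method is designed around.
- **r2_iso / r2_hv** — per-channel thresholds, R² > 0.88 (dilute
  polymer) or 0.90 (stationary mucus).
- **outlier_dt / outlier_dr** — values more than 5 sample standard
  deviations from the stack mean are flagged for visual review (air
  bubbles, artifacts) but never auto-excluded.

Culture mode disables the R² and outlier screens (mucus on live cultures
is expected to be heterogeneous and changing). All screens are pure
threshold checks, hence idempotent and monotone under tightening.
Intrasample variability is summarized as CV% = 100·std/mean (sample
standard deviation) over valid ROIs.

## Hydration assay

Diffusion is normalized to same-day solvent references
(`Dnorm = D/Dsolvent`; theoretical references for water come from
Stokes–Einstein with the rod's hydrodynamic radius

    RH = (L/2) / [ln(L/W) + 0.312 + 0.565·(W/L) − 0.1·(W/L)²]

and the Tirado–García de la Torre rigid-rod rotational formula
`DR = 3kBT·[ln(L/W) − 0.662 + 0.917·(W/L) − 0.05·(W/L)²]/(πηL³)`,
defaults 293 K and η = 1.002 mPa·s). The built-in "hbe_mucus"
calibration maps

    wt.% = −2.75·DT,norm + 2.53    valid result in [−0.5, 2] wt.%
    wt.% = −8.62·DR,norm + 8.14    valid result in [1, 8] wt.%

Estimates valid under both maps are averaged (provenance `averaged`);
otherwise the single valid map is used (`DT_only`/`DR_only`), else the
cell is `undefined`. The rotational window extrapolates beyond its
largest calibrated concentration of 6.4 wt.%; cells above that are
flagged `extrapolated`. Calibrations are stored constants (the
underlying measurement tables are not distributable); `fit_calibration`
refits either map from a user CSV by ordinary least squares.

## Synthetic-data generator

Two backends produce complex HH/HV series with exactly known ground
truth:

- **Analytic process** (default): products of three independent
  unit-variance complex circular-Gaussian AR(1) processes — `P` with
  lag-1 coefficient `exp(−q²·DT·dt)`, `Q`, `Q′` with `exp(−6·DR·dt)` —
  combined as `HH = P·(√5 + 2Q)/3` and `HV = P·Q′`. Independence makes
  the field autocorrelations equal the rod model *exactly* at every lag,
  at O(N) cost and fully seeded. (AR(1) is the exact discretization of
  an Ornstein–Uhlenbeck process, so there is no step-size bias.)
- **Rod ensemble** (oracle): explicit rods with 1-D Brownian phase
  coordinates (variance `2·DT·dt` per step) and orientations performing
  a tangent-plane random walk on the sphere (std `√(2·DR·dt)` per
  tangent direction, renormalized), summed coherently with the dipole
  polarization factors. The tangent-step update requires
  `DR·dt ≤ 0.05`; coarser steps raise an error rather than bias the
  oracle. Both backends agree within Monte-Carlo error (tested at
  max |Δg| < 0.05).

Phantom stacks simulate depth pixels independently (no axial PSF
crosstalk — the analysis averages windows of pixels anyway), with: noise-
only pixels above a surface index; a strong static specular surface
pixel (amplitude 20× the dynamic field, with a 5% cross-polarized leak);
an optional static-scattering fraction implemented as a power-preserving
mixture `√(1−f)·dynamic + √f·(constant complex offset)`; and additive
complex white noise on both channels at a chosen fraction of the dynamic
amplitude. Default study conditions for stationary acquisitions are
62.5 kHz A-line rate, 800 nm center wavelength, n = 1.33, 1.5 μm depth
pixels, 64-pixel × 30,000-A-line records, surface at pixel 10 and
noise level 0.05.

What the generator does **not** emulate: axial/lateral PSF correlations,
flow and mucociliary advection, polydisperse rod batches, multiple
scattering, detector nonlinearity, and non-diffusive (anomalous or
confined) probe motion. Passing recovery tests therefore demonstrates
correctness of the estimation chain under the stated diffusion model,
not robustness to every artifact of real acquisitions.

## Numerical choices and degenerate inputs

- Biased autocovariance (divide by N) keeps estimates positive
  semidefinite; the induced bias at the lags used (≲N/4) is negligible.
- Constant (zero-variance) series raise a degenerate-signal error;
  within stacks such pixels are skipped and the window average uses the
  remaining pixels.
- Fits whose converged rate implies no measurable decay over the fitted
  range (`rate·τ_max < 10⁻⁶`) are rejected as censored rather than
  returned as near-zero diffusion.
- Depth intervals are half-open, 0-based pixel ranges; a final partial
  window is kept only if it spans at least half the nominal height.
- Seeds: every simulator takes an integer seed (or a NumPy generator);
  identical seed + specification gives bit-identical output. Multi-record
  runs derive child seeds via `SeedSequence`.

## Problem sizes

The test suite and the reproduction script use 64-pixel × 30,000-sample
stacks (2 ROIs per record at the 20-pixel stationary geometry), 5 records
per solvent recovery, 30 records for the variability study, and a
400-rod × 30,000-step ensemble (4 seeds) for backend equivalence —
sizes at which the Monte-Carlo error of each check is several times
smaller than its tolerance.

## Known limitations

- The rotational estimator inherits the `q²·DT/6` offset unless the
  correction is enabled; for strongly hindered samples (small DT) it is
  negligible, for solvent it is a few percent.
- Decay anisotropy and dynamic-range screening use discrete crossing
  times, quantized to the A-line period; at very fast decays the
  anisotropy ratio is coarse.
- The assay's affine calibrations are empirical and
  instrument/batch-specific; refitting from same-instrument tables is
  recommended, and solvent references must come from the same session.
- Stretched-exponential or anomalous-diffusion decays are out of scope;
  strongly confined probes that no longer follow simple diffusion will
  fail the R² screen rather than be modeled.
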
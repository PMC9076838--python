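# Methods

This note documents the models implemented in `flimaggr`, the defaults and
numerical choices behind them, and what the synthetic generators do and do
not emulate.

## Mean-arrival lifetime estimation

A TCSPC decay is a histogram of photon arrival times relative to the laser
pulse, binned at the channel width Δt inside the repetition window T
(defaults: 20 MHz repetition → T = 50 ns; Δt = 0.016 ns, i.e. 3125
channels). The estimator is the centroid ("fast FLIM") readout: the average
channel index of the decay minus the average channel index of the IRF,
multiplied by Δt. Both centroids use the left-edge index convention, so the
half-channel discretisation offset cancels in the subtraction and only the
distance between the two centroids is meaningful.

Properties relied on by the tests:

* **Truncation bias.** Arrival times of a mono-exponential emitter are
  wrapped into [0, T), so the estimate converges to
  `τ_obs = τ − T·e^(−T/τ)/(1 − e^(−T/τ))`, not τ. At T = 50 ns the bias is
  < 2·10⁻⁵ ns for τ = 3.3 ns and ≈ 0.07 ns for τ = 7.6 ns. The readout is
  reported uncorrected, as centroid FLIM conventionally is;
  `invert_truncation_bias` (and the `correct_truncation` flag) solves the
  bias law for τ when an unbiased value is wanted. The law saturates at
  T/2, so observed values at or above T/2 are uninvertible (returned as
  inf).
* **Linearity.** The centroid of a photon-fraction mixture is the
  fraction-weighted mean of the component centroids, and the estimate is
  invariant under count scaling.
* **Shot noise.** With N photons the centroid standard deviation is ≈
  τ/√N. The per-pixel validity threshold `min_photons` defaults to 100
  (≈ 0.33 ns at τ = 3.3 ns); pixels below it are NaN, never estimated. No
  dark-count background subtraction is applied (a limitation; the synthetic
  scenes contain no dark counts either).

Per-cell statistics (mean pixel lifetime, normalised pixel-lifetime
frequency distributions) exclude the background label and report regions
without valid pixels as flagged-empty rather than failing.

## Aggregate detection and metrics

Aggregates are pixels whose lifetime exceeds a threshold, default 5.0 ns —
between the folded-probe peak (≈ 3.3 ns) and the aggregate plateau
(4.9–7.6 ns). Within each labelled cell, threshold-positive valid pixels
are grouped into connected components (8-connectivity default,
4 selectable) and components smaller than `min_particle_area` (default
4 px²) are discarded. Labelling runs inside each cell mask, so a component
spanning a boundary is split between cells and clipped away from
background. Invalid pixels neither count as aggregate nor contribute to the
cell area. Metrics: per-cell aggregate area fraction, percentage of cells
with ≥ 1 particle, and particle-size frequency distributions converted to
µm² via the pixel size. Cell segmentation is an input (synthetic or
user-supplied label image), not a stage of this package.

Exactness regime: on synthetic scenes with puncta at ≥ 6 ns over a ≤ 3.5 ns
background, ≥ 500 photons/pixel and puncta at least twice the minimum area,
the detector's precision and recall are both 1 (verified over 20 seeds);
the shot-noise separation between background (> 11 σ below threshold) and
puncta makes pixel misclassification astronomically unlikely there. Near
the threshold (puncta at 4.9–5.1 ns) detection is necessarily partial.

## FCS and DLS

The autocorrelation model is pure 3-D diffusion — no triplet term, no
photophysics:

    G(τ) − 1 = (1/N) Σᵢ fᵢ (1 + τ/τ_D,i)⁻¹ (1 + τ/(κ² τ_D,i))^(−1/2)

with mean occupancy N, diffusion times τ_D,i, amplitude fractions fᵢ
(Σfᵢ = 1) and axial ratio κ (fixed at 5 by default — a typical confocal
value — and optionally free). Fitting is least squares on residuals scaled
by the measured amplitude (FCS noise grows with G; absolute residuals are a
flag away), with positivity enforced by log-parameterisation. The
two-species fit parameterises the amplitude split by a single logit (the
sum-to-one constraint is exact), orders species by τ_D, parameterises the
second diffusion time as τ_D,1 plus a positive increment, and restarts from
several initial guesses including the embedded one-species solution — which
is why its residual norm never exceeds the one-species fit's. Two species
with coinciding τ_D are reported with a `degenerate` flag and a warning
(fractions unidentifiable).

Calibration and conversions: `w₀ = √(4 D_ref τ_D,ref)` from a reference dye
(default Atto655-COOH, D = 425 µm²/s in water at 25 °C);
`D = w₀²/(4 τ_D)`; `R_h = k_B T/(6 π η D)` with defaults T = 298.15 K,
η = 8.9·10⁻⁴ Pa·s. DLS correlograms fit `β e^(−2Γτ)` (log-linear start,
nonlinear refinement), `D = Γ/q²`, hydrodynamic diameter `D_h = 2 R_h`;
the scattering vector can be given directly or as
(θ, λ, n) via `q = 4π n sin(θ/2)/λ`.

## Two-state unfolding thermodynamics

The denatured fraction comes from a two-baseline spectral ratio
(tryptophan I330/I355 by default):
`f_D = (ratio − ratio_N)/(ratio_D − ratio_N)`, clipped to [0, 1] with a
flag. Baselines are urea-independent constants, supplied or estimated from
the three points at each end of the urea range. Pointwise free energies
`ΔG⁰ = −RT ln(f_D/(1 − f_D))` (R = 1.9872·10⁻³ kcal mol⁻¹ K⁻¹,
T = 298.15 K default) are computed only for f_D inside a usable window,
default [0.02, 0.98], outside which the log-odds divergence makes single
points dominate; excluded points are signalled, not raised. The linear
extrapolation `ΔG⁰_urea = ΔG⁰_water − m[urea]` is then fitted by weighted
least squares.

The weights are the package's main numerical choice here: constant noise on
the ratio propagates to `σ_ΔG ∝ 1/(f_D(1 − f_D))`, i.e. points near the
window edges are an order of magnitude noisier than points near C_m, and an
unweighted fit lets them dominate the long extrapolation back to zero urea.
The default weights `w = (f_D(1 − f_D))²` are the corresponding inverse
variances; `weighting="none"` restores plain OLS. On noiseless two-state
data both are exact (as is fitting the raw sigmoid directly — the
transform-then-regress route is implemented because it makes the pointwise
ΔG⁰ values, the quantity of interest, explicit).

Derived constants: `C_m = ΔG⁰_water/m`, `K_unf = exp(−ΔG⁰_water/RT)`
(strictly decreasing in ΔG⁰, equal to 1 at zero stability). The
aggregation–metastability relation is an OLS of per-variant aggregate area
fraction on K_unf with R² and slope uncertainty; an all-equal K_unf design
is returned flagged-degenerate.

## Growth and turnover kinetics

Growth: `conf_t = conf₀·2^(t/t_d)` fitted as log₂(conf) vs t; slope ≤ 0 is
returned flagged (infinite or negative doubling time), not raised.
Turnover: intensity is divided by confluence before fitting — the labelled
cohort is shared between daughter cells at division, so the per-cell
amount, not the total, decays with the degradation rate — then
`ln(I/conf)` vs t gives `k_d = −slope` and `t_{1/2} = ln2/k_d` (the
identity holds exactly in every report). Log-linear least squares is the
default because it is exact on noiseless data and convex; a nonlinear
exponential refinement sits behind `nonlinear=True`. Points with
non-positive normalised intensity, or intensity below 3× a supplied
background estimate, are excluded with a warning. A fitted half-life longer
than the observation span is flagged (`half-life exceeds observation
span`); the reported t_{1/2} standard error, which grows as 1/k_d², conveys
the extrapolation uncertainty. A non-positive rate yields k_d = 0,
t_{1/2} = ∞, flag `stable`.

## Synthetic generators

Each generator is the measurable inverse of its fitting stage: noiseless
output recovers the generating parameters to numerical precision (tested
for every pair). Conditions emulated by default:

* **TCSPC decays** — photon-by-photon sampling: arrival = Gaussian IRF draw
  (default centre 2 ns, FWHM 0.2 ns; the IRF shape is a modelling choice,
  as scattered-light IRFs are shape-unspecified) + exponential lifetime
  draw, wrapped modulo the 50 ns window and binned; histograms contain
  exactly the requested photon number. The closed-form expected histogram
  (exponentially-modified Gaussian CDF summed over wraps) is exposed
  separately and serves as the independent distributional oracle in a
  chi-square test.
* **FLIM scenes** — non-overlapping elliptical cells on a dark background;
  in-cell pixels draw lifetimes from N(3.3, 0.1) ns, aggregate puncta are
  circular, fully inside their parent cell with 1-px clearance (so
  8-connected components stay distinct), with per-punctum lifetimes drawn
  Uniform(4.9, 7.6) ns — the observed plateau is a range, not a
  distribution, so uniform is the least-informative stand-in — and
  2× the background brightness (the dye is dim on non-aggregated probe; the
  enrichment factor is unreported, 2 is a modelling default). Photon counts
  are Poisson around 500/pixel. A punctum that cannot be placed raises a
  generation error naming the cell. Not emulated: dark counts, detector
  afterpulsing, optical blur (puncta have hard edges), partial-volume
  pixels, sub-diffraction oligomer populations. Passing detector tests
  therefore demonstrate correctness of the threshold/labelling logic and
  photon-statistics handling, not robustness to blur or camera noise.
* **FCS curves** — generated at the correlation level (not photon traces)
  from particle radii via Stokes–Einstein, with multiplicative Gaussian
  noise (default grids: 64 log-spaced lags over 1 µs–10 s). Triplet
  kinetics and afterpulsing are out of scope.
* **Urea melts** — `f_D(urea) = 1/(1 + e^{ΔG/RT})` between two ratio
  baselines (defaults 1.9/0.9) with additive Gaussian ratio noise, urea
  0–8 M in 0.5 M steps.
* **Growth/turnover series** — 4-hourly sampling over 96 h, confluence
  from 5%, doubling time 20 h, multiplicative noise on the intensity
  channel; infinite half-life gives a constant intensity/confluence ratio.

Problem sizes in the test-suite simulations (96×96 scenes with 0.25 ns
channels, 50-seed noise studies, 10⁶-photon decays at 0.016 ns channels)
were chosen so each check exercises the regime it validates while the whole
suite stays desk-scale.

## Pipeline and provenance

Runs are driven by one schema-validated configuration (pydantic; the first
invalid field is named in the error). Artifacts: FLIM cubes as multi-frame
TIFF + JSON sidecar, label masks and lifetime maps as TIFF, curves/tables
as CSV with `# key = value` provenance headers, fits as JSON with a
provenance block (tool version, seed, config SHA-256 — never timestamps).
The manifest lists every artifact with its checksum; identical
(config, seed) reproduce identical checksums bit for bit. The seed is
echoed at INFO on stderr.

## Known limitations

* The centroid estimator is single-component by construction; mixtures
  within a pixel report the photon-weighted mean lifetime, not the
  components (no multi-exponential or phasor analysis).
* No background/dark-count model in either the estimator or the scenes.
* DLS analysis is single-exponential (no cumulant polydispersity).
* The metastability regression treats per-variant aggregate loads as
  independent scalar observations; no error-in-variables handling of K_unf.
* No empirical mass → R_h relation is provided; users supply reference
  radii where needed.
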
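# flimaggr

Quantitative analysis of protein aggregation as seen by fluorescence
lifetime imaging, built for the workflow in which a solvatochromic dye on a
metastable reporter protein (a destabilised HaloTag expressed in the ER)
reports aggregation through a lifetime shift: the folded probe fluoresces
near 3.3 ns while aggregated species shift to 4.9–7.6 ns and appear as
bright puncta. The package turns the raw measurements of that workflow —
TCSPC photon cubes, FCS/DLS correlograms, urea melts, confluence/intensity
time series — into the numbers used to characterise aggregation and its
clearance, and ships synthetic-data generators with exact ground truth so
every stage is testable without a microscope.

## What it computes

* **Mean-arrival (fast FLIM) lifetimes** — per pixel, the distance between
  the intensity centroid of the TCSPC decay and the centroid of the IRF,
  times the channel width: `τ̄ = (⟨i⟩_decay − ⟨i⟩_IRF)·Δt`. For a
  mono-exponential emitter in a finite window T the estimate converges to
  the wrapped-exponential mean `τ − T·e^(−T/τ)/(1 − e^(−T/τ))`; the bias is
  documented and invertible on request.
* **Aggregate metrics** — threshold the lifetime image (default 5 ns),
  label connected components inside each cell, and report per-cell area
  fractions, the % of cells bearing aggregates, and particle-size
  distributions in µm².
* **FCS/DLS particle sizing** — the pure 3-D diffusion autocorrelation
  `G(τ)−1 = N⁻¹ Σᵢ fᵢ (1+τ/τ_{D,i})⁻¹ (1+τ/(κ²τ_{D,i}))^{−1/2}` fitted with
  1 or 2 species, focal-volume calibration from a reference dye
  (`w₀ = √(4 D_ref τ_{D,ref})`, Atto655 default D = 425 µm²/s), and
  Stokes–Einstein conversion `R_h = k_B T / (6πη D)`; DLS correlograms fit
  `β·e^(−2Γτ)` with `D = Γ/q²`.
* **Two-state unfolding thermodynamics** — `ΔG⁰ = −RT ln(f_D/(1−f_D))`
  pointwise, then the linear extrapolation `ΔG⁰_urea = ΔG⁰_water − m[urea]`
  by (error-propagation-weighted) least squares; derives C_m and
  `K_unf = exp(−ΔG⁰_water/RT)`, and regresses aggregation load on K_unf.
* **Growth and pulse-chase turnover** — `conf_t = conf_0·2^(t/t_d)` for the
  doubling time, and the confluence-normalised label decay
  `I_t/conf_t = (I_0/conf_0)·e^(−k_d t)` with `t_{1/2} = ln2/k_d`.

## Worked example

```python
import flimaggr as fa

# size heat-induced aggregates from a (simulated) FCS curve
curve = fa.simulate_fcs_curve([(48.0, 1.0)], n_mean=5.0, noise_sd_rel=0.01, seed=7)
fit = fa.fit_fcs(curve, n_species=1)
print(f"FCS: tau_D = {fit.tau_d_s[0]*1e3:.2f} ms, D = {fit.d_um2_s[0]:.2f} um^2/s, "
      f"Rh = {fit.rh_nm[0]:.1f} nm")

# stability of the destabilised reporter from a urea melt
melt = fa.simulate_denaturation_curve(2.0, 1.0, noise_sd=0.01, seed=7)
sfit = fa.stability_fit(melt, baselines=(1.9, 0.9))
print(f"Stability: dG0_water = {sfit.dg_water:.2f} kcal/mol, m = {sfit.m_value:.2f}, "
      f"K_unf = {sfit.k_unf:.4f}")

# reporter turnover from a 96 h pulse-chase series sampled every 4 h
series = fa.simulate_growth_turnover(20.0, 41.0, duration=96.0, noise_sd_rel=0.02, seed=7)
kfit = fa.fit_turnover(series)
print(f"Turnover: kd = {kfit.kd_per_h:.4f} /h, t1/2 = {kfit.t_half_h:.1f} h, "
      f"td = {kfit.doubling_time_h:.1f} h")
```

prints

```
FCS: tau_D = 3.07 ms, D = 5.09 um^2/s, Rh = 48.2 nm
Stability: dG0_water = 1.97 kcal/mol, m = 0.99, K_unf = 0.0362
Turnover: kd = 0.0171 /h, t1/2 = 40.6 h, td = 20.0 h
```

The FCS fit recovers the 48 nm hydrodynamic radius the curve was generated
with; the melt fit returns the generating stability (2.0 kcal/mol) and its
unfolding equilibrium constant; the turnover fit returns the generating
41 h half-life with growth divided out.

The same flows run from the shell:

```bash
flimaggr run --config examples/demo_config.json --out demo_out
# status: complete; 20 artifacts
```

which simulates a puncta-bearing cell scene, computes the lifetime image,
detects aggregates (per-cell CSV + summary JSON + mask TIFF), and fits the
FCS, denaturation and turnover branches, writing a `manifest.json` with a
SHA-256 checksum per artifact — identical config + seed reproduces
identical checksums. Individual subcommands (`simulate`, `lifetime`,
`aggregates`, `fcs-fit`, `dls-fit`, `thermo-fit`, `turnover`) expose each
stage on files.

## Layout

| module | contents |
| --- | --- |
| `flimaggr.synthetic` | generators for TCSPC decays, FLIM scenes, FCS curves, melts, turnover series |
| `flimaggr.lifetime` | TCSPC containers, centroid estimator, lifetime images, per-cell histograms |
| `flimaggr.aggregates` | threshold + connected-component detector and aggregation metrics |
| `flimaggr.fcs` | diffusion model/fits, calibration, Stokes–Einstein, DLS |
| `flimaggr.thermo` | two-state linear extrapolation, K_unf, metastability regression |
| `flimaggr.turnover` | growth and confluence-normalised decay fits |
| `flimaggr.io` / `flimaggr.pipeline` / `flimaggr.cli` | file contracts, config schema, staged runs, CLI |

See `docs/methods.md` for the models, defaults and their rationale.
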
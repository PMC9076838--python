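"""Synthetic generators for every input the analysis pipeline consumes.

Each generator is the measurable inverse of its fitting stage and carries its
ground truth, so downstream estimators can be validated without instrument
data:

* ``simulate_tcspc`` — photon-by-photon TCSPC decays: arrival time = IRF draw
  (Gaussian, default FWHM 0.2 ns) + exponential lifetime draw, wrapped into
  the 50 ns window of a 20 MHz pulsed laser and binned at the channel width.
* ``simulate_flim_scene`` — cell scenes: elliptical cells with a native probe
  population (lifetimes ~ N(3.3, 0.1) ns, the folded-probe peak) carrying
  bright circular aggregate puncta whose lifetimes are drawn uniformly from
  the 4.9–7.6 ns plateau observed for the aggregated probe.
* ``simulate_fcs_curve`` — diffusion autocorrelation curves from particle
  radii via Stokes–Einstein, with multiplicative Gaussian noise.
* ``simulate_denaturation_curve`` — two-state urea melts: the denatured
  fraction follows f_D = 1/(1+exp(dG/RT)) with dG = dG_water − m·[urea], read
  out as a fluorescence intensity ratio between two baselines.
* ``simulate_growth_turnover`` — confluence and pulse-labelled intensity
  series sampled every 4 h: exponential growth with doubling time t_d and
  label decay with half-life t_1/2, total label conserved across divisions so
  intensity/confluence decays at exp(−ln2·t/t_1/2).

All randomness flows through one ``numpy.random.Generator`` seeded per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import disk as _disk_pixels
from skimage.draw import ellipse as _ellipse_pixels

from .exceptions import GenerationError, InvalidParameterError
from .fcs import (
    FCSCurve,
    ROOM_TEMPERATURE_K,
    WATER_VISCOSITY_PA_S,
    diffusion_from_radius,
    fcs_model,
)
from .lifetime import FLIMStack, TCSPCHistogram
from .thermo import DenaturationCurve, R_KCAL
from .turnover import TurnoverSeries

__all__ = [
    "SceneSpec",
    "CellSpec",
    "GroundTruth",
    "simulate_tcspc",
    "irf_histogram",
    "expected_decay_histogram",
    "default_cells",
    "simulate_flim_scene",
    "simulate_fcs_curve",
    "simulate_denaturation_curve",
    "simulate_growth_turnover",
]

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))

# default acquisition: 20 MHz repetition -> 50 ns window, 16 ps channels
DEFAULT_REP_PERIOD_NS = 50.0
DEFAULT_BIN_WIDTH_NS = 0.016
DEFAULT_IRF = (2.0, 0.2)            # (centre ns, FWHM ns)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _n_bins(rep_period: float, bin_width: float) -> int:
    if bin_width <= 0 or rep_period <= 0:
        raise InvalidParameterError("bin_width and rep_period must be positive")
    if bin_width >= rep_period:
        raise InvalidParameterError("bin_width must be smaller than rep_period")
    n = rep_period / bin_width
    if abs(n - round(n)) > 1e-6:
        raise InvalidParameterError(
            "rep_period must be an integer number of bins (rep_period/bin_width "
            f"= {n!r})"
        )
    return int(round(n))


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------

def _draw_arrivals(
    rng: np.random.Generator,
    taus: np.ndarray,
    irf: tuple[float, float],
    rep_period: float,
) -> np.ndarray:
    """Photon arrival times: IRF draw + exponential draw, wrapped mod T."""
    center, fwhm = irf
    t = rng.exponential(taus)
    if fwhm > 0:
        t = t + rng.normal(center, fwhm / FWHM_TO_SD, size=t.shape)
    else:
        t = t + center
    return np.mod(t, rep_period)


def simulate_tcspc(
    components: list[tuple[float, float]],
    n_photons: int,
    rep_period: float = DEFAULT_REP_PERIOD_NS,
    bin_width: float = DEFAULT_BIN_WIDTH_NS,
    irf: tuple[float, float] = (0.0, 0.0),
    seed=None,
) -> TCSPCHistogram:
    """Simulate a multi-exponential TCSPC decay histogram of exactly n_photons.

    ``components`` is a list of (lifetime_ns, photon_fraction) pairs whose
    fractions must sum to one; ``irf`` is (centre_ns, fwhm_ns) of a Gaussian
    instrument response (FWHM 0 = delta).
    """
    if n_photons <= 0:
        raise InvalidParameterError("n_photons must be positive")
    taus = np.array([c[0] for c in components], dtype=float)
    fracs = np.array([c[1] for c in components], dtype=float)
    if taus.size == 0 or np.any(taus <= 0):
        raise InvalidParameterError("component lifetimes must be positive")
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("photon fractions must sum to 1")
    n_bins = _n_bins(rep_period, bin_width)
    rng = _rng(seed)
    which = rng.choice(taus.size, size=int(n_photons), p=fracs / fracs.sum())
    arrivals = _draw_arrivals(rng, taus[which], irf, rep_period)
    bins = np.minimum((arrivals / bin_width).astype(np.int64), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins).astype(np.int64)
    return TCSPCHistogram(counts, bin_width, rep_period)


def irf_histogram(
    center: float = DEFAULT_IRF[0],
    fwhm: float = DEFAULT_IRF[1],
    rep_period: float = DEFAULT_REP_PERIOD_NS,
    bin_width: float = DEFAULT_BIN_WIDTH_NS,
    n_photons: int = 1_000_000,
    seed=None,
) -> TCSPCHistogram:
    """Sampled IRF histogram (scattered-light measurement surrogate)."""
    if n_photons <= 0:
        raise InvalidParameterError("n_photons must be positive")
    n_bins = _n_bins(rep_period, bin_width)
    rng = _rng(seed)
    if fwhm > 0:
        t = np.mod(rng.normal(center, fwhm / FWHM_TO_SD, size=int(n_photons)), rep_period)
        bins = np.minimum((t / bin_width).astype(np.int64), n_bins - 1)
        counts = np.bincount(bins, minlength=n_bins)
    else:
        counts = np.zeros(n_bins, dtype=np.int64)
        counts[min(int(center / bin_width), n_bins - 1)] = int(n_photons)
    return TCSPCHistogram(counts.astype(np.int64), bin_width, rep_period)


def expected_decay_histogram(
    components: list[tuple[float, float]],
    rep_period: float = DEFAULT_REP_PERIOD_NS,
    bin_width: float = DEFAULT_BIN_WIDTH_NS,
    irf: tuple[float, float] = (0.0, 0.0),
    total: float = 1.0,
    n_wraps: int = 10,
) -> TCSPCHistogram:
    """Noiseless expected-count decay (float counts) under the same model.

    The arrival-time law of a Gaussian IRF plus an exponential lifetime is
    the exponentially-modified Gaussian; wrapping into the repetition window
    sums its CDF over ``n_wraps`` periods (plus one negative wrap for the
    Gaussian's left tail).  Serves as an independent closed-form oracle for
    the sampling generator.
    """
    taus = np.array([c[0] for c in components], dtype=float)
    fracs = np.array([c[1] for c in components], dtype=float)
    if np.any(taus <= 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("invalid components")
    n_bins = _n_bins(rep_period, bin_width)
    edges = np.arange(n_bins + 1) * bin_width
    center, fwhm = irf
    probs = np.zeros(n_bins)
    for tau, f in zip(taus, fracs):
        if fwhm > 0:
            sigma = fwhm / FWHM_TO_SD
            dist = stats.exponnorm(K=tau / sigma, loc=center, scale=sigma)
        else:
            dist = stats.expon(loc=center, scale=tau)
        cdf = np.zeros(n_bins + 1)
        for k in range(-1, n_wraps + 1):
            cdf += dist.cdf(edges + k * rep_period)
        probs += f * np.diff(cdf)
    return TCSPCHistogram(total * probs, bin_width, rep_period)


# ---------------------------------------------------------------------------
# FLIM scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    """One elliptical cell: centroid (row, col), semi-axes (px) and label."""

    centroid: tuple[float, float]
    axes: tuple[float, float]
    label: int


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic FLIM scene (see module docstring).

    Defaults emulate the live-cell regime: a folded-probe background at
    3.3 ns, aggregate puncta drawn uniformly from the 4.9–7.6 ns plateau,
    and puncta twice as bright as the surrounding reticular signal (the
    probe dye is dim on the non-aggregated protein; the enrichment factor
    is a modelling choice).
    """

    image_size: tuple[int, int] = (64, 64)
    pixel_size: float = 0.1                      # µm
    cells: tuple[CellSpec, ...] = ()
    native_tau_mean: float = 3.3                 # ns
    native_tau_sd: float = 0.1                   # ns
    puncta_per_cell: int = 2
    puncta_tau_range: tuple[float, float] = (4.9, 7.6)
    puncta_radius_range: tuple[float, float] = (2.0, 4.0)
    photons_per_pixel: float = 500.0
    brightness_ratio_aggregate: float = 2.0
    seed: int = 0

    def validate(self, rep_period: float) -> None:
        if self.photons_per_pixel <= 0:
            raise InvalidParameterError("photons_per_pixel must be positive")
        if self.brightness_ratio_aggregate < 1:
            raise InvalidParameterError("brightness_ratio_aggregate must be >= 1")
        lo, hi = self.puncta_tau_range
        if not (0 < lo <= hi < rep_period):
            raise InvalidParameterError("puncta_tau_range must lie inside (0, rep_period)")
        if self.native_tau_mean <= 0 or self.native_tau_sd < 0:
            raise InvalidParameterError("native lifetime parameters invalid")
        if self.puncta_per_cell < 0:
            raise InvalidParameterError("puncta_per_cell must be >= 0")
        rlo, rhi = self.puncta_radius_range
        if not (0 < rlo <= rhi):
            raise InvalidParameterError("puncta_radius_range invalid")


@dataclass(frozen=True)
class GroundTruth:
    """Ground truth of a simulated scene: labels, aggregate mask, puncta table."""

    cell_labels: np.ndarray
    aggregate_mask: np.ndarray
    puncta: pd.DataFrame       # cell_label, punctum_id, row, col, radius_px, tau_ns, area_px2


def default_cells(
    image_size: tuple[int, int] = (64, 64),
    n_cells: int = 4,
    margin: int = 2,
) -> tuple[CellSpec, ...]:
    """Lay out ``n_cells`` non-overlapping elliptical cells on a grid."""
    rows, cols = image_size
    n_side_c = int(np.ceil(np.sqrt(n_cells)))
    n_side_r = int(np.ceil(n_cells / n_side_c))
    tile_r, tile_c = rows / n_side_r, cols / n_side_c
    cells = []
    for k in range(n_cells):
        i, j = divmod(k, n_side_c)
        cr = (i + 0.5) * tile_r
        cc = (j + 0.5) * tile_c
        ar = tile_r / 2.0 - margin
        ac = tile_c / 2.0 - margin
        if ar < 3 or ac < 3:
            raise InvalidParameterError("image too small for the requested cell count")
        cells.append(CellSpec(centroid=(cr, cc), axes=(ar, ac), label=k + 1))
    return tuple(cells)


def _render_cells(spec: SceneSpec) -> np.ndarray:
    labels = np.zeros(spec.image_size, dtype=np.int32)
    for cell in spec.cells:
        rr, cc = _ellipse_pixels(
            cell.centroid[0], cell.centroid[1], cell.axes[0], cell.axes[1],
            shape=spec.image_size,
        )
        if np.any(labels[rr, cc] != 0):
            raise InvalidParameterError(f"cell {cell.label} overlaps another cell")
        labels[rr, cc] = cell.label
    return labels


def _place_puncta(
    rng: np.random.Generator, spec: SceneSpec, labels: np.ndarray
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Place non-touching circular puncta fully inside their parent cells."""
    punctum_id_map = np.zeros(spec.image_size, dtype=np.int32)
    records = []
    pid = 0
    rlo, rhi = spec.puncta_radius_range
    tlo, thi = spec.puncta_tau_range
    for cell in spec.cells:
        in_cell = np.argwhere(labels == cell.label)
        for _ in range(spec.puncta_per_cell):
            radius = rng.uniform(rlo, rhi)
            tau = rng.uniform(tlo, thi)
            placed = False
            for _try in range(200):
                r0, c0 = in_cell[rng.integers(len(in_cell))]
                rr, cc = _disk_pixels((r0, c0), radius, shape=spec.image_size)
                # fully inside the parent cell, not touching an existing punctum
                # (1-px clearance so 8-connected components stay separate)
                rr_pad, cc_pad = _disk_pixels((r0, c0), radius + 1.5, shape=spec.image_size)
                if np.all(labels[rr, cc] == cell.label) and np.all(
                    punctum_id_map[rr_pad, cc_pad] == 0
                ):
                    pid += 1
                    punctum_id_map[rr, cc] = pid
                    records.append(
                        {
                            "cell_label": cell.label,
                            "punctum_id": pid,
                            "row": int(r0),
                            "col": int(c0),
                            "radius_px": float(radius),
                            "tau_ns": float(tau),
                            "area_px2": int(len(rr)),
                        }
                    )
                    placed = True
                    break
            if not placed:
                raise GenerationError(
                    f"could not place a punctum of radius {radius:.1f}px inside "
                    f"cell {cell.label}",
                    cell_label=cell.label,
                )
    puncta = pd.DataFrame(
        records,
        columns=["cell_label", "punctum_id", "row", "col", "radius_px", "tau_ns", "area_px2"],
    )
    return punctum_id_map, puncta, punctum_id_map > 0


def simulate_flim_scene(
    spec: SceneSpec,
    rep_period: float = DEFAULT_REP_PERIOD_NS,
    bin_width: float = DEFAULT_BIN_WIDTH_NS,
    irf: tuple[float, float] = DEFAULT_IRF,
) -> tuple[FLIMStack, GroundTruth]:
    """Simulate a FLIM photon-count cube of puncta-bearing cells + ground truth.

    Every in-cell pixel draws Poisson(photons_per_pixel) photons (scaled by
    the aggregate brightness ratio inside puncta) whose arrival times follow
    the pixel's lifetime: a per-pixel native draw on the reticular
    background, the punctum's own lifetime inside an aggregate.  Background
    outside cells is dark.
    """
    spec.validate(rep_period)
    n_bins = _n_bins(rep_period, bin_width)
    rng = _rng(spec.seed)
    labels = _render_cells(spec)
    punctum_id_map, puncta, aggregate_mask = _place_puncta(rng, spec, labels)

    tau_map = np.zeros(spec.image_size, dtype=float)
    in_cells = labels > 0
    native = rng.normal(spec.native_tau_mean, spec.native_tau_sd, size=int(in_cells.sum()))
    tau_map[in_cells] = np.clip(native, 1e-3, None)
    if len(puncta):
        tau_lookup = np.concatenate([[0.0], puncta["tau_ns"].to_numpy()])
        tau_map[aggregate_mask] = tau_lookup[punctum_id_map[aggregate_mask]]

    expected = np.where(in_cells, spec.photons_per_pixel, 0.0)
    expected = np.where(aggregate_mask, expected * spec.brightness_ratio_aggregate, expected)
    n_per_px = rng.poisson(expected)

    flat_idx = np.repeat(np.arange(n_per_px.size), n_per_px.ravel())
    taus = tau_map.ravel()[flat_idx]
    arrivals = _draw_arrivals(rng, taus, irf, rep_period)
    bins = np.minimum((arrivals / bin_width).astype(np.int64), n_bins - 1)
    counts = np.bincount(flat_idx * n_bins + bins, minlength=n_per_px.size * n_bins)
    data = counts.reshape(*spec.image_size, n_bins).astype(np.int32)

    stack = FLIMStack(data, bin_width=bin_width, rep_period=rep_period, pixel_size=spec.pixel_size)
    truth = GroundTruth(cell_labels=labels, aggregate_mask=aggregate_mask, puncta=puncta)
    return stack, truth


# ---------------------------------------------------------------------------
# FCS curves
# ---------------------------------------------------------------------------

def simulate_fcs_curve(
    species: list[tuple[float, float]],
    n_mean: float,
    w0: float = 0.25,
    kappa: float = 5.0,
    temperature: float = ROOM_TEMPERATURE_K,
    viscosity: float = WATER_VISCOSITY_PA_S,
    lag_grid: np.ndarray | None = None,
    noise_sd_rel: float = 0.0,
    seed=None,
) -> FCSCurve:
    """Simulate G(tau)−1 for a mixture of spherical species given by Rh (nm).

    Diffusion times follow tau_D = w0²/(4D) with D from Stokes–Einstein;
    noise is multiplicative Gaussian with relative sd ``noise_sd_rel``.
    """
    if temperature <= 0 or viscosity <= 0:
        raise InvalidParameterError("temperature and viscosity must be physical")
    if n_mean <= 0:
        raise InvalidParameterError("n_mean must be positive")
    radii = np.array([s[0] for s in species], dtype=float)
    fracs = np.array([s[1] for s in species], dtype=float)
    if np.any(radii <= 0):
        raise InvalidParameterError("hydrodynamic radii must be positive")
    if abs(fracs.sum() - 1.0) > 1e-9 or np.any(fracs < 0):
        raise InvalidParameterError("amplitude fractions must sum to 1")
    if lag_grid is None:
        lag_grid = np.logspace(-6, 1, 64)
    lag = np.asarray(lag_grid, dtype=float)
    if lag.size == 0 or np.any(lag <= 0) or np.any(np.diff(lag) <= 0):
        raise InvalidParameterError("lag_grid must be positive and strictly increasing")
    tau_ds = [
        w0 ** 2 / (4.0 * diffusion_from_radius(rh, temperature, viscosity))
        for rh in radii
    ]
    g = fcs_model(lag, n_mean, list(zip(tau_ds, fracs)), kappa)
    if noise_sd_rel > 0:
        rng = _rng(seed)
        g = g * (1.0 + rng.normal(0.0, noise_sd_rel, size=g.shape))
    return FCSCurve(lag_times=lag, g_minus_1=g)


# ---------------------------------------------------------------------------
# denaturation curves
# ---------------------------------------------------------------------------

def simulate_denaturation_curve(
    dg_water: float,
    m_value: float,
    ratio_native: float = 1.9,
    ratio_denatured: float = 0.9,
    urea_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    temperature: float = ROOM_TEMPERATURE_K,
    seed=None,
) -> DenaturationCurve:
    """Two-state urea melt read out as a tryptophan I330/I355 intensity ratio."""
    if m_value <= 0:
        raise InvalidParameterError("m_value must be positive")
    if ratio_native == ratio_denatured:
        raise InvalidParameterError("native and denatured baselines must differ")
    if urea_grid is None:
        urea_grid = np.arange(0.0, 8.0 + 1e-9, 0.5)
    urea = np.asarray(urea_grid, dtype=float)
    if urea.size == 0:
        raise InvalidParameterError("urea grid must be non-empty")
    rt = R_KCAL * temperature
    dg = dg_water - m_value * urea
    f_d = 1.0 / (1.0 + np.exp(dg / rt))
    ratio = ratio_native + f_d * (ratio_denatured - ratio_native)
    if noise_sd > 0:
        rng = _rng(seed)
        ratio = ratio + rng.normal(0.0, noise_sd, size=ratio.shape)
    return DenaturationCurve(urea=urea, intensity_ratio=ratio, temperature=temperature)


# ---------------------------------------------------------------------------
# growth / turnover series
# ---------------------------------------------------------------------------

def simulate_growth_turnover(
    doubling_time: float,
    half_life: float,
    duration: float = 96.0,
    interval: float = 4.0,
    conf0: float = 5.0,
    intensity0: float = 1000.0,
    noise_sd_rel: float = 0.0,
    seed=None,
) -> TurnoverSeries:
    """Confluence + pulse-labelled intensity series at fixed imaging interval.

    conf_t = conf0·2^(t/td); intensity_t = intensity0·2^(t/td)·exp(−ln2·t/t½)
    (total label conserved across divisions, so intensity/confluence decays
    with the protein's half-life).  ``half_life=inf`` gives a stable label.
    Multiplicative Gaussian noise applies to the intensity channel.
    """
    if doubling_time <= 0 or half_life <= 0:
        raise InvalidParameterError("doubling_time and half_life must be positive")
    if conf0 <= 0:
        raise InvalidParameterError("conf0 must be positive")
    if interval <= 0 or interval > duration:
        raise InvalidParameterError("interval must be positive and <= duration")
    t = np.arange(0.0, duration + 1e-9, interval)
    growth = 2.0 ** (t / doubling_time)
    conf = conf0 * growth
    decay = np.exp(-np.log(2.0) * t / half_life) if np.isfinite(half_life) else np.ones_like(t)
    intensity = intensity0 * growth * decay
    if noise_sd_rel > 0:
        rng = _rng(seed)
        intensity = intensity * (1.0 + rng.normal(0.0, noise_sd_rel, size=t.shape))
    return TurnoverSeries(time_h=t, confluence_pct=conf, tmr_intensity=intensity)
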
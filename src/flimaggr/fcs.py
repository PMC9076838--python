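"""FCS diffusion fitting, focal-volume calibration and Stokes–Einstein sizing.

The autocorrelation of fluorescence fluctuations from a 3-D Gaussian confocal
volume with mean occupancy N and diffusion time tau_D per species i is the
pure-diffusion model (no triplet term):

    G(tau) - 1 = (1/N) * sum_i f_i * (1 + tau/tau_D,i)^-1
                              * (1 + tau/(kappa^2 tau_D,i))^-1/2

with kappa the axial-to-lateral beam-waist ratio and amplitude fractions f_i
summing to one.  The lateral waist w0 is calibrated from a reference dye of
known diffusion coefficient (Atto655-COOH, D = 425 µm²/s in water at 25 °C),
w0 = sqrt(4 D_ref tau_D,ref); fitted diffusion times convert to diffusion
coefficients via D = w0²/(4 tau_D) and to hydrodynamic radii through the
Stokes–Einstein relation R_h = k_B T / (6 pi eta D).

DLS correlograms are fitted to a single-exponential field correlation,
g2(tau) - 1 = beta exp(-2 Gamma tau), with D = Gamma/q² and the hydrodynamic
diameter D_h = 2 R_h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .exceptions import (
    FitFailureError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "FCSCurve",
    "DiffusionFit",
    "DLSFit",
    "fcs_model",
    "fit_fcs",
    "calibrate_focal_volume",
    "diffusion_from_tau",
    "stokes_einstein_radius",
    "diffusion_from_radius",
    "scattering_vector",
    "dls_fit",
    "BOLTZMANN_J_PER_K",
    "WATER_VISCOSITY_PA_S",
    "ROOM_TEMPERATURE_K",
]

BOLTZMANN_J_PER_K = 1.380649e-23
WATER_VISCOSITY_PA_S = 8.9e-4   # water at 25 °C
ROOM_TEMPERATURE_K = 298.15

_FRACTION_TOL = 1e-9


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FCSCurve:
    """Normalised autocorrelation data: lag times (s) vs G(tau) − 1."""

    lag_times: np.ndarray
    g_minus_1: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        lag = np.asarray(self.lag_times, dtype=float)
        g = np.asarray(self.g_minus_1, dtype=float)
        if lag.ndim != 1 or lag.shape != g.shape:
            raise InvalidInputError("lag_times and g_minus_1 must be matching 1-D arrays")
        if np.any(lag <= 0) or np.any(np.diff(lag) <= 0):
            raise InvalidInputError("lag_times must be positive and strictly increasing")
        if not (np.all(np.isfinite(lag)) and np.all(np.isfinite(g))):
            raise InvalidInputError("curve values must be finite")
        object.__setattr__(self, "lag_times", lag)
        object.__setattr__(self, "g_minus_1", g)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != lag.shape or np.any(w < 0):
                raise InvalidInputError("weights must be non-negative and match the grid")
            object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class DiffusionFit:
    """Fitted FCS diffusion parameters and their physical conversions.

    Species are ordered by diffusion time ascending; ``d_um2_s`` and
    ``rh_nm`` are derived from ``tau_d_s`` under the recorded calibration
    (w0) and solution conditions (temperature, viscosity).
    """

    n_mean: float
    tau_d_s: tuple[float, ...]
    fractions: tuple[float, ...]
    kappa: float
    d_um2_s: tuple[float, ...]
    rh_nm: tuple[float, ...]
    residual_norm: float
    temperature: float
    viscosity: float
    w0_um: float
    kappa_free: bool = False
    degenerate: bool = False

    @property
    def n_species(self) -> int:
        return len(self.tau_d_s)


@dataclass(frozen=True)
class DLSFit:
    """Single-exponential DLS fit: decay rate, D and hydrodynamic diameter."""

    gamma_per_s: float
    beta: float
    d_um2_s: float
    dh_nm: float
    residual_norm: float
    q_per_m: float
    temperature: float
    viscosity: float


# ---------------------------------------------------------------------------
# physical conversions
# ---------------------------------------------------------------------------

def calibrate_focal_volume(tau_d_ref: float, d_ref: float = 425.0) -> float:
    """Lateral beam waist w0 (µm) from a reference dye's diffusion time.

    Defaults to the Atto655-COOH calibration value D = 425 µm²/s in water
    at 25 °C.
    """
    if tau_d_ref <= 0 or d_ref <= 0:
        raise InvalidParameterError("tau_d_ref and d_ref must be positive")
    return float(np.sqrt(4.0 * d_ref * tau_d_ref))


def diffusion_from_tau(tau_d: float, w0: float) -> float:
    """Diffusion coefficient D = w0²/(4 tau_D) in µm²/s (w0 in µm, tau_D in s)."""
    if tau_d <= 0 or w0 <= 0:
        raise InvalidParameterError("tau_d and w0 must be positive")
    return w0 ** 2 / (4.0 * tau_d)


def stokes_einstein_radius(
    d_um2_s: float,
    temperature: float = ROOM_TEMPERATURE_K,
    viscosity: float = WATER_VISCOSITY_PA_S,
) -> float:
    """Hydrodynamic radius R_h (nm) from D (µm²/s) via Stokes–Einstein."""
    if d_um2_s <= 0 or temperature <= 0 or viscosity <= 0:
        raise InvalidParameterError("D, temperature and viscosity must be positive")
    d_si = d_um2_s * 1e-12                     # m²/s
    rh_m = BOLTZMANN_J_PER_K * temperature / (6.0 * np.pi * viscosity * d_si)
    return rh_m * 1e9


def diffusion_from_radius(
    rh_nm: float,
    temperature: float = ROOM_TEMPERATURE_K,
    viscosity: float = WATER_VISCOSITY_PA_S,
) -> float:
    """Diffusion coefficient (µm²/s) of a sphere of radius rh_nm (inverse of above)."""
    if rh_nm <= 0 or temperature <= 0 or viscosity <= 0:
        raise InvalidParameterError("Rh, temperature and viscosity must be positive")
    d_si = BOLTZMANN_J_PER_K * temperature / (6.0 * np.pi * viscosity * rh_nm * 1e-9)
    return d_si * 1e12


def scattering_vector(theta_deg: float, wavelength_nm: float, refractive_index: float) -> float:
    """DLS scattering vector q = 4 pi n sin(theta/2) / lambda, in 1/m."""
    if wavelength_nm <= 0 or refractive_index <= 0:
        raise InvalidParameterError("wavelength and refractive index must be positive")
    return (
        4.0 * np.pi * refractive_index
        * np.sin(np.deg2rad(theta_deg) / 2.0)
        / (wavelength_nm * 1e-9)
    )


# ---------------------------------------------------------------------------
# FCS model and fit
# ---------------------------------------------------------------------------

def fcs_model(
    lag: np.ndarray,
    n_mean: float,
    species: list[tuple[float, float]],
    kappa: float,
) -> np.ndarray:
    """Pure 3-D diffusion autocorrelation G(tau) − 1 (see module docstring)."""
    lag = np.asarray(lag, dtype=float)
    if n_mean <= 0 or kappa <= 0:
        raise InvalidParameterError("n_mean and kappa must be positive")
    taus = np.array([s[0] for s in species], dtype=float)
    fracs = np.array([s[1] for s in species], dtype=float)
    if np.any(taus <= 0):
        raise InvalidParameterError("diffusion times must be positive")
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > _FRACTION_TOL:
        raise InvalidParameterError("fractions must be non-negative and sum to 1")
    g = np.zeros_like(lag)
    for tau_d, f in zip(taus, fracs):
        x = lag / tau_d
        g += f / ((1.0 + x) * np.sqrt(1.0 + x / kappa ** 2))
    return g / n_mean


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit

    return expit(x)


def _unpack(theta: np.ndarray, n_species: int, kappa_fixed: float | None):
    n_mean = np.exp(theta[0])
    if n_species == 1:
        taus = [np.exp(theta[1])]
        fracs = [1.0]
        k_idx = 2
    else:
        t1 = np.exp(theta[1])
        taus = [t1, t1 + np.exp(theta[2])]        # enforces tau_D,2 > tau_D,1
        f1 = _logistic(theta[3])
        fracs = [f1, 1.0 - f1]
        k_idx = 4
    kappa = kappa_fixed if kappa_fixed is not None else 1.0 + np.exp(theta[k_idx])
    return n_mean, list(zip(taus, fracs)), kappa


def fit_fcs(
    curve: FCSCurve,
    n_species: int = 1,
    kappa: float = 5.0,
    kappa_free: bool = False,
    init: dict | None = None,
    relative_residuals: bool = True,
    w0: float = 0.25,
    temperature: float = ROOM_TEMPERATURE_K,
    viscosity: float = WATER_VISCOSITY_PA_S,
) -> DiffusionFit:
    """Weighted least-squares fit of the 1- or 2-species diffusion model.

    Residuals are relative (scaled by the measured amplitude) by default
    since FCS noise scales with the correlation amplitude; set
    ``relative_residuals=False`` for absolute residuals.  The two-species
    fit parameterises the amplitude split through a single logit so the
    fractions sum to one exactly, and orders species by diffusion time.
    Optimisation restarts from several initial guesses (including the
    embedded one-species solution), which keeps the two-species residual
    norm at or below the one-species norm on the same curve.
    """
    if n_species not in (1, 2):
        raise InvalidParameterError("n_species must be 1 or 2")
    lag, g = curve.lag_times, curve.g_minus_1
    if g[0] <= 0:
        raise InvalidInputError("curve amplitude must be positive near tau -> 0")

    scale = np.abs(g) if relative_residuals else np.ones_like(g)
    scale = np.where(scale < 1e-12, 1e-12, scale)
    if curve.weights is not None:
        scale = scale / np.sqrt(np.where(curve.weights > 0, curve.weights, 1e-12))

    kappa_fixed = None if kappa_free else float(kappa)

    def residuals(theta):
        n_mean, species, kap = _unpack(theta, n_species, kappa_fixed)
        return (fcs_model(lag, n_mean, species, kap) - g) / scale

    # data-driven initial guess: amplitude -> N, half-amplitude lag -> tau_D
    n0 = 1.0 / g[0]
    half = g[0] / 2.0
    below = np.nonzero(g <= half)[0]
    tau0 = lag[below[0]] if below.size else lag[lag.size // 2]
    if init:
        n0 = init.get("n_mean", n0)
        tau0 = init.get("tau_d", tau0)

    def pack(n_mean, tau1, tau2=None, f1=None):
        theta = [np.log(n_mean), np.log(tau1)]
        if n_species == 2:
            theta += [np.log(max(tau2 - tau1, 1e-12 * tau1)),
                      np.log(f1 / (1.0 - f1))]
        if kappa_fixed is None:
            theta.append(np.log(max(kappa, 1.0 + 1e-6) - 1.0))
        return np.array(theta)

    if n_species == 1:
        starts = [pack(n0, tau0)]
    else:
        starts = [
            pack(n0, tau0 / 3.0, tau0 * 3.0, 0.5),
            pack(n0, tau0, tau0 * 10.0, 0.9),
            pack(n0, tau0 / 10.0, tau0, 0.1),
            pack(n0, tau0, tau0 * 10.0, 1.0 - 1e-6),   # one-species embedding
        ]

    best = None
    for theta0 in starts:
        try:
            sol = least_squares(
                residuals, theta0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=20000,
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError(
            "FCS fit did not converge",
            details={"n_species": n_species, "starts": len(starts)},
        )

    n_mean, species, kap = _unpack(best.x, n_species, kappa_fixed)
    taus = [s[0] for s in species]
    fracs = [s[1] for s in species]
    degenerate = False
    if n_species == 2 and (taus[1] - taus[0]) < 1e-3 * taus[0]:
        degenerate = True
        warnings.warn(
            "two-species diffusion times coincide; amplitude fractions are "
            "unidentifiable", RuntimeWarning, stacklevel=2,
        )
    d = [diffusion_from_tau(t, w0) for t in taus]
    rh = [stokes_einstein_radius(di, temperature, viscosity) for di in d]
    return DiffusionFit(
        n_mean=float(n_mean),
        tau_d_s=tuple(float(t) for t in taus),
        fractions=tuple(float(f) for f in fracs),
        kappa=float(kap),
        d_um2_s=tuple(float(x) for x in d),
        rh_nm=tuple(float(x) for x in rh),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        temperature=temperature,
        viscosity=viscosity,
        w0_um=w0,
        kappa_free=kappa_free,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# DLS
# ---------------------------------------------------------------------------

def dls_fit(
    delay_s: np.ndarray,
    g2_minus_1: np.ndarray,
    q: float | tuple[float, float, float],
    temperature: float = ROOM_TEMPERATURE_K,
    viscosity: float = WATER_VISCOSITY_PA_S,
) -> DLSFit:
    """Fit beta*exp(−2 Gamma tau) to a DLS correlogram and size the particle.

    ``q`` is the scattering vector in 1/m, or a tuple
    (theta_deg, wavelength_nm, refractive_index) from which it is computed.
    Returns the decay rate, D = Gamma/q² (µm²/s) and hydrodynamic diameter
    D_h = 2 R_h (nm).
    """
    delay = np.asarray(delay_s, dtype=float)
    g2 = np.asarray(g2_minus_1, dtype=float)
    if delay.shape != g2.shape or delay.ndim != 1 or delay.size < 4:
        raise InvalidInputError("need matching 1-D arrays with >= 4 points")
    if isinstance(q, tuple):
        q = scattering_vector(*q)
    if q <= 0:
        raise InvalidParameterError("scattering vector must be positive")
    if g2[0] <= 0 or g2[0] <= g2[-1]:
        raise FitFailureError("correlogram does not decay; cannot fit an exponential")

    # log-linear start from the positive early part of the trace
    pos = g2 > 0
    slope, intercept = np.polyfit(delay[pos], np.log(g2[pos]), 1)
    gamma0 = max(-slope / 2.0, 1.0 / (delay[-1] - delay[0]))
    beta0 = float(np.exp(intercept))
    try:
        popt, _ = curve_fit(
            lambda t, beta, gamma: beta * np.exp(-2.0 * gamma * t),
            delay, g2, p0=[beta0, gamma0], maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"DLS exponential fit failed: {exc}") from exc
    beta, gamma = float(popt[0]), float(popt[1])
    if gamma <= 0:
        raise FitFailureError("fitted decay rate is non-positive")
    d_si = gamma / q ** 2                      # m²/s
    d_um = d_si * 1e12
    dh = 2.0 * stokes_einstein_radius(d_um, temperature, viscosity)
    resid = g2 - beta * np.exp(-2.0 * gamma * delay)
    return DLSFit(
        gamma_per_s=gamma, beta=beta, d_um2_s=d_um, dh_nm=dh,
        residual_norm=float(np.linalg.norm(resid)),
        q_per_m=float(q), temperature=temperature, viscosity=viscosity,
    )
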
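"""Two-state unfolding thermodynamics by linear extrapolation.

Chemical denaturation of a two-state folder is analysed in two steps:

1. pointwise free energies,  dG0 = −RT ln(f_D / (1 − f_D)),  from the
   denatured fraction f_D inferred from a spectroscopic ratio between the
   native and denatured baselines;
2. the linear extrapolation model,  dG0_urea = dG0_water − m·[urea],  fitted
   by least squares over points whose f_D lies inside a usable window
   (default [0.02, 0.98]; the log-odds diverge at the extremes).

The default regression is weighted: a constant spectroscopic noise on the
ratio propagates through the log-odds transform to a dG0 standard deviation
proportional to 1/(f_D(1−f_D)), so points near the window edges are far
noisier than points near the midpoint.  Weights w = (f_D(1−f_D))² are the
corresponding inverse variances (constant factors drop out); unweighted
ordinary least squares is available via ``weighting="none"``.  Both are
exact on noiseless two-state data.

The intercept is the unfolding free energy in water, the negative slope the
m-value, C_m = dG0_water/m the midpoint, and the unfolding equilibrium
constant K_unf = exp(−dG0_water/RT) serves as the metastability measure that
the aggregation load is regressed against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "R_KCAL",
    "DenaturationCurve",
    "StabilityFit",
    "MetastabilityRegression",
    "fraction_denatured",
    "dg_from_fraction",
    "equilibrium_constant",
    "stability_fit",
    "metastability_regression",
]

R_KCAL = 1.9872e-3       # gas constant, kcal mol^-1 K^-1
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_FD_WINDOW = (0.02, 0.98)


@dataclass(frozen=True)
class DenaturationCurve:
    """[urea] (M) vs tryptophan I330/I355 intensity ratio at one temperature."""

    urea: np.ndarray
    intensity_ratio: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        urea = np.asarray(self.urea, dtype=float)
        ratio = np.asarray(self.intensity_ratio, dtype=float)
        if urea.ndim != 1 or urea.shape != ratio.shape or urea.size == 0:
            raise InvalidParameterError("urea and ratio must be matching non-empty 1-D arrays")
        if np.any(urea < 0) or not np.all(np.isfinite(ratio)):
            raise InvalidParameterError("urea must be >= 0 and ratios finite")
        object.__setattr__(self, "urea", urea)
        object.__setattr__(self, "intensity_ratio", ratio)


@dataclass(frozen=True)
class StabilityFit:
    """Linear-extrapolation fit result: dG0_water, m-value and derived constants."""

    dg_water: float            # kcal/mol
    m_value: float             # kcal/mol/M
    cm: float                  # M, = dg_water/m_value
    k_unf: float               # exp(−dg_water/RT)
    temperature: float
    window: tuple[float, float]
    n_used: int
    used_mask: np.ndarray      # which curve points entered the regression
    r_squared: float
    residuals: np.ndarray      # kcal/mol, over used points
    stderr_dg: float
    stderr_m: float
    baselines: tuple[float, float]


@dataclass(frozen=True)
class MetastabilityRegression:
    """OLS of aggregation load on K_unf across probe variants."""

    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float
    p_value: float
    degenerate: bool = False


def fraction_denatured(
    ratio: np.ndarray | float,
    ratio_native: float,
    ratio_denatured: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Denatured fraction from a spectral ratio, clipped to [0, 1].

    Returns ``(f_d, clipped)`` where ``clipped`` flags values that fell
    outside [0, 1] before clipping (baseline noise).
    """
    if ratio_native == ratio_denatured:
        raise InvalidParameterError("native and denatured baselines must differ")
    ratio = np.asarray(ratio, dtype=float)
    f_d = (ratio - ratio_native) / (ratio_denatured - ratio_native)
    clipped = (f_d < 0.0) | (f_d > 1.0)
    return np.clip(f_d, 0.0, 1.0), clipped


def dg_from_fraction(
    f_d: np.ndarray | float,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> np.ndarray | float:
    """Pointwise unfolding free energy −RT ln(f_D/(1−f_D)) in kcal/mol.

    Values at or outside {0, 1} return NaN (excluded-point signal) rather
    than raising.
    """
    f = np.asarray(f_d, dtype=float)
    rt = R_KCAL * temperature
    with np.errstate(divide="ignore", invalid="ignore"):
        dg = -rt * np.log(f / (1.0 - f))
    dg = np.where((f <= 0.0) | (f >= 1.0), np.nan, dg)
    return float(dg) if np.isscalar(f_d) else dg


def equilibrium_constant(
    dg_water: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Unfolding equilibrium constant K_unf = exp(−dG0_water/RT)."""
    return float(np.exp(-dg_water / (R_KCAL * temperature)))


def _estimate_baselines(curve: DenaturationCurve, n_points: int = 3) -> tuple[float, float]:
    """Constant baselines from the curve's flat ends (lowest/highest [urea])."""
    order = np.argsort(curve.urea)
    ratio = curve.intensity_ratio[order]
    return float(ratio[:n_points].mean()), float(ratio[-n_points:].mean())


def _weighted_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """WLS line fit: (intercept, slope, se_intercept, se_slope, r²)."""
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    sxx = (w * (x - xb) ** 2).sum()
    slope = (w * (x - xb) * (y - yb)).sum() / sxx
    intercept = yb - slope * xb
    resid = y - (intercept + slope * x)
    dof = max(x.size - 2, 1)
    s2 = (w * resid ** 2).sum() / dof
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / W + xb ** 2 / sxx))
    syy = (w * (y - yb) ** 2).sum()
    r2 = 1.0 - (w * resid ** 2).sum() / syy if syy > 0 else np.nan
    return intercept, slope, se_intercept, se_slope, r2, resid


def stability_fit(
    curve: DenaturationCurve,
    baselines: tuple[float, float] | None = None,
    window: tuple[float, float] = DEFAULT_FD_WINDOW,
    temperature: float | None = None,
    weighting: str = "propagated",
) -> StabilityFit:
    """Two-state linear-extrapolation fit of a urea denaturation curve.

    ``baselines`` is (ratio_native, ratio_denatured); when omitted both are
    estimated as the mean of the three points at each end of the urea range.
    Only points with f_D strictly inside ``window`` enter the regression;
    fewer than three usable points raises ``InsufficientDataError``.
    ``weighting="propagated"`` (default) weights each point by the inverse
    variance of its transformed dG0 under constant ratio noise,
    w = (f_D(1−f_D))²; ``weighting="none"`` gives unweighted OLS.
    """
    if weighting not in ("propagated", "none"):
        raise InvalidParameterError("weighting must be 'propagated' or 'none'")
    temp = curve.temperature if temperature is None else temperature
    if baselines is None:
        baselines = _estimate_baselines(curve)
    f_d, _clipped = fraction_denatured(curve.intensity_ratio, *baselines)
    usable = (f_d > window[0]) & (f_d < window[1])
    if int(usable.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(usable.sum())} points with f_D inside {window}; need >= 3"
        )
    f_use = f_d[usable]
    dg = dg_from_fraction(f_use, temp)
    urea = curve.urea[usable]
    if weighting == "propagated":
        w = (f_use * (1.0 - f_use)) ** 2
    else:
        w = np.ones_like(f_use)
    intercept, slope, se_i, se_s, r2, resid = _weighted_line(urea, dg, w)
    dg_water = float(intercept)
    m_value = float(-slope)
    return StabilityFit(
        dg_water=dg_water,
        m_value=m_value,
        cm=dg_water / m_value if m_value != 0 else np.nan,
        k_unf=equilibrium_constant(dg_water, temp),
        temperature=temp,
        window=tuple(window),
        n_used=int(usable.sum()),
        used_mask=usable,
        r_squared=float(r2),
        residuals=resid,
        stderr_dg=float(se_i),
        stderr_m=float(se_s),
        baselines=tuple(float(b) for b in baselines),
    )


def metastability_regression(
    k_unf: np.ndarray,
    aggregate_area_fraction: np.ndarray,
) -> MetastabilityRegression:
    """OLS of per-variant aggregation load on the unfolding equilibrium constant."""
    k = np.asarray(k_unf, dtype=float)
    y = np.asarray(aggregate_area_fraction, dtype=float)
    if k.shape != y.shape or k.ndim != 1:
        raise InvalidParameterError("k_unf and area fractions must be matching 1-D arrays")
    if k.size < 3:
        raise InsufficientDataError("need at least 3 variants for the regression")
    if np.allclose(k, k[0]):
        return MetastabilityRegression(
            slope=np.nan, intercept=np.nan, r_squared=np.nan,
            stderr_slope=np.nan, p_value=np.nan, degenerate=True,
        )
    res = _stats.linregress(k, y)
    return MetastabilityRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        stderr_slope=float(res.stderr),
        p_value=float(res.pvalue),
    )
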
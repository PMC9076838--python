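"""Growth and pulse-chase turnover kinetics from automated-microscopy series.

Two single-exponential fits on co-sampled confluence/intensity time series:

* growth — % conf_t = % conf_t0 · 2^(t/td); log2-linear least squares gives
  the doubling time td as 1/slope.
* turnover — the pulse-labelled probe intensity is first divided by
  confluence (label is shared between daughter cells at division, so the
  per-cell amount, not the total, reports degradation), then
  I_t/conf_t = (I_0/conf_0) · exp(−kd·t) is fitted log-linearly; kd = −slope
  and t1/2 = ln2/kd.

Log-linear least squares is the default (exact on noiseless data, convex);
a nonlinear exponential refinement is available behind ``nonlinear=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats
from scipy.optimize import curve_fit

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = ["TurnoverSeries", "GrowthFit", "KineticsFit", "fit_growth", "fit_turnover"]

LN2 = float(np.log(2.0))
_SLOPE_EPS = 1e-12


@dataclass(frozen=True)
class TurnoverSeries:
    """Time (h), % confluence and TMR integrated intensity, co-sampled."""

    time_h: np.ndarray
    confluence_pct: np.ndarray
    tmr_intensity: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        conf = np.asarray(self.confluence_pct, dtype=float)
        if t.ndim != 1 or t.shape != conf.shape or t.size == 0:
            raise InvalidParameterError("time and confluence must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("time must be strictly increasing")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "confluence_pct", conf)
        if self.tmr_intensity is not None:
            i = np.asarray(self.tmr_intensity, dtype=float)
            if i.shape != t.shape:
                raise InvalidParameterError("intensity must be co-sampled with time")
            object.__setattr__(self, "tmr_intensity", i)

    @property
    def span_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])


@dataclass(frozen=True)
class GrowthFit:
    doubling_time_h: float
    stderr_h: float
    r_squared: float
    negative_growth: bool = False


@dataclass(frozen=True)
class KineticsFit:
    """Degradation fit; t_half_h = ln2/kd holds exactly by construction."""

    kd_per_h: float
    t_half_h: float
    stderr_kd: float
    stderr_t_half: float
    residual_norm: float
    n_used: int
    doubling_time_h: float
    flags: tuple[str, ...] = ()


def fit_growth(series: TurnoverSeries) -> GrowthFit:
    """Doubling time from log2-linear least squares on the confluence series."""
    t, conf = series.time_h, series.confluence_pct
    if t.size < 4:
        raise InsufficientDataError("growth fit needs >= 4 points")
    if np.any(conf <= 0):
        raise InvalidParameterError("confluence must be positive")
    res = _stats.linregress(t, np.log2(conf))
    slope = float(res.slope)
    if slope <= _SLOPE_EPS:
        return GrowthFit(
            doubling_time_h=np.inf if abs(slope) <= _SLOPE_EPS else 1.0 / slope,
            stderr_h=np.nan,
            r_squared=float(res.rvalue ** 2) if np.isfinite(res.rvalue) else np.nan,
            negative_growth=True,
        )
    td = 1.0 / slope
    return GrowthFit(
        doubling_time_h=td,
        stderr_h=float(res.stderr) * td ** 2,     # delta method on 1/slope
        r_squared=float(res.rvalue ** 2),
    )


def fit_turnover(
    series: TurnoverSeries,
    background: float = 0.0,
    nonlinear: bool = False,
) -> KineticsFit:
    """Degradation rate and half-life from a confluence-normalised decay.

    Points with non-positive normalised intensity, or intensity below three
    times ``background``, are excluded with a warning.  When the fitted
    half-life exceeds the observation span the result is flagged
    ``half-life exceeds observation span`` (its uncertainty is then
    dominated by extrapolation).  A non-positive fitted rate yields kd = 0,
    t1/2 = inf and the ``stable`` flag.
    """
    t = series.time_h
    if series.tmr_intensity is None:
        raise InvalidParameterError("series has no intensity channel")
    if np.any(series.confluence_pct <= 0):
        raise InvalidParameterError("confluence must be positive for normalisation")
    y = series.tmr_intensity / series.confluence_pct
    usable = (y > 0) & (series.tmr_intensity > 3.0 * background)
    if not np.all(usable):
        warnings.warn(
            f"excluded {int((~usable).sum())} non-positive/background points",
            RuntimeWarning, stacklevel=2,
        )
    if int(usable.sum()) < 4:
        raise InsufficientDataError("turnover fit needs >= 4 usable points")
    tt, yy = t[usable], y[usable]
    res = _stats.linregress(tt, np.log(yy))
    kd = -float(res.slope)
    se_kd = float(res.stderr)
    if nonlinear and kd > 0:
        try:
            popt, pcov = curve_fit(
                lambda x, a, k: a * np.exp(-k * x), tt, yy,
                p0=[float(yy[0]), kd], maxfev=20000,
            )
            kd = float(popt[1])
            se_kd = float(np.sqrt(pcov[1, 1]))
        except RuntimeError:
            warnings.warn("nonlinear refinement failed; keeping log-linear fit",
                          RuntimeWarning, stacklevel=2)
    flags: list[str] = []
    try:
        growth = fit_growth(series)
        td = growth.doubling_time_h
    except (InsufficientDataError, InvalidParameterError):
        td = np.nan
    if kd <= 0:
        flags.append("stable")
        kd_out, t_half, se_thalf = 0.0, np.inf, np.inf
    else:
        kd_out = kd
        t_half = LN2 / kd
        se_thalf = LN2 / kd ** 2 * se_kd
        if t_half > series.span_h:
            flags.append("half-life exceeds observation span")
    fitted = res.intercept + res.slope * tt
    return KineticsFit(
        kd_per_h=kd_out,
        t_half_h=t_half,
        stderr_kd=se_kd,
        stderr_t_half=se_thalf,
        residual_norm=float(np.linalg.norm(np.log(yy) - fitted)),
        n_used=int(usable.sum()),
        doubling_time_h=td,
        flags=tuple(flags),
    )
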
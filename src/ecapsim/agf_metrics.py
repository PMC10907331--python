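"""Sigmoid fits of eCAP AGFs and the three IPG-effect metrics.

The amplitude-growth function is summarised by the asymmetric sigmoid

    y(x) = y0 + B / (1 + exp(-D (x - C)))^z

with baseline y0 (uV), maximum observable amplitude B (uV), symmetric
inflection parameter C (nC), rate of change D (1/nC) and asymmetry z.
From the fitted parameters follow, in closed form, the asymmetry-adjusted
inflection point x0 = C + ln(z)/D, the AGF slope at the steepest point
theta = B D (z/(z+1))^(z+1), and the eCAP threshold
x_THR = C + (ln(z) - (z+1)/z)/D, the charge at which the tangent through
(x0, y(x0)) meets the baseline.

The inter-phase-gap (IPG) effect between a short- and a long-IPG AGF of
the same condition is computed three ways: the absolute effect
theta_long - theta_short, the relative effect theta_long / theta_short
(both on the linear input-output scale), and the IPG offset — the mean
horizontal distance, in dB re 1 nC, between the two AGFs on a log-log
scale over the amplitude range where both grow linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .ecap import AGF


def sigmoid(x, y0, b, c, d, z):
    """Asymmetric sigmoid y0 + B / (1 + e^{-D(x-C)})^z, overflow-safe."""
    x = np.asarray(x, dtype=float)
    # (1 + e^t)^(-z) = exp(-z * log(1 + e^t))
    return y0 + b * np.exp(-z * np.logaddexp(0.0, -d * (x - c)))


@dataclass
class SigmoidFit:
    """Fitted sigmoid parameters with derived AGF characteristics."""

    y0: float
    b: float
    c: float
    d: float
    z: float
    rss: float = np.nan
    accepted: bool = True
    message: str = ""

    @property
    def x0(self) -> float:
        """Asymmetry-adjusted inflection point, nC."""
        return self.c + np.log(self.z) / self.d

    @property
    def theta(self) -> float:
        """Slope at the inflection point, uV/nC."""
        return self.b * self.d * (self.z / (self.z + 1.0)) ** (self.z + 1.0)

    @property
    def x_thr(self) -> float:
        """eCAP threshold: tangent-baseline intersection, nC."""
        return self.c + (np.log(self.z) - (self.z + 1.0) / self.z) / self.d

    def predict(self, x):
        return sigmoid(x, self.y0, self.b, self.c, self.d, self.z)


def slope(fit: SigmoidFit) -> float:
    """theta = B D (z/(z+1))^(z+1), uV/nC."""
    return fit.theta


def threshold(fit: SigmoidFit) -> float:
    """x_THR = C + (ln z - (z+1)/z)/D, nC."""
    return fit.x_thr


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    y0 = float(y.min())
    b = float(y.max() - y.min())
    if b <= 0:
        b = 1.0
    half = y0 + 0.5 * b
    above = np.flatnonzero(y >= half)
    c = float(x[above[0]]) if above.size else float(np.median(x))
    dy = np.gradient(y, x)
    rough = float(np.max(dy)) if np.all(np.isfinite(dy)) else b / max(np.ptp(x), 1e-9)
    d = max(4.0 * rough / b, 1e-3)
    return y0, b, c, d, 1.0


def fit_sigmoid(agf: AGF | tuple, max_nfev: int = 20_000) -> SigmoidFit:
    """Least-squares sigmoid fit of an AGF (Levenberg-Marquardt).

    Requires at least six points spanning sub- and supra-threshold
    charges.  If the unconstrained LM solution lands outside the accepted
    region (B, D, z > 0) or fails, a bounded trust-region fit is tried;
    fits that still fail are returned with ``accepted=False`` and are
    excluded from the IPG metrics downstream.
    """
    if isinstance(agf, AGF):
        x, y = agf.charges, agf.amplitudes
    else:
        x, y = np.asarray(agf[0], dtype=float), np.asarray(agf[1], dtype=float)
    if x.size < 6:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, accepted=False,
                          message="need >= 6 AGF points")
    if np.allclose(y, y[0]):
        return SigmoidFit(float(y[0]), np.nan, np.nan, np.nan, np.nan, accepted=False,
                          message="degenerate (flat) AGF")

    p0 = _initial_guess(x, y)

    def _result(popt, message=""):
        resid = y - sigmoid(x, *popt)
        return SigmoidFit(*map(float, popt), rss=float(resid @ resid), message=message)

    try:
        popt, _ = curve_fit(sigmoid, x, y, p0=p0, method="lm", maxfev=max_nfev)
        if popt[1] > 0 and popt[3] > 0 and popt[4] > 0 and np.all(np.isfinite(popt)):
            return _result(popt, "lm")
    except (RuntimeError, ValueError):
        pass
    # bounded fallback: keep B, D, z positive
    try:
        lo = [-np.inf, 1e-9, -np.inf, 1e-6, 1e-3]
        hi = [np.inf, np.inf, np.inf, np.inf, 1e3]
        p0b = np.clip(p0, lo, hi)
        popt, _ = curve_fit(sigmoid, x, y, p0=p0b, bounds=(lo, hi), method="trf",
                            max_nfev=max_nfev)
        fit = _result(popt, "trf (bounded)")
        at_bound = np.any(np.isclose(popt, lo, rtol=1e-6) | np.isclose(popt, hi, rtol=1e-6))
        if at_bound:
            fit.accepted = False
            fit.message += "; parameter at bound"
        return fit
    except (RuntimeError, ValueError) as exc:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, accepted=False,
                          message=f"fit failed: {exc}")


def ipg_effect_absolute(fit_short: SigmoidFit, fit_long: SigmoidFit) -> float:
    """theta(long IPG) - theta(short IPG), uV/nC."""
    return fit_long.theta - fit_short.theta


def ipg_effect_relative(fit_short: SigmoidFit, fit_long: SigmoidFit) -> float:
    """theta(long IPG) / theta(short IPG); NaN when the short slope vanishes."""
    if not np.isfinite(fit_short.theta) or fit_short.theta == 0:
        return np.nan
    return fit_long.theta / fit_short.theta


@dataclass
class OffsetResult:
    offset_db: float  # dB re 1 nC; positive = long IPG needs less charge
    range_db: tuple[float, float]  # applicable eCAP range, dB re 1 uV
    valid: bool = True
    message: str = ""


def _log_log_curve(agf: AGF, fit: SigmoidFit | None, n_grid: int = 400):
    """Monotone (X, Y) curve of an AGF in dB: X = 20 log10(x), Y = 20 log10(y - y0)."""
    if fit is None or not fit.accepted:
        fit = fit_sigmoid(agf)
    if not fit.accepted:
        return None
    x_lo = max(float(agf.charges[agf.charges > 0].min()), 1e-3) if np.any(agf.charges > 0) else 1e-3
    x = np.geomspace(x_lo, float(agf.charges.max()), n_grid)
    y_net = fit.predict(x) - fit.y0
    ok = y_net > 1e-9
    if ok.sum() < 8:
        return None
    x, y_net = x[ok], y_net[ok]
    return 20.0 * np.log10(x), 20.0 * np.log10(y_net), fit


def _linear_range(
    X: np.ndarray, Y: np.ndarray, slope_tol: float, ref_y: float | None = None
) -> tuple[float, float] | None:
    """Y-interval of near-constant log-log slope around a mid-curve anchor.

    The anchor defaults to 6 dB below the maximum amplitude (the half-
    maximum point); the interval grows contiguously from there while the
    local slope stays within ``slope_tol`` (relative) of the anchor slope,
    which excludes both the exponential foot and the saturating top.
    """
    s = np.gradient(Y, X)
    if ref_y is None:
        ref_y = float(Y.max()) - 6.0
    i_ref = int(np.argmin(np.abs(Y - ref_y)))
    s_ref = s[i_ref]
    if not np.isfinite(s_ref) or s_ref <= 0.05:
        return None
    near = np.abs(s - s_ref) <= slope_tol * s_ref
    lo = i_ref
    while lo > 0 and near[lo - 1]:
        lo -= 1
    hi = i_ref
    while hi < Y.size - 1 and near[hi + 1]:
        hi += 1
    if hi - lo < 3:
        return None
    return float(Y[lo]), float(Y[hi])


def ipg_offset(
    agf_short: AGF,
    agf_long: AGF,
    fit_short: SigmoidFit | None = None,
    fit_long: SigmoidFit | None = None,
    amplitude_range_db: tuple[float, float] | None = None,
    slope_tol: float = 0.25,
    n_levels: int = 50,
) -> OffsetResult:
    """Mean horizontal offset (dB re 1 nC) between the log-log AGFs.

    Both AGFs are expressed as eCAP amplitude (dB re 1 uV, baseline
    corrected) versus charge (dB re 1 nC).  Unless
    ``amplitude_range_db`` overrides it, the applicable eCAP range is
    found automatically as the amplitude interval over which each curve's
    local slope stays within ``slope_tol`` of its median growth slope,
    intersected across the two curves.  The offset is the mean, over a
    grid of amplitude levels in that range, of X_short(Y) - X_long(Y);
    positive values mean the long-IPG AGF reaches the same amplitude at
    less charge.
    """
    cs = _log_log_curve(agf_short, fit_short)
    cl = _log_log_curve(agf_long, fit_long)
    if cs is None or cl is None:
        return OffsetResult(np.nan, (np.nan, np.nan), False, "degenerate or unfit AGF")
    Xs, Ys, _ = cs
    Xl, Yl, _ = cl

    if amplitude_range_db is None:
        rs = _linear_range(Xs, Ys, slope_tol)
        rl = _linear_range(Xl, Yl, slope_tol)
        if rs is None or rl is None:
            return OffsetResult(np.nan, (np.nan, np.nan), False, "no linear growth region")
        lo, hi = max(rs[0], rl[0]), min(rs[1], rl[1])
    else:
        lo, hi = amplitude_range_db
    lo = max(lo, float(Ys.min()), float(Yl.min()))
    hi = min(hi, float(Ys.max()), float(Yl.max()))
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        return OffsetResult(np.nan, (lo, hi), False, "empty applicable range")

    levels = np.linspace(lo, hi, n_levels)
    # invert the monotone Y(X) curves: charge (dB) at each amplitude level
    x_s = np.interp(levels, Ys, Xs)
    x_l = np.interp(levels, Yl, Xl)
    return OffsetResult(float(np.mean(x_s - x_l)), (lo, hi))
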
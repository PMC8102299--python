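"""Nonlinear least-squares estimators for every model in :mod:`core_models`.

All fits share the same strategy: decay constants / positions / widths are
seeded on coarse deterministic grids, the amplitudes entering linearly are
solved by non-negative linear least squares (a variable-projection style
initialisation), and the best few seeds are polished by bounded
trust-region least squares.  Model order, where optional, is chosen by the
corrected Akaike criterion with a two-unit guard in favour of the smaller
model.  1-sigma uncertainties come from the Jacobian-based covariance
``s^2 (J^T J)^+`` and can be rendered in parenthesis notation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares, nnls

from . import core_models as cm
from .constants import GAMMA_MIXED
from .datasets import FIDTrace, HydrationCourse, IsothermData, SoluteRatios, Spectrum

__all__ = [
    "EstimationError",
    "FitResult",
    "ThresholdFit",
    "fit_kinetics",
    "fit_dehydration",
    "fit_isotherm",
    "fit_fid",
    "fit_spectrum",
    "fit_solute_combined",
    "detect_threshold",
    "aicc",
    "format_parenthesis",
]

_TINY = 1e-12


class EstimationError(RuntimeError):
    """A fit could not be completed; carries the best candidate if any."""

    def __init__(self, message: str, best: Optional["FitResult"] = None):
        super().__init__(message)
        self.best = best


@dataclass
class FitResult:
    """A fitted parameter bundle with uncertainties and diagnostics."""

    params: object
    sigma: dict
    rss: float
    n_points: int
    model_order: int = 1
    criterion_values: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def summary(self) -> dict:
        """Human-readable parameter strings in parenthesis notation."""
        out = {}
        for name, err in self.sigma.items():
            out[name] = format_parenthesis(getattr(self.params, name), err)
        return out


@dataclass
class ThresholdFit:
    """Result of rational-to-linear changepoint detection on L/S data.

    ``below_params`` encodes the rational segment as a
    :class:`~hydronmr.core_models.SoluteModelParams` with ``gamma = delta = 1``
    so that ``cs/(1-cs)`` equals the fitted rational coefficient; only ``k``
    and that coefficient are identified from L/S data alone.
    """

    threshold: Optional[float]
    below_params: Optional[cm.SoluteModelParams]
    above_slope: Optional[float]
    above_intercept: Optional[float]
    evidence: float
    criterion_values: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shared numerics
# ---------------------------------------------------------------------------


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit."""
    rss = max(float(rss), 1e-300)
    value = n * math.log(rss / n) + 2 * k
    if n - k - 1 <= 0:
        return math.inf
    return value + 2.0 * k * (k + 1) / (n - k - 1)


def format_parenthesis(value: float, sigma: float) -> str:
    """Render ``value`` with 1-sigma uncertainty in parenthesis notation.

    Examples: (0.51, 0.05) -> "0.51(5)"; (0.88, 0.12) -> "0.88(12)";
    (9.81, 1.02) -> "9.8(1.0)".  Two significant digits are kept on the
    uncertainty when its leading digit is 1 or 2, one otherwise.
    """
    if not np.isfinite(sigma) or sigma <= 0:
        return f"{value:g}"
    lead = int(f"{sigma:e}"[0])
    ndig = 2 if lead in (1, 2) else 1
    exp = math.floor(math.log10(sigma))
    dec = max(-(exp - ndig + 1), 0)
    rounded_sigma = round(sigma, dec if dec > 0 else -exp)
    if rounded_sigma < 1:
        paren = f"{round(rounded_sigma * 10 ** dec):d}"
    else:
        paren = f"{rounded_sigma:.{dec}f}"
    return f"{value:.{dec}f}({paren})"


def _refine(resid, x0, bounds, max_nfev=20000):
    x0 = np.clip(np.asarray(x0, float), bounds[0], bounds[1])
    return least_squares(
        resid, x0, bounds=bounds, method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_nfev,
    )


def _covariance_sigma(jac: np.ndarray, rss: float, n: int) -> np.ndarray:
    """1-sigma parameter uncertainties from J at the solution.

    Uses the pseudo-inverse so that rank-deficient (non-identifiable)
    directions surface as very large uncertainties rather than crashes.
    """
    p = jac.shape[1]
    if n <= p:
        return np.full(p, np.inf)
    s2 = rss / (n - p)
    jtj = jac.T @ jac
    cov = s2 * np.linalg.pinv(jtj, rcond=1e-15)
    diag = np.clip(np.diag(cov), 0.0, None)
    return np.sqrt(diag)


def _numeric_jacobian(fun, x, rel_step=1e-6):
    x = np.asarray(x, float)
    f0 = np.asarray(fun(x))
    jac = np.empty((f0.size, x.size))
    for i in range(x.size):
        h = rel_step * max(abs(x[i]), 1e-8)
        xp = x.copy()
        xp[i] += h
        jac[:, i] = (np.asarray(fun(xp)) - f0) / h
    return jac


def _choose_order(candidates: dict, y_scale: float = 0.0) -> tuple[int, dict]:
    """Pick model order by AICc; the larger model must improve by >= 2.

    RSS values are floored at the square of 1e-10 times the signal norm so
    that fits which are both exact to machine precision tie (and the
    parameter penalty then favours the smaller model).
    """
    floor = (1e-10 * y_scale) ** 2
    crit = {
        f"aicc_order{k}": aicc(max(r.rss, floor), r.n_points, _n_free(r))
        for k, r in candidates.items()
    }
    orders = sorted(candidates)
    best = orders[0]
    for k in orders[1:]:
        if crit[f"aicc_order{best}"] - crit[f"aicc_order{k}"] >= 2.0:
            best = k
    return best, crit


def _n_free(result: FitResult) -> int:
    return len(result.sigma)


# ---------------------------------------------------------------------------
# sorption kinetics
# ---------------------------------------------------------------------------

_KINETICS_TAU_GRID = np.geomspace(0.1, 100.0, 25)  # hours
_N_RESTARTS = 5


def fit_kinetics(course: HydrationCourse, order="auto") -> FitResult:
    """Fit the 1- or 2-component hydration kinetics model to a time course.

    ``order`` may be 1, 2 or ``"auto"``; auto fits both and keeps the
    larger model only when it improves AICc by at least two units.
    """
    t = course.time_h
    y = course.dm_over_m0
    if order not in (1, 2, "auto"):
        raise ValueError("order must be 1, 2 or 'auto'")
    min_pts = {1: 6, 2: 10}
    if np.ptp(y) < 1e-12 * max(1.0, float(np.abs(y).max())):
        params = cm.KineticsParams(A0=float(y.mean()), A1=0.0, t1=1.0)
        return FitResult(
            params=params,
            sigma={"A0": 0.0, "A1": 0.0, "t1": np.inf},
            rss=float(np.sum((y - y.mean()) ** 2)),
            n_points=len(y), model_order=1,
            flags=["degenerate: constant course, zero-amplitude fit"],
        )

    candidates = {}
    for k in ([1, 2] if order == "auto" else [int(order)]):
        if len(t) < min_pts[k]:
            if order == "auto":
                continue
            raise EstimationError(
                f"need >= {min_pts[k]} points for order {k}, got {len(t)}"
            )
        candidates[k] = _fit_kinetics_order(t, y, k)
    if not candidates:
        raise EstimationError("too few points for any model order")
    best, crit = _choose_order(candidates, float(np.linalg.norm(y)))
    result = candidates[best]
    result.criterion_values = crit
    return result


def _hydration_design(t, taus):
    cols = [np.ones_like(t)] + [-np.expm1(-t / tau) for tau in taus]
    return np.column_stack(cols)


def _fit_kinetics_order(t, y, k: int) -> FitResult:
    # seed decay times on a log grid, amplitudes by NNLS (variable projection)
    seeds = []
    if k == 1:
        for tau in _KINETICS_TAU_GRID:
            amps, rnorm = nnls(_hydration_design(t, [tau]), y)
            seeds.append((rnorm, [amps[0], amps[1], tau]))
    else:
        for i, tau1 in enumerate(_KINETICS_TAU_GRID):
            for tau2 in _KINETICS_TAU_GRID[i + 1:]:
                amps, rnorm = nnls(_hydration_design(t, [tau1, tau2]), y)
                seeds.append((rnorm, [amps[0], amps[1], tau1, amps[2], tau2]))
    seeds.sort(key=lambda s: s[0])

    if k == 1:
        def resid(x):
            return x[0] + x[1] * -np.expm1(-t / x[2]) - y
        lo = [0.0, 0.0, _TINY]
        hi = [np.inf, np.inf, np.inf]
        names = ["A0", "A1", "t1"]
    else:
        def resid(x):
            return (
                x[0]
                + x[1] * -np.expm1(-t / x[2])
                + x[3] * -np.expm1(-t / x[4])
                - y
            )
        lo = [0.0, 0.0, _TINY, 0.0, _TINY]
        hi = [np.inf] * 5
        names = ["A0", "A1", "t1", "A2", "t2"]

    best = None
    for _, x0 in seeds[:_N_RESTARTS]:
        res = _refine(resid, x0, (lo, hi))
        if best is None or res.cost < best.cost:
            best = res
    x = best.x
    rss = float(2 * best.cost)
    sig = _covariance_sigma(best.jac, rss, len(y))
    if k == 2 and x[2] > x[4]:  # order components fast-to-slow
        x = np.array([x[0], x[3], x[4], x[1], x[2]])
        sig = sig[[0, 3, 4, 1, 2]]
    if k == 1:
        params = cm.KineticsParams(A0=x[0], A1=x[1], t1=max(x[2], _TINY))
    else:
        params = cm.KineticsParams(
            A0=x[0], A1=x[1], t1=max(x[2], _TINY),
            A2=x[3], t2=max(x[4], _TINY),
        )
    return FitResult(
        params=params, sigma=dict(zip(names, sig)), rss=rss,
        n_points=len(y), model_order=k,
    )


def fit_dehydration(course: HydrationCourse) -> FitResult:
    """Fit the decreasing mono-exponential dehydration model."""
    t = course.time_h
    y = course.dm_over_m0
    if len(t) < 6:
        raise EstimationError(f"need >= 6 points, got {len(t)}")
    flags = []
    if np.ptp(y) < 1e-12 * max(1.0, float(np.abs(y).max())):
        flags.append("degenerate: constant course, zero-amplitude fit")

    seeds = []
    for tau in _KINETICS_TAU_GRID:
        design = np.column_stack([np.ones_like(t), np.exp(-t / tau)])
        amps, rnorm = nnls(design, y)
        seeds.append((rnorm, [amps[0], amps[1], tau]))
    seeds.sort(key=lambda s: s[0])

    def resid(x):
        return x[0] + x[1] * np.exp(-t / x[2]) - y

    best = None
    for _, x0 in seeds[:_N_RESTARTS]:
        res = _refine(resid, x0, ([0.0, 0.0, _TINY], [np.inf] * 3))
        if best is None or res.cost < best.cost:
            best = res
    rss = float(2 * best.cost)
    sig = _covariance_sigma(best.jac, rss, len(y))
    if best.x[1] < 1e-9 * max(1.0, float(np.abs(y).max())) and not flags:
        flags.append("dehydration amplitude pinned near zero")
    params = cm.KineticsParams(
        A0=best.x[0], direction="dehydration",
        Ad=best.x[1], td=max(best.x[2], _TINY),
    )
    return FitResult(
        params=params, sigma=dict(zip(["A0", "Ad", "td"], sig)),
        rss=rss, n_points=len(y), model_order=1, flags=flags,
    )


# ---------------------------------------------------------------------------
# sorption isotherm
# ---------------------------------------------------------------------------


def fit_isotherm(points: IsothermData, model="GAB", method="direct") -> FitResult:
    """Fit the multilayer sorption isotherm.

    ``method="direct"`` performs nonlinear least squares on the isotherm
    itself; ``method="parabolic"`` regresses h/(dm/m0) on h as a quadratic
    and inverts the coefficients analytically.  On noiseless model data the
    two agree to full precision.  ``model="BET"`` pins ``b = 1``.
    """
    if model not in ("GAB", "BET"):
        raise ValueError("model must be 'GAB' or 'BET'")
    if method not in ("direct", "parabolic"):
        raise ValueError("method must be 'direct' or 'parabolic'")
    h = points.p_over_p0
    c = points.c_h
    nz = h > 0
    if nz.sum() < 5:
        raise EstimationError("need >= 5 nonzero-humidity points")
    if method == "parabolic":
        return _fit_isotherm_parabolic(h[nz], c[nz], model, len(h))
    return _fit_isotherm_direct(h, c, model)


def _fit_isotherm_parabolic(h, c, model, n_total) -> FitResult:
    if np.any(c <= 0):
        raise EstimationError("parabolic method requires positive hydration values")
    y = h / c
    if model == "GAB":
        design = np.column_stack([np.ones_like(h), h, h * h])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        abc = np.array([coef[0], coef[1], -coef[2]])
        names = 3
    else:
        # BET constraint b = 1 implies C = A + B:
        # y = A (1 - h^2) + B (h - h^2)
        design = np.column_stack([1 - h * h, h - h * h])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        abc = np.array([coef[0], coef[1], coef[0] + coef[1]])
        names = 2
    resid = design @ coef - y
    rss = float(resid @ resid)
    params = cm.parabola_to_gab(cm.ParabolicCoeffs(*abc), model_tag=model)

    # delta-method propagation of the regression covariance through Eq-5
    sig_coef = _covariance_sigma(design, rss, len(h))
    cov_coef = np.linalg.pinv(design.T @ design) * (
        rss / max(len(h) - names, 1)
    )

    def to_params(coefvec):
        if model == "GAB":
            abc_ = cm.ParabolicCoeffs(coefvec[0], coefvec[1], -coefvec[2])
        else:
            abc_ = cm.ParabolicCoeffs(
                coefvec[0], coefvec[1], coefvec[0] + coefvec[1]
            )
        p = cm.parabola_to_gab(abc_, model_tag=model)
        return np.array([p.dM_over_m0, p.b, p.b1])

    jac = _numeric_jacobian(to_params, coef)
    cov_p = jac @ cov_coef @ jac.T
    sig = np.sqrt(np.clip(np.diag(cov_p), 0.0, None))
    sigma = {"dM_over_m0": sig[0], "b": sig[1], "b1": sig[2]}
    if model == "BET":
        sigma["b"] = 0.0
    return FitResult(
        params=params, sigma=sigma, rss=rss, n_points=len(h), model_order=1,
        criterion_values={"method": "parabolic"},
    )


def _fit_isotherm_direct(h, c, model) -> FitResult:
    # seed from the parabolic inversion when it is usable
    try:
        seed = _fit_isotherm_parabolic(
            h[h > 0], c[h > 0], model, len(h)
        ).params
        x0 = [seed.dM_over_m0, min(max(seed.b, 0.01), 1.0), seed.b1]
    except (EstimationError, cm.ModelConfigError, cm.ModelDomainError):
        x0 = [max(float(c.max()), 0.01) / 2.0, 0.8, 10.0]

    if model == "GAB":
        def resid(x):
            den = (1.0 - x[1] * h) * (1.0 + x[2] * h - x[1] * h)
            bad = den <= 0
            out = np.where(bad, 1e6, x[0] * x[2] * h / np.where(bad, 1.0, den) - c)
            return out
        lo = [_TINY, _TINY, _TINY]
        hi = [np.inf, 1.0, np.inf]
        names = ["dM_over_m0", "b", "b1"]
    else:
        def resid(x):
            den = (1.0 - h) * (1.0 + x[1] * h - h)
            den = np.where(den <= 0, np.nan, den)
            out = x[0] * x[1] * h / den - c
            return np.nan_to_num(out, nan=1e6)
        x0 = [x0[0], x0[2]]
        lo = [_TINY, _TINY]
        hi = [np.inf, np.inf]
        names = ["dM_over_m0", "b1"]

    res = _refine(resid, x0, (lo, hi))
    rss = float(2 * res.cost)
    sig = _covariance_sigma(res.jac, rss, len(h))
    if model == "GAB":
        params = cm.IsothermParams(
            dM_over_m0=res.x[0], b=min(res.x[1], 1.0), b1=res.x[2]
        )
        sigma = dict(zip(names, sig))
    else:
        params = cm.IsothermParams(
            dM_over_m0=res.x[0], b=1.0, b1=res.x[1], model_tag="BET"
        )
        sigma = {"dM_over_m0": sig[0], "b": 0.0, "b1": sig[1]}
    return FitResult(
        params=params, sigma=sigma, rss=rss, n_points=len(h), model_order=1,
        criterion_values={"method": "direct"},
    )


# ---------------------------------------------------------------------------
# FID decomposition
# ---------------------------------------------------------------------------

_FID_SOLID_GRID = np.geomspace(3.0, 60.0, 6)     # us
_FID_LIQUID_GRID = np.geomspace(5.0, 5000.0, 12)  # us


def fit_fid(trace: FIDTrace, liquid_order="auto", skip_points: int = 0) -> FitResult:
    """Decompose an FID into a Gaussian solid plus 1-2 exponential liquids.

    ``skip_points`` drops the first n samples (receiver dead time).
    """
    if liquid_order not in (1, 2, "auto"):
        raise ValueError("liquid_order must be 1, 2 or 'auto'")
    t = trace.time_us[skip_points:]
    y = trace.amplitude[skip_points:]
    if len(t) < 8:
        raise EstimationError("too few FID points")
    candidates = {}
    for k in ([1, 2] if liquid_order == "auto" else [int(liquid_order)]):
        candidates[k] = _fit_fid_order(t, y, k)
    best, crit = _choose_order(candidates, float(np.linalg.norm(y)))
    result = candidates[best]
    result.criterion_values = crit
    return result


def _fid_design(t, t2s, taus):
    cols = [np.exp(-((t / t2s) ** 2))] + [np.exp(-t / tau) for tau in taus]
    return np.column_stack(cols)


def _fit_fid_order(t, y, k: int) -> FitResult:
    seeds = []
    for t2s in _FID_SOLID_GRID:
        liquid = _FID_LIQUID_GRID[_FID_LIQUID_GRID > t2s]
        if k == 1:
            for tau in liquid:
                amps, rnorm = nnls(_fid_design(t, t2s, [tau]), y)
                seeds.append((rnorm, [amps[0], t2s, amps[1], tau]))
        else:
            for i, tau1 in enumerate(liquid):
                for tau2 in liquid[i + 1:]:
                    amps, rnorm = nnls(_fid_design(t, t2s, [tau1, tau2]), y)
                    seeds.append(
                        (rnorm, [amps[0], t2s, amps[1], tau1, amps[2], tau2])
                    )
    seeds.sort(key=lambda s: s[0])

    if k == 1:
        def resid(x):
            return x[0] * np.exp(-((t / x[1]) ** 2)) + x[2] * np.exp(-t / x[3]) - y
        lo = [0.0, _TINY, 0.0, _TINY]
        names = ["S", "T2S_star", "L1", "T2L1_star"]
    else:
        def resid(x):
            return (
                x[0] * np.exp(-((t / x[1]) ** 2))
                + x[2] * np.exp(-t / x[3])
                + x[4] * np.exp(-t / x[5])
                - y
            )
        lo = [0.0, _TINY, 0.0, _TINY, 0.0, _TINY]
        names = ["S", "T2S_star", "L1", "T2L1_star", "L2", "T2L2_star"]

    best = None
    for _, x0 in seeds[:_N_RESTARTS]:
        res = _refine(resid, x0, (lo, [np.inf] * len(lo)))
        if best is None or res.cost < best.cost:
            best = res
    x = best.x.copy()
    rss = float(2 * best.cost)
    sig = _covariance_sigma(best.jac, rss, len(y))
    flags = []
    if k == 2 and x[3] > x[5]:  # sort the liquid components slow-last
        x[[2, 3, 4, 5]] = x[[4, 5, 2, 3]]
        sig[[2, 3, 4, 5]] = sig[[4, 5, 2, 3]]
    # enforce the strict ordering the component model requires
    times = [1, 3] + ([5] if k == 2 else [])
    for a, b in zip(times, times[1:]):
        if x[b] <= x[a]:
            x[b] = x[a] * (1 + 1e-9)
            flags.append("decay-time ordering enforced post fit")
    if k == 1:
        params = cm.FIDComponents(S=x[0], T2S_star=x[1], L1=x[2], T2L1_star=x[3])
    else:
        params = cm.FIDComponents(
            S=x[0], T2S_star=x[1], L1=x[2], T2L1_star=x[3],
            L2=x[4], T2L2_star=x[5],
        )
        if x[4] < 1e-9 * max(1.0, float(np.abs(y).max())):
            flags.append("L2 amplitude pinned near zero")
    return FitResult(
        params=params, sigma=dict(zip(names, sig)), rss=rss,
        n_points=len(y), model_order=k, flags=flags,
    )


# ---------------------------------------------------------------------------
# spectral deconvolution
# ---------------------------------------------------------------------------

_SPEC_LOR_WIDTHS = np.array([300.0, 800.0, 1500.0, 3000.0, 6000.0])  # Hz
_SPEC_GAUSS_WIDTHS = np.array([30e3, 45e3, 60e3])  # Hz


def fit_spectrum(spectrum: Spectrum, lorentzian_order="auto") -> FitResult:
    """Deconvolve a spectrum into one Gaussian and 1-2 Lorentzian lines."""
    if lorentzian_order not in (1, 2, "auto"):
        raise ValueError("lorentzian_order must be 1, 2 or 'auto'")
    nu = spectrum.freq_hz
    a = spectrum.amplitude
    if len(nu) < 200:
        raise EstimationError("need >= 200 spectral points")
    candidates = {}
    for k in ([1, 2] if lorentzian_order == "auto" else [int(lorentzian_order)]):
        candidates[k] = _fit_spectrum_order(nu, a, k)
    best, crit = _choose_order(candidates, float(np.linalg.norm(a)))
    result = candidates[best]
    result.criterion_values = crit
    return result


def _narrow_peak_positions(nu, a, n: int) -> list[float]:
    """Positions of the n tallest well-separated local maxima."""
    positions = []
    work = a.copy()
    for _ in range(n):
        i = int(np.argmax(work))
        positions.append(float(nu[i]))
        mask = np.abs(nu - nu[i]) < 500.0  # suppress the found line
        work = np.where(mask, -np.inf, work)
    return positions


def _spectrum_shapes(nu, nu_g, dnu_g, lor):
    ln4 = math.log(4.0)
    g = np.exp(-2.0 * ln4 * ((nu - nu_g) / dnu_g) ** 2) / (
        dnu_g * math.sqrt(ln4 * math.pi / 2.0)
    )
    cols = [g]
    for (nu_l, dnu_l) in lor:
        cols.append(
            (2.0 / math.pi) * dnu_l / (4.0 * (nu - nu_l) ** 2 + dnu_l ** 2)
        )
    return np.column_stack(cols)


def _fit_spectrum_order(nu, a, k: int) -> FitResult:
    peaks = _narrow_peak_positions(nu, a, k)
    nu_g0 = float(np.sum(nu * np.clip(a, 0, None)) / max(np.sum(np.clip(a, 0, None)), _TINY))
    seeds = []
    for dnu_g in _SPEC_GAUSS_WIDTHS:
        for w in _SPEC_LOR_WIDTHS:
            lor = [(p, w) for p in peaks]
            design = _spectrum_shapes(nu, nu_g0, dnu_g, lor)
            amps, rnorm = nnls(design, np.clip(a, 0, None))
            x0 = [amps[0], nu_g0, dnu_g]
            for (p, _), amp in zip(lor, amps[1:]):
                x0.extend([amp, p, w])
            seeds.append((rnorm, x0))
    seeds.sort(key=lambda s: s[0])

    span = float(nu.max() - nu.min())

    def resid(x):
        model = x[0] * _spectrum_shapes(nu, x[1], x[2], [])[:, 0]
        for j in range(k):
            amp, pos, wid = x[3 + 3 * j: 6 + 3 * j]
            model = model + (2.0 * amp / math.pi) * wid / (
                4.0 * (nu - pos) ** 2 + wid * wid
            )
        return model - a

    lo = [0.0, float(nu.min()), 1.0] + [0.0, float(nu.min()), 1.0] * k
    hi = [np.inf, float(nu.max()), 10 * span] + [
        np.inf, float(nu.max()), span
    ] * k

    best = None
    for _, x0 in seeds[:_N_RESTARTS]:
        res = _refine(resid, x0, (lo, hi))
        if best is None or res.cost < best.cost:
            best = res
    x = best.x.copy()
    rss = float(2 * best.cost)
    sig = _covariance_sigma(best.jac, rss, len(a))
    flags = []
    names = ["A_G", "nu_G", "dnu_G", "A_L1", "nu_L1", "dnu_L1"]
    if k == 2:
        names += ["A_L2", "nu_L2", "dnu_L2"]
        if x[5] < x[8]:  # L1 must be the broader line
            x[[3, 4, 5, 6, 7, 8]] = x[[6, 7, 8, 3, 4, 5]]
            sig[[3, 4, 5, 6, 7, 8]] = sig[[6, 7, 8, 3, 4, 5]]
        if x[8] >= x[5]:
            x[8] = x[5] * (1 - 1e-9)
            flags.append("Lorentzian width ordering enforced post fit")
    kwargs = dict(A_G=x[0], nu_G=x[1], dnu_G=x[2], A_L1=x[3], nu_L1=x[4], dnu_L1=x[5])
    if k == 2:
        kwargs.update(A_L2=x[6], nu_L2=x[7], dnu_L2=x[8])
    params = cm.SpectralComponents(**kwargs)
    return FitResult(
        params=params, sigma=dict(zip(names, sig)), rss=rss,
        n_points=len(a), model_order=k, flags=flags,
    )


# ---------------------------------------------------------------------------
# combined solute fit and changepoint detection
# ---------------------------------------------------------------------------


def _as_xy(points, attr):
    if isinstance(points, SoluteRatios):
        y = getattr(points, attr)
        if y is None:
            raise EstimationError(f"dataset lacks {attr}")
        return points.dm_over_m0, y
    dm, y = points
    return np.asarray(dm, float), np.asarray(y, float)


def fit_solute_combined(
    ls_points,
    l1l_points,
    gamma_mode: str = "free",
    gamma_value: Optional[float] = None,
    weights: Optional[tuple] = None,
) -> FitResult:
    """Jointly fit the L/S and L1/L hydration dependences.

    Minimises the stacked squared residuals of the rational L/S law and the
    L1/L pool-partition law over (cs, gamma, delta, k, m1); each dataset's
    residuals are divided by that dataset's spread unless explicit
    ``weights = (w_ls, w_l1l)`` are given.  ``gamma_mode="fixed"`` pins
    gamma at ``gamma_value`` (default: the mixed sugar/polyol literature
    value), which is what makes cs identifiable when the solute is unknown:
    from L/S and L1/L alone only gamma*cs/(1-cs) is determined, so in
    ``"free"`` mode the cs and gamma uncertainties are reported from the
    rank-deficient covariance and flagged as jointly unidentifiable.
    """
    dm_ls, ls = _as_xy(ls_points, "l_over_s")
    dm_l1, l1l = _as_xy(l1l_points, "l1_over_l")
    if len(dm_ls) == 0 or len(dm_l1) == 0:
        raise EstimationError("both ratio datasets must be non-empty")
    if gamma_mode not in ("free", "fixed"):
        raise ValueError("gamma_mode must be 'free' or 'fixed'")
    gamma_fix = (gamma_value if gamma_value is not None else GAMMA_MIXED) if gamma_mode == "fixed" else None

    if weights is None:
        w_ls = 1.0 / max(float(np.std(ls)), _TINY)
        w_l1 = 1.0 / max(float(np.std(l1l)), _TINY)
    else:
        w_ls, w_l1 = weights
    dm_max = float(max(dm_ls.max(), dm_l1.max()))

    free = gamma_fix is None

    def unpack(x):
        if free:
            cs, gamma, delta, k, m1 = x
        else:
            cs, delta, k, m1 = x
            gamma = gamma_fix
        return cs, gamma, delta, k, m1

    def resid(x):
        cs, gamma, delta, k, m1 = unpack(x)
        g = (gamma / delta) * cs / (1.0 - cs)
        den = 1.0 - g * dm_ls
        bad = den <= 1e-9
        r_ls = np.where(
            bad, 1e3 * (1.0 + np.abs(den)),
            (k + g) * dm_ls / np.where(bad, 1.0, den) - ls,
        )
        dm2 = np.clip(dm_l1 - m1, 0.0, None)
        r_l1 = m1 / (m1 + (1.0 + gamma * cs / (1.0 - cs)) * dm2) - l1l
        return np.concatenate([w_ls * r_ls, w_l1 * r_l1])

    # deterministic multi-start
    k0 = float(ls[0] / dm_ls[0]) if dm_ls[0] > 0 else 1.0
    below = dm_l1[l1l >= 0.999]
    m1_0 = float(below.max()) if below.size else float(dm_l1.min())
    m1_0 = min(max(m1_0, 1e-3), dm_max)
    starts = []
    for cs0 in (0.2, 0.5):
        for delta0 in (0.4, 1.0):
            x0 = [cs0, GAMMA_MIXED, delta0, max(k0, 0.05), m1_0]
            if not free:
                del x0[1]
            starts.append(x0)

    if free:
        lo = [1e-6, 0.01, 0.01, _TINY, 1e-6]
        hi = [0.95, 10.0, 10.0, 1e3, dm_max]
        names = ["cs", "gamma", "delta", "k", "m1"]
    else:
        lo = [1e-6, 0.01, _TINY, 1e-6]
        hi = [0.95, 10.0, 1e3, dm_max]
        names = ["cs", "delta", "k", "m1"]

    best = None
    for x0 in starts[:_N_RESTARTS]:
        res = _refine(resid, x0, (lo, hi))
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise EstimationError("combined solute fit failed to converge")
    rss = float(2 * best.cost)
    n = len(dm_ls) + len(dm_l1)
    sig = _covariance_sigma(best.jac, rss, n)
    flags = []
    jtj = best.jac.T @ best.jac
    if np.linalg.cond(jtj) > 1e10 and free:
        flags.append(
            "gamma and cs are only jointly identified (gamma*cs/(1-cs)); "
            "their individual uncertainties are very wide"
        )
    cs, gamma, delta, k, m1 = unpack(best.x)
    params = cm.SoluteModelParams(
        cs=max(cs, _TINY), gamma=gamma, delta=delta,
        k=max(k, _TINY), m1=max(m1, _TINY),
    )
    sigma = dict(zip(names, sig))
    if not free:
        sigma["gamma"] = 0.0
    return FitResult(
        params=params, sigma=sigma, rss=rss, n_points=n,
        model_order=1, flags=flags,
        criterion_values={"gamma_mode": gamma_mode},
    )


def _fit_rational_ls(dm, y):
    """Fit y = (k + r) dm / (1 - r dm) by seeded least squares."""
    dm_max = float(dm.max())
    r_grid = np.linspace(0.0, 0.95 / dm_max, 12)
    seeds = []
    for r in r_grid:
        basis = dm / (1.0 - r * dm)
        s = float(basis @ y / max(basis @ basis, _TINY))
        k = max(s - r, 0.0)
        rss = float(np.sum(((k + r) * basis - y) ** 2))
        seeds.append((rss, [k, r]))
    seeds.sort(key=lambda s: s[0])

    def resid(x):
        den = 1.0 - x[1] * dm
        return (x[0] + x[1]) * dm / den - y

    best = None
    for _, x0 in seeds[:3]:
        res = _refine(resid, x0, ([0.0, 0.0], [np.inf, 0.999 / dm_max]))
        if best is None or res.cost < best.cost:
            best = res
    return float(best.x[0]), float(best.x[1]), float(2 * best.cost)


def _fit_line(x, y):
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((design @ coef - y) ** 2))
    return float(coef[0]), float(coef[1]), rss


def detect_threshold(ls_points, min_segment: int = 3) -> ThresholdFit:
    """Detect a rational-to-linear changepoint in the L/S hydration curve.

    Exhaustive search over interior data points: below the candidate the
    rational dissolution law is fitted, above it an unconstrained line
    (continuity is not enforced); the piecewise model must beat the best
    single-model AICc by two units, with ties broken toward the smaller
    threshold.  Returns ``threshold=None`` when no changepoint is supported;
    when a single line describes everything the threshold collapses to the
    smallest observed hydration level.
    """
    dm, y = _as_xy(ls_points, "l_over_s")
    if len(dm) < 12:
        raise EstimationError("need >= 12 points for changepoint detection")

    k_r, r_r, rss_rational = _fit_rational_ls(dm, y)
    slope_all, icpt_all, rss_line = _fit_line(dm, y)
    n = len(dm)
    crit = {
        "single_rational": aicc(rss_rational, n, 2),
        "single_line": aicc(rss_line, n, 2),
    }
    single_best = min(crit["single_rational"], crit["single_line"])

    best_piece = None
    for c in dm[min_segment - 1: n - min_segment]:
        below = dm <= c
        if below.sum() < min_segment or (~below).sum() < min_segment:
            continue
        kb, rb, rss_b = _fit_rational_ls(dm[below], y[below])
        sl, ic, rss_a = _fit_line(dm[~below], y[~below])
        score = aicc(rss_b + rss_a, n, 5)
        if best_piece is None or score < best_piece[0] - 1e-12:
            best_piece = (score, float(c), kb, rb, sl, ic)
    if best_piece is not None:
        crit["piecewise"] = best_piece[0]

    def rational_params(k, r):
        if r <= 0:
            r = _TINY
        return cm.SoluteModelParams(
            cs=r / (1.0 + r), gamma=1.0, delta=1.0, k=max(k, _TINY), m1=1.0
        )

    if best_piece is not None and single_best - best_piece[0] >= 2.0:
        score, c, kb, rb, sl, ic = best_piece
        return ThresholdFit(
            threshold=c, below_params=rational_params(kb, rb),
            above_slope=sl, above_intercept=ic,
            evidence=single_best - score, criterion_values=crit,
        )
    # no supported changepoint: fall back to the better single model
    evidence = single_best - (best_piece[0] if best_piece else math.inf)
    if crit["single_line"] < crit["single_rational"]:
        return ThresholdFit(
            threshold=float(dm.min()), below_params=None,
            above_slope=slope_all, above_intercept=icpt_all,
            evidence=evidence, criterion_values=crit,
        )
    return ThresholdFit(
        threshold=None, below_params=rational_params(k_r, r_r),
        above_slope=None, above_intercept=None,
        evidence=evidence, criterion_values=crit,
    )
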
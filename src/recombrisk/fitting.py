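"""Parameter estimation from (ERR, endpoint) panels.

Two families of estimators coexist:

* the *constrained mechanistic* fits — the cubic hyper-recombination model
  with its zero intercept and the k0 = k1·ERRmax²/4 tie, and the logistic
  G2/M escape model in its (c0, g_max, g_min) parameterization;
* the *unconstrained empirical* fits — plain polynomials and the linear
  composite calibration, matching how panel figures are usually annotated.

Every fit reports the Pearson correlation between observed values and model
predictions. ``correlation_screen`` provides the significance screen used
to declare an endpoint uninformative for ERR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .models import GModelParams, HModelParams, LinearCalibration, g_of_err, h_of_err

__all__ = [
    "ModelKind",
    "FitResult",
    "FitError",
    "InsufficientDataError",
    "fit_h_mechanistic",
    "fit_polynomial",
    "fit_logistic",
    "fit_linear",
    "correlation_screen",
    "CorrelationScreen",
    "smoothed_sem_weights",
]


class FitError(RuntimeError):
    pass


class InsufficientDataError(FitError):
    pass


class ModelKind(str, Enum):
    H_MECHANISTIC = "H_MECHANISTIC"
    POLY2 = "POLY2"
    POLY3 = "POLY3"
    LOGISTIC = "LOGISTIC"
    LINEAR = "LINEAR"


@dataclass
class FitResult:
    """Outcome of one model fit.

    ``coeffs`` are the raw coefficient vector (ascending powers for
    polynomials); ``params`` is the typed parameter bundle for mechanistic
    models (HModelParams / GModelParams / LinearCalibration), None for
    plain polynomials. ``r`` is Pearson's correlation between observed and
    fitted values; ``flags`` records degeneracies (e.g. "constant-response").
    """

    model: ModelKind
    coeffs: np.ndarray
    r: float
    residuals: np.ndarray
    n_points: int
    params: object = None
    flags: list[str] = field(default_factory=list)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.model is ModelKind.H_MECHANISTIC:
            return h_of_err(x, self.params)
        if self.model is ModelKind.LOGISTIC:
            return g_of_err(x, self.params)
        # polynomial / linear: coeffs in ascending powers
        return np.polynomial.polynomial.polyval(x, self.coeffs)

    def to_dict(self) -> dict:
        return {
            "model": self.model.value,
            "coeffs": [float(c) for c in self.coeffs],
            "r": float(self.r),
            "n_points": int(self.n_points),
            "flags": list(self.flags),
        }


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be a sequence of (x, y) pairs")
    return arr[:, 0], arr[:, 1]


def _pearson_obs_pred(y: np.ndarray, yhat: np.ndarray) -> tuple[float, list[str]]:
    flags: list[str] = []
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        return 0.0, ["constant-response"]
    r = float(stats.pearsonr(y, yhat).statistic)
    return r, flags


def _weights_vector(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have length {n}")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    return w


def smoothed_sem_weights(means, sems) -> np.ndarray:
    """Inverse-variance weights from a smoothed SEM-vs-mean relation.

    Raw per-point SEMs estimated from few replicates are too unstable to
    weight by directly (a lucky tiny SEM dominates the fit). Instead the
    SEMs are regressed linearly on the means, and weights are 1/fitted²,
    with the fitted values floored at 30% of the median SEM.
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sems, dtype=float)
    if m.shape != s.shape or m.ndim != 1:
        raise ValueError("means and sems must be 1-D arrays of equal length")
    if np.all(s == 0):
        return np.ones_like(m)
    b, a = np.polyfit(m, s, 1)
    fitted = np.maximum(a + b * m, 0.3 * float(np.median(s[s > 0])))
    return 1.0 / fitted**2


def fit_h_mechanistic(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> FitResult:
    """Least-squares fit of the constrained cubic H(ERR) model.

    Estimates (k1, err_max) under H(0) = 0 and the k0 constraint; k0 is
    reported only as a derived quantity. Optional ``weights`` (e.g.
    1/SEM²) scale the squared residuals.
    """
    x, y = _as_xy(points)
    if len(np.unique(x)) < 3:
        raise InsufficientDataError("need at least 3 distinct err values")
    w = np.sqrt(_weights_vector(weights, len(x)))

    flags: list[str] = []
    if np.allclose(y, 0.0):
        flags.append("zero-signal:k1-at-boundary")

    # starting values from an unconstrained cubic: coeff of x^3 is ~k1/3
    try:
        c = np.polynomial.polynomial.polyfit(x, y, 3)
        k1_0 = max(3.0 * c[3], 1e-6)
        em_0 = max(-2.0 * c[2] / k1_0, 1e-3) if c[2] < 0 else max(x.max(), 1e-3)
    except Exception:  # pragma: no cover - degenerate polyfit
        k1_0, em_0 = 1.0, max(x.max(), 1.0)

    def resid(theta):
        k1, em = theta
        return w * ((k1 / 3) * x**3 - (k1 * em / 2) * x**2 + (k1 * em**2 / 4) * x - y)

    sol = optimize.least_squares(
        resid,
        x0=[k1_0, em_0],
        bounds=([0.0, 1e-6], [np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=10_000,
    )
    if not sol.success:
        raise FitError(f"mechanistic H fit did not converge: {sol.message}")
    k1, em = sol.x
    params = HModelParams(k1=float(k1), err_max=float(em))
    yhat = h_of_err(x, params)
    r, rflags = _pearson_obs_pred(y, yhat)
    return FitResult(
        model=ModelKind.H_MECHANISTIC,
        coeffs=np.array([0.0, params.k0, -k1 * em / 2, k1 / 3]),
        r=r,
        residuals=y - yhat,
        n_points=len(x),
        params=params,
        flags=flags + rflags,
    )


def fit_polynomial(points: Sequence[tuple[float, float]], degree: int) -> FitResult:
    """Ordinary least-squares polynomial fit (unconstrained, degree 2 or 3).

    Coefficients are returned in ascending powers (intercept first), the
    convention used to annotate panel figures.
    """
    if degree not in (2, 3):
        raise ValueError("degree must be 2 or 3")
    x, y = _as_xy(points)
    if len(x) <= degree + 1:
        raise InsufficientDataError(f"need more than {degree + 1} points for degree {degree}")
    if len(np.unique(x)) <= degree:
        raise FitError("rank-deficient design: too few distinct x values")
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    yhat = np.polynomial.polynomial.polyval(x, coeffs)
    r, flags = _pearson_obs_pred(y, yhat)
    return FitResult(
        model=ModelKind.POLY2 if degree == 2 else ModelKind.POLY3,
        coeffs=coeffs,
        r=r,
        residuals=y - yhat,
        n_points=len(x),
        flags=flags,
    )


def fit_logistic(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
    n_restarts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Nonlinear least squares for the logistic G(ERR) model.

    Parameterization (c0, g_max, g_min) of
    G = g_max / (1 + (g_max/g_min − 1)·e^(−c0·ERR)). Initialization:
    g_max ← 1.05·max(y), g_min ← max(min(y), 1e−3), c0 ← 4/range(x), plus
    jittered restarts (deterministic given ``seed``); the best converged
    start wins.
    """
    x, y = _as_xy(points)
    if len(np.unique(x)) < 4:
        raise InsufficientDataError("need at least 4 points spanning the sigmoid rise")
    w = np.sqrt(_weights_vector(weights, len(x)))

    g_max0 = 1.05 * float(np.max(y))
    g_min0 = max(float(np.min(y)), 1e-3)
    if g_max0 <= g_min0:
        g_max0 = g_min0 * 2 + 1e-3
    c00 = 4.0 / max(float(np.ptp(x)), 1e-6)
    base = np.array([c00, g_max0, g_min0])

    def resid(theta):
        c0, gmax, gmin = theta
        return w * (gmax / (1.0 + (gmax / gmin - 1.0) * np.exp(-c0 * x)) - y)

    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(n_restarts):
        starts.append(base * rng.uniform(0.5, 2.0, size=3))

    best = None
    tried = []
    for x0 in starts:
        tried.append(x0.tolist())
        try:
            sol = optimize.least_squares(
                resid,
                x0=x0,
                bounds=([1e-8, 1e-6, 1e-8], [np.inf, np.inf, np.inf]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=10_000,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError(f"logistic fit failed to converge from any start; tried {tried}")
    c0, gmax, gmin = best.x
    if gmin >= gmax:  # fold degenerate solutions back into the valid cone
        raise FitError("logistic fit converged to g_min >= g_max")
    params = GModelParams(c0=float(c0), g_max=float(gmax), g_min=float(gmin))
    yhat = g_of_err(x, params)
    r, flags = _pearson_obs_pred(y, yhat)
    return FitResult(
        model=ModelKind.LOGISTIC,
        coeffs=np.array([c0, gmax, gmin]),
        r=r,
        residuals=y - yhat,
        n_points=len(x),
        params=params,
        flags=flags,
    )


def fit_linear(points: Sequence[tuple[float, float]]) -> FitResult:
    """Ordinary least-squares line with Pearson r (the composite calibration)."""
    x, y = _as_xy(points)
    if len(np.unique(x)) < 2:
        raise FitError("need at least 2 distinct x values")
    flags: list[str] = []
    if np.ptp(y) == 0:
        slope, intercept, r = 0.0, float(y[0]), 0.0
        flags.append("constant-response")
        coeffs = np.array([intercept, slope])
        yhat = np.full_like(y, intercept)
        return FitResult(ModelKind.LINEAR, coeffs, r, y - yhat, len(x), params=None, flags=flags)
    res = stats.linregress(x, y)
    coeffs = np.array([res.intercept, res.slope])
    yhat = res.intercept + res.slope * x
    cal = None
    if res.slope != 0:
        cal = LinearCalibration(intercept=float(res.intercept), slope=float(res.slope), r=float(res.rvalue))
    else:
        flags.append("zero-slope")
    return FitResult(
        model=ModelKind.LINEAR,
        coeffs=coeffs,
        r=float(res.rvalue),
        residuals=y - yhat,
        n_points=len(x),
        params=cal,
        flags=flags,
    )


@dataclass(frozen=True)
class CorrelationScreen:
    r: float
    p_value: float
    significant: bool
    flags: tuple[str, ...] = ()

    @property
    def verdict(self) -> str:
        return "significant" if self.significant else "not significant"


def correlation_screen(points: Sequence[tuple[float, float]], alpha: float = 0.05) -> CorrelationScreen:
    """Pearson correlation screen with a two-sided t-test.

    Declares the association "significant" iff p < ``alpha`` (default
    0.05). Zero variance in either variable yields r = 0, p = 1 with an
    ``undefined-correlation`` flag rather than an error.
    """
    x, y = _as_xy(points)
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationScreen(0.0, 1.0, False, ("undefined-correlation",))
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationScreen(r, p, bool(p < alpha))
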
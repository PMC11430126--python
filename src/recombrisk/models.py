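"""Mechanistic dose-response models linking assay endpoints to excess
relative cancer risk (ERR).

Hyper-recombination model
    The hyper-recombination rate H (percent) grows with ERR at a basal rate
    k0 that is opposed by a quadratic "brake" k_H(ERR) = k1·ERR·(ERRmax − ERR)
    exerted by nuclear ATM monomers:

        dH/dERR = k0 − k1·ERR·(ERRmax − ERR),   H(0) = 0.

    Requiring dH/dERR ≥ 0 with equality exactly at ERR = ERRmax/2 (the point
    of maximal brake) ties the basal rate to the brake parameters,
    k0 = k1·ERRmax²/4, and yields the constrained cubic

        H(ERR) = (k1/3)·ERR³ − (k1·ERRmax/2)·ERR² + (k1·ERRmax²/4)·ERR.

G2/M escape model
    The escape G (percent) is bounded between a floor Gmin (escape of
    zero-excess-risk cells) and a ceiling Gmax, and follows the logistic
    equation in ERR

        dG/dERR = c0·G·(1 − G/Gmax),   G(0) = Gmin,

    whose solution is G(ERR) = Gmax / (1 + (Gmax/Gmin − 1)·e^(−c0·ERR)).

Composite predictor
    H×G (reported as percent: the percent×percent product divided by 100)
    is approximately linear in ERR over the syndrome panel and is inverted —
    either through a linear calibration or exactly through the monotone
    composite — to predict ERR from measured endpoints.

Default parameter values are the panel-calibrated ones; the ODE integrators
exist purely as numerical cross-checks of the closed forms.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "HModelParams",
    "GModelParams",
    "LinearCalibration",
    "DEFAULT_H_PARAMS",
    "DEFAULT_G_PARAMS",
    "DEFAULT_CALIBRATION",
    "h_of_err",
    "dh_derr",
    "k0_from",
    "err_max_from",
    "g_of_err",
    "dg_derr",
    "hg_product",
    "predict_err",
    "invert_hg",
    "integrate_h_ode",
    "integrate_g_ode",
    "params_to_json",
    "params_from_json",
    "NegativePredictionWarning",
]


class NegativePredictionWarning(UserWarning):
    """A predicted ERR fell below zero and was clamped."""


@dataclass(frozen=True)
class HModelParams:
    """Parameters of the constrained cubic hyper-recombination model.

    k1       brake rate constant (percent per ERR³)
    err_max  ERR at which the brake vanishes again (dimensionless)
    k0       derived basal rate k1·err_max²/4 (percent per ERR); never
             stored independently — the constraint is enforced exactly.
    """

    k1: float
    err_max: float

    def __post_init__(self):
        if self.k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {self.k1}")
        if self.err_max <= 0:
            raise ValueError(f"err_max must be > 0, got {self.err_max}")

    @property
    def k0(self) -> float:
        return k0_from(self.k1, self.err_max) if self.k1 > 0 else 0.0


@dataclass(frozen=True)
class GModelParams:
    """Parameters of the logistic G2/M escape model (percent scale)."""

    c0: float
    g_max: float
    g_min: float

    def __post_init__(self):
        if self.c0 <= 0:
            raise ValueError(f"c0 must be > 0, got {self.c0}")
        if not 0 < self.g_min < self.g_max:
            raise ValueError(
                f"need 0 < g_min < g_max, got g_min={self.g_min}, g_max={self.g_max}"
            )

    @property
    def shape_factor(self) -> float:
        """The factor multiplying e^(−c0·ERR) in the solution: Gmax/Gmin − 1."""
        return self.g_max / self.g_min - 1.0


@dataclass(frozen=True)
class LinearCalibration:
    """Linear map H×G(%) = intercept + slope·ERR, with its Pearson r."""

    intercept: float
    slope: float
    r: float = float("nan")

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("slope must be nonzero for invertibility")
        if not math.isnan(self.r) and not -1.0 <= self.r <= 1.0:
            raise ValueError(f"r must lie in [-1, 1], got {self.r}")


#: Panel-calibrated defaults.
DEFAULT_H_PARAMS = HModelParams(k1=0.9, err_max=10.28)
DEFAULT_G_PARAMS = GModelParams(c0=0.5473, g_max=10.98, g_min=0.8655)
DEFAULT_CALIBRATION = LinearCalibration(intercept=-0.3, slope=0.623, r=0.983)


def _check_err(err):
    err = np.asarray(err, dtype=float)
    if np.any(err < 0):
        raise ValueError("err must be >= 0")
    return err


def k0_from(k1: float, err_max: float) -> float:
    """Basal hyper-recombination rate k0 = k1·err_max²/4."""
    if k1 <= 0 or err_max <= 0:
        raise ValueError("k1 and err_max must be > 0")
    return k1 * err_max**2 / 4.0


def err_max_from(k0: float, k1: float) -> float:
    """Invert the constraint: err_max = 2·√(k0/k1)."""
    if k0 <= 0 or k1 <= 0:
        raise ValueError("k0 and k1 must be > 0")
    return 2.0 * math.sqrt(k0 / k1)


def h_of_err(err, p: HModelParams = DEFAULT_H_PARAMS):
    """Closed-form hyper-recombination rate H(ERR), percent.

    Non-decreasing on [0, ∞) with H(0) = 0; accepts scalars or arrays.
    """
    err = _check_err(err)
    k1, em = p.k1, p.err_max
    out = (k1 / 3.0) * err**3 - (k1 * em / 2.0) * err**2 + (k1 * em**2 / 4.0) * err
    return float(out) if out.ndim == 0 else out


def dh_derr(err, p: HModelParams = DEFAULT_H_PARAMS):
    """Growth rate dH/dERR = k0 − k1·ERR·(ERRmax − ERR).

    Non-negative everywhere; zero exactly at ERR = ERRmax/2.
    """
    err = _check_err(err)
    out = p.k0 - p.k1 * err * (p.err_max - err)
    return float(out) if out.ndim == 0 else out


def g_of_err(err, p: GModelParams = DEFAULT_G_PARAMS):
    """Closed-form logistic G2/M escape G(ERR), percent.

    Strictly increasing from G(0) = g_min towards the asymptote g_max.
    """
    err = _check_err(err)
    out = p.g_max / (1.0 + p.shape_factor * np.exp(-p.c0 * err))
    return float(out) if out.ndim == 0 else out


def dg_derr(g, p: GModelParams = DEFAULT_G_PARAMS):
    """Logistic growth rate dG/dERR = c0·G·(1 − G/Gmax), as a function of G."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0) or np.any(g > p.g_max):
        raise ValueError(f"g must lie in [0, g_max={p.g_max}]")
    out = p.c0 * g * (1.0 - g / p.g_max)
    return float(out) if out.ndim == 0 else out


def hg_product(
    err,
    hp: HModelParams = DEFAULT_H_PARAMS,
    gp: GModelParams = DEFAULT_G_PARAMS,
    scale: Literal["percent", "raw"] = "percent",
):
    """Composite predictor H(ERR)·G(ERR).

    ``raw`` is the literal percent×percent product; ``percent`` (default, the
    reporting convention of the calibration axis) divides by 100 — i.e. H as
    a fraction times G in percent.
    """
    if scale not in ("percent", "raw"):
        raise ValueError(f"scale must be 'percent' or 'raw', got {scale!r}")
    prod = np.asarray(h_of_err(err, hp)) * np.asarray(g_of_err(err, gp))
    if scale == "percent":
        prod = prod / 100.0
    return float(prod) if prod.ndim == 0 else prod


def predict_err(hg_percent: float, cal: LinearCalibration = DEFAULT_CALIBRATION) -> float:
    """Invert the linear calibration: ERR = (H×G − intercept)/slope.

    Negative predictions are clamped to 0 (ERR is non-negative by
    definition) with :class:`NegativePredictionWarning`.
    """
    pred = (hg_percent - cal.intercept) / cal.slope
    if pred < 0:
        warnings.warn(
            f"predicted ERR {pred:.3f} < 0 clamped to 0 (H*G = {hg_percent:.3f})",
            NegativePredictionWarning,
            stacklevel=2,
        )
        return 0.0
    return float(pred)


def invert_hg(
    hg_percent: float,
    hp: HModelParams = DEFAULT_H_PARAMS,
    gp: GModelParams = DEFAULT_G_PARAMS,
    *,
    err_hi: float | None = None,
    xtol: float = 1e-10,
) -> float:
    """Exact inverse of the monotone composite: the ERR with hg_product = hg_percent.

    The composite is strictly increasing on (0, ∞), so the root is unique.
    Values at or below the composite's value at 0 (i.e. ≤ 0) return 0 with a
    warning; values beyond ``err_hi`` (default 2·err_max) raise.
    """
    if hg_percent <= 0.0:
        if hg_percent < 0.0:
            warnings.warn(
                f"H*G = {hg_percent:.3f} <= 0; predicted ERR clamped to 0",
                NegativePredictionWarning,
                stacklevel=2,
            )
        return 0.0
    hi = err_hi if err_hi is not None else 2.0 * hp.err_max
    f = lambda e: hg_product(e, hp, gp) - hg_percent
    if f(hi) < 0:
        raise ValueError(
            f"H*G = {hg_percent:.3f} exceeds the composite's value at err = {hi:.2f}"
        )
    return float(brentq(f, 0.0, hi, xtol=xtol))


def _integrate(rhs, y0: float, err_grid, rtol: float, atol: float) -> np.ndarray:
    grid = np.asarray(err_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValueError("err_grid must be a 1-D grid with at least two points")
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("err_grid must start at 0 and be strictly increasing")
    sol = solve_ivp(
        rhs, (grid[0], grid[-1]), [y0], t_eval=grid, method="RK45", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]


def integrate_h_ode(
    p: HModelParams = DEFAULT_H_PARAMS,
    err_grid=None,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> np.ndarray:
    """Numerically integrate dH/dERR = k0 − k1·ERR·(ERRmax − ERR), H(0)=0.

    Cross-check of the closed form: agrees with :func:`h_of_err` to solver
    tolerance on the grid. Default grid is 0..err_max step 0.1.
    """
    if err_grid is None:
        err_grid = np.arange(0.0, p.err_max + 1e-12, 0.1)
    k0 = p.k0
    rhs = lambda e, y: [k0 - p.k1 * e * (p.err_max - e)]
    return _integrate(rhs, 0.0, err_grid, rtol, atol)


def integrate_g_ode(
    p: GModelParams = DEFAULT_G_PARAMS,
    err_grid=None,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> np.ndarray:
    """Numerically integrate dG/dERR = c0·G·(1 − G/Gmax), G(0)=Gmin."""
    if err_grid is None:
        err_grid = np.arange(0.0, 10.0 + 1e-12, 0.1)
    rhs = lambda e, y: [p.c0 * y[0] * (1.0 - y[0] / p.g_max)]
    return _integrate(rhs, p.g_min, err_grid, rtol, atol)


# ---------------------------------------------------------------------------
# Flat JSON serialization of the full parameter bundle
# ---------------------------------------------------------------------------

def params_to_json(
    hp: HModelParams = DEFAULT_H_PARAMS,
    gp: GModelParams = DEFAULT_G_PARAMS,
    cal: LinearCalibration = DEFAULT_CALIBRATION,
    path: str | Path | None = None,
) -> str:
    """Serialize a parameter bundle to a flat JSON document.

    Keys: k1, err_max, c0, g_max, g_min, cal_intercept, cal_slope (plus
    cal_r when known). k0 is derived and intentionally not serialized.
    """
    doc = {
        "k1": hp.k1,
        "err_max": hp.err_max,
        "c0": gp.c0,
        "g_max": gp.g_max,
        "g_min": gp.g_min,
        "cal_intercept": cal.intercept,
        "cal_slope": cal.slope,
    }
    if not math.isnan(cal.r):
        doc["cal_r"] = cal.r
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def params_from_json(source: str | Path) -> tuple[HModelParams, GModelParams, LinearCalibration]:
    """Load a parameter bundle written by :func:`params_to_json`.

    ``source`` may be a JSON string or a path to a JSON file.
    """
    text = source
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
        text = Path(source).read_text()
    doc = json.loads(text)
    hp = HModelParams(k1=doc["k1"], err_max=doc["err_max"])
    gp = GModelParams(c0=doc["c0"], g_max=doc["g_max"], g_min=doc["g_min"])
    cal = LinearCalibration(
        intercept=doc["cal_intercept"], slope=doc["cal_slope"], r=doc.get("cal_r", float("nan"))
    )
    return hp, gp, cal
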
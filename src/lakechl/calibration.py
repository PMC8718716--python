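"""Regionalized chlorophyll-from-IOPs model, refitting and diagnostics.

The model maps the three water-column absorption components to a
chlorophyll a concentration::

    Chl = A * (a_pig + B * (a_det + a_cdom)) ** C        [mg m^-3]

with canonical regional coefficients A=21, B=0.77, C=1.04. Refitting is a
bounded nonlinear least squares on log-transformed concentrations;
goodness-of-fit (r^2, RMSE) is reported on the linear scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CalibrationCoefficients",
    "CalibrationFitResult",
    "CANONICAL_COEFFICIENTS",
    "chl_from_iops",
    "fit_regional_coefficients",
    "evaluate_fit",
]


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Coefficients (A, B, C) of the regional Chl model.

    ``scale`` (A, mg m^-3) multiplies the combined absorption; ``weight``
    (B, dimensionless) weights detritus+CDOM absorption relative to pigment
    absorption; ``exponent`` (C, dimensionless) is the power-law exponent.
    """

    scale: float = 21.0
    weight: float = 0.77
    exponent: float = 1.04

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")
        if self.exponent <= 0:
            raise ValueError(f"exponent must be > 0, got {self.exponent}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.scale, self.weight, self.exponent)


#: Published regional coefficient set.
CANONICAL_COEFFICIENTS = CalibrationCoefficients(21.0, 0.77, 1.04)


@dataclass
class CalibrationFitResult:
    coefficients: CalibrationCoefficients
    r_squared: float
    rmse: float
    n: int
    converged: bool
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                "scale": self.coefficients.scale,
                "weight": self.coefficients.weight,
                "exponent": self.coefficients.exponent,
            },
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n": self.n,
            "converged": self.converged,
            "message": self.message,
        }


def chl_from_iops(a_pig, a_det, a_cdom,
                  coeffs: CalibrationCoefficients = CANONICAL_COEFFICIENTS):
    """Chlorophyll a (mg m^-3) from absorption components (m^-1).

    Applies elementwise to arrays; returns a scalar for scalar input.
    Negative absorptions raise ``ValueError`` (real processor output can
    contain them, but such pixels are flagged invalid upstream).
    """
    ap = np.asarray(a_pig, dtype=float)
    ad = np.asarray(a_det, dtype=float)
    ac = np.asarray(a_cdom, dtype=float)
    for name, arr in (("a_pig", ap), ("a_det", ad), ("a_cdom", ac)):
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValueError(f"negative {name} value passed to chl_from_iops")
    inner = ap + coeffs.weight * (ad + ac)
    chl = coeffs.scale * np.power(inner, coeffs.exponent)
    if np.isscalar(a_pig) and np.isscalar(a_det) and np.isscalar(a_cdom):
        return float(chl)
    return chl


def _predict(theta: np.ndarray, ap, ad, ac) -> np.ndarray:
    a, b, c = theta
    return a * np.power(ap + b * (ad + ac), c)


def fit_regional_coefficients(
    a_pig: Sequence[float],
    a_det: Sequence[float],
    a_cdom: Sequence[float],
    chl_insitu: Sequence[float],
    init: CalibrationCoefficients = CANONICAL_COEFFICIENTS,
    free: Sequence[str] = ("scale", "weight", "exponent"),
) -> CalibrationFitResult:
    """Refit the regional coefficients against match-up data.

    Least squares on log(Chl) residuals (concentrations are positive and
    span orders of magnitude), parameters bounded positive, deterministic
    given ``init``. ``free`` selects which of ``scale`` / ``weight`` /
    ``exponent`` are fitted; the others stay at their ``init`` values
    (``free=("weight",)`` mirrors refitting only the detritus+CDOM weight).

    Diagnostics (r^2, RMSE) are computed on the linear mg m^-3 scale.
    """
    ap = np.asarray(a_pig, dtype=float)
    ad = np.asarray(a_det, dtype=float)
    ac = np.asarray(a_cdom, dtype=float)
    obs = np.asarray(chl_insitu, dtype=float)
    n = obs.size
    if not (ap.size == ad.size == ac.size == n):
        raise ValueError("IOP and chlorophyll arrays must have equal length")
    if n < 5:
        raise ValueError(f"need at least 5 match-ups to fit, got {n}")
    if np.any(obs <= 0):
        raise ValueError("all in-situ chlorophyll values must be > 0")
    unknown = set(free) - {"scale", "weight", "exponent"}
    if unknown:
        raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
    if not free:
        raise ValueError("at least one parameter must be free")

    names = ("scale", "weight", "exponent")
    x0_full = np.array(init.as_tuple())
    free_idx = [i for i, nm in enumerate(names) if nm in free]
    log_obs = np.log(obs)
    tiny = 1e-300

    def residuals(x_free: np.ndarray) -> np.ndarray:
        theta = x0_full.copy()
        theta[free_idx] = x_free
        pred = _predict(theta, ap, ad, ac)
        return np.log(np.maximum(pred, tiny)) - log_obs

    lower = np.full(len(free_idx), 1e-9)
    res = least_squares(
        residuals,
        x0=x0_full[free_idx],
        bounds=(lower, np.inf),
        method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(
            f"coefficient fit did not converge: {res.message} "
            f"(status {res.status}, cost {res.cost:.3g})"
        )
    theta = x0_full.copy()
    theta[free_idx] = res.x
    coeffs = CalibrationCoefficients(*theta)
    pred = _predict(theta, ap, ad, ac)
    r2, rmse = evaluate_fit(pred, obs)
    return CalibrationFitResult(
        coefficients=coeffs, r_squared=r2, rmse=rmse, n=int(n),
        converged=True, message=res.message,
    )


def evaluate_fit(predicted: Sequence[float], observed: Sequence[float]
                 ) -> tuple[float, float]:
    """(r^2, RMSE) of predicted vs observed on the linear scale.

    r^2 is the squared Pearson correlation; it is NaN when either vector
    has zero variance. RMSE is the root mean squared difference in the
    data's units (mg m^-3).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size < 2:
        raise ValueError("need at least 2 points to evaluate a fit")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    if np.std(p) == 0 or np.std(o) == 0:
        return (math.nan, rmse)
    r = float(np.corrcoef(p, o)[0, 1])
    return (r * r, rmse)
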
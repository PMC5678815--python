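"""Deterministic sigmoid dose-response model for the fibrosis index (FI).

The population-mean FI after a total dose ``D`` is modelled with a
probit-type sigmoid (a modified Kallman form):

    FI(D) = (A/2) * {1 - erf(sqrt(pi) * gamma * (1 - D / ED50))}

where ``A`` is the saturation constant (maximal attainable FI, measured
experimentally as 7.20 in the murine whole-thorax photon study this
package models), ``ED50`` is the dose producing half-maximal fibrosis
(FI = A/2) and ``gamma`` is the maximum normalised dose-response
gradient (steepness).  The model is deterministic: FI is a continuous
severity score, not an incidence probability, so ED50 is the dose at
which the *average* animal reaches half the maximal fibrosis.

The closed-form inverse maps an FI level back to the dose that produces
it, which is the workhorse of isoeffect (alpha/beta) analysis:

    D(FI) = ED50 * [1 - erfinv(1 - 2 FI / A) / (sqrt(pi) * gamma)]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf, erfinv

from .errors import DomainError, FitError, ValidationError

__all__ = [
    "FiModelFit",
    "predict_fi",
    "inverse_dose",
    "fit_fi_model",
    "adjusted_r2",
    "DEFAULT_SATURATION",
]

#: Saturation constant A of the FI model (FI units); the experimentally
#: measured maximal fibrosis index that normalises all FI values.
DEFAULT_SATURATION = 7.20

_SQRT_PI = np.sqrt(np.pi)


@dataclass(frozen=True)
class FiModelFit:
    """Fitted FI-model parameters for one fractionation arm.

    Attributes
    ----------
    a : float
        Saturation constant A (FI units), > 0.
    gamma : float
        Maximum normalised dose-response gradient, > 0 (dimensionless).
    ed50 : float
        Dose (Gy) at which FI = A/2.
    a_fixed : bool
        Whether A was held fixed during fitting.
    adj_r2 : float
        Adjusted R-squared of the fit (NaN for fits constructed from
        literature parameters rather than data).
    se : dict
        Standard error per free parameter, keyed by parameter name.
    n : int
        Number of observations used in the fit (0 if constructed).
    """

    a: float
    gamma: float
    ed50: float
    a_fixed: bool = True
    adj_r2: float = float("nan")
    se: dict = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.gamma > 0 and self.ed50 > 0):
            raise ValidationError(
                f"FiModelFit requires A, gamma, ED50 > 0; got "
                f"A={self.a}, gamma={self.gamma}, ED50={self.ed50}"
            )

    def predict(self, total_dose):
        return predict_fi(self, total_dose)

    def inverse(self, fi):
        return inverse_dose(self, fi)


def predict_fi(fit: FiModelFit, total_dose):
    """Evaluate the FI model at one or more total doses (Gy).

    Strictly increasing in dose, bounded in (0, A); at ``D = ED50`` the
    erf argument vanishes and the model returns exactly ``A/2``.
    """
    d = np.asarray(total_dose, dtype=float)
    out = 0.5 * fit.a * (1.0 - erf(_SQRT_PI * fit.gamma * (1.0 - d / fit.ed50)))
    return out if out.ndim else float(out)


def inverse_dose(fit: FiModelFit, fi):
    """Dose (Gy) at which the model reaches a given FI level.

    Exact closed-form inverse of :func:`predict_fi`; defined for
    ``0 < FI < A`` only.
    """
    f = np.asarray(fi, dtype=float)
    if np.any(f <= 0.0) or np.any(f >= fit.a):
        raise DomainError(
            f"inverse_dose requires 0 < FI < A={fit.a}; got {fi!r}"
        )
    out = fit.ed50 * (1.0 - erfinv(1.0 - 2.0 * f / fit.a) / (_SQRT_PI * fit.gamma))
    return out if out.ndim else float(out)


def _model_free_a(d, a, ed50, gamma):
    return 0.5 * a * (1.0 - erf(_SQRT_PI * gamma * (1.0 - d / ed50)))


def _init_ed50(doses: np.ndarray, fis: np.ndarray, a: float) -> float:
    """Initial ED50: dose where group-mean FI crosses A/2, by linear
    interpolation between bracketing dose levels; median dose fallback."""
    levels = np.unique(doses)
    means = np.array([fis[doses == lv].mean() for lv in levels])
    half = a / 2.0
    above = means >= half
    if above.any() and (~above).any():
        i = int(np.argmax(above))  # first level at/above the midpoint
        if i > 0:
            x0, x1 = levels[i - 1], levels[i]
            y0, y1 = means[i - 1], means[i]
            if y1 != y0:
                return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
    return float(np.median(levels))


def fit_fi_model(doses, fis, fix_a: float | None = DEFAULT_SATURATION,
                 group_means: bool = False) -> FiModelFit:
    """Fit the FI sigmoid to (dose, FI) data by nonlinear least squares.

    Parameters
    ----------
    doses, fis : array-like
        Per-animal total doses (Gy) and observed fibrosis indices.
    fix_a : float or None
        Hold the saturation constant at this value (default 7.20, the
        experimentally measured maximum); ``None`` fits A as well.
    group_means : bool
        Fit dose-group mean FI instead of individual animals.

    Returns
    -------
    FiModelFit with parameter standard errors (from the fit covariance)
    and adjusted R-squared.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(fis, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValidationError("doses and fis must be 1-D arrays of equal length")
    if np.any(y < 0):
        raise ValidationError("FI values must be >= 0")
    if group_means:
        levels = np.unique(d)
        y = np.array([y[d == lv].mean() for lv in levels])
        d = levels

    n_free = 2 if fix_a is not None else 3
    if len(np.unique(d)) < 3:
        raise ValidationError("need at least 3 distinct dose levels")
    if len(d) < n_free + 1:
        raise ValidationError("fewer observations than free parameters + 1")
    if np.allclose(y, y[0]):
        raise FitError("FI data carry no dose-response signal (constant response)")

    a0 = fix_a if fix_a is not None else max(float(y.max()), 1e-3)
    ed50_0 = _init_ed50(d, y, a0)
    dmax = float(d.max())
    gamma0 = 1.0

    try:
        if fix_a is not None:
            def model(dd, ed50, gamma):
                return _model_free_a(dd, fix_a, ed50, gamma)

            popt, pcov = curve_fit(
                model, d, y, p0=[ed50_0, gamma0],
                bounds=([1e-9, 1e-9], [10.0 * dmax, 20.0]), maxfev=20000,
            )
            a, (ed50, gamma) = fix_a, popt
            names = ["ed50", "gamma"]
        else:
            popt, pcov = curve_fit(
                _model_free_a, d, y, p0=[a0, ed50_0, gamma0],
                bounds=([1e-9, 1e-9, 1e-9], [10.0 * a0, 10.0 * dmax, 20.0]),
                maxfev=20000,
            )
            a, ed50, gamma = popt
            names = ["a", "ed50", "gamma"]
    except RuntimeError as exc:  # curve_fit non-convergence
        raise FitError(f"FI-model fit did not converge: {exc}") from exc

    fit = FiModelFit(a=float(a), gamma=float(gamma), ed50=float(ed50),
                     a_fixed=fix_a is not None, n=len(d))
    pred = predict_fi(fit, d)
    se = dict(zip(names, np.sqrt(np.clip(np.diag(pcov), 0.0, None))))
    r2 = adjusted_r2(y, pred, n_free)
    return FiModelFit(a=float(a), gamma=float(gamma), ed50=float(ed50),
                      a_fixed=fix_a is not None, adj_r2=r2, se=se, n=len(d))


def adjusted_r2(observed, predicted, n_free_params: int) -> float:
    """Adjusted R² with the residual-vs-total convention for nonlinear fits:
    R² = 1 − SSres/SStot, adjusted = 1 − (1−R²)(n−1)/(n−p−1)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    n = len(y)
    if n < n_free_params + 2:
        raise ValidationError("need at least n_free_params + 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("zero total variance: R-squared undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_free_params - 1)
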
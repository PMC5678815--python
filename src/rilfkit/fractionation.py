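"""Fractionation-sensitivity (alpha/beta) estimation from isoeffect data.

Three classical routes to the linear-quadratic alpha/beta ratio are
implemented, all anchored to the biologically-effective-dose identity
for two isoeffective schedules (total dose D at dose-per-fraction d):

    D1 (1 + d1/(a/b)) = D2 (1 + d2/(a/b))
        =>  a/b = (D2 d2 - D1 d1) / (D1 - D2)

1. **Isoeffect pairing** - invert the fitted FI sigmoids of two
   fractionation arms at the same FI level to get (D1, D2), then apply
   the identity above; sweeping FI over its effective range yields the
   dose-dependent alpha/beta profile.
2. **Fe plot** - regress reciprocal total isoeffect dose on dose per
   fraction; under the LQ model 1/D is exactly linear in d and
   alpha/beta = intercept/slope.
3. **LQ fit** - regress a log-transformed response on (D, dD), reading
   alpha and beta off directly.

Isoeffect curves (d and D vs fraction number at fixed alpha/beta) and a
three-parameter exponential-decay summary fit round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dose_response import FiModelFit, inverse_dose
from .errors import DomainError, FitError, ValidationError

__all__ = [
    "Schedule",
    "IsoeffectPair",
    "LQFit",
    "FePlotFit",
    "alpha_beta_from_pair",
    "alpha_beta_profile",
    "fe_plot",
    "fit_lq",
    "isoeffect_curve",
    "fit_exp_decay",
    "DEFAULT_FI_GRID",
    "FI_FLOOR",
]

#: Effective FI range swept when profiling alpha/beta (FI units).
DEFAULT_FI_GRID = np.round(np.arange(0.05, 7.15 + 1e-9, 0.05), 10)

#: FI values below this are floored before log transformation.
FI_FLOOR = 0.05


@dataclass(frozen=True)
class Schedule:
    """A fractionation schedule: n fractions of d Gy, total D = n*d."""

    n_fractions: int
    dose_per_fraction: float
    total_dose: float

    def __post_init__(self) -> None:
        if self.n_fractions < 1 or self.dose_per_fraction <= 0 or self.total_dose <= 0:
            raise ValidationError("schedule components must be positive")
        if abs(self.total_dose - self.n_fractions * self.dose_per_fraction) > 1e-9:
            raise ValidationError(
                f"total dose {self.total_dose} != "
                f"{self.n_fractions} x {self.dose_per_fraction}"
            )

    @classmethod
    def from_nd(cls, n_fractions: int, dose_per_fraction: float) -> "Schedule":
        return cls(n_fractions, dose_per_fraction,
                   n_fractions * dose_per_fraction)


@dataclass(frozen=True)
class IsoeffectPair:
    """Two (total dose, dose/fraction) schedules producing the same FI."""

    d1_total: float
    d1_per_fraction: float
    d2_total: float
    d2_per_fraction: float
    fi_level: float = float("nan")


@dataclass(frozen=True)
class LQFit:
    alpha: float
    beta: float
    intercept: float
    alpha_beta: float
    r2: float = float("nan")


@dataclass(frozen=True)
class FePlotFit:
    slope: float
    intercept: float
    alpha_beta: float
    residual_ss: float = 0.0


def alpha_beta_from_pair(pair: IsoeffectPair) -> float:
    """alpha/beta from one isoeffective schedule pair:
    (D2 d2 - D1 d1) / (D1 - D2).

    With d1 = d2 the identity degenerates to -d, which lies outside the
    model's assumptions; the value is returned as-is so callers can
    flag it, but equal *total* doses raise.
    """
    if pair.d1_total == pair.d2_total:
        raise DomainError("degenerate pair: equal total doses")
    return (pair.d2_total * pair.d2_per_fraction
            - pair.d1_total * pair.d1_per_fraction) / (pair.d1_total - pair.d2_total)


def alpha_beta_profile(fit_1fx: FiModelFit, fit_nfx: FiModelFit,
                       n_fractions: int, fi_grid=None):
    """Dose-dependent alpha/beta over a grid of FI levels.

    For each FI level the isoeffective total doses of the two arms are
    obtained from the sigmoid inverses (D1 single-fraction, D2 in
    ``n_fractions`` fractions, d2 = D2/n), then paired through the BED
    identity.  Returns ``(table, summary)`` where the table has columns
    ``fi, d1_gy, d2_gy, dose_per_fraction_2_gy, alpha_beta_gy`` and the
    summary reports mean and SD of alpha/beta over the grid.
    """
    grid = DEFAULT_FI_GRID if fi_grid is None else np.asarray(fi_grid, dtype=float)
    amax = min(fit_1fx.a, fit_nfx.a)
    if np.any(grid <= 0) or np.any(grid >= amax):
        raise DomainError(f"fi_grid must lie strictly inside (0, {amax})")
    d1 = inverse_dose(fit_1fx, grid)
    d2 = inverse_dose(fit_nfx, grid)
    ab = np.array([
        alpha_beta_from_pair(IsoeffectPair(a, a, b, b / n_fractions, fi))
        for fi, a, b in zip(grid, d1, d2)
    ])
    table = pd.DataFrame({
        "fi": grid, "d1_gy": d1, "d2_gy": d2,
        "dose_per_fraction_2_gy": d2 / n_fractions, "alpha_beta_gy": ab,
    })
    summary = {"alpha_beta_mean_gy": float(ab.mean()),
               "alpha_beta_sd_gy": float(ab.std(ddof=1)) if len(ab) > 1 else 0.0,
               "n_levels": int(len(ab))}
    return table, summary


def fe_plot(points) -> FePlotFit:
    """Fe-plot estimate of alpha/beta.

    ``points`` is a sequence of isoeffective ``(dose_per_fraction,
    total_dose)`` pairs.  Ordinary least squares of 1/D on d gives a
    line whose intercept/slope ratio is alpha/beta (exact under the LQ
    model, where 1/D = (alpha + beta d)/E is linear in d).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValidationError("need >= 2 (d, D) points")
    d, total = pts[:, 0], pts[:, 1]
    if len(np.unique(d)) < 2:
        raise ValidationError("rank-deficient Fe plot: all dose-per-fraction equal")
    if np.any(total <= 0):
        raise ValidationError("total doses must be positive")
    y = 1.0 / total
    design = np.column_stack([np.ones_like(d), d])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    intercept, slope = coef
    if slope == 0:
        raise FitError("Fe-plot slope is zero; alpha/beta undefined")
    resid = y - design @ coef
    return FePlotFit(slope=float(slope), intercept=float(intercept),
                     alpha_beta=float(intercept / slope),
                     residual_ss=float(resid @ resid))


def fit_lq(schedules, fis, transform=None, fi_floor: float = FI_FLOOR) -> LQFit:
    """Fit the linear-quadratic model to transformed FI responses.

    ``schedules`` is a sequence of ``(total_dose, dose_per_fraction)``
    pairs and ``fis`` the matching FI values.  The response is
    ``transform(FI)`` (default: -log10 of FI floored at ``fi_floor``)
    and is regressed as

        y = c - (alpha * D + beta * d * D)

    by linear least squares.  Separating alpha from beta needs at least
    two distinct dose-per-fraction values in the design.
    """
    sched = np.asarray(schedules, dtype=float)
    y_raw = np.asarray(fis, dtype=float)
    if sched.ndim != 2 or sched.shape[1] != 2 or len(sched) != len(y_raw):
        raise ValidationError("schedules must be (D, d) pairs matching fis")
    if len({(a, b) for a, b in sched}) < 3:
        raise ValidationError("need >= 3 distinct schedules")
    total, per_fx = sched[:, 0], sched[:, 1]
    if len(np.unique(per_fx[total > 0])) < 2:
        raise ValidationError(
            "cannot separate alpha from beta: single dose-per-fraction design")

    if transform is None:
        fl = np.maximum(y_raw, fi_floor)
        if np.any(fl <= 0):
            raise ValidationError("nonpositive FI after flooring")
        y = -np.log10(fl)
    else:
        y = np.asarray(transform(y_raw), dtype=float)

    design = np.column_stack([np.ones_like(total), -total, -per_fx * total])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    c, alpha, beta = coef
    if beta == 0:
        raise FitError("beta estimated as zero; alpha/beta undefined")
    pred = design @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return LQFit(alpha=float(alpha), beta=float(beta), intercept=float(c),
                 alpha_beta=float(alpha / beta), r2=r2)


def isoeffect_curve(alpha_beta: float, reference: Schedule, n_list):
    """Schedules isoeffective with ``reference`` at a given alpha/beta.

    For each fraction number n, solves the BED identity
    ``n d (1 + d/(a/b)) = BED_ref`` for the dose per fraction (positive
    quadratic root) and returns a list of ``(n, d, D)`` tuples.
    """
    if alpha_beta <= 0:
        raise ValidationError("alpha_beta must be > 0")
    bed_ref = reference.total_dose * (1.0 + reference.dose_per_fraction / alpha_beta)
    out = []
    for n in n_list:
        n = int(n)
        if n < 1:
            raise ValidationError("fraction numbers must be >= 1")
        # d^2/ab + d - bed_ref/n = 0
        disc = 1.0 + 4.0 * bed_ref / (n * alpha_beta)
        if disc <= 0:
            raise DomainError(f"no positive root for n={n}")
        d = 0.5 * alpha_beta * (np.sqrt(disc) - 1.0)
        if d <= 0:
            raise DomainError(f"no positive root for n={n}")
        out.append((n, float(d), float(n * d)))
    return out


def fit_exp_decay(x, y):
    """Fit y = a*exp(-x/b) + c by nonlinear least squares.

    The decay constant is initialised from the data range (b0 = span/3)
    and the plateau from the tail, making the fit deterministic for a
    given data set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4 or len(x) != len(y):
        raise ValidationError("need >= 4 (x, y) points")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    c0 = float(ys[-1])
    a0 = float(ys[0] - c0) or 1e-6
    span = float(xs[-1] - xs[0]) or 1.0
    b0 = span / 3.0
    try:
        import warnings

        from scipy.optimize import OptimizeWarning
        with warnings.catch_warnings():
            # flat data leave the decay constant unidentified; the point
            # estimate (a ~ 0, c ~ mean) is still well defined
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(lambda t, a, b, c: a * np.exp(-t / b) + c,
                                x, y, p0=[a0, b0, c0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exponential-decay fit did not converge: {exc}") from exc
    return tuple(float(v) for v in popt)
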
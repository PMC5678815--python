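"""Biologically effective dose (BED) and the FI-vs-BED logistic.

BED = D (1 + d/(a/b)) puts schedules with different fractionation on a
common effect scale.  Pooling both fractionation arms on that scale,
the fibrosis index follows a four-parameter log-logistic (Hill-type)
curve

    FI(BED) = A2 + (A1 - A2) / (1 + (BED/k)^p)

with lower asymptote A1, upper asymptote A2, midpoint k (the BED at
FI = (A1+A2)/2) and shape exponent p.  Three clinically meaningful
landmarks are extracted from the fitted curve:

* ``bed_tr`` - the maximum-curvature point on the rising toe, read as
  the threshold BED at which fibrosis starts to develop;
* ``bed_cutoff`` - the maximum-slope point (steepest response); for
  p > 1 this has the closed form k ((p-1)/(p+1))^(1/p);
* ``bed_ed50`` - the BED producing half-maximal FI (= k when A1 = 0).

Curvature is the geometric (arc-length) curvature of the curve in
(Gy, FI) coordinates, kappa = f'' / (1 + f'^2)^(3/2); because landmark
positions depend on the axis scaling, an option to normalise both axes
to [0, 1] before maximising is provided and the choice is always
explicit in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .dose_response import adjusted_r2
from .errors import FitError, ValidationError

__all__ = [
    "BedLogisticFit",
    "bed",
    "bed_logistic",
    "fit_bed_logistic",
    "extract_landmarks",
    "max_slope_closed_form",
]


def bed(total_dose, dose_per_fraction, alpha_beta: float):
    """Biologically effective dose D (1 + d/(a/b)) in Gy; >= D always."""
    if alpha_beta <= 0:
        raise ValidationError("alpha_beta must be > 0")
    d_tot = np.asarray(total_dose, dtype=float)
    d_fx = np.asarray(dose_per_fraction, dtype=float)
    if np.any(d_tot <= 0) or np.any(d_fx <= 0):
        raise ValidationError("doses must be > 0")
    if np.any(d_fx > d_tot + 1e-12):
        raise ValidationError("dose per fraction cannot exceed total dose")
    out = d_tot * (1.0 + d_fx / alpha_beta)
    return out if out.ndim else float(out)


def bed_logistic(x, a1: float, a2: float, k: float, p: float):
    """The four-parameter FI-vs-BED log-logistic, safe at BED = 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        u = np.where(x > 0, (x / k) ** p, 0.0)
    out = a2 + (a1 - a2) / (1.0 + u)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BedLogisticFit:
    a1: float
    a2: float
    k: float
    p: float
    bed_tr: float = float("nan")
    bed_cutoff: float = float("nan")
    bed_ed50: float = float("nan")
    adj_r2: float = float("nan")
    se: dict = field(default_factory=dict)
    normalized_axes: bool = False
    n: int = 0

    def __post_init__(self) -> None:
        if not (self.a2 > self.a1):
            raise ValidationError("upper asymptote A2 must exceed A1")
        if self.k <= 0 or self.p <= 0:
            raise ValidationError("k and p must be > 0")

    def predict(self, x):
        return bed_logistic(x, self.a1, self.a2, self.k, self.p)


def max_slope_closed_form(k: float, p: float) -> float:
    """Analytic argmax of the logistic slope: k ((p-1)/(p+1))^(1/p).

    Only defined for p > 1; for p <= 1 the slope is monotone decreasing
    and has no interior maximum.
    """
    if p <= 1:
        raise ValidationError("no interior slope maximum for p <= 1")
    return k * ((p - 1.0) / (p + 1.0)) ** (1.0 / p)


def _derivs(x, a1, a2, k, p):
    """Analytic first and second derivatives of the logistic in FI/Gy."""
    x = np.asarray(x, dtype=float)
    u = np.where(x > 0, (x / k) ** p, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(x > 0, (a2 - a1) * p * u / (x * (1.0 + u) ** 2), 0.0)
        f2 = np.where(
            x > 0,
            (a2 - a1) * p * u * ((p - 1.0) - (p + 1.0) * u)
            / (x ** 2 * (1.0 + u) ** 3),
            0.0,
        )
    return f1, f2


def extract_landmarks(a1: float, a2: float, k: float, p: float,
                      bed_max: float | None = None,
                      normalize_axes: bool = False,
                      grid_points: int = 4096):
    """Landmarks of the fitted FI-vs-BED logistic.

    Returns ``(bed_tr, bed_cutoff, bed_ed50)``:

    * maximum-slope point by numeric argmax of f' on a dense grid with
      golden-section refinement (the closed form for p > 1 serves as an
      independent oracle in the test-suite);
    * maximum-curvature point of kappa = f''/(1+f'^2)^(3/2) on the
      rising toe below the maximum-slope point;
    * BED at half-maximal FI, solved from the model (equal to k when
      A1 = 0).

    ``normalize_axes=True`` rescales BED by ``bed_max`` and FI by
    (A2 - A1) before computing curvature; the slope argmax and ed50 are
    scale-invariant and unaffected.
    """
    if p <= 1:
        raise ValidationError(
            "p <= 1: logistic has no interior slope maximum; landmarks undefined")
    hi = float(bed_max) * 1.5 if bed_max else 3.0 * k
    hi = max(hi, 1.5 * k)

    xs, ys = 1.0, 1.0
    if normalize_axes:
        xs = hi  # BED axis -> [0, 1.5]/1.5 span
        ys = a2 - a1

    def neg_slope(x):
        f1, _ = _derivs(x, a1, a2, k, p)
        return -float(f1) * xs / ys

    grid = np.linspace(hi / grid_points, hi, grid_points)
    f1g, f2g = _derivs(grid, a1, a2, k, p)
    i_slope = int(np.argmax(f1g))
    bed_cutoff = _refine(neg_slope, grid, i_slope)

    def neg_curv(x):
        f1, f2 = _derivs(x, a1, a2, k, p)
        f1 = float(f1) * xs / ys
        f2 = float(f2) * xs ** 2 / ys
        return -f2 / (1.0 + f1 ** 2) ** 1.5

    toe = grid[grid <= bed_cutoff]
    if len(toe) < 3:
        toe = np.linspace(bed_cutoff / grid_points, bed_cutoff, grid_points)
    curv = np.array([-neg_curv(x) for x in toe])
    i_curv = int(np.argmax(curv))
    bed_tr = _refine(neg_curv, toe, i_curv)

    # FI = (A1+A2)/2 occurs exactly at k; "half-maximal FI" solves FI = A2/2
    target = a2 / 2.0
    if target <= a1:
        bed_ed50 = float("nan")
    elif a1 == 0:
        bed_ed50 = k
    else:
        bed_ed50 = k * ((a1 - a2) / (target - a2) - 1.0) ** (1.0 / p)
    return float(bed_tr), float(bed_cutoff), float(bed_ed50)


def _refine(objective, grid, i, tol: float = 1e-6):
    """Golden-section refinement of a grid minimum of ``objective``."""
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo >= hi:
        return float(grid[i])
    res = minimize_scalar(objective, bounds=(float(lo), float(hi)),
                          method="bounded", options={"xatol": tol})
    return float(res.x)


def fit_bed_logistic(beds, fis, fix_a1: float | None = None,
                     fix_a2: float | None = None,
                     normalize_axes: bool = False) -> BedLogisticFit:
    """Fit the FI-vs-BED logistic by nonlinear least squares.

    ``fix_a1`` / ``fix_a2`` pin the asymptotes (typical presets: 0 and
    the FI saturation constant 7.20).  Landmarks are derived from the
    fitted parameters via :func:`extract_landmarks`.
    """
    x = np.asarray(beds, dtype=float)
    y = np.asarray(fis, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("beds and fis must be 1-D arrays of equal length")
    if len(np.unique(x)) < 5:
        raise ValidationError("need >= 5 distinct BED values spanning the rise")
    if np.ptp(y) <= 0:
        raise FitError("FI values carry no signal")

    a1_0 = float(y.min()) if fix_a1 is None else fix_a1
    a2_0 = float(y.max()) if fix_a2 is None else fix_a2
    k0 = float(np.interp((a1_0 + a2_0) / 2.0, np.sort(y),
                         x[np.argsort(y)])) or float(np.median(x[x > 0]))
    p0 = 3.0

    names, p_init, lo, up = [], [], [], []
    if fix_a1 is None:
        names.append("a1"); p_init.append(a1_0); lo.append(-np.inf); up.append(np.inf)
    if fix_a2 is None:
        names.append("a2"); p_init.append(a2_0); lo.append(-np.inf); up.append(np.inf)
    names += ["k", "p"]
    p_init += [max(k0, 1e-6), p0]
    lo += [1e-9, 1e-9]
    up += [np.inf, 50.0]

    def model(xx, *theta):
        it = iter(theta)
        a1 = fix_a1 if fix_a1 is not None else next(it)
        a2 = fix_a2 if fix_a2 is not None else next(it)
        k = next(it)
        p = next(it)
        return bed_logistic(xx, a1, a2, k, p)

    try:
        popt, pcov = curve_fit(model, x, y, p0=p_init, bounds=(lo, up),
                               maxfev=40000)
    except RuntimeError as exc:
        raise FitError(f"BED-logistic fit did not converge: {exc}") from exc

    vals = dict(zip(names, popt))
    a1 = fix_a1 if fix_a1 is not None else float(vals["a1"])
    a2 = fix_a2 if fix_a2 is not None else float(vals["a2"])
    k, p = float(vals["k"]), float(vals["p"])
    if not a2 > a1:
        raise FitError("fitted upper asymptote does not exceed the lower one")

    if p > 1:
        bed_tr, bed_cutoff, bed_ed50 = extract_landmarks(
            a1, a2, k, p, bed_max=float(x.max()), normalize_axes=normalize_axes)
    else:  # shallow fit: slope has no interior maximum; landmarks undefined
        bed_tr = bed_cutoff = bed_ed50 = float("nan")
    se = dict(zip(names, np.sqrt(np.clip(np.diag(pcov), 0.0, None))))
    r2 = adjusted_r2(y, model(x, *popt), len(names))
    return BedLogisticFit(a1=a1, a2=a2, k=k, p=p, bed_tr=bed_tr,
                          bed_cutoff=bed_cutoff, bed_ed50=bed_ed50,
                          adj_r2=r2, se=se, normalized_axes=normalize_axes,
                          n=len(x))
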
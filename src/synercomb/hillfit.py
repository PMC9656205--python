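"""Four-parameter log-logistic (Hill) dose-response fitting.

The monotherapy model is

    E(d) = E0 + (Emax - E0) * d**h / (C**h + d**h)

with E0 the response at zero dose, Emax the plateau at infinite dose, C the
half-maximal concentration (relative EC50, nM) and h the Hill slope.  On the
inhibition scale the resistant plateau of cells surviving at high dose is
100 - Emax.

Fits are unweighted least squares with C and h estimated on the log scale and
a deterministic multi-start initialization, so identical inputs always give
identical fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .matrixio import ResponseMatrix


class DegenerateFitError(ValueError):
    """Response carries no dose information (flat within tolerance)."""


@dataclass
class HillCurve:
    """Fitted (or specified) four-parameter log-logistic curve."""

    E0: float
    Emax: float
    C: float
    h: float
    r_squared: float = 1.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.h <= 0:
            raise ValueError("h must be > 0")

    @property
    def resistant_fraction(self) -> float:
        """Plateau of surviving cells, 100 - Emax, on the inhibition scale."""
        return 100.0 - self.Emax


def hill_predict(curve: HillCurve, dose) -> np.ndarray | float:
    """Predicted response at *dose* (nM, scalar or array); E(0)=E0, E(inf)=Emax."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    with np.errstate(over="ignore"):
        frac = np.where(d > 0, 1.0 / (1.0 + (curve.C / np.where(d > 0, d, 1.0)) ** curve.h), 0.0)
    out = curve.E0 + (curve.Emax - curve.E0) * frac
    return float(out) if np.ndim(dose) == 0 else out


def _hill_model(d, E0, Emax, logC, logh):
    d = np.asarray(d, dtype=float)
    h = math.exp(logh)
    C = math.exp(logC)
    with np.errstate(divide="ignore", over="ignore"):
        frac = np.where(d > 0, 1.0 / (1.0 + (C / np.where(d > 0, d, 1.0)) ** h), 0.0)
    return E0 + (Emax - E0) * frac


def fit_hill(
    doses,
    responses,
    bounds: dict | None = None,
    fix_E0: float | None = None,
    fix_Emax: float | None = None,
) -> HillCurve:
    """Least-squares Hill fit; deterministic given identical inputs.

    Parameters
    ----------
    doses, responses
        Paired observations; at least 4 distinct doses unless asymptotes are
        fixed (ZIP-style two-parameter fits need only 2).
    bounds
        Optional dict with ``h`` and ``C`` (min, max) overrides.
    fix_E0, fix_Emax
        Pin the lower / upper asymptote (e.g. 0 / 100 for ZIP-convention fits
        on the inhibition scale).

    Raises
    ------
    DegenerateFitError
        If the responses are flat (zero total sum of squares).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses must have the same length")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    n_free = 4 - (fix_E0 is not None) - (fix_Emax is not None)
    if len(np.unique(d)) < max(n_free, 2):
        raise ValueError(f"need >= {max(n_free, 2)} distinct doses")

    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise DegenerateFitError("flat response: total sum of squares is zero")

    bounds = bounds or {}
    h_lo, h_hi = bounds.get("h", (0.05, 20.0))
    pos = d[d > 0]
    c_default = (pos.min() / 10.0 if pos.size else 1e-3, pos.max() * 10.0 if pos.size else 1e3)
    c_lo, c_hi = bounds.get("C", c_default)

    # deterministic start list: C at the dose bracketing the half-range
    # response, h in {0.5, 1, 2}
    e0_init = fix_E0 if fix_E0 is not None else float(y[np.argmin(d)])
    emax_init = fix_Emax if fix_Emax is not None else float(y[np.argmax(d)])
    half = 0.5 * (e0_init + emax_init)
    if pos.size:
        order = np.argsort(d)
        ds, ys = d[order], y[order]
        idx = int(np.argmin(np.abs(ys - half)))
        c_init = float(ds[idx]) if ds[idx] > 0 else float(np.sqrt(pos.min() * pos.max()))
    else:
        c_init = math.sqrt(c_lo * c_hi)
    c_init = min(max(c_init, c_lo * 1.001), c_hi * 0.999)

    y_span = max(y.max() - y.min(), 1.0)

    def residuals(theta):
        E0, Emax, logC, logh = _unpack(theta)
        return _hill_model(d, E0, Emax, logC, logh) - y

    def _unpack(theta):
        t = list(theta)
        E0 = fix_E0 if fix_E0 is not None else t.pop(0)
        Emax = fix_Emax if fix_Emax is not None else t.pop(0)
        logC, logh = t
        return E0, Emax, logC, logh

    lo, hi = [], []
    if fix_E0 is None:
        lo.append(y.min() - 2 * y_span); hi.append(y.max() + 2 * y_span)
    if fix_Emax is None:
        lo.append(y.min() - 2 * y_span); hi.append(y.max() + 2 * y_span)
    lo += [math.log(c_lo), math.log(h_lo)]
    hi += [math.log(c_hi), math.log(h_hi)]

    best = None
    for h0 in (0.5, 1.0, 2.0):
        x0 = []
        if fix_E0 is None:
            x0.append(e0_init)
        if fix_Emax is None:
            x0.append(emax_init)
        x0 += [math.log(c_init), math.log(min(max(h0, h_lo * 1.01), h_hi * 0.99))]
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        warnings.warn("Hill fit failed to converge from any start")
        return HillCurve(
            E0=e0_init, Emax=emax_init, C=c_init, h=1.0,
            r_squared=float("-inf"), converged=False,
        )

    E0, Emax, logC, logh = _unpack(best.x)
    ssres = float(2.0 * best.cost)
    r2 = 1.0 - ssres / sstot
    return HillCurve(
        E0=float(E0), Emax=float(Emax), C=math.exp(logC), h=math.exp(logh),
        r_squared=r2, converged=bool(best.success),
    )


def absolute_ic50(curve: HillCurve) -> float | None:
    """Dose giving 50% inhibition, or None when the curve never reaches 50.

    Distinct from the relative EC50 (parameter C): the absolute IC50 solves
    E(d) = 50 on the curve's own scale.
    """
    lo, hi = min(curve.E0, curve.Emax), max(curve.E0, curve.Emax)
    if not (lo < 50.0 <= hi) and not (lo <= 50.0 < hi):
        return None
    # invert E0 + (Emax-E0) * f = 50 with f = d^h / (C^h + d^h)
    f = (50.0 - curve.E0) / (curve.Emax - curve.E0)
    if f <= 0.0 or f >= 1.0:
        return None if f != 0.0 else 0.0
    return float(curve.C * (f / (1.0 - f)) ** (1.0 / curve.h))


def curve_shift(matrix: ResponseMatrix, along: str = "row") -> list[dict]:
    """Monotherapy-style Hill fits conditioned on each partner dose.

    Fits the responses along the *along* drug's dose axis once per fixed
    partner concentration, tabulating how the IC50 shifts as the partner dose
    rises.  Degenerate fits are flagged per entry, not fatal.
    """
    m = matrix.to_inhibition()
    entries: list[dict] = []
    if along == "row":
        partner_doses, var_doses = m.doses_col, m.doses_row
        columns = (m.response[:, j] for j in range(len(m.doses_col)))
    elif along == "col":
        partner_doses, var_doses = m.doses_row, m.doses_col
        columns = (m.response[i, :] for i in range(len(m.doses_row)))
    else:
        raise ValueError("along must be 'row' or 'col'")
    for partner_dose, y in zip(partner_doses, columns):
        entry: dict = {"partner_dose": float(partner_dose)}
        try:
            curve = fit_hill(var_doses, y)
            entry["curve"] = curve
            entry["absolute_ic50"] = absolute_ic50(curve)
            entry["flagged"] = not curve.converged
        except (DegenerateFitError, ValueError) as exc:
            entry["curve"] = None
            entry["absolute_ic50"] = None
            entry["flagged"] = True
            entry["reason"] = str(exc)
        entries.append(entry)
    return entries
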
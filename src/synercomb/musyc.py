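"""MuSyC two-drug dose-response surface: steady state, fitting, α/β/γ.

The MuSyC framework describes a population of cells distributed over four
states — U (unaffected), A1 (affected by drug 1), A2 (affected by drug 2)
and A12 (affected by both) — with mass-action transitions whose rates are
Hill-type functions of the two doses.  At steady state the observed response
is the state-weighted mean

    E(d1, d2) = U*E0 + A1*E1 + A2*E2 + A12*E3

and the three synergy axes are decoupled:

* **α** (potency): fold change of one drug's effective dose in cells already
  affected by the other.  ``alpha21`` scales drug 1's dose in the A2 → A12
  transition; ``alpha12`` scales drug 2's dose in A1 → A12.
* **β** (efficacy): ``(min(E1, E2) - E3) / (E0 - min(E1, E2))`` — the
  fractional increase of the combination's maximal effect beyond the most
  efficacious single agent.
* **γ** (cooperativity): fold change of a drug's Hill slope induced by the
  other drug.

Responses are modelled on a viability-fraction scale (untreated E0 ≈ 1, full
kill → 0) so β's sign convention matches "percent increase in maximal
efficacy"; % inhibition input is converted internally.  Only rate ratios
matter at steady state, so the forward rate constants r1 = r2 = 1 are fixed,
removing two unidentifiable parameters.  Fold parameters (α, γ) are fitted
in log space, which enforces positivity and makes synergy and antagonism
symmetric around 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .hillfit import DegenerateFitError, fit_hill
from .matrixio import ResponseMatrix

_FOLD_BOUNDS = (1e-5, 1e5)
_H_BOUNDS = (0.05, 20.0)


@dataclass
class MuSyCSurface:
    """Parameters of the four-state MuSyC surface (viability-fraction scale)."""

    E0: float
    E1: float
    E2: float
    E3: float
    h1: float
    h2: float
    C1: float
    C2: float
    alpha12: float
    alpha21: float
    gamma12: float = 1.0
    gamma21: float = 1.0
    r_squared: float = float("nan")
    converged: bool = True
    unstable: dict | None = None   # per-parameter instability flags

    def __post_init__(self) -> None:
        for name in ("h1", "h2", "C1", "C2", "alpha12", "alpha21", "gamma12", "gamma21"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def beta(self) -> float:
        """Efficacy synergy derived from the four asymptotes."""
        return derive_beta(self.E0, self.E1, self.E2, self.E3)


def derive_beta(E0: float, E1: float, E2: float, E3: float) -> float:
    """Efficacy synergy: (min(E1, E2) - E3) / (E0 - min(E1, E2)).

    Positive when the combination's maximal effect exceeds the stronger
    single agent's; zero when it merely matches it.
    """
    strongest = min(E1, E2)
    denom = E0 - strongest
    if denom == 0:
        raise ZeroDivisionError("no single-agent efficacy: E0 equals min(E1, E2)")
    return (strongest - E3) / denom


def _pow(base: float, expo: float) -> float:
    """base**expo guarded against overflow (caps at exp(700))."""
    if base == 0.0:
        return 0.0
    logv = expo * math.log(base)
    return math.exp(min(logv, 700.0))


def _rates(surface: MuSyCSurface, d1: float, d2: float):
    """The eight mass-action transition rates at a dose pair (r1 = r2 = 1)."""
    s = surface
    return {
        ("U", "A1"): _pow(d1, s.h1),
        ("A1", "U"): _pow(s.C1, s.h1),
        ("U", "A2"): _pow(d2, s.h2),
        ("A2", "U"): _pow(s.C2, s.h2),
        ("A2", "A12"): _pow(s.alpha21 * d1, s.gamma21 * s.h1),
        ("A12", "A2"): _pow(s.C1, s.gamma21 * s.h1),
        ("A1", "A12"): _pow(s.alpha12 * d2, s.gamma12 * s.h2),
        ("A12", "A1"): _pow(s.C2, s.gamma12 * s.h2),
    }


_STATES = ("U", "A1", "A2", "A12")


def musyc_state_fractions(surface: MuSyCSurface, d1: float, d2: float) -> np.ndarray:
    """Steady-state occupancies (U, A1, A2, A12); nonnegative, sum to 1.

    Solves the 4×4 linear balance system with one balance row replaced by the
    normalization U + A1 + A2 + A12 = 1.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be >= 0")
    if d1 == 0 and d2 == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    rates = _rates(surface, d1, d2)
    idx = {s: i for i, s in enumerate(_STATES)}
    A = np.zeros((4, 4))
    for (src, dst), k in rates.items():
        A[idx[src], idx[src]] -= k
        A[idx[dst], idx[src]] += k
    A[0, :] = 1.0          # replace U-balance row with normalization
    b = np.array([1.0, 0.0, 0.0, 0.0])
    # scale balance rows for conditioning (rates span many decades)
    scale = np.abs(A[1:, :]).max(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    A[1:, :] /= scale
    try:
        frac = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        frac, *_ = np.linalg.lstsq(A, b, rcond=None)
    # tiny negative round-off snapped to 0
    frac = np.clip(frac, 0.0, None)
    total = frac.sum()
    if not np.isfinite(total) or total <= 0:
        frac, *_ = np.linalg.lstsq(A, b, rcond=None)
        frac = np.clip(frac, 0.0, None)
        total = frac.sum()
        if not np.isfinite(total) or total <= 0:
            return np.array([0.25, 0.25, 0.25, 0.25])
    return frac / total


def musyc_steady_state(surface: MuSyCSurface, d1, d2):
    """Steady-state response E(d1, d2) = U·E0 + A1·E1 + A2·E2 + A12·E3."""
    E = np.array([surface.E0, surface.E1, surface.E2, surface.E3])
    d1a, d2a = np.broadcast_arrays(np.asarray(d1, float), np.asarray(d2, float))
    out = np.empty(d1a.shape)
    for i in np.ndindex(d1a.shape):
        out[i] = musyc_state_fractions(surface, float(d1a[i]), float(d2a[i])) @ E
    return float(out) if out.ndim == 0 else out


def musyc_grid(surface: MuSyCSurface, doses_row, doses_col) -> np.ndarray:
    """Steady-state surface evaluated on a full checkerboard grid."""
    d1, d2 = np.meshgrid(doses_row, doses_col, indexing="ij")
    return musyc_steady_state(surface, d1, d2)


# ---------------------------------------------------------------------------
# fitting


def _pack(s: MuSyCSurface) -> np.ndarray:
    return np.array([
        s.E0, s.E1, s.E2, s.E3,
        math.log(s.h1), math.log(s.h2),
        math.log(s.C1), math.log(s.C2),
        math.log(s.alpha12), math.log(s.alpha21),
        math.log(s.gamma12), math.log(s.gamma21),
    ])


def _unpack(x: np.ndarray) -> MuSyCSurface:
    return MuSyCSurface(
        E0=x[0], E1=x[1], E2=x[2], E3=x[3],
        h1=math.exp(x[4]), h2=math.exp(x[5]),
        C1=math.exp(x[6]), C2=math.exp(x[7]),
        alpha12=math.exp(x[8]), alpha21=math.exp(x[9]),
        gamma12=math.exp(x[10]), gamma21=math.exp(x[11]),
    )


def musyc_fit(
    matrix: ResponseMatrix,
    init: dict | None = None,
    fit_gamma: bool = True,
    instability_fold: float = 100.0,
) -> MuSyCSurface:
    """Fit the MuSyC surface to a checkerboard by nonlinear least squares.

    The matrix is converted internally to viability fractions (1 = untreated).
    Initialization is deterministic: asymptotes, slopes and EC50s come from
    the monotherapy Hill fits, E3 starts at the minimum observed viability,
    and the fold parameters start from a small fixed grid of candidate values
    (the best start by residual wins, ties broken by start order).  Bounds:
    folds in [1e-5, 1e5], Hill slopes in [0.05, 20].

    Parameters whose profile is boundary-unstable — a refit at a
    ``instability_fold``-fold perturbed value changes the residual by less
    than 0.1 % — are flagged in ``surface.unstable`` so aggregation can
    exclude them; values are never clipped.
    """
    m = matrix.to_inhibition()
    if not m.has_control_cell:
        raise ValueError("matrix must carry monotherapy edges (zero-dose row/col)")
    if m.response.size < 12:
        raise ValueError("fewer cells than parameters")
    if len(m.doses_row) < 4 or len(m.doses_col) < 4:
        raise ValueError("need >= 4 doses per drug (including the zero dose)")
    init = init or {}

    # viability-fraction observations; raw (unclipped) values are fitted
    viab = 1.0 - m.response / 100.0
    d1 = m.doses_row
    d2 = m.doses_col

    try:
        hill1 = fit_hill(d1, viab[:, 0])
        hill2 = fit_hill(d2, viab[0, :])
    except DegenerateFitError as exc:
        raise DegenerateFitError(f"flat monotherapy edge: {exc}") from exc

    e0_init = float(init.get("E0", 0.5 * (hill1.E0 + hill2.E0)))
    surf0 = MuSyCSurface(
        E0=e0_init,
        E1=float(init.get("E1", hill1.Emax)),
        E2=float(init.get("E2", hill2.Emax)),
        E3=float(init.get("E3", float(viab.min()))),
        h1=float(np.clip(init.get("h1", hill1.h), *_H_BOUNDS)),
        h2=float(np.clip(init.get("h2", hill2.h), *_H_BOUNDS)),
        C1=float(init.get("C1", hill1.C)),
        C2=float(init.get("C2", hill2.C)),
        alpha12=1.0, alpha21=1.0, gamma12=1.0, gamma21=1.0,
    )

    D1, D2 = np.meshgrid(d1, d2, indexing="ij")
    dd1, dd2 = D1.ravel(), D2.ravel()
    y = viab.ravel()

    n_gamma = 2 if fit_gamma else 0

    def residuals(x):
        if not fit_gamma:
            x = np.concatenate([x, [0.0, 0.0]])
        s = _unpack(x)
        pred = np.array([
            musyc_state_fractions(s, a, b) @ (s.E0, s.E1, s.E2, s.E3)
            for a, b in zip(dd1, dd2)
        ])
        return pred - y

    # asymptotes stay near the observed response range: an asymptote far
    # outside anything measured is unidentified (it only shows up through
    # barely-populated states) and lets E3 run away
    span = max(float(y.max() - y.min()), 0.1)
    margin = max(0.15, 0.25 * span)
    # a viability fraction cannot go below 0: the lower asymptote bound stops
    # just under 0 (small allowance for noise around a complete kill)
    asym_lo = max(y.min() - margin, min(float(y.min()), -0.02))
    lo = np.array(
        [asym_lo] * 4
        + [math.log(_H_BOUNDS[0])] * 2
        + [math.log(d1[1] * 1e-3), math.log(d2[1] * 1e-3)]
        + [math.log(_FOLD_BOUNDS[0])] * (2 + n_gamma)
    )
    hi = np.array(
        [y.max() + margin] * 4
        + [math.log(_H_BOUNDS[1])] * 2
        + [math.log(d1[-1] * 1e3), math.log(d2[-1] * 1e3)]
        + [math.log(_FOLD_BOUNDS[1])] * (2 + n_gamma)
    )

    # deterministic multi-start over the potency folds
    starts = []
    for a0 in init.get("alpha_starts", (1.0, 4.0, 0.25)):
        s = replace(surf0, alpha12=a0, alpha21=a0)
        x0 = _pack(s)
        starts.append(x0 if fit_gamma else x0[:-2])

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost * (1 - 1e-9):
            best = res

    sstot = float(np.sum((y - y.mean()) ** 2))
    if best is None:
        warnings.warn("MuSyC fit failed from every start; returning init surface")
        surf0.r_squared = float("-inf")
        surf0.converged = False
        return surf0

    x = best.x if fit_gamma else np.concatenate([best.x, [0.0, 0.0]])
    fitted = _unpack(x)
    ssres = float(2.0 * best.cost)
    fitted.r_squared = 1.0 - ssres / sstot if sstot > 0 else float("-inf")
    fitted.converged = bool(best.success)

    fitted.unstable = _flag_unstable(fitted, residuals, best, fit_gamma, instability_fold)
    return fitted


def _flag_unstable(fitted, residuals, best, fit_gamma, fold):
    """Mark fold parameters whose value barely constrains the residual.

    Mirrors the behaviour of boundary-runaway fits (enormous α/γ with even
    larger dispersions): if multiplying a fold parameter by ``fold`` changes
    the sum of squares by < 0.1 %, its fitted value is not identified and is
    flagged so consensus aggregation can drop it.
    """
    names = ["alpha12", "alpha21"] + (["gamma12", "gamma21"] if fit_gamma else [])
    offsets = {"alpha12": 8, "alpha21": 9, "gamma12": 10, "gamma21": 11}
    base_ss = float(2.0 * best.cost)
    flags: dict[str, bool] = {}
    for name in names:
        i = offsets[name] if fit_gamma else offsets[name]
        x_pert = best.x.copy()
        x_pert[i] = x_pert[i] + math.log(fold)
        ss = float(np.sum(residuals(x_pert) ** 2))
        flags[name] = abs(ss - base_ss) < 1e-3 * max(base_ss, 1e-12)
    return flags


def surface_from_inhibition_params(**kw) -> MuSyCSurface:
    """Build a surface from asymptotes given in % inhibition (converted)."""
    for key in ("E0", "E1", "E2", "E3"):
        if key in kw:
            kw[key] = 1.0 - kw[key] / 100.0
    return MuSyCSurface(**kw)
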
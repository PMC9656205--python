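"""Reference-model expectations and δ synergy scores.

Four non-interaction reference models are implemented on the % inhibition
scale:

* **Bliss independence** — the two drugs act as independent probabilistic
  events: expected inhibition fraction ``y1 + y2 - y1*y2``.
* **HSA (highest single agent)** — the expectation is the better monotherapy
  response at the component doses, ``max(y1, y2)``.
* **Loewe additivity** — the combination behaves like a drug combined with
  itself; the expected response solves ``d1/D1(y) + d2/D2(y) = 1`` where
  ``Di`` is drug i's inverse Hill function.
* **ZIP (zero interaction potency)** — potency-shifted conditional Hill fits
  along each axis, compared against the Bliss expectation of the fitted
  monotherapy curves.

The δ score of a cell is the observed inhibition minus the model expectation,
in percentage points; the matrix δ is the mean over combination cells (both
doses > 0), excluding monotherapy edges which have zero expected interaction
by construction.  Expectations use fitted monotherapy Hill curves rather than
raw edge observations (the ZIP model requires fitted curves; the same
convention is applied to all models for consistency; pass
``use_fitted_edges=False`` for raw edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hillfit import DegenerateFitError, HillCurve, fit_hill, hill_predict
from .matrixio import ResponseMatrix

MODELS = ("zip", "loewe", "hsa", "bliss")


@dataclass
class DeltaScores:
    """Cell-wise and matrix-mean δ for one reference model."""

    model: str
    cellwise_delta: np.ndarray        # full grid; NaN on edges/control
    mean_delta: float
    sd_delta: float
    n_cells: int
    flagged_cells: list[tuple[int, int]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "model": self.model,
            "mean_delta": self.mean_delta,
            "sd_delta": self.sd_delta,
            "n_cells": self.n_cells,
        }


def _check_fraction(y, name):
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError(f"{name} must be an inhibition fraction in [0, 1]")
    return y


def bliss_expected(y1, y2):
    """Expected inhibition fraction of two independently acting drugs."""
    y1 = _check_fraction(y1, "y1")
    y2 = _check_fraction(y2, "y2")
    out = y1 + y2 - y1 * y2
    return float(out) if out.ndim == 0 else out


def hsa_expected(y1, y2):
    """Highest-single-agent expectation: the better monotherapy fraction."""
    y1 = _check_fraction(y1, "y1")
    y2 = _check_fraction(y2, "y2")
    out = np.maximum(y1, y2)
    return float(out) if out.ndim == 0 else out


def _inverse_hill(curve: HillCurve, y: float) -> float:
    """Dose at which the curve predicts inhibition y; inf if unreachable."""
    lo, hi = curve.E0, curve.Emax
    if y >= hi:
        return float("inf")
    if y <= lo:
        return 0.0
    f = (y - lo) / (hi - lo)
    return float(curve.C * (f / (1.0 - f)) ** (1.0 / curve.h))


def loewe_expected(
    curve1: HillCurve,
    curve2: HillCurve,
    d1: float,
    d2: float,
    tol: float = 1e-9,
) -> float:
    """Loewe-additive expected inhibition % at the dose pair (d1, d2).

    Solves d1/D1(y) + d2/D2(y) = 1 for y by bisection over the jointly
    achievable response range.  When y exceeds one drug's Emax that drug's
    equivalent dose is infinite and its term vanishes, so the expectation can
    rise up to the larger Emax.  Both curves must be on the inhibition scale
    with Emax > E0.
    """
    for c in (curve1, curve2):
        if c.Emax <= c.E0:
            raise ValueError("Loewe requires increasing curves (Emax > E0)")
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be >= 0")
    if d1 == 0 and d2 == 0:
        return float(max(curve1.E0, curve2.E0))
    if d2 == 0:
        return float(hill_predict(curve1, d1))
    if d1 == 0:
        return float(hill_predict(curve2, d2))

    def excess(y: float) -> float:
        # > 0 while the dose pair exceeds the iso-effect requirement at y
        t1 = d1 / _inverse_hill(curve1, y) if np.isfinite(_inverse_hill(curve1, y)) else 0.0
        D2 = _inverse_hill(curve2, y)
        t2 = d2 / D2 if np.isfinite(D2) else 0.0
        return t1 + t2 - 1.0

    lo = max(curve1.E0, curve2.E0)
    hi = max(curve1.Emax, curve2.Emax)
    f_lo = excess(lo + tol)
    if f_lo <= 0.0:
        return float(lo)
    f_hi = excess(hi - tol)
    if f_hi >= 0.0:
        # doses exceed what the most efficacious drug can report: boundary
        return float(hi)
    a, b = lo + tol, hi - tol
    while b - a > tol:
        mid = 0.5 * (a + b)
        if excess(mid) > 0.0:
            a = mid
        else:
            b = mid
    return float(0.5 * (a + b))


# ---------------------------------------------------------------------------
# matrix-level scoring


def _split_edges(matrix: ResponseMatrix):
    """Monotherapy edge vectors (doses, responses) including the control cell."""
    m = matrix.to_inhibition()
    if not m.has_control_cell:
        raise ValueError("matrix must carry monotherapy edges (zero-dose row/col)")
    row_doses = m.doses_row
    col_doses = m.doses_col
    y_row = m.response[:, 0]   # row drug alone (col dose 0)
    y_col = m.response[0, :]   # col drug alone
    return m, row_doses, col_doses, y_row, y_col


def _fit_monotherapies(matrix: ResponseMatrix, zip_convention: bool = False):
    m, row_doses, col_doses, y_row, y_col = _split_edges(matrix)
    kw = dict(fix_E0=0.0, fix_Emax=100.0) if zip_convention else {}
    c_row = fit_hill(row_doses, y_row, **kw)
    c_col = fit_hill(col_doses, y_col, **kw)
    return m, c_row, c_col


def _collect(model: str, matrix: ResponseMatrix, delta: np.ndarray, flagged=None) -> DeltaScores:
    mask = np.zeros_like(delta, dtype=bool)
    mask[1:, 1:] = True  # combination cells only: both doses > 0
    cells = delta[mask]
    grid = np.where(mask, delta, np.nan)
    return DeltaScores(
        model=model,
        cellwise_delta=grid,
        mean_delta=float(np.mean(cells)),
        sd_delta=float(np.std(cells, ddof=1)) if cells.size > 1 else 0.0,
        n_cells=int(cells.size),
        flagged_cells=flagged or [],
    )


def zip_delta_matrix(matrix: ResponseMatrix) -> DeltaScores:
    """ZIP δ scores for a checkerboard with monotherapy edges.

    Monotherapy curves are fitted with asymptotes pinned at 0 and 100 %
    inhibition.  For each fixed partner dose a two-parameter Hill is fitted
    along the other axis with its lower asymptote pinned at the fitted
    monotherapy response to the partner dose; the cell δ is the average of
    the two conditional fits minus the Bliss expectation of the fitted
    monotherapy values.  Rows or columns whose conditional fit fails fall
    back to the unconditioned Bliss expectation and are flagged.
    """
    m, c_row, c_col = _fit_monotherapies(matrix, zip_convention=True)
    clipped = m.clipped()
    nr, nc = clipped.response.shape
    y1 = np.clip(hill_predict(c_row, m.doses_row), 0.0, 100.0)   # row drug alone
    y2 = np.clip(hill_predict(c_col, m.doses_col), 0.0, 100.0)

    # conditional fits along rows (varying row drug, fixed col dose) ...
    cond_rowwise = np.full((nr, nc), np.nan)   # y_c(d1 | d2)
    cond_colwise = np.full((nr, nc), np.nan)   # y_c(d2 | d1)
    flagged: list[tuple[int, int]] = []

    for j in range(1, nc):
        base = float(y2[j])
        try:
            fit = fit_hill(m.doses_row, clipped.response[:, j], fix_E0=base, fix_Emax=100.0)
            cond_rowwise[:, j] = hill_predict(fit, m.doses_row)
        except (DegenerateFitError, ValueError):
            cond_rowwise[:, j] = 100.0 * bliss_expected(y1 / 100.0, base / 100.0)
            flagged += [(i, j) for i in range(1, nr)]
    for i in range(1, nr):
        base = float(y1[i])
        try:
            fit = fit_hill(m.doses_col, clipped.response[i, :], fix_E0=base, fix_Emax=100.0)
            cond_colwise[i, :] = hill_predict(fit, m.doses_col)
        except (DegenerateFitError, ValueError):
            cond_colwise[i, :] = 100.0 * bliss_expected(base / 100.0, y2 / 100.0)
            flagged += [(i, j) for j in range(1, nc)]

    expected = 100.0 * bliss_expected(
        np.repeat(y1[:, None], nc, axis=1) / 100.0,
        np.repeat(y2[None, :], nr, axis=0) / 100.0,
    )
    delta = 0.5 * (cond_rowwise + cond_colwise) - expected
    return _collect("zip", m, delta, sorted(set(flagged)))


def delta_matrix(
    matrix: ResponseMatrix,
    model: str,
    use_fitted_edges: bool = True,
) -> DeltaScores:
    """δ scores of a checkerboard under one reference model.

    For Bliss and HSA the cell δ is observed inhibition minus 100 × the
    expected fraction from the monotherapy responses; for Loewe, observed
    minus the dose-additive expectation; ZIP delegates to
    :func:`zip_delta_matrix`.
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if model == "zip":
        return zip_delta_matrix(matrix)

    m, c_row, c_col = _fit_monotherapies(matrix)
    clipped = m.clipped()
    nr, nc = clipped.response.shape
    if use_fitted_edges:
        y1 = np.clip(hill_predict(c_row, m.doses_row), 0.0, 100.0)
        y2 = np.clip(hill_predict(c_col, m.doses_col), 0.0, 100.0)
    else:
        y1 = clipped.response[:, 0]
        y2 = clipped.response[0, :]

    expected = np.zeros((nr, nc))
    if model == "bliss":
        expected = 100.0 * bliss_expected(
            np.repeat(y1[:, None], nc, axis=1) / 100.0,
            np.repeat(y2[None, :], nr, axis=0) / 100.0,
        )
    elif model == "hsa":
        expected = 100.0 * hsa_expected(
            np.repeat(y1[:, None], nc, axis=1) / 100.0,
            np.repeat(y2[None, :], nr, axis=0) / 100.0,
        )
    elif model == "loewe":
        for i in range(nr):
            for j in range(nc):
                expected[i, j] = loewe_expected(
                    c_row, c_col, float(m.doses_row[i]), float(m.doses_col[j])
                )
    delta = clipped.response - expected
    return _collect(model, m, delta)


def score_all_models(matrix: ResponseMatrix, models=MODELS) -> dict[str, DeltaScores]:
    """Convenience: δ scores under every requested reference model."""
    return {mod: delta_matrix(matrix, mod) for mod in models}
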
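"""Slow independent oracles used to cross-check the fast implementations."""

import numpy as np
from scipy.integrate import solve_ivp

from synercomb import HillCurve, MuSyCSurface
from synercomb.musyc import _rates


def random_surface(rng) -> MuSyCSurface:
    """Pharmacologically plausible random MuSyC parameter draw."""
    return MuSyCSurface(
        E0=1.0,
        E1=rng.uniform(0.0, 0.6),
        E2=rng.uniform(0.0, 0.6),
        E3=rng.uniform(0.0, 0.3),
        h1=rng.uniform(0.5, 2.5),
        h2=rng.uniform(0.5, 2.5),
        C1=10 ** rng.uniform(-1, 2),
        C2=10 ** rng.uniform(-1, 2),
        alpha12=10 ** rng.uniform(-0.7, 0.7),
        alpha21=10 ** rng.uniform(-0.7, 0.7),
        gamma12=10 ** rng.uniform(-0.3, 0.3),
        gamma21=10 ** rng.uniform(-0.3, 0.3),
    )


def ode_steady_state(surface: MuSyCSurface, d1: float, d2: float) -> np.ndarray:
    """Long-time integration of the four mass-action rate equations.

    Independent of the steady-state linear solve: the ODE system is first
    integrated adaptively over one fast time unit, then propagated with the
    exact solution operator expm(M*t) over doubling horizons until the state
    stops moving.  Stiffness ratios of the rate network can exceed 1e15, so a
    step integrator alone cannot reach the slow manifold's equilibration in
    bounded time.
    """
    from scipy.linalg import expm

    rates = _rates(surface, d1, d2)
    idx = {"U": 0, "A1": 1, "A2": 2, "A12": 3}
    M = np.zeros((4, 4))
    for (src, dst), k in rates.items():
        M[idx[src], idx[src]] -= k
        M[idx[dst], idx[src]] += k
    # only rate ratios matter: rescale time so the fastest rate is 1
    M = M / np.abs(M).max()
    sol = solve_ivp(
        lambda t, y: M @ y, (0.0, 1.0), [1.0, 0.0, 0.0, 0.0],
        method="Radau", rtol=1e-10, atol=1e-14,
    )
    x = sol.y[:, -1]
    def renormalize(P):
        # the exact propagator is a Markov (column-stochastic, nonnegative)
        # matrix; restoring that structure keeps repeated squaring stable
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=0, keepdims=True)

    propagator = renormalize(expm(M))   # one fast time unit
    for _ in range(120):
        x_new = propagator @ x
        if np.max(np.abs(x_new - x)) < 1e-12:
            return x_new
        x = x_new
        propagator = renormalize(propagator @ propagator)   # doubled horizon
    return x


def loewe_grid_scan(c1: HillCurve, c2: HillCurve, d1: float, d2: float,
                    step: float = 1e-4) -> float:
    """Brute-force scan of the dose-additivity equation over a y grid."""
    y = np.arange(max(c1.E0, c2.E0) + step, max(c1.Emax, c2.Emax), step)

    def inv(c, yy):
        f = np.clip((yy - c.E0) / (c.Emax - c.E0), None, 1 - 1e-12)
        return np.where(f <= 0, 0.0, c.C * (f / (1 - f)) ** (1 / c.h))

    with np.errstate(divide="ignore"):
        t1 = np.where(y >= c1.Emax, 0.0, d1 / inv(c1, y))
        t2 = np.where(y >= c2.Emax, 0.0, d2 / inv(c2, y))
    return float(y[np.argmin(np.abs(t1 + t2 - 1.0))])
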
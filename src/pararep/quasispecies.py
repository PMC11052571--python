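"""Deterministic single-peak quasispecies analysis: exponential (Eigen)
versus parabolic growth.

Two-variable replicator dynamics under constant organization
(``x + y = 1``), with a single master genotype of reproductive value ``A``
and a lumped mutant class of reproductive value ``a`` (default 1).  ``Q``
is the probability of error-free master replication and ``pB`` an optional
back-mutation probability from the mutant cloud to the master.

Exponential (first-order) growth::

    dx/dt = A*Q*x + a*pB*y - x*Ebar,      Ebar = A*x + a*y
    dy/dt = A*(1-Q)*x + a*(1-pB)*y - y*Ebar

has, for ``pB = 0``, the equilibrium master concentration
``x_e = (A*Q - a) / (A - a)`` clipped at zero: the master vanishes beyond
the error threshold ``Q* = a / A`` (``1/A`` for ``a = 1``).

Parabolic (half-order) growth replaces each reproductive flux by its
square-root form::

    dx/dt = A*Q*sqrt(x) + a*pB*sqrt(y) - x*Ebar_p,
    Ebar_p = A*sqrt(x) + a*sqrt(y)

and keeps a strictly positive master equilibrium for every ``Q > 0`` — the
error threshold is absent.  With ``pB > 0`` the threshold disappears from
the exponential regime as well.

Equilibria are computed by bracketed root finding and cross-validated by
long-time stiff integration (:func:`scipy.integrate.solve_ivp`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq


@dataclass
class LandscapeParams:
    """Single-peak landscape: reproductive superiority A, mutant value a,
    copying fidelity Q, back-mutation probability pB."""

    A: float = 10.0
    a: float = 1.0
    Q: float = 0.5
    pB: float = 0.0

    def validate(self) -> None:
        if not self.A > self.a > 0:
            raise ValueError("need reproductive superiority A > a > 0")
        if not 0 <= self.Q <= 1:
            raise ValueError("Q is a probability")
        if not 0 <= self.pB <= 1:
            raise ValueError("pB is a probability")


def _master_rate(lp: LandscapeParams, x: float, parabolic: bool) -> float:
    """dx/dt on the simplex x + y = 1."""
    y = 1.0 - x
    if parabolic:
        gx, gy = math.sqrt(max(x, 0.0)), math.sqrt(max(y, 0.0))
    else:
        gx, gy = x, y
    ebar = lp.A * gx + lp.a * gy
    return lp.A * lp.Q * gx + lp.a * lp.pB * gy - x * ebar


def exponential_equilibrium(lp: LandscapeParams) -> float:
    """Stable equilibrium master fraction under exponential dynamics.

    For ``pB = 0`` this is the closed form ``(A*Q - a)/(A - a)`` clipped to
    zero (error threshold at ``Q = a/A``); with back mutations the positive
    root of the quadratic equilibrium condition is returned.
    """
    lp.validate()
    if lp.pB == 0:
        return max(0.0, (lp.A * lp.Q - lp.a) / (lp.A - lp.a))
    return _root_equilibrium(lp, parabolic=False)


def parabolic_equilibrium(lp: LandscapeParams) -> float:
    """Stable equilibrium master fraction under parabolic dynamics:
    strictly positive for every ``Q > 0`` (and exactly 0 at ``Q = 0``,
    ``pB = 0``)."""
    lp.validate()
    if lp.Q == 0 and lp.pB == 0:
        return 0.0
    return _root_equilibrium(lp, parabolic=True)


def _root_equilibrium(lp: LandscapeParams, parabolic: bool,
                      x_start: float = 0.5) -> float:
    """Bracketed root of dx/dt = 0: the stable rest point reached from
    *x_start* (matching the integration cross-check by construction; near
    Q = 1 the parabolic flow can hold several rest points)."""
    f = lambda x: _master_rate(lp, x, parabolic)
    if lp.Q == 1 and lp.pB == 0:
        return 1.0
    grid = np.linspace(1e-15, 1.0, 2049)
    vals = np.array([f(x) for x in grid])
    f0 = f(x_start)
    if f0 == 0.0:
        return x_start
    if f0 > 0:  # flow moves up: first sign change above x_start
        idx = np.nonzero((grid[:-1] >= x_start) &
                         (vals[:-1] > 0) & (vals[1:] <= 0))[0]
        if len(idx) == 0:
            return 1.0
        k = idx[0]
    else:  # flow moves down: nearest sign change below x_start
        idx = np.nonzero((grid[1:] <= x_start) &
                         (vals[:-1] >= 0) & (vals[1:] < 0))[0]
        if len(idx) == 0:
            return 0.0
        k = idx[-1]
    if vals[k] == 0.0:
        return float(grid[k])
    return brentq(f, grid[k], grid[k + 1], xtol=1e-14, rtol=8.9e-16)


def integrate_to_equilibrium(lp: LandscapeParams, parabolic: bool,
                             x0: float = 0.5, t_final: float = 1e4,
                             atol: float = 1e-10) -> float:
    """Long-time numerical integration of the replicator ODE from x0;
    independent cross-check for the root-finding equilibria.  The state is
    (x, y); the integrator conserves x + y = 1 to within *atol*."""
    lp.validate()

    def rhs(_, z):
        x, y = z
        if parabolic:
            gx, gy = math.sqrt(max(x, 0.0)), math.sqrt(max(y, 0.0))
        else:
            gx, gy = max(x, 0.0), max(y, 0.0)
        ebar = lp.A * gx + lp.a * gy
        return [lp.A * lp.Q * gx + lp.a * lp.pB * gy - x * ebar,
                lp.A * (1 - lp.Q) * gx + lp.a * (1 - lp.pB) * gy - y * ebar]

    sol = solve_ivp(rhs, (0.0, t_final), [x0, 1.0 - x0], method="LSODA",
                    rtol=1e-10, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    x, y = sol.y[:, -1]
    if abs(x + y - 1.0) > 100 * atol:
        raise RuntimeError(f"simplex constraint violated: x+y = {x + y}")
    return float(x)


def with_back_mutations(lp: LandscapeParams) -> tuple[float, float]:
    """(exponential, parabolic) equilibria for a landscape with pB > 0;
    both are positive for every Q in (0, 1)."""
    return exponential_equilibrium(lp), parabolic_equilibrium(lp)


def threshold_scan(A_grid, Q_grid, a: float = 1.0,
                   tolerance: float = 1e-9) -> dict:
    """Error-threshold scan over a grid.

    For each A, the smallest Q with a positive exponential equilibrium —
    refined by bisection between the bracketing grid points, so it matches
    ``a/A`` to the *tolerance* — and the minimum parabolic equilibrium
    over the positive-Q grid (certifying persistence).
    """
    A_grid = np.asarray(A_grid, float)
    Q_grid = np.asarray(Q_grid, float)
    exp_threshold = np.full(A_grid.shape, np.nan)
    par_min_x = np.full(A_grid.shape, np.inf)
    x_exp = np.zeros((len(A_grid), len(Q_grid)))
    x_par = np.zeros((len(A_grid), len(Q_grid)))
    for i, A in enumerate(A_grid):
        for j, Q in enumerate(Q_grid):
            lp = LandscapeParams(A=A, a=a, Q=Q)
            x_exp[i, j] = exponential_equilibrium(lp)
            x_par[i, j] = parabolic_equilibrium(lp)
            if Q > 0:
                par_min_x[i] = min(par_min_x[i], x_par[i, j])
        above = np.nonzero(x_exp[i] > tolerance)[0]
        if len(above):
            k = above[0]
            if k == 0:
                exp_threshold[i] = Q_grid[0]
            else:
                lo, hi = Q_grid[k - 1], Q_grid[k]
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    if exponential_equilibrium(
                            LandscapeParams(A=A, a=a, Q=mid)) > tolerance:
                        hi = mid
                    else:
                        lo = mid
                exp_threshold[i] = hi
    return {"A": A_grid, "Q": Q_grid, "x_exponential": x_exp,
            "x_parabolic": x_par, "exponential_threshold": exp_threshold,
            "parabolic_min_positive_Q": par_min_x}
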
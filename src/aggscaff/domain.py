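"""Analytic steady state of a single absorbing scaffold domain.

A condensed scaffold domain of radius ``R`` sits in a membrane populated by
diffusing scaffold-receptor complexes.  Particles are delivered to the
membrane with flux density ``J`` and removed everywhere with rate ``k``, so
that far from the domain the free concentration is ``c0 = J/k``.  The domain
edge absorbs incoming particles, which imposes a depleted layer of width
``lam = sqrt(D0/k)`` around the domain.  The steady concentration field
outside the disc solves the screened diffusion equation

    D0 * laplacian(c) - k*c + J = 0,      c(R) = 0,  c(inf) = c0,

whose radially symmetric solution is ``c(r) = c0 * [1 - K0(r/lam)/K0(R/lam)]``
with ``K0`` the modified Bessel function of the second kind.  Balancing the
diffusive influx through the perimeter against the turnover efflux ``k*N``
from the domain area fixes the stationary size:

    N = rho * (D0/k) * Phi(c0/rho),       Phi(u) = pi * x(u)**2,

where ``x = R/lam`` is the root of ``x*K0(x)/K1(x) = 2*u``.  The domain size
is therefore set by the dimensionless ratio ``c0/rho`` and the single length
scale ``lam``, and grows linearly in ``D0/k`` at fixed ``c0/rho``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import k0e, k1e

from .params import PhysicalParams

__all__ = [
    "DomainSolution",
    "solve_phi",
    "domain_size",
    "concentration_profile",
    "sweep_domain_size",
]

_EULER_GAMMA = 0.5772156649015329

# Bracket for the reduced radius x = R/lam.  x*K0/K1 is strictly increasing
# from 0, so any root in (0, inf) is unique; 1e3 covers u arbitrarily close
# to the c0 < rho limit (x*K0/K1 -> x - 1/2 for large x).
_X_LO = 1e-12
_X_HI = 1e3


@dataclass(frozen=True)
class DomainSolution:
    """Stationary single-domain solution.

    Attributes
    ----------
    N : float
        Stationary domain size in particles (gephyrin trimers).
    R : float
        Domain radius (um).
    lam : float
        Depletion/diffusion length sqrt(D0/k) (um).
    x : float
        Reduced radius R/lam (dimensionless).
    phi : float
        Value of Phi(c0/rho) = pi*x^2 (dimensionless).
    """

    N: float
    R: float
    lam: float
    x: float
    phi: float


def _flux_balance(x: float, u: float) -> float:
    # x*K0(x)/K1(x) - 2u, written with exponentially scaled Bessels for
    # stability at large x (the exponential factors cancel in the ratio).
    return x * k0e(x) / k1e(x) - 2.0 * u


def solve_phi(u: float) -> float:
    """Dimensionless domain-size function Phi(u), u = c0/rho.

    Phi is strictly increasing on (0, 1) with Phi(u) -> 0 as u -> 0+; for
    small u it follows the log-corrected quadratic root
    ``x**2 * (ln(2/x) - gamma) = 2u``.
    """
    if not 0.0 < u < 1.0:
        raise ValueError(f"concentration ratio u = c0/rho must lie in (0, 1), got {u!r}")
    lo, hi = _X_LO, _X_HI
    f_lo, f_hi = _flux_balance(lo, u), _flux_balance(hi, u)
    if not (f_lo < 0.0 < f_hi):
        raise RuntimeError(
            "flux-balance root not bracketed: "
            f"f({lo})={f_lo:.3e}, f({hi})={f_hi:.3e} for u={u!r}"
        )
    x = brentq(_flux_balance, lo, hi, args=(u,), xtol=1e-300, rtol=1e-14)
    return math.pi * x * x


def domain_size(p: PhysicalParams) -> DomainSolution:
    """Stationary size of a single absorbing scaffold domain.

    Returns the particle number ``N = rho*(D0/k)*Phi(c0/rho)`` together
    with the domain radius, depletion length, and the reduced radius.  At
    the returned solution the turnover efflux ``k*N`` balances the diffusive
    influx through the domain perimeter to floating precision.
    """
    u = p.c0 / p.rho
    phi = solve_phi(u)
    lam = p.lam
    x = math.sqrt(phi / math.pi)
    N = p.rho * (p.D0 / p.k) * phi
    R = x * lam
    return DomainSolution(N=N, R=R, lam=lam, x=x, phi=phi)


def influx(sol: DomainSolution, p: PhysicalParams) -> float:
    """Diffusive influx of particles through the domain perimeter (1/s).

    2*pi*R * D0 * dc/dr|_R with the screened-diffusion profile; equals the
    turnover efflux k*N at the stationary solution.
    """
    # dc/dr|_R = c0 * K1(R/lam) / (lam * K0(R/lam))
    grad = p.c0 * k1e(sol.x) / (sol.lam * k0e(sol.x))
    return 2.0 * math.pi * sol.R * p.D0 * grad


def concentration_profile(r, sol: DomainSolution, p: PhysicalParams):
    """Free-particle concentration c(r) outside the domain (um^-2).

    ``c(R) = 0`` at the absorbing edge and ``c -> c0`` monotonically over a
    layer of width ~lam.  Accepts scalar or array ``r >= R``.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < sol.R * (1.0 - 1e-12)):
        raise ValueError(f"r must be >= domain radius R={sol.R}")
    s = r_arr / sol.lam
    # K0(s)/K0(x) via scaled Bessels: k0e(s)*exp(-s) / (k0e(x)*exp(-x))
    ratio = k0e(s) / k0e(sol.x) * np.exp(sol.x - s)
    c = p.c0 * (1.0 - ratio)
    return c if c.shape else float(c)


def sweep_domain_size(
    p: PhysicalParams,
    vary: Literal["c0", "k"],
    grid: Iterable[float],
) -> pd.DataFrame:
    """Stationary domain size along a 1-D parameter sweep.

    Returns a DataFrame with columns (``vary``, ``N``, ``R_um``,
    ``lambda_um``).  N increases with c0 and decreases with k.
    """
    if vary not in ("c0", "k"):
        raise ValueError(f"vary must be 'c0' or 'k', got {vary!r}")
    rows = []
    for v in grid:
        if not v > 0:
            raise ValueError(f"grid values must be positive, got {v!r}")
        q = PhysicalParams(
            D0=p.D0,
            k=v if vary == "k" else p.k,
            c0=v if vary == "c0" else p.c0,
            rho=p.rho,
        )
        sol = domain_size(q)
        rows.append({vary: v, "N": sol.N, "R_um": sol.R, "lambda_um": sol.lam})
    return pd.DataFrame(rows)
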
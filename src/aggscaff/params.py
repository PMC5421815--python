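"""Biophysical parameters and unit conversion.

All public interfaces work in micrometres and seconds.  The particle
simulator internally uses the natural simulation units: length ``l0 = a``
(the diameter of a single scaffold particle, i.e. a gephyrin trimer bound
to its receptors) and time ``t0 = a**2 / D0`` (the time a single particle
needs to diffuse over its own diameter).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PhysicalParams", "DimensionlessParams", "to_dimensionless", "from_dimensionless"]


@dataclass(frozen=True)
class PhysicalParams:
    """Biophysical parameter set of the aggregation-removal model.

    Parameters
    ----------
    D0 : float
        Diffusion constant of a single scaffold-receptor complex (um^2/s).
    k : float
        Effective turnover (removal) rate of scaffold particles (1/s).
    c0 : float
        Total surface concentration of scaffold particles (um^-2).
    rho : float
        Particle number density inside a condensed domain (um^-2).
    """

    D0: float
    k: float
    c0: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("D0", "k", "c0", "rho"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not self.c0 < self.rho:
            raise ValueError(
                f"c0 must be smaller than the condensed-phase density rho "
                f"(got c0={self.c0}, rho={self.rho})"
            )

    @property
    def lam(self) -> float:
        """Depletion/diffusion length sqrt(D0/k) in um."""
        return (self.D0 / self.k) ** 0.5


@dataclass(frozen=True)
class DimensionlessParams:
    """Parameter set expressed in simulation units (length a, time a^2/D0).

    ``k_tilde`` is the desorption probability per particle per unit t0,
    ``c0_tilde`` and ``rho_tilde`` are concentrations per a^2, ``sigma`` is
    the exponent of the size-dependent cluster diffusion law
    D(n) = D0 * n**(-sigma).
    """

    k_tilde: float
    c0_tilde: float
    rho_tilde: float
    sigma: float
    a: float

    def __post_init__(self) -> None:
        for name in ("k_tilde", "c0_tilde", "rho_tilde", "a"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma!r}")


def to_dimensionless(p: PhysicalParams, a: float, sigma: float = 0.0) -> DimensionlessParams:
    """Convert physical parameters to simulation units.

    ``a`` is the particle diameter in um; rates are expressed per
    t0 = a^2/D0 and concentrations per a^2.
    """
    if not a > 0:
        raise ValueError(f"particle diameter a must be positive, got {a!r}")
    return DimensionlessParams(
        k_tilde=p.k * a**2 / p.D0,
        c0_tilde=p.c0 * a**2,
        rho_tilde=p.rho * a**2,
        sigma=sigma,
        a=a,
    )


def from_dimensionless(d: DimensionlessParams, D0: float) -> PhysicalParams:
    """Inverse of :func:`to_dimensionless`, given the physical D0 (um^2/s)."""
    if not D0 > 0:
        raise ValueError(f"D0 must be positive, got {D0!r}")
    return PhysicalParams(
        D0=D0,
        k=d.k_tilde * D0 / d.a**2,
        c0=d.c0_tilde / d.a**2,
        rho=d.rho_tilde / d.a**2,
    )
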
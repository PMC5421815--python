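"""Poisson maximum-likelihood fit of model size distributions to counts.

Super-resolution (PALM) imaging of a membrane area ``A_exp`` yields the
number ``#_i`` of scaffold clusters of each size ``i`` (in gephyrin
trimers, the model's elementary particle).  For model parameters
S = (k/D0, sigma, c0) the stationary rate-equation solution predicts the
concentrations ``c_i(S)``, hence expected counts ``n_i = A_exp * c_i(S)``,
and the data likelihood is a product of independent Poissons over sizes
i = 2..i_max (monomer counts are excluded as dominated by impurities and
detection noise; i_max is the largest observed size):

    L({#_i}; S) = prod_i  n_i**#_i * exp(-n_i) / #_i!

Only the ratio k/D0 and c0 identify the stationary shape (the kernel
constant is proportional to D0, with the dimensionless encounter prefactor
absorbed; concentrations are non-dimensionalised by the in-domain density
rho).  The fit scans a parameter grid, profiles c0 per culture (each
culture may have its own total concentration), and maximises the joint
log-likelihood over cultures for (k/D0, sigma).  Confidence regions come
from bootstrap resampling of the individual observed clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.special import gammaln

from .rate_equations import KernelSpec, RateParams, stationary_distribution

__all__ = [
    "ObservedCounts",
    "FitGrid",
    "FitResult",
    "ModelTable",
    "predicted_counts",
    "poisson_log_likelihood",
    "profile_c0",
    "grid_fit_joint",
    "bootstrap_region",
    "RHO_TRIMER",
]

RHO_TRIMER = 5000.0 / 3.0  # in-domain gephyrin trimer density (um^-2)
NEG_INF = -np.inf


@dataclass
class ObservedCounts:
    """Per-culture cluster-size histogram with the imaged membrane area.

    ``counts[i-1]`` is the number of observed clusters of size i (trimers);
    ``area`` is the observed membrane area A_exp in um^2.
    """

    culture_id: str
    counts: np.ndarray
    area: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if not self.area >= 0:
            raise ValueError("area must be nonnegative")
        # trim trailing zeros so i_max is the largest observed size
        nz = np.nonzero(self.counts)[0]
        if len(nz):
            self.counts = self.counts[: nz[-1] + 1]

    @property
    def i_max(self) -> int:
        return len(self.counts)

    @property
    def cluster_sizes(self) -> np.ndarray:
        """Individual cluster records (one size per observed cluster)."""
        sizes = np.arange(1, self.i_max + 1)
        return np.repeat(sizes, self.counts)

    @classmethod
    def from_cluster_sizes(
        cls, culture_id: str, sizes: Sequence[int], area: float
    ) -> "ObservedCounts":
        sizes = np.asarray(sizes, dtype=int)
        if len(sizes) == 0:
            return cls(culture_id, np.zeros(1, dtype=int), area)
        return cls(culture_id, np.bincount(sizes)[1:], area)


@dataclass(frozen=True)
class FitGrid:
    """Parameter grid: k/D0 (um^-2), sigma, and per-culture c0 (um^-2)."""

    k_over_D0: np.ndarray
    sigma: np.ndarray
    c0: np.ndarray

    def __post_init__(self) -> None:
        for name in ("k_over_D0", "sigma", "c0"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if name != "sigma" and np.any(v <= 0):
                raise ValueError(f"{name} grid values must be positive")
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} grid must be strictly increasing")

    @classmethod
    def default(cls) -> "FitGrid":
        """Default grid bracketing the experimentally plausible ranges:
        k/D0 in [1.4e-2, 4.2e-1] um^-2, sigma in [0, 1], c0 in [0.3, 8] um^-2."""
        return cls(
            k_over_D0=np.geomspace(1.4e-2, 4.2e-1, 7),
            sigma=np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
            c0=np.geomspace(0.3, 8.0, 7),
        )


def predicted_counts(
    k_over_D0: float,
    sigma: float,
    c0: float,
    area: float,
    rho: float = RHO_TRIMER,
    i_max: int | None = None,
    rtol: float = 1e-9,
) -> np.ndarray:
    """Expected counts n_i = A_exp * c_i(S) for sizes i = 1..i_max.

    The stationary distribution is solved with concentrations
    non-dimensionalised by rho and the kernel constant set by D0 (B = D0),
    so the stationary shape depends on parameters only through k/D0, sigma
    and c0.
    """
    if not area >= 0:
        raise ValueError("area must be nonnegative")
    p = RateParams(
        k=k_over_D0 / rho, c0=c0 / rho, kernel=KernelSpec(B=1.0, sigma=sigma)
    )
    sol = stationary_distribution(p, rtol=rtol)
    c_i = sol.c * rho  # back to um^-2
    if i_max is not None:
        if i_max > len(c_i):
            c_i = np.concatenate([c_i, np.zeros(i_max - len(c_i))])
        c_i = c_i[:i_max]
    return area * c_i


def poisson_log_likelihood(obs: ObservedCounts, means: np.ndarray) -> float:
    """Poisson log-likelihood over sizes i = 2..i_max.

    ``means[i-1]`` must align with sizes i = 1..i_max (entry 0 is ignored).
    A zero predicted mean with a positive observed count yields -inf with a
    warning.
    """
    if len(means) < obs.i_max:
        raise ValueError("means must cover sizes up to i_max")
    n = np.asarray(means[: obs.i_max], dtype=float)[1:]  # i >= 2
    x = obs.counts[1:].astype(float)
    if np.any((n <= 0) & (x > 0)):
        warnings.warn(
            f"culture {obs.culture_id}: zero predicted mean with positive count; "
            "log-likelihood is -inf",
            stacklevel=2,
        )
        return NEG_INF
    ok = n > 0
    return float(np.sum(x[ok] * np.log(n[ok]) - gammaln(x[ok] + 1.0)) - np.sum(n))


class ModelTable:
    """Cache of predicted concentrations over a fit grid.

    Stationary solutions are expensive relative to likelihood evaluations;
    fits, bootstraps and recovery sweeps therefore share one precomputed
    table of c_i (um^-2) for every (k/D0, sigma, c0) grid point.
    """

    def __init__(self, grid: FitGrid, rho: float = RHO_TRIMER, i_max: int = 256,
                 rtol: float = 1e-9):
        self.grid = grid
        self.rho = rho
        self.i_max = i_max
        # conc[ki, si, ci, i-1], um^-2
        self.conc = np.zeros(
            (len(grid.k_over_D0), len(grid.sigma), len(grid.c0), i_max)
        )
        for ki, k in enumerate(grid.k_over_D0):
            for si, s in enumerate(grid.sigma):
                for ci, c0 in enumerate(grid.c0):
                    self.conc[ki, si, ci] = predicted_counts(
                        k, s, c0, area=1.0, rho=rho, i_max=i_max, rtol=rtol
                    )

    def means(self, ki: int, si: int, ci: int, area: float) -> np.ndarray:
        return area * self.conc[ki, si, ci]


def profile_c0(
    obs: ObservedCounts,
    ki: int,
    si: int,
    table: ModelTable,
) -> tuple[int, float, bool]:
    """Most likely c0 grid index for one culture at fixed (k/D0, sigma).

    Returns (c0 index, profiled log-likelihood, boundary flag); ties break
    toward smaller c0 and the flag marks an argmax on the grid edge.
    """
    n_c0 = len(table.grid.c0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logls = np.array([
            poisson_log_likelihood(obs, table.means(ki, si, ci, obs.area))
            for ci in range(n_c0)
        ])
    if np.all(np.isneginf(logls)):
        raise ValueError(
            f"culture {obs.culture_id}: likelihood is -inf on the whole c0 grid "
            f"at grid point ki={ki}, si={si}"
        )
    best = int(np.argmax(logls))  # first max = smallest c0
    return best, float(logls[best]), best in (0, n_c0 - 1)


@dataclass
class FitResult:
    """Joint maximum-likelihood estimate with the profiled surface."""

    best_k_over_D0: float
    best_sigma: float
    per_culture_c0: dict[str, float]
    logl_surface: np.ndarray  # (n_k, n_sigma) profiled joint log-likelihood
    grid: FitGrid
    boundary: bool
    region: list[tuple[float, float]] | None = None
    region_weights: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)


def grid_fit_joint(
    cultures: Sequence[ObservedCounts],
    grid: FitGrid,
    rho: float = RHO_TRIMER,
    table: ModelTable | None = None,
) -> FitResult:
    """Joint fit over cultures: profile c0 per culture, maximise over (k/D0, sigma).

    The joint log-likelihood at each (k/D0, sigma) is the sum over cultures
    of the c0-profiled log-likelihoods.  Grid points where every c0 gives
    -inf for some culture are excluded.  Deterministic; ties break toward
    the smallest k/D0 then sigma.
    """
    if len(cultures) == 0:
        raise ValueError("need at least one culture")
    if table is None:
        i_max = max(c.i_max for c in cultures)
        table = ModelTable(grid, rho=rho, i_max=max(i_max, 8))
    n_k, n_s = len(grid.k_over_D0), len(grid.sigma)
    surface = np.full((n_k, n_s), NEG_INF)
    c0_idx = np.zeros((n_k, n_s, len(cultures)), dtype=int)
    any_boundary = np.zeros((n_k, n_s), dtype=bool)
    for ki in range(n_k):
        for si in range(n_s):
            total = 0.0
            try:
                for j, obs in enumerate(cultures):
                    ci, logl, at_edge = profile_c0(obs, ki, si, table)
                    c0_idx[ki, si, j] = ci
                    any_boundary[ki, si] |= at_edge
                    total += logl
            except ValueError:
                continue
            surface[ki, si] = total
    if np.all(np.isneginf(surface)):
        raise ValueError("no solvable grid point: joint likelihood is -inf everywhere")
    ki, si = np.unravel_index(int(np.argmax(surface)), surface.shape)
    return FitResult(
        best_k_over_D0=float(grid.k_over_D0[ki]),
        best_sigma=float(grid.sigma[si]),
        per_culture_c0={
            obs.culture_id: float(grid.c0[c0_idx[ki, si, j]])
            for j, obs in enumerate(cultures)
        },
        logl_surface=surface,
        grid=grid,
        boundary=bool(any_boundary[ki, si]),
        metadata={"argmax_indices": (int(ki), int(si))},
    )


def _logl_tensors(cultures, table):
    """Per-culture tensors for fast bootstrap refits.

    For counts vector x (sizes 1..i_max): logL(ki,si,ci) up to an additive
    data-only constant is  sum_i x_i*log(n_i) - cumsum(n)_[i_max_r], where
    the mean sums run over i = 2..i_max_r of the resample.
    """
    out = []
    for obs in cultures:
        means = table.conc * obs.area  # (K,S,C,I)
        # zero means get a large negative log so that a positive count at
        # that size vetoes the grid point while a zero count contributes 0
        log_means = np.where(means > 0, np.log(np.maximum(means, 1e-300)), -1e30)
        cum_means = np.cumsum(means, axis=-1)  # sum over i<=imax; subtract i=1 later
        out.append((log_means, cum_means, means))
    return out


def bootstrap_region(
    cultures: Sequence[ObservedCounts],
    grid: FitGrid,
    n_boot: int = 10000,
    seed: int = 0,
    rho: float = RHO_TRIMER,
    table: ModelTable | None = None,
    coverage: float = 0.95,
) -> FitResult:
    """Bootstrap confidence region for (k/D0, sigma).

    Individual observed clusters (size >= 2, the records entering the
    likelihood) are resampled with replacement per culture; each resample
    is refit with per-culture c0 profiling and its argmax recorded.  The
    region is the smallest set of grid points covering ``coverage`` of the
    resample argmaxes.  Returns the full-data fit with the region attached.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if table is None:
        i_max = max(c.i_max for c in cultures)
        table = ModelTable(grid, rho=rho, i_max=max(i_max, 8))
    full = grid_fit_joint(cultures, grid, rho=rho, table=table)
    rng = np.random.default_rng(seed)
    tensors = _logl_tensors(cultures, table)
    records = [obs.cluster_sizes for obs in cultures]
    records = [r[r >= 2] for r in records]
    if any(len(r) == 0 for r in records):
        raise ValueError("every culture needs at least one cluster of size >= 2")
    n_k, n_s = len(grid.k_over_D0), len(grid.sigma)
    votes = np.zeros((n_k, n_s), dtype=np.int64)
    for _ in range(n_boot):
        joint = np.zeros((n_k, n_s))
        for (log_means, cum_means, _), rec in zip(tensors, records):
            sample = rng.choice(rec, size=len(rec), replace=True)
            x = np.bincount(sample, minlength=table.i_max + 1)[1:].astype(float)
            i_max_r = int(np.max(sample))
            # sum over i=2..i_max_r of x_i log n_i  -  n_i
            dot = np.einsum("ksci,i->ksc", log_means[..., 1:i_max_r], x[1:i_max_r])
            sums = cum_means[..., i_max_r - 1] - cum_means[..., 0]
            logl = dot - sums
            joint += np.max(logl, axis=-1)
        ki, si = np.unravel_index(int(np.argmax(joint)), joint.shape)
        votes[ki, si] += 1
    order = np.argsort(votes.ravel())[::-1]
    cum = np.cumsum(votes.ravel()[order])
    n_pts = int(np.searchsorted(cum, coverage * n_boot) + 1)
    region = []
    for flat in order[:n_pts]:
        ki, si = np.unravel_index(int(flat), votes.shape)
        region.append((float(grid.k_over_D0[ki]), float(grid.sigma[si])))
    full.region = region
    full.region_weights = votes / n_boot
    full.metadata.update({"n_boot": n_boot, "seed": seed, "coverage": coverage})
    return full
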
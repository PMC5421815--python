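"""Tagged-cluster size dynamics: jump process, autocorrelation, time asymmetry.

A single ("tagged") cluster embedded in the stationary bath of clusters is
described by a birth-death jump process on its size n: it gains m particles
by fusing with an ambient cluster of size m at rate ``K(n, m) * c_m``
(mean-field: the bath is frozen at the stationary distribution, spatial
correlations are ignored), and loses single particles by desorption at
rate ``k * n``.  Trajectories are simulated exactly with the Gillespie
algorithm.

Two statistics characterise the fluctuations:

* the autocorrelation ``C2(tau) = <n(t+tau) n(t)> - <n>^2``, which decays
  approximately exponentially with characteristic rate k, so the size
  memory time is tau_fluc ~ 1/k;
* the third-order moment ``Y(tau) = <n(t+tau) n(t)^2> - <n(t+tau)^2 n(t)>``,
  which vanishes identically for any process obeying detailed balance.
  Here Y is non-zero -- fusion gains are sudden jumps while desorption
  losses are gradual -- a direct signature that aggregation-removal is a
  non-equilibrium process.  Its shape is approximately
  ``Y(tau) ~ exp(-k tau) * [1 - exp(-k tau)]``, with a maximum at
  ``tau = ln(2)/k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .rate_equations import KernelSpec, StationaryDistribution

__all__ = [
    "TrajectoryConfig",
    "Trajectory",
    "CorrelationFunction",
    "jump_rates",
    "simulate_trajectory",
    "simulate_ensemble",
    "autocorrelation",
    "time_reversal_moment",
    "analytic_forms",
    "fit_decay_rate",
    "fit_y_shape",
    "simulate_birth_death",
]


@dataclass(frozen=True)
class TrajectoryConfig:
    """Configuration of a tagged-cluster jump-process simulation.

    ``background`` provides the ambient concentrations c_m (same units as
    the kernel rates); the tagged cluster does not deplete it.
    """

    background: StationaryDistribution
    k: float
    kernel: KernelSpec
    n0: int
    t_max: float
    record_dt: float
    seed: int

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError(f"initial size n0 must be >= 1, got {self.n0!r}")
        if not self.record_dt > 0:
            raise ValueError("record_dt must be positive")
        if not self.k >= 0:
            raise ValueError("removal rate k must be nonnegative")


@dataclass
class Trajectory:
    """Sampled size time series of one tagged cluster."""

    times: np.ndarray
    sizes: np.ndarray
    end_reason: str = "t_max"  # "t_max" | "evaporated"
    metadata: dict[str, Any] = field(default_factory=dict)


@dataclass
class CorrelationFunction:
    """Correlation statistic on a lag grid, with a jackknife standard error."""

    lags: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    n_trajectories: int


def jump_rates(n: int, cfg: TrajectoryConfig) -> tuple[np.ndarray, float]:
    """Event rates for the tagged cluster at size n.

    Returns (gain_rates, loss_rate): ``gain_rates[m-1] = K(n, m+...) * c_m``
    for each ambient size m, and the single-particle loss rate ``k * n``.
    """
    if n < 1:
        raise ValueError("cluster size must be >= 1")
    c = cfg.background.c
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("background concentrations must be finite and nonnegative")
    m = np.arange(1, len(c) + 1, dtype=float)
    gains = cfg.kernel.B * (float(n) ** -cfg.kernel.sigma + m ** -cfg.kernel.sigma) * c
    return gains, cfg.k * n


def simulate_trajectory(cfg: TrajectoryConfig) -> Trajectory:
    """Exact (Gillespie) simulation of one tagged-cluster trajectory.

    The size is recorded on the uniform ``record_dt`` grid.  The trajectory
    terminates at ``t_max`` or when the cluster evaporates (size 0).
    Deterministic given the seed.

    The gain rates split as ``B*n**-sigma * c_m + B * m**-sigma * c_m``, so
    the partner size is drawn from a two-component mixture of fixed
    distributions; only the mixture weights depend on n.
    """
    rng = np.random.default_rng(cfg.seed)
    c = cfg.background.c
    m = np.arange(1, len(c) + 1, dtype=float)
    M0 = float(np.sum(c))  # weight of the n**-sigma * c_m component
    S = float(np.sum(m ** -cfg.kernel.sigma * c))
    cdf_c = np.cumsum(c) / M0 if M0 > 0 else None
    w = m ** -cfg.kernel.sigma * c
    cdf_w = np.cumsum(w) / S if S > 0 else None
    B, sigma, k = cfg.kernel.B, cfg.kernel.sigma, cfg.k

    n_rec = int(np.floor(cfg.t_max / cfg.record_dt)) + 1
    times = np.arange(n_rec) * cfg.record_dt
    sizes = np.zeros(n_rec, dtype=np.int64)

    t = 0.0
    n = int(cfg.n0)
    i_rec = 0
    end_reason = "t_max"
    while True:
        g_n = B * float(n) ** -sigma * M0
        g_m = B * S
        loss = k * n
        total = g_n + g_m + loss
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        t_next = t + dt
        # fill records up to the event time with the current size
        while i_rec < n_rec and times[i_rec] <= t_next:
            sizes[i_rec] = n
            i_rec += 1
        if i_rec >= n_rec or t_next >= cfg.t_max:
            break
        t = t_next
        u = rng.random() * total
        if u < loss:
            n -= 1
            if n == 0:
                end_reason = "evaporated"
                break
        elif u < loss + g_n:
            n += int(np.searchsorted(cdf_c, rng.random())) + 1
        else:
            n += int(np.searchsorted(cdf_w, rng.random())) + 1
    return Trajectory(times=times[:i_rec], sizes=sizes[:i_rec], end_reason=end_reason)


def simulate_ensemble(cfg: TrajectoryConfig, n_traj: int) -> list[Trajectory]:
    """Independent tagged-cluster trajectories with per-trajectory seeds."""
    out = []
    ss = np.random.SeedSequence(cfg.seed)
    for child in ss.spawn(n_traj):
        seed = int(child.generate_state(1)[0] % (2**31))
        out.append(simulate_trajectory(
            TrajectoryConfig(
                background=cfg.background, k=cfg.k, kernel=cfg.kernel,
                n0=cfg.n0, t_max=cfg.t_max, record_dt=cfg.record_dt, seed=seed,
            )
        ))
    return out


def _pooled_moments(
    trajs: Sequence[Trajectory] | Sequence[np.ndarray],
    lags: np.ndarray,
    record_dt: float,
    burn_in: float,
    kind: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-trajectory lagged moments averaged over the ensemble.

    kind "C2": <x_{t+j} x_t> - mu^2 with the pooled mean mu.
    kind "Y":  <x_{t+j} x_t^2> - <x_{t+j}^2 x_t>.
    """
    j_lags = np.rint(np.asarray(lags) / record_dt).astype(int)
    series = []
    for tr in trajs:
        x = tr.sizes if isinstance(tr, Trajectory) else np.asarray(tr)
        i0 = int(np.ceil(burn_in / record_dt))
        x = np.asarray(x[i0:], dtype=float)
        if len(x) > j_lags.max():
            series.append(x)
    if not series:
        raise ValueError("no trajectory segment is longer than the largest lag")
    if kind == "C2":
        mu = np.mean(np.concatenate(series))
    per_traj = np.empty((len(series), len(j_lags)))
    for s_i, x in enumerate(series):
        for l_i, j in enumerate(j_lags):
            a, b = x[: len(x) - j or None], x[j:]
            if kind == "C2":
                per_traj[s_i, l_i] = np.mean((a - mu) * (b - mu))
            else:
                per_traj[s_i, l_i] = np.mean(b * a**2 - b**2 * a)
    values = per_traj.mean(axis=0)
    stderr = per_traj.std(axis=0, ddof=1) / np.sqrt(len(series)) if len(series) > 1 \
        else np.full(len(j_lags), np.nan)
    return values, stderr, len(series)


def autocorrelation(
    trajs: Sequence[Trajectory],
    lags: np.ndarray,
    record_dt: float,
    burn_in: float = 0.0,
) -> CorrelationFunction:
    """Size autocorrelation C2(tau) pooled over stationary trajectory segments.

    The pooled mean over all segments (after discarding ``burn_in``) is used,
    so C2(0) estimates the stationary variance of n.
    """
    values, stderr, n_used = _pooled_moments(trajs, lags, record_dt, burn_in, "C2")
    return CorrelationFunction(
        lags=np.asarray(lags, dtype=float), values=values, stderr=stderr,
        n_trajectories=n_used,
    )


def time_reversal_moment(
    trajs: Sequence[Trajectory],
    lags: np.ndarray,
    record_dt: float,
    burn_in: float = 0.0,
) -> CorrelationFunction:
    """Third-moment asymmetry Y(tau) = <n(t+tau) n(t)^2> - <n(t+tau)^2 n(t)>.

    Y(0) = 0 exactly by construction; Y == 0 for all tau under detailed
    balance, so a non-zero Y certifies broken time-reversal symmetry.
    """
    values, stderr, n_used = _pooled_moments(trajs, lags, record_dt, burn_in, "Y")
    return CorrelationFunction(
        lags=np.asarray(lags, dtype=float), values=values, stderr=stderr,
        n_trajectories=n_used,
    )


def analytic_forms(k: float, lags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale-free model shapes: C2 ~ exp(-k tau), Y ~ exp(-k tau)(1 - exp(-k tau)).

    The Y shape peaks at tau = ln(2)/k.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    tau = np.asarray(lags, dtype=float)
    e = np.exp(-k * tau)
    return e, e * (1.0 - e)


def fit_decay_rate(corr: CorrelationFunction) -> float:
    """Decay rate of an exponential fit A*exp(-r*tau) to C2(tau)."""
    tau, y = corr.lags, corr.values
    mask = y > 0
    if mask.sum() < 3:
        raise ValueError("too few positive correlation values to fit a decay")
    # crude initial rate from the first e-folding
    y0 = y[0]
    below = np.nonzero(y < y0 / np.e)[0]
    r0 = 1.0 / tau[below[0]] if len(below) and tau[below[0]] > 0 else 1.0 / tau[mask][-1]
    popt, _ = curve_fit(
        lambda t, A, r: A * np.exp(-r * t), tau[mask], y[mask],
        p0=(y0, r0), maxfev=10000,
    )
    return float(popt[1])


def fit_y_shape(corr: CorrelationFunction) -> tuple[float, float]:
    """Fit A*exp(-r tau)(1-exp(-r tau)) to Y(tau); returns (r, argmax = ln2/r)."""
    tau, y = corr.lags, corr.values
    i_peak = int(np.argmax(y))
    if not y[i_peak] > 0:
        raise ValueError("Y(tau) has no positive peak to fit")
    r0 = np.log(2.0) / tau[i_peak] if tau[i_peak] > 0 else 1.0
    popt, _ = curve_fit(
        lambda t, A, r: A * np.exp(-r * t) * (1.0 - np.exp(-r * t)), tau, y,
        p0=(4.0 * y[i_peak], r0), maxfev=10000,
    )
    r = float(popt[1])
    return r, float(np.log(2.0) / r)


def simulate_birth_death(
    birth: float,
    death_per_unit: float,
    n0: int,
    t_max: float,
    record_dt: float,
    seed: int,
) -> Trajectory:
    """Reversible birth-death control process (M/M/infinity queue).

    Constant birth rate and per-unit death rate; its stationary law is
    Poisson(birth/death_per_unit) and it obeys detailed balance, so
    Y(tau) == 0 up to estimator noise.  Used as the equilibrium control
    against which the aggregation-removal asymmetry is judged.
    """
    rng = np.random.default_rng(seed)
    n_rec = int(np.floor(t_max / record_dt)) + 1
    times = np.arange(n_rec) * record_dt
    sizes = np.zeros(n_rec, dtype=np.int64)
    t, n, i_rec = 0.0, int(n0), 0
    while True:
        total = birth + death_per_unit * n
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        t_next = t + dt
        while i_rec < n_rec and times[i_rec] <= t_next:
            sizes[i_rec] = n
            i_rec += 1
        if i_rec >= n_rec or t_next >= t_max:
            break
        t = t_next
        if rng.random() * total < birth:
            n += 1
        else:
            n -= 1
    return Trajectory(times=times[:i_rec], sizes=sizes[:i_rec])
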
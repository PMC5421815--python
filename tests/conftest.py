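import numpy as np
import pytest

import aggscaff as ag


@pytest.fixture(scope="session")
def reference_params() -> ag.PhysicalParams:
    """Literature parameter estimates for gephyrin/GlyR at inhibitory synapses:
    D0 = 0.02 um^2/s, k = 1/(30 min), c0 = 4/3 um^-2, rho = 5000/3 um^-2."""
    return ag.PhysicalParams(D0=0.02, k=1.0 / 1800.0, c0=4.0 / 3.0, rho=5000.0 / 3.0)


@pytest.fixture(scope="session")
def recovery_grid() -> ag.FitGrid:
    """Fit grid containing the synthetic ground truth (sigma = 0.5, k/D0 = 1/30)."""
    return ag.FitGrid(
        k_over_D0=np.array([1.0 / 60.0, 1.0 / 30.0, 1.0 / 15.0, 2.0 / 15.0]),
        sigma=np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
        c0=np.geomspace(0.5, 8.0, 5),
    )


@pytest.fixture(scope="session")
def model_table(recovery_grid) -> ag.ModelTable:
    """Predicted concentrations over the recovery grid, shared across tests
    (stationary solves dominate the fit cost)."""
    return ag.ModelTable(recovery_grid, i_max=256)


@pytest.fixture(scope="session")
def meq_ensemble():
    """Tagged-cluster MEQ ensemble at the reference simulation conditions
    (k = 2e-5*D0*rho, c0 = 0.9e-3*rho, rho = 0.77/a^2, sigma = 0.5), 2000
    trajectories of length 30/k recorded every 0.05/k."""
    k = 2.0e-5 * 0.77
    c0 = 0.9e-3 * 0.77
    spec = ag.KernelSpec(B=1.0, sigma=0.5)
    bg = ag.stationary_distribution(ag.RateParams(k=k, c0=c0, kernel=spec))
    cfg = ag.TrajectoryConfig(
        background=bg, k=k, kernel=spec, n0=10,
        t_max=30.0 / k, record_dt=0.05 / k, seed=0,
    )
    trajs = ag.simulate_ensemble(cfg, 2000)
    return {"trajs": trajs, "k": k, "cfg": cfg, "background": bg}
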
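import numpy as np
import pytest

from rhizostate import core
from rhizostate.synthetic import SyntheticConfig, make_synthetic_study


@pytest.fixture(scope="session")
def tiny_study():
    """One-year, 2-scanner, 2-image synthetic study (T = 36)."""
    return make_synthetic_study(
        SyntheticConfig(years=1, S=2, C=2, seed=5, missingness_rate=0.1))


@pytest.fixture(scope="session")
def tiny_forcing(tiny_study):
    return tiny_study.forcing


@pytest.fixture(scope="session")
def micro_instance():
    """T = 6 hand-checkable instance for oracle comparisons."""
    periods = [(2011, 1, "early"), (2011, 1, "mid"), (2011, 1, "late"),
               (2011, 2, "early"), (2011, 2, "mid"), (2011, 2, "late")]
    forcing = core.EnvForcingSeries(
        periods=periods,
        st=np.array([2.0, 5.0, 8.0, 12.0, 6.0, 3.0]),
        sm=np.array([20.0, 25.0, 18.0, 30.0, 22.0, 19.0]),
        v=np.array([10.0, 10.0, 11.0, 10.0, 10.0, 8.0]),
    )
    rng = np.random.default_rng(11)
    scalars = core.ScalarParams(b1=1.2, gamma=0.004, beta_base=2e-4,
                                stmin=4.0, sigma_le=0.4, sigma_st=0.1,
                                sigma_sm=0.01)
    le = -7.0 + np.cumsum(rng.normal(0, 0.3, 6))
    bst = 1.0 + np.cumsum(rng.normal(0, 0.05, 6))
    bsm = 0.02 + np.cumsum(rng.normal(0, 0.005, 6))
    traj = core.biomass_trajectory(scalars.b1, le, bst, bsm, forcing, scalars)
    T, S, C = 6, 2, 2
    lam_t = rng.uniform(500, 2000, T)
    lam_s = rng.uniform(500, 2000, (T, S))
    # arbitrary positive values near the latent means: the oracle comparison
    # needs valid inputs, not distributionally faithful ones
    ps = traj.p[:, None] * rng.uniform(0.5, 2.0, (T, S))
    disp = core.DispersionParams(lambda_t=lam_t, lambda_s=lam_s, ps=ps)
    F = ps[:, :, None] * rng.uniform(0.5, 2.0, (T, S, C))
    tt, ss, cc = np.meshgrid(np.arange(T), np.arange(S), np.arange(C),
                             indexing="ij")
    keep = np.ones(T * S * C, bool)
    keep[[3, 17]] = False  # two missing records
    obs = core.ProductionObservations(t=tt.ravel()[keep], s=ss.ravel()[keep],
                                      c=cc.ravel()[keep],
                                      value=F.ravel()[keep], S=S, C=C)
    return forcing, scalars, traj, disp, obs
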
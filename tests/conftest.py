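import numpy as np
import pytest

from btc_cea import load_model_config, run_psa
from btc_cea.params import WeibullParams

# published Weibull parameters, (strategy, endpoint) -> (lam, gamma)
TABLE1 = {
    ("XELOX", "pfs"): WeibullParams(0.201, 0.690),
    ("GEMOX", "pfs"): WeibullParams(0.199, 0.739),
    ("XELOX", "os"): WeibullParams(0.068, 0.958),
    ("GEMOX", "os"): WeibullParams(0.038, 1.260),
}


@pytest.fixture(scope="session")
def default_config():
    return load_model_config()


@pytest.fixture(scope="session")
def psa_samples(default_config):
    """One shared 1,000-draw PSA run (fixed seed) for CEAC-based tests."""
    return run_psa(default_config, n_iter=1000, seed=20220722)


def microsim_occupancy(config, strategy, n_patients, seed):
    """Individual-level simulation oracle for the cohort trace.

    Each simulated patient gets one uniform draw U; progression and death
    times follow by inverse-transform from the PFS and OS curves (comonotone
    coupling, so a patient can never progress after dying).  State occupancy
    at each cycle boundary is the fraction of patients progression-free,
    progressed, or dead at that time.
    """
    rng = np.random.default_rng(seed)
    curves = config.survival(strategy)
    u = rng.uniform(size=n_patients)
    t_pfs = (-np.log(u) / curves.pfs.lam) ** (1.0 / curves.pfs.gamma)
    t_os = (-np.log(u) / curves.os.lam) ** (1.0 / curves.os.gamma)
    t_prog = np.minimum(t_pfs, t_os)  # progression cannot postdate death
    t = np.arange(0, config.econ.horizon_cycles + 1, dtype=float)
    grid = t[:, None]
    pfs = np.mean(grid < t_prog[None, :], axis=1)
    dead = np.mean(grid >= t_os[None, :], axis=1)
    return pfs, 1.0 - pfs - dead, dead
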
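import numpy as np
import pytest

from flagrd.params import NondimParams
from flagrd.stability import critical_activity
from flagrd.solver import simulate_rd


#: the (mu, eta, zeta, fstar) point used for the linear-theory comparisons
FIG_POINT = dict(mu=100.0, eta=0.14, zeta=0.3, fstar=2.0)


@pytest.fixture(scope="session")
def fig_point():
    crit = critical_activity(**FIG_POINT)
    return {**FIG_POINT, "mu_a_crit": crit}


@pytest.fixture(scope="session")
def mbo2ish_run():
    """A supercritical limit-cycle run in the mbo2-like regime (fast path)."""
    p = NondimParams(mu_a=500.0, mu=10.0, eta=0.34, zeta=0.9, fstar=2.0)
    return simulate_rd(p, t_end=100.0, method="semi", dt_out=0.02)


@pytest.fixture(scope="session")
def recovery_study():
    """Seeded parameter-recovery study: 10 noisy synthetic targets fitted
    on a reduced 80-candidate grid around the generating point.

    Candidate simulations are shared across seeds through a mode cache.
    Returns (per-seed error array in grid steps, list of fit results).
    """
    from flagrd.fitting import SlidingControlBeat, parameter_grid
    from flagrd.synthetic import SyntheticSpec, generate_synthetic_experiment

    gen = (1200.0, 0.10, 0.9)
    steps = (100.0, 0.04, 0.1)
    grid = parameter_grid(
        np.arange(1000.0, 1401.0, 100.0),
        np.array([0.06, 0.10, 0.14, 0.18]),
        np.array([0.7, 0.8, 0.9, 1.0]),
    )
    cache = {}
    errors = []
    results = []
    for seed in range(10):
        spec = SyntheticSpec(
            params=NondimParams(mu_a=gen[0], mu=10.0, eta=gen[1], zeta=gen[2], fstar=2.0),
            noise_sigma=0.02, seed=seed)
        record, _ = generate_synthetic_experiment(spec)
        model = SlidingControlBeat(record, mu=10.0)
        res = model.fit(grid=grid, mode_cache=cache)
        p = res.params
        errors.append([abs(p["mu_a"] - gen[0]) / steps[0],
                       abs(p["eta"] - gen[1]) / steps[1],
                       abs(p["zeta"] - gen[2]) / steps[2]])
        results.append(res)
    return np.asarray(errors), results
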
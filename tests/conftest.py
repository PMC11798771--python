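import numpy as np
import pandas as pd
import pytest

import spataft as sp


def plain_dataset(time, event, *, household=None, state=None,
                  metric=None, factors=None, frame_extra=None):
    """Minimal SurvivalDataset from raw arrays (single cluster default)."""
    time = np.asarray(time, dtype=float)
    n = len(time)
    frame = pd.DataFrame({
        "time": time,
        "event": np.asarray(event, dtype=int),
        "household_id": np.zeros(n, dtype=int) if household is None
        else np.asarray(household),
        "state_id": np.full(n, "0") if state is None
        else np.asarray(state, dtype=object),
        "region_id": np.ones(n, dtype=int),
    })
    metric_cols = {}
    if metric:
        for name, vals in metric.items():
            frame[name] = np.asarray(vals, dtype=float)
            metric_cols[name] = vals
    factor_schema = {}
    if factors:
        for name, (levels, vals) in factors.items():
            frame[name] = np.asarray(vals, dtype=object)
            factor_schema[name] = tuple(levels)
    if frame_extra:
        for name, vals in frame_extra.items():
            frame[name] = vals
    return sp.SurvivalDataset(frame, metric=tuple(metric or ()),
                              factors=factor_schema)


TWO_FACTORS = {
    "x1": sp.FactorSpec(("a", "b"), (0.5, 0.5), (0.3,)),
    "x2": sp.FactorSpec(("c", "d"), (0.6, 0.4), (-0.5,)),
}


def small_sim_config(seed=0, n_subjects=600, n_households=60,
                     rows=4, cols=4, **kwargs):
    """Compact two-covariate simulation used across the suite."""
    defaults = dict(
        n_subjects=n_subjects, n_households=n_households,
        graph=sp.make_lattice_graph(rows, cols), intercept=2.9, shape=2.0,
        tau_u=4.0, tau_s=2.0, metric={}, factors=dict(TWO_FACTORS),
        region=None, seed=seed)
    defaults.update(kwargs)
    return sp.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def sim_small():
    cfg = small_sim_config(seed=7)
    dataset, truth = sp.simulate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    """One moderately long fit of the full model, shared by summaries."""
    cfg, dataset, truth = sim_small
    samples = sp.run_mcmc(
        dataset, sp.ModelSpec(), cfg.graph,
        sp.SamplerSettings(iterations=1500, burnin=700, seed=3))
    return cfg, dataset, truth, samples
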
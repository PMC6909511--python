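import numpy as np
import pytest

import septraj as st


def healthy_record(admission_id="A", day=1, **overrides):
    """A fully healthy patient-day; override fields to fire criteria."""
    from septraj.simulate import _healthy_record_kwargs

    kw = _healthy_record_kwargs(admission_id, day)
    kw.update(crp=50.0, wbc=9.0, temperature=37.0, resp_rate=16.0, heart_rate=80.0)
    kw.update(overrides)
    return st.PatientDayRecord(**kw)


@pytest.fixture(scope="session")
def small_sims():
    cfg = st.SimulationConfig(n_admissions=150, seed=42)
    return st.simulate_trajectories(cfg)


@pytest.fixture(scope="session")
def small_panels(small_sims):
    return st.panels_from_latent(small_sims)


@pytest.fixture(scope="session")
def medium_panels():
    cfg = st.SimulationConfig(n_admissions=800, seed=7)
    return st.panels_from_latent(st.simulate_trajectories(cfg))


@pytest.fixture(scope="session")
def nocov_fit():
    """Covariate-free fit on a medium simulated cohort (shared: slow)."""
    truth = st.default_true_model(covariate_names=())
    cfg = st.SimulationConfig(
        n_admissions=1000, seed=11, true_model=truth, missingness_rate=0.0
    )
    panels = st.panels_from_latent(st.simulate_trajectories(cfg))
    return truth, panels, st.fit(panels, epochs=(1, 3, 7))


def rng(seed=0):
    return np.random.default_rng(seed)
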
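import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

import switchddm as sw  # noqa: E402


@pytest.fixture(scope="session")
def tiny_config():
    """One pre, two training, one post block of 120 trials."""
    return sw.SessionConfig(n_pre_blocks=1, n_training_blocks=2,
                            n_post_blocks=1, trials_per_block=120)


@pytest.fixture(scope="session")
def endpoint_grid(tiny_config):
    """Study-endpoint parameters on the tiny design, no dispersion."""
    return sw.GenerativeGrid.from_endpoints(config=tiny_config)


@pytest.fixture(scope="session")
def small_session(tiny_config, endpoint_grid):
    st = sw.build_session_structure(tiny_config)
    return sw.simulate_session(st, endpoint_grid, "s1", seed=123,
                               config=tiny_config)


@pytest.fixture(scope="session")
def two_condition_cohort():
    """16 subjects in two feedback conditions sharing one generative
    grid (a null condition contrast)."""
    cfg = sw.SessionConfig(n_pre_blocks=1, n_training_blocks=3,
                           n_post_blocks=1, trials_per_block=60)
    grid = sw.GenerativeGrid.from_endpoints(
        config=cfg, dispersion={"v": 0.3, "a": 0.3, "t0": 0.05})
    st = sw.build_session_structure(cfg)
    st = st[st["block_phase"] == "training"].reset_index(drop=True)
    tables = []
    for i, ss in enumerate(np.random.SeedSequence([2024, 5]).spawn(16)):
        rng = np.random.default_rng(ss)
        cond = "NFB" if i < 8 else "AFB"
        cfg_i = sw.SessionConfig(**{**cfg.__dict__, "condition": cond,
                                    "coin_value_cents": None})
        tables.append(sw.simulate_session(st, grid.draw_subject(rng),
                                          f"s{i:02d}", rng, config=cfg_i))
    return pd.concat(tables, ignore_index=True)
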
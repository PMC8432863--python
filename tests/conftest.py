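import numpy as np
import pytest
from hypothesis import settings

import camtraptime as ct

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

TWO_PI = 2.0 * np.pi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180901)


@pytest.fixture(scope="session")
def guild():
    """A default independent three-species guild, simulated once per session."""
    cfg = ct.default_guild_config(seed=7)
    records, deployments, ledger = ct.simulate_guild(cfg)
    events = ct.deduplicate(records)
    return {
        "config": cfg,
        "records": records,
        "deployments": deployments,
        "ledger": ledger,
        "events": events,
    }


@pytest.fixture(scope="session")
def following_guild():
    """Guild with lion injected to follow leopard at a ~30 min lag."""
    inter = ct.InteractionSpec(
        "leopard", "lion", mode="following", p_effect=0.5,
        lag_mean_hours=0.5, lag_sd_hours=0.2,
    )
    cfg = ct.default_guild_config(seed=11, interactions=(inter,))
    records, deployments, ledger = ct.simulate_guild(cfg)
    events = ct.deduplicate(records)
    return {
        "config": cfg,
        "records": records,
        "deployments": deployments,
        "ledger": ledger,
        "events": events,
    }
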
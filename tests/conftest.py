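import logging

import pandas as pd
import pytest

from targetrank.simulate import SimulationConfig

logging.disable(logging.INFO)


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """Small, fast simulation used by smoke-level tests."""
    return SimulationConfig(n_proteins=40, n_targets=2, seed=123)


@pytest.fixture
def noise_free_config() -> SimulationConfig:
    """All noise sources and effects switched off."""
    return SimulationConfig(
        n_proteins=12,
        n_targets=3,
        seed=5,
        target_delta_tm=0.0,
        target_log2fc=0.0,
        target_delta_ox=0.0,
        tm_jitter_sd=0.0,
        tpp_channel_sd=0.0,
        abundance_sd=0.0,
        ox_noise_kappa=0.0,
        background_log2fc_sd=0.0,
    )


def make_fits(records) -> pd.DataFrame:
    """Melting-fit table from (protein, condition, replicate, tm) tuples."""
    rows = [
        {
            "protein_id": pid,
            "condition": cond,
            "replicate": rep,
            "a": 550.0,
            "b": 10.0,
            "plateau": 0.0,
            "tm": tm,
            "r_squared": 0.99,
            "converged": tm == tm,  # NaN means unconverged
        }
        for pid, cond, rep, tm in records
    ]
    return pd.DataFrame(rows)
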
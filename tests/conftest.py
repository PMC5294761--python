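import numpy as np
import pandas as pd
import pytest

from credset import ABFConfig, SimConfig, finemap_signals, simulate_signals

#: prior effect variance used with z-scale input (V = 1): prior z-SD 5,
#: matching the synthetic design's causal z-score mean of 5.
Z_SCALE_W = 25.0


@pytest.fixture(scope="session")
def z_abf_config() -> ABFConfig:
    return ABFConfig(W=Z_SCALE_W)


def make_posterior_frame(log_abfs, signal_ids=None, variant_ids=None) -> pd.DataFrame:
    """Hand-built posterior table for enrichment-model unit tests."""
    log_abfs = np.asarray(log_abfs, dtype=float)
    n = len(log_abfs)
    return pd.DataFrame(
        {
            "variant_id": variant_ids or [f"v{i}" for i in range(n)],
            "signal_id": signal_ids or ["s0"] * n,
            "log_abf": log_abfs,
        }
    )


@pytest.fixture(scope="session")
def small_study(z_abf_config):
    """80 simulated signals with one true ln(4)-enriched annotation."""
    cfg = SimConfig(n_signals=80, seed=11)
    stats, annotations, truth = simulate_signals(cfg)
    posteriors, credsets = finemap_signals(stats, z_abf_config)
    return cfg, stats, annotations, truth, posteriors, credsets
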
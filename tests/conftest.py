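import numpy as np
import pandas as pd
import pytest

from vnseeg import SynthConfig, generate_trial_tensor


@pytest.fixture(scope="session")
def balanced_labels():
    """2 x 2 labels, 30 trials per cell, blocked in canonical order."""
    return pd.DataFrame(
        {
            "frequency_level": np.repeat(["low", "low", "high", "high"], 30),
            "amplitude_level": np.tile(np.repeat(["low", "high"], 30), 2),
        }
    )


@pytest.fixture(scope="session")
def null_tensor():
    """Pure-noise z-scale tensor, 8 electrodes x 1500 samples x 120 trials."""
    cfg = SynthConfig(
        n_channels=8,
        n_trials_per_condition=30,
        seed=7,
        effect_sizes={c: (0.0, 0.0) for c in
                      [("low", "low"), ("low", "high"),
                       ("high", "low"), ("high", "high")]},
    )
    tensor, truth = generate_trial_tensor(cfg)
    return tensor


@pytest.fixture(scope="session")
def effect_tensor():
    """Tensor with the default planted condition-dependent shifts."""
    cfg = SynthConfig(n_channels=8, n_trials_per_condition=30, seed=11)
    return generate_trial_tensor(cfg)
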
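import numpy as np
import pandas as pd
import pytest

from nanotess import SmlmSimConfig


def make_table(rows):
    """Localization table from (frame, x, y) tuples."""
    return pd.DataFrame(rows, columns=["frame", "x", "y"])


@pytest.fixture
def sparse_config():
    """Sparse, low-noise acquisition: molecules far apart relative to ω."""
    return SmlmSimConfig(field_size=10.0, background_density=0.5,
                         domain_density=0.0, fraction_in_domains=0.0,
                         loc_precision_sigma=1.0, n_frames=20_000,
                         blink_continue_prob=0.3, mean_on_frames=3.0,
                         mean_off_frames=5.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
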
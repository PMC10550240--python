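import numpy as np
import pytest

from secgate import ChannelSpec, CohortSpec, gen_cn_channel, gen_secretin_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    return gen_secretin_cohort(CohortSpec(n_sequences=20, seed=11))


@pytest.fixture
def c15_channel():
    """C15 channel with the default planted gate (radius 7 Å) and one
    bridge-compatible / one negative residue."""
    return gen_cn_channel(
        ChannelSpec(
            n_chains=15,
            barrel_radius=40.0,
            gate_radius=7.0,
            planted_pair_positions=[5],
            planted_negative_positions=[20],
            seed=7,
        )
    )
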
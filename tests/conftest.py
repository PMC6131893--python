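import pytest

from ferrovol import ForwardModelParams


@pytest.fixture
def mc_params() -> ForwardModelParams:
    """Forward-model defaults at reduced Monte Carlo size for fast tests."""
    return ForwardModelParams(n_reps=2000, seed=20260919)
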
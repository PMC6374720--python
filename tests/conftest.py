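import pytest

from hybridiag import Config, CrossDesign, simulate_cross_dataset


@pytest.fixture
def cfg() -> Config:
    return Config()

@pytest.fixture
def small_cross():
    """A small error-free cross with every specimen class present."""
    design = CrossDesign(
        n_parent_a=8, n_parent_b=8, n_f1=6, n_bc1a=6, n_bc1b=6, n_f2=6,
        n_auto_diag=24, n_xlinked_diag=6, n_nondiag=10, seed=42,
    )
    return simulate_cross_dataset(design)
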
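"""Shared fixtures: phantom datasets generated once per session."""

import pytest

from nervelocate import phantom as ph


@pytest.fixture(scope="session")
def noiseless_dataset() -> ph.PhantomDataset:
    """Full 12 x 4 x 5 factorial phantom with every noise source off."""
    cfg = ph.PhantomConfig(noise_scale=0.0, seed=11)
    return ph.generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset_small() -> ph.PhantomDataset:
    """Default-noise phantom at reduced subject count for fast fitting."""
    cfg = ph.PhantomConfig(noise_scale=1.0, n_subjects=4, seed=23)
    return ph.generate_dataset(cfg)
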
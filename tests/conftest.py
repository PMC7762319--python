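import numpy as np
import pytest

import nirtaste as nt
from nirtaste.preprocess import PreprocessConfig


@pytest.fixture(scope="session")
def tiny_bundle():
    """Tiny synthetic bundle (18 samples, 10 channels) with ground truth.

    Preprocessed with absorbance only: on a 10-channel grid the SNV
    statistics are signal-dominated and the window-5 median spans half the
    spectrum, so the enumeration-scale oracle fixture skips both.
    """
    ds, chem, truth = nt.simulate_dataset(nt.tiny_config(0))
    pre = nt.preprocess(ds, PreprocessConfig(apply_snv=False, median_window=1))
    return ds, pre, chem, truth


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic bundle: 3x50 samples on the full 751-channel grid."""
    ds, chem, truth = nt.simulate_dataset(nt.SyntheticConfig(seed=0))
    pre = nt.preprocess(ds)
    return ds, pre, chem, truth


selection_split = nt.selection_split
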
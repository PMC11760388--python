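import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ecgcl import model as M
from ecgcl.synthetic import SyntheticRecordSpec, make_synthetic_dataset, synthesize_record

FS = 128.0


@pytest.fixture(scope="session")
def clean_normal_record():
    return synthesize_record(
        SyntheticRecordSpec(rhythm_class="non-AF", noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def clean_af_record():
    return synthesize_record(
        SyntheticRecordSpec(rhythm_class="AF", noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """64 labelled + 32 unlabelled pairs, balanced."""
    return make_synthetic_dataset(64, 32, af_fraction=0.5, seed=5)


@pytest.fixture(scope="session")
def tiny_encoder_cfg():
    """Small encoder for fast forward/backward tests (T0 = 3840, T = 60)."""
    return M.EncoderConfig(channel_plan=(2, 2, 4, 4, 4, 4), hidden_dim=4,
                           encoder_dim=8)
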
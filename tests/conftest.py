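import numpy as np
import pytest

from sleepssm.data import zscore_recordings
from sleepssm.synthetic import GeneratorConfig, synth_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic study conditions: 10 subjects × 200
    epochs with the Sleep-EDF-20 class mix, seed 42, z-scored."""
    recs = synth_dataset(
        GeneratorConfig(n_subjects=10, epochs_per_subject=200, seed=42))
    return zscore_recordings(recs)


@pytest.fixture(scope="session")
def default_arrays(default_dataset):
    xs, ys, groups = [], [], []
    for i, rec in enumerate(default_dataset):
        x, y = rec.to_arrays()
        xs.append(x)
        ys.append(y)
        groups.append(np.full(len(y), i))
    return (np.concatenate(xs), np.concatenate(ys), np.concatenate(groups))
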
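import pandas as pd
import pytest

import apquant as aq


def make_dataset(seed, **config_kwargs):
    truth = aq.generate_ground_truth(seed=seed)
    fasta = aq.generate_sequences(truth, seed=seed)
    config = aq.SimulationConfig(seed=seed, **config_kwargs)
    return aq.simulate_pulldown(truth, fasta, config)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Noise-free, dropout-free pulldown: iBAQ must be exactly proportional
    to copy number."""
    return make_dataset(seed=11, noise_sd_log2=0.0, dropout=False)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default measurement model (log2 noise 0.2, mild MNAR dropout)."""
    return make_dataset(seed=11)


@pytest.fixture(scope="session")
def noise_free_ibaq(noise_free_dataset):
    ds = noise_free_dataset
    return aq.compute_ibaq_table(ds.protein_groups, ds.fasta, ds.design)


@pytest.fixture()
def small_design():
    return aq.SampleDesign(
        groups={"a1": "a", "a2": "a", "a3": "a", "b1": "b", "b2": "b", "b3": "b"},
        treatment="a",
        control="b",
    )


def make_matrix(values, design, index=None):
    frame = pd.DataFrame(values, columns=list(design.groups), index=index)
    return aq.LogIntensityMatrix(values=frame.astype(float), design=design)
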
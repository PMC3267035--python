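import pytest

from dualroute import build_model, generate_dataset
from dualroute.generative_model import build_lead_field, default_geometry


@pytest.fixture(scope="session")
def cs_model():
    return build_model("CS")


@pytest.fixture(scope="session")
def c_model():
    return build_model("C")


@pytest.fixture(scope="session")
def small_cs_dataset():
    """4 synthetic subjects from the dual-route ground truth (default noise)."""
    return generate_dataset("CS", n_subjects=4, seed=11)


@pytest.fixture(scope="session")
def small_cs_leadfield(small_cs_dataset, cs_model):
    dataset, _ = small_cs_dataset
    geom = default_geometry(
        cs_model.labels, n_channels=len(dataset.channel_labels)
    )
    return build_lead_field(geom, rng_seed=dataset.provenance["seed"])


def window_times(dataset, T):
    """Times of the [0, T] window on the dataset grid."""
    mask = (dataset.times_ms >= 0) & (dataset.times_ms <= T + 1e-9)
    return dataset.times_ms[mask]
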
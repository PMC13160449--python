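import numpy as np
import pytest

from hypermatch import ModalityMatrix, SyntheticSpec, generate_multimodal


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pair():
    """Tiny two-modality dataset with ground truth, fast enough for unit tests."""
    spec = SyntheticSpec(
        n_types=3, proportions=(0.5, 0.3, 0.2), nx=80, ny=100,
        latent_dim=6, px=50, py=40, p_link=15,
        linkage_strength=0.9, noise_sd=0.3, seed=7,
    )
    return generate_multimodal(spec)


def make_modality(values, prefix="f", cell_prefix="c", labels=None, tag="test"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ModalityMatrix(
        values,
        np.array([f"{prefix}{j}" for j in range(p)], object),
        np.array([f"{cell_prefix}{i}" for i in range(n)], object),
        None if labels is None else np.asarray(labels, object),
        tag,
    )
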
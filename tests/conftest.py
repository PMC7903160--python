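import numpy as np
import pytest

from unlearn.io import MultiSiteDataset, Sample
from unlearn.synthetic import StudyDesign, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """3 sites x 20 phantoms at 16x16: enough structure for contract tests."""
    design = StudyDesign(n_sites=3, per_site_n=[20, 20, 20], size=16, seed=7)
    return generate_dataset(design)


@pytest.fixture
def two_site_dataset():
    design = StudyDesign(n_sites=2, per_site_n=[25, 15], size=16, seed=3)
    return generate_dataset(design)


def make_flat_dataset(n_per_domain, n_domains=2, rng=None, image_shape=(8, 8)):
    """Dataset of pure-noise images with arbitrary labels, for plumbing tests."""
    rng = rng or np.random.default_rng(0)
    samples = []
    for d in range(1, n_domains + 1):
        for j in range(n_per_domain):
            samples.append(Sample(
                image=rng.normal(size=image_shape),
                domain_label=d,
                main_label=float(rng.uniform(20, 90)),
                confound_labels={"sex": int(rng.integers(2))},
            ))
    return MultiSiteDataset(samples)
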
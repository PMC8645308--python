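import numpy as np
import pytest

from texturality.pyramid import PyramidConfig
from texturality.ps_statistics import compute_ps_statistics
from texturality.stimuli import dataset_records, render_record
from texturality.summary_features import FrequencyMap, summarize


@pytest.fixture
def default_config():
    return PyramidConfig()


@pytest.fixture
def small_config():
    return PyramidConfig(image_size=128)


@pytest.fixture
def fmap():
    return FrequencyMap()


@pytest.fixture
def noise_image():
    return np.random.default_rng(42).standard_normal((256, 256))


def features_for_images(images, config=None, fmap_=None):
    config = config or PyramidConfig()
    fmap_ = fmap_ or FrequencyMap(
        image_size=config.image_size, n_scales=config.n_scales
    )
    vecs = [summarize(compute_ps_statistics(img, config), fmap_) for img in images]
    return np.array([v.as_array() for v in vecs]), vecs[0].labels


@pytest.fixture(scope="session")
def dataset_features():
    """Summary features of make_dataset(100/class, master seed 1).

    Shared by the screening-recovery and end-to-end classification tests;
    computing ~200 feature vectors takes on the order of a minute, so this is
    session-scoped.
    Returns (ids, X, labels, y).
    """
    records = dataset_records(100, 1)
    config = PyramidConfig()
    fm = FrequencyMap()
    ids, rows, y = [], [], []
    for rec in records:
        img = render_record(rec)
        rows.append(summarize(compute_ps_statistics(img, config), fm))
        ids.append(rec["id"])
        y.append(rec["label"])
    X = np.array([v.as_array() for v in rows])
    return ids, X, rows[0].labels, np.array(y)
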
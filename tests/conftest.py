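import numpy as np
import pytest

from betadisc.cluster_detect import Cluster, ClusterDictionary
from betadisc.frames import Frame, FrameRole


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cluster(patch, mask=None, label="beta", bbox=None):
    patch = np.asarray(patch, dtype=float)
    if mask is None:
        mask = patch > 0
    if bbox is None:
        bbox = (0, 0, patch.shape[0], patch.shape[1])
    return Cluster(patch=patch, mask=np.asarray(mask, bool), bbox=bbox, label=label)


def make_dictionary(clusters, label):
    return ClusterDictionary(clusters=list(clusters), label=label)


@pytest.fixture
def tiny_corrected():
    """5x5 corrected frame with an L-shaped 3-pixel event and a lone pixel."""
    px = np.zeros((5, 5))
    px[1, 1], px[2, 1], px[2, 2] = 3.0, 5.0, 7.0  # L-shape
    px[4, 4] = 12.0  # isolated single pixel
    return Frame(px, FrameRole.CORRECTED)
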
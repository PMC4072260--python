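import numpy as np
import pytest

import fibroquant as fq
from fibroquant.stain_deconvolution import StainMatrix


@pytest.fixture(scope="session")
def stain_model():
    return fq.default_stain_model()


@pytest.fixture(scope="session")
def stain_matrix(stain_model):
    return StainMatrix(stain_model.od_vectors)


@pytest.fixture(scope="session")
def phantom30():
    """256x256 phantom with 30% fibrosis of tissue."""
    return fq.generate_phantom(256, 256, 0.30, seed=7)


@pytest.fixture(scope="session")
def tile30(phantom30, stain_model):
    """Noiseless rendering of the 30%-fibrosis phantom."""
    return fq.render_trichrome(phantom30, stain_model, noise_sd=0.0, seed=1)


def make_label_tile(label_value, shape=(32, 32)):
    """A phantom whose every pixel is one class (bypasses the generator)."""
    lm = np.full(shape, int(label_value), dtype=np.uint8)
    return fq.TissuePhantom(lm)
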
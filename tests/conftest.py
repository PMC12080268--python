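import numpy as np
import pytest

from evotherm.potts import PottsModel


def random_model(rng, L=6, q=5, coupling_scale=0.3, alphabet=None):
    """Random symmetric Potts model (gapless focus = per-site argmax)."""
    if alphabet is None:
        alphabet = "-" + "ACDEFGHIKLMNPQRSTVWY"[: q - 1]
    h = rng.normal(size=(L, q))
    J = rng.normal(size=(L, L, q, q)) * coupling_scale
    J = 0.5 * (J + J.transpose(1, 0, 3, 2))
    for i in range(L):
        J[i, i] = 0.0
    focus = (np.argmax(h[:, 1:], axis=1) + 1).astype(np.int8)
    return PottsModel(h=h, J=J, alphabet=alphabet, focus_seq=focus)


def brute_force_energy(model, sigma):
    """Independent triple-loop statistical energy (test oracle)."""
    e = 0.0
    for i in range(model.L):
        e += model.h[i, sigma[i]]
        for j in range(i + 1, model.L):
            e += model.J[i, j, sigma[i], sigma[j]]
    return e


@pytest.fixture(scope="session")
def table_potts_model():
    from evotherm.fixtures import table_model

    return table_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
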
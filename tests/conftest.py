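import warnings

import numpy as np
import pytest

import suturemorph as sm

warnings.filterwarnings("ignore", message="paired width is defined")


@pytest.fixture(scope="session")
def synth_cfg():
    return sm.SyntheticConfig(seed=11, n_subjects=8)


@pytest.fixture(scope="session")
def population(synth_cfg):
    return sm.generate_population(synth_cfg)


@pytest.fixture(scope="session")
def noiseless_population():
    cfg = sm.SyntheticConfig(seed=7, n_subjects=10, noise_sd=0.0)
    return sm.generate_population(cfg)


@pytest.fixture(scope="session")
def subject(population):
    return population.subjects[0]


@pytest.fixture(scope="session")
def semilandmarks(subject):
    return sm.assemble_semilandmarks(subject.curves)


@pytest.fixture(scope="session")
def partition(semilandmarks):
    return sm.partition_sutures(semilandmarks)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
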
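import numpy as np
import pytest

from profgen.lstm import init_params
from profgen.teacher import TeacherConfig, make_teacher, sample_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_params(rng):
    """Hand-sized model: embedding dim 2, hidden size 3."""
    return init_params(embed_dim=2, hidden_size=3, rng=rng)


@pytest.fixture
def small_params(rng):
    return init_params(embed_dim=4, hidden_size=8, rng=rng)


@pytest.fixture
def random_profile(rng):
    def _make(n, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        m = r.dirichlet(np.ones(20), size=n)
        from profgen.types import ProfileMatrix

        return ProfileMatrix(m, source="teacher")

    return _make


@pytest.fixture(scope="session")
def toy_dataset():
    """Short-context teacher pairs shared by training-behaviour tests."""
    teacher = make_teacher(TeacherConfig(context_k=1, length_range=(30, 50), seed=7))
    rng = np.random.default_rng(8)
    return sample_dataset(teacher, 120, rng)
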
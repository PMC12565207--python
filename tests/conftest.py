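import dataclasses
import pytest

from lesionseg.io import normalize_volume
from lesionseg.phantom import PhantomConfig, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    """A 48^3 phantom configuration: fast, holds several lesions and patches."""
    return PhantomConfig(shape=(48, 48, 48), seed=0)


@pytest.fixture(scope="session")
def phantom_subject(small_phantom_config):
    return generate_subject(small_phantom_config)


@pytest.fixture(scope="session")
def normalized_subjects(small_phantom_config):
    """Eight normalized phantom subjects (seeds 0-7) shared by training tests."""
    subjects = []
    for i in range(8):
        s = generate_subject(dataclasses.replace(small_phantom_config, seed=i))
        subjects.append((normalize_volume(s.volume), s.mask))
    return subjects


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A 3-subject phantom cohort written to disk in the subject layout."""
    out = tmp_path_factory.mktemp("cohort")
    config = PhantomConfig(shape=(32, 32, 32), seed=7)
    records = generate_cohort(3, config, out)
    return out, records


def numeric_gradient(fn, arr, indices, eps=1e-5):
    """Central finite differences of scalar ``fn`` at selected flat indices."""
    grads = {}
    flat = arr.reshape(-1)
    for idx in indices:
        orig = flat[idx]
        flat[idx] = orig + eps
        hi = fn()
        flat[idx] = orig - eps
        lo = fn()
        flat[idx] = orig
        grads[idx] = (hi - lo) / (2 * eps)
    return grads
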
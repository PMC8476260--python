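import numpy as np
import pytest

from multiatlas import CohortSpec, PhantomSpec, make_cohort, make_phantom
from multiatlas.image_io import LabelMap, Volume


def make_volume(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> Volume:
    return Volume(np.asarray(arr, dtype=float), np.asarray(spacing), np.asarray(origin))


def make_label(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> LabelMap:
    return LabelMap(np.asarray(arr), np.asarray(spacing), np.asarray(origin))


@pytest.fixture(scope="session")
def phantom_default():
    """The default 64³ @ 0.5 mm skull-base phantom (shared, read-only)."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Default-size phantom cohort on disk: 20 atlases + 10 test cases."""
    out = tmp_path_factory.mktemp("cohort")
    make_cohort(CohortSpec(), PhantomSpec(), out)
    return out


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 4-atlas / 1-test cohort for fast pipeline plumbing tests."""
    out = tmp_path_factory.mktemp("small_cohort")
    make_cohort(CohortSpec(n_atlases=4, n_tests=1), PhantomSpec(), out)
    return out
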
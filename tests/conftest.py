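import numpy as np
import pytest

from glioradiomics import PhantomSpec, generate_cohort
from glioradiomics.features import extract_cohort_features

#: Reduced geometry for fast unit tests: same nested-shell structure, a
#: quarter of the default volume.
SMALL_SPEC_KWARGS = dict(
    grid_shape=(36, 36, 24),
    semi_axes=((3.5, 3.0, 2.5), (6.0, 5.0, 4.0), (9.0, 8.0, 6.0), (12.5, 11.0, 8.5)),
    n_subjects=3,
)


def make_small_spec(**overrides) -> PhantomSpec:
    kwargs = {**SMALL_SPEC_KWARGS, **overrides}
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(make_small_spec(seed=5))


@pytest.fixture(scope="session")
def cohort_features_sep1():
    """Feature table of the full-scale study cohort (23 subjects, separation 1)."""
    spec = PhantomSpec(separation=1.0, seed=0)
    return extract_cohort_features(generate_cohort(spec))


@pytest.fixture(scope="session")
def cohort_features_sep0():
    """Feature table of the null cohort (separation 0: identical profiles)."""
    spec = PhantomSpec(separation=0.0, seed=0)
    return extract_cohort_features(generate_cohort(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
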
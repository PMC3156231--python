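import numpy as np
import pytest

from nrpred.descriptors import load_property_scales
from nrpred.fknn import ReferenceSet
from nrpred.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def scales():
    return load_property_scales()


@pytest.fixture(scope="session")
def fixture_records():
    """Default synthetic 8-class family collection (7 motifs + background)."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def separable_reference():
    """7 well-separated Gaussian clusters, 20 points each: between-class
    distance far exceeds within-class spread."""
    rng = np.random.default_rng(7)
    X, labels = [], []
    for c in range(7):
        center = np.zeros(7)
        center[c] = 10.0
        X.append(center + 0.1 * rng.standard_normal((20, 7)))
        labels += [f"C{c}"] * 20
    return ReferenceSet(np.vstack(X), labels)
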
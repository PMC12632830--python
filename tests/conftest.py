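import numpy as np
import pytest

from cytogeom.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture
def toy():
    """Default four-chain toy complex (A/B receptors, C/D binders)."""
    return make_toy_complex()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_toy_spec(rng: np.random.Generator, **overrides) -> ToyComplexSpec:
    """A randomised but non-degenerate toy-complex geometry."""
    ca = rng.uniform(-20, 20, 3) + np.array([-25.0, 0.0, 35.0])
    cb = rng.uniform(-20, 20, 3) + np.array([25.0, 0.0, 35.0])
    # anchors well below the centroids, laterally separated
    aa = ca + np.array([rng.uniform(-4, 4), rng.uniform(-4, 4), rng.uniform(-30, -18)])
    ab = cb + np.array([rng.uniform(-4, 4), rng.uniform(-4, 4), rng.uniform(-30, -18)])
    kwargs = dict(
        receptor_a_centroid=tuple(ca),
        receptor_b_centroid=tuple(cb),
        anchor_a=tuple(aa),
        anchor_b=tuple(ab),
        seed=int(rng.integers(2**31)),
    )
    kwargs.update(overrides)
    return ToyComplexSpec(**kwargs)
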
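import numpy as np
import pytest

import foveate as fv


@pytest.fixture(scope="session")
def glyph_data():
    """Default-condition glyph suite, split 80/20 (800 train / 200 test)."""
    spec = fv.GlyphDatasetSpec(n_per_class=100, seed=1)
    images, labels = fv.generate_glyphs(spec)
    return fv.split_dataset(images, labels, seed=2)


@pytest.fixture(scope="session")
def bank(glyph_data):
    tr_x, tr_y, _, _ = glyph_data
    return fv.fit_model_bank(list(tr_x), tr_y)


@pytest.fixture(scope="session")
def test_pyramids(glyph_data):
    _, _, te_x, te_y = glyph_data
    return [fv.haar_decompose(x) for x in te_x], te_y


@pytest.fixture(scope="session")
def toy_worlds():
    rng = np.random.default_rng(11)
    return [
        fv.generate_toy_world(fv.ToyWorldSpec(seed=int(rng.integers(2**31))))
        for _ in range(20)
    ]


def make_context(world, rng, with_history=True):
    """A consistent MetricContext from one enumerated toy-world transition."""
    u_prev = int(rng.integers(world.n_actions))
    x_prev = int(rng.integers(world.n_symbols))
    u = int(rng.integers(world.n_actions))
    x = int(rng.integers(world.n_symbols))
    q_prev2 = fv.Belief(world.prior)
    ll_last = world.loglik(x_prev, u_prev)
    post = np.exp(ll_last) * world.prior
    q_prev = fv.Belief(post / post.sum())
    return fv.MetricContext.from_loglik(
        q_prev,
        world.loglik(x, u),
        q_prev2 if with_history else None,
        ll_last if with_history else None,
    )
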
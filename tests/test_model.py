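"""The interaction CNN: shapes, forward contract, gradients, constraints."""

import numpy as np
import pytest

from neurixn.model import (
    InteractionDecoder,
    ModelConfig,
    build_model,
    count_parameters,
    extract_spatial_filters,
    forward,
    interaction_stage,
    set_spatial_filters,
)
from neurixn.training import Adam


@pytest.fixture(scope="module")
def model320():
    m = build_model(ModelConfig(), window_len=320, seed=0)
    # readout starts at zero; randomize so outputs depend on the input
    m.params["W6"] = np.random.default_rng(0).normal(
        0, 0.3, size=m.params["W6"].shape
    ).astype(m.dtype)
    return m


class TestArchitectureShapes:
    def test_stage_shapes_for_5s_window(self, model320, rng):
        x = rng.normal(size=(2, 30, 320))
        probs, cache = model320.forward(x, train=False, return_cache=True)
        assert cache["shapes"]["z1"] == (2, 4, 30, 320)  # 4 temporal maps of 30 x T
        assert cache["shapes"]["u"] == (2, 4, 10, 320)  # one signal per region
        assert cache["shapes"]["v"] == (2, 4, 45, 320)  # 45 interaction channels
        assert probs.shape == (2, 2)

    def test_post_pooling_rate_is_16_hz(self):
        assert ModelConfig().pooled_fs == 16.0

    def test_wrong_channel_count_rejected(self, model320, rng):
        with pytest.raises(ValueError):
            model320.forward(rng.normal(size=(2, 29, 320)))

    def test_wrong_window_length_rejected(self, model320, rng):
        with pytest.raises(ValueError):
            model320.forward(rng.normal(size=(2, 30, 256)))


class TestForward:
    def test_rows_are_probability_vectors(self, model320, rng):
        probs = forward(model320, rng.normal(size=(7, 30, 320)))
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_inputs_identical_outputs(self, model320):
        x = np.zeros((2, 30, 320))
        probs = forward(model320, x)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_per_sample_independence(self, model320, rng):
        x = rng.normal(size=(3, 30, 320))
        batch = np.concatenate([x, x[1:2]])
        probs = forward(model320, batch)
        np.testing.assert_allclose(probs[1], probs[3], atol=1e-6)


class TestInteractionStage:
    def test_all_ones_gives_all_ones(self, pair_index):
        out = interaction_stage(np.ones((10, 16)), pair_index)
        np.testing.assert_array_equal(out, np.ones((45, 16)))

    def test_constant_rows_match_pairwise_products(self, pair_index, rng):
        from neurixn.data_model import REGION_ORDER

        c = rng.normal(size=10)
        out = interaction_stage(np.tile(c[:, None], (1, 8)), pair_index)
        pos = {code: i for i, code in enumerate(REGION_ORDER)}
        for k, (a, b) in enumerate(pair_index.pairs):
            assert out[k, 0] == pytest.approx(c[pos[a]] * c[pos[b]])

    def test_output_has_45_rows(self, pair_index, rng):
        assert interaction_stage(rng.normal(size=(10, 32)), pair_index).shape == (45, 32)

    def test_symmetric_in_pair_orientation(self, pair_index, rng):
        x = rng.normal(size=(10, 32))
        out = interaction_stage(x, pair_index)
        for k, (a, b) in enumerate(pair_index.pairs):
            assert pair_index.index_of(b, a) == k
            np.testing.assert_array_equal(out[pair_index.index_of(b, a)], out[k])

    def test_wrong_row_count_rejected(self, pair_index, rng):
        with pytest.raises(ValueError):
            interaction_stage(rng.normal(size=(9, 32)), pair_index)


class TestSpatialFilters:
    def test_shape_and_alignment(self, model320):
        sf = extract_spatial_filters(model320)
        assert sf.filters.shape == (4, 45)
        assert len(sf.pair_index) == 45

    def test_round_trip_bit_identical(self, model320, rng):
        new = rng.normal(size=(4, 45)).astype(model320.dtype)
        set_spatial_filters(model320, new)
        np.testing.assert_array_equal(extract_spatial_filters(model320).filters, new)

    def test_maxnorm_projection_bounds_rows(self, rng):
        m = build_model(ModelConfig(), window_len=64, seed=3)
        opt = Adam(m.params, lr=0.05)
        x = rng.normal(size=(8, 30, 64)).astype(np.float32)
        y = np.array([0, 1] * 4)
        g = np.random.default_rng(0)
        for _ in range(5):
            _, grads = m.loss_and_grads(x, y, g)
            opt.step(m.params, grads)
            m.project_maxnorm()
            norms = np.linalg.norm(m.params["W4"], axis=1)
            assert np.all(norms <= m.config.maxnorm + 1e-6)


class TestParameterCount:
    def test_stage1_closed_form(self, model320):
        assert model320.params["W1"].size == 4 * 31 == 124

    def test_doubling_maps_doubles_stage1(self):
        m8 = build_model(
            ModelConfig(n_temporal_maps=8, n_spatial_filters=8), window_len=320
        )
        assert m8.params["W1"].size == 2 * 4 * 31

    def test_total_matches_tensor_enumeration(self, model320):
        total = sum(v.size for v in model320.params.values())
        assert count_parameters(model320) == total == 1848


class TestGradients:
    def test_backprop_matches_numerical_gradients(self):
        """Hand-written backward pass against central finite differences."""
        m = build_model(ModelConfig(), window_len=64, seed=2, dtype=np.float64)
        r = np.random.default_rng(3)
        # readout defaults to zeros; randomize so gradients reach every layer
        m.params["W6"] = r.normal(0, 0.3, size=m.params["W6"].shape)
        x = r.normal(size=(4, 30, 64))
        y = np.array([0, 1, 1, 0])
        _, grads = m.loss_and_grads(x, y, np.random.default_rng(42))
        eps = 1e-6
        sel = np.random.default_rng(7)
        for name, param in m.params.items():
            flat = param.ravel()
            for i in sel.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = m.loss_and_grads(x, y, np.random.default_rng(42))[0]
                flat[i] = orig - eps
                lm = m.loss_and_grads(x, y, np.random.default_rng(42))[0]
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[i]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), name

    def test_loss_decreases_on_separable_toy_batch(self, rng):
        m = build_model(ModelConfig(), window_len=64, seed=1)
        x = rng.normal(size=(16, 30, 64)).astype(np.float32)
        x[:8, 3] *= 4.0  # class-0 windows get a loud LP channel
        y = np.array([0] * 8 + [1] * 8)
        opt = Adam(m.params, lr=3e-3)
        g = np.random.default_rng(0)
        first = m.loss_and_grads(x, y, g)[0]
        for _ in range(60):
            loss, grads = m.loss_and_grads(x, y, g)
            opt.step(m.params, grads)
            m.project_maxnorm()
        assert loss < first
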
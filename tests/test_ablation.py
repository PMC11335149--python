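"""Kernel knockouts and input-band manipulations of trained decoders."""

import numpy as np
import pytest

from neurixn.ablation import (
    ABLATION_BANDS,
    AblationMask,
    WrongMaskKindError,
    ablate_baseline,
    ablation_report,
    apply_kernel_mask,
    band_filter_inputs,
    cluster_mask,
    hemisphere_mask,
    region_mask,
)
from neurixn.data_model import WindowSample
from neurixn.gedb import InvalidBandError
from neurixn.model import ModelConfig, build_model
from neurixn.training import BaselineModel


@pytest.fixture(scope="module")
def model():
    m = build_model(ModelConfig(), window_len=320, seed=4)
    # the readout starts at zero; give it weights so logits depend on inputs
    m.params["W6"] = np.random.default_rng(4).normal(
        0, 0.3, size=m.params["W6"].shape
    ).astype(m.dtype)
    return m


def _windows(rng, n=6, T=320):
    return [
        WindowSample(
            data=rng.normal(size=(30, T)),
            label="left" if i % 2 == 0 else "right",
            trial_id=i,
            block_id=0,
        )
        for i in range(n)
    ]


class TestMaskGeometry:
    def test_region_mask_has_17_indices(self, pair_index):
        for lobe in ("occipital", "parietal", "temporal", "central", "frontal"):
            assert len(region_mask(lobe, pair_index).zeroed_pair_indices) == 17

    def test_region_masks_cover_all_pairs(self, pair_index):
        union = set()
        for lobe in ("occipital", "parietal", "temporal", "central", "frontal"):
            union |= region_mask(lobe, pair_index).zeroed_pair_indices
        assert union == set(range(45))

    def test_hemisphere_mask_counts(self, pair_index):
        left = hemisphere_mask("left", pair_index).zeroed_pair_indices
        right = hemisphere_mask("right", pair_index).zeroed_pair_indices
        assert len(left) == len(right) == 35
        assert left | right == set(range(45))
        assert len(left & right) == 25  # the inter-hemisphere pairs

    def test_cluster_mask_single_dominant_entry(self):
        c = np.zeros(45)
        c[8] = 12.0
        assert cluster_mask(c).zeroed_pair_indices == {8}

    def test_cluster_mask_threshold_one_takes_everything(self, rng):
        c = rng.normal(size=45)
        assert cluster_mask(c, p_threshold=1.0).zeroed_pair_indices == set(range(45))

    def test_unknown_names_rejected(self, pair_index):
        with pytest.raises(ValueError):
            region_mask("insular", pair_index)
        with pytest.raises(ValueError):
            hemisphere_mask("dorsal", pair_index)

    def test_kind_field_validation(self):
        with pytest.raises(WrongMaskKindError):
            AblationMask(kind="region", band=(8.0, 13.0))
        with pytest.raises(WrongMaskKindError):
            AblationMask(kind="band_stop", zeroed_pair_indices=frozenset({1}))


class TestApplyKernelMask:
    def test_empty_mask_is_identity(self, model, rng):
        mask = AblationMask(kind="region", zeroed_pair_indices=frozenset())
        x = rng.normal(size=(3, 30, 320))
        np.testing.assert_array_equal(
            apply_kernel_mask(model, mask).forward(x), model.forward(x)
        )

    def test_full_mask_makes_logits_input_invariant(self, model, rng):
        mask = AblationMask(kind="region", zeroed_pair_indices=frozenset(range(45)))
        ablated = apply_kernel_mask(model, mask)
        p1 = ablated.forward(rng.normal(size=(2, 30, 320)))
        p2 = ablated.forward(rng.normal(size=(2, 30, 320)) * 13.0)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_region_knockout_nullifies_that_regions_input(self, model, pair_index, rng):
        mask = region_mask("parietal", pair_index)
        ablated = apply_kernel_mask(model, mask)
        x = rng.normal(size=(2, 30, 320)).astype(np.float32)
        x2 = x.copy()
        # parietal channels: LP is region 1, RP region 6 (region-major layout)
        for r in (1, 6):
            x2[:, 3 * r : 3 * r + 3] = rng.normal(size=(2, 3, 320))
        np.testing.assert_allclose(ablated.forward(x), ablated.forward(x2), atol=1e-6)

    def test_original_model_untouched(self, model, pair_index):
        before = model.params["W4"].copy()
        apply_kernel_mask(model, hemisphere_mask("left", pair_index))
        np.testing.assert_array_equal(model.params["W4"], before)

    def test_idempotent(self, model, pair_index):
        mask = region_mask("occipital", pair_index)
        once = apply_kernel_mask(model, mask)
        twice = apply_kernel_mask(once, mask)
        np.testing.assert_array_equal(once.params["W4"], twice.params["W4"])

    def test_input_kind_mask_rejected(self, model):
        with pytest.raises(WrongMaskKindError):
            apply_kernel_mask(model, AblationMask(kind="band_stop", band=(8.0, 13.0)))


class TestBandFilterInputs:
    def test_stop_removes_band_power(self, rng):
        wins = _windows(rng, n=3)
        stopped = band_filter_inputs(wins, "alpha", mode="stop")
        from neurixn.gedb import bandpass

        for w0, w1 in zip(wins, stopped):
            before = bandpass(w0.data, 8, 13, 64.0).var()
            after = bandpass(w1.data, 8, 13, 64.0).var()
            assert after <= 0.05 * before
            assert w1.data.shape == w0.data.shape

    def test_pass_keeps_in_band_sinusoid(self):
        t = np.arange(320) / 64.0
        data = np.tile(np.sin(2 * np.pi * 10 * t), (30, 1))
        w = WindowSample(data=data, label="left", trial_id=0, block_id=0)
        passed = band_filter_inputs([w], "alpha", mode="pass")[0]
        assert passed.data.var() >= 0.8 * data.var()

    def test_degenerate_band_rejected(self, rng):
        with pytest.raises(InvalidBandError):
            band_filter_inputs(_windows(rng, 1), (13.0, 8.0), mode="stop")


class TestAblationReport:
    def test_original_row_has_zero_delta(self, model, pair_index, rng):
        wins = _windows(rng, n=8)
        table = ablation_report(
            model,
            [("parietal", region_mask("parietal", pair_index)),
             ("alpha_stop", AblationMask(kind="band_stop", band=ABLATION_BANDS["alpha"]))],
            wins,
        )
        orig = table[table.condition == "original"].iloc[0]
        assert orig.delta_accuracy == 0.0
        assert set(table.condition) == {"original", "parietal", "alpha_stop"}
        assert table.accuracy.between(0, 1).all()


class TestBaselineAblation:
    def test_region_zeroing_pattern(self):
        mdl = BaselineModel(weights=np.arange(40.0), intercept=0.0)
        out = ablate_baseline(mdl, region="parietal")
        # LP is region index 1, RP region index 6; 4 bands each
        zeroed = list(range(4, 8)) + list(range(24, 28))
        assert np.all(out.weights[zeroed] == 0)
        kept = [i for i in range(40) if i not in zeroed]
        np.testing.assert_array_equal(out.weights[kept], mdl.weights[kept])

    def test_band_zeroing_pattern(self):
        mdl = BaselineModel(weights=np.ones(40), intercept=0.0)
        out = ablate_baseline(mdl, band="alpha")
        assert np.all(out.weights[2::4] == 0)
        assert out.weights.sum() == 30

    def test_exactly_one_axis_required(self):
        mdl = BaselineModel(weights=np.ones(40), intercept=0.0)
        with pytest.raises(ValueError):
            ablate_baseline(mdl)
        with pytest.raises(ValueError):
            ablate_baseline(mdl, region="parietal", band="alpha")
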
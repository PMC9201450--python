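"""Backbone geometry: receptive field, stride, locality, layout validation."""

import numpy as np
import pytest

from patchvote._tensor import Tensor, no_grad
from patchvote.backbone import (BackboneConfig, ImageSample, build_backbone,
                                empirical_receptive_field, extract_features,
                                receptive_field)


def compose_rf(layers):
    """Independent hand application of the composition rule (oracle)."""
    rf, j = 1, 1
    for k, s in layers:
        rf += (k - 1) * j
        j *= s
    return rf, j


class TestAnalyticReceptiveField:
    def test_canonical_restricted_layout_gives_39_and_stride_16(self):
        assert receptive_field(BackboneConfig()) == (39, 16)

    def test_width_scaling_preserves_geometry(self):
        cfg = BackboneConfig(width_scale=0.25, cardinality=8)
        assert receptive_field(cfg) == (39, 16)
        assert cfg.out_channels == 512

    def test_unrestricted_layout_expands_receptive_field(self):
        rf, stride = receptive_field(BackboneConfig(restricted=False))
        assert stride == 16
        assert rf > 39

    def test_matches_hand_composition_on_simple_stacks(self):
        # 7x7/2 stem alone, then stem + one 3x3/1
        assert compose_rf([(7, 2)]) == (7, 2)
        assert compose_rf([(7, 2), (3, 1)]) == (11, 2)
        assert compose_rf([(1, 1)]) == (1, 1)  # pointwise layer

    def test_layer_sequence_agrees_with_oracle(self):
        for cfg in (BackboneConfig(), BackboneConfig(restricted=False),
                    BackboneConfig(stage_block_counts=(1, 1, 1, 1), cardinality=8,
                                   width_scale=0.25)):
            assert receptive_field(cfg) == compose_rf(cfg.layer_sequence())


class TestEmpiricalFootprint:
    def test_probe_agrees_with_analytic_value(self, small_extractor):
        assert empirical_receptive_field(small_extractor) == 39

    def test_probe_on_shallow_variant(self):
        cfg = BackboneConfig(stage_block_counts=(1, 1, 1, 1), cardinality=8,
                             width_scale=0.25)
        ex = build_backbone(cfg, np.random.default_rng(3))
        assert empirical_receptive_field(ex) == receptive_field(cfg)[0]

    def test_locality_outside_window(self, small_extractor):
        """Zeroing pixels outside one cell's rf window leaves it unchanged."""
        rng = np.random.default_rng(11)
        size = 112
        x = rng.uniform(0.2, 1.0, (1, 1, size, size))
        small_extractor.eval()
        cell = 3  # interior cell of the 7x7 grid
        # locate the cell's input window with a gradient probe
        xt = Tensor(x.copy(), requires_grad=True)
        y = small_extractor(xt)
        g = np.zeros_like(y.data)
        g[0, :, cell, cell] = 1.0
        y.backward(g)
        footprint = np.abs(xt.grad[0, 0]) > 0
        rows = np.flatnonzero(footprint.any(axis=1))
        cols = np.flatnonzero(footprint.any(axis=0))
        assert rows[-1] - rows[0] + 1 <= 39
        with no_grad():
            full = small_extractor(Tensor(x)).data
        masked = np.zeros_like(x)
        sl = np.s_[:, :, rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        masked[sl] = x[sl]
        with no_grad():
            part = small_extractor(Tensor(masked)).data
        np.testing.assert_allclose(part[0, :, cell, cell],
                                   full[0, :, cell, cell], atol=1e-8)


class TestFeatureGridGeometry:
    @pytest.mark.parametrize("size", [64, 96])
    def test_grid_is_input_over_16(self, small_extractor, size, rng):
        sample = ImageSample(rng.uniform(size=(size, size)), [0])
        grid = extract_features(small_extractor, sample)
        assert grid.values.shape == (size // 16, size // 16, 512)
        assert grid.stride == 16 and grid.rf == 39

    def test_doubling_height_doubles_grid_height(self, small_extractor, rng):
        a = extract_features(small_extractor,
                             ImageSample(rng.uniform(size=(64, 64)), [0]))
        b = extract_features(small_extractor,
                             ImageSample(rng.uniform(size=(128, 64)), [0]))
        assert b.values.shape[0] == 2 * a.values.shape[0]
        assert b.values.shape[1] == a.values.shape[1]

    def test_non_divisible_dims_raise_naming_axis(self):
        with pytest.raises(ValueError, match="width"):
            ImageSample(np.zeros((64, 100)), [0])
        with pytest.raises(ValueError, match="height"):
            ImageSample(np.zeros((100, 64)), [0])

    def test_deterministic_given_weights(self, small_extractor, rng):
        sample = ImageSample(rng.uniform(size=(64, 64)), [0])
        g1 = extract_features(small_extractor, sample)
        g2 = extract_features(small_extractor, sample)
        np.testing.assert_array_equal(g1.values, g2.values)


class TestConfigValidation:
    def test_cardinality_must_divide_grouped_width(self):
        with pytest.raises(ValueError, match="cardinality"):
            BackboneConfig(width_scale=0.125)  # grouped width 16 < 32 groups

    def test_width_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            BackboneConfig(width_scale=0.0)

    def test_label_mask_consistency_enforced(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10, 10] = True
        with pytest.raises(ValueError, match="mask"):
            ImageSample(np.zeros((64, 64)), [0], mask=mask)
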
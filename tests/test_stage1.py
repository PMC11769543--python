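"""Stage one: organ net structure, VOI extraction, crop/paste geometry."""

import numpy as np
import pytest

from renalseg.grids import LabelMask, Voi, crop, paste
from renalseg.stage1 import (
    CnnOrganNet,
    OrganNetConfig,
    SwinOrganNet,
    build_organ_net,
    expand_box,
    extract_vois,
    segment_kidney,
    sliding_window_predict,
)


@pytest.fixture(scope="module")
def small_swin():
    cfg = OrganNetConfig(encoder_steps=4, transformer_blocks_per_step=2,
                         window_input_size=16, base_channels=4, window_size=2,
                         num_heads=2, backend="swin", seed=1)
    return build_organ_net(cfg)


class TestOrganNet:
    def test_default_swin_structure(self, small_swin):
        rows = small_swin.describe()
        assert len(rows) == 4
        assert all(r["transformer_blocks"] == 2 for r in rows)
        assert [r["channels"] for r in rows] == [4, 8, 16, 32]

    def test_forward_shape_and_sigmoid_range(self, small_swin, rng):
        x = rng.standard_normal((1, 16, 16, 16)).astype(np.float32)
        y = small_swin(x)
        assert y.shape == (1, 16, 16, 16)
        assert 0.0 < y.min() and y.max() < 1.0

    def test_forward_deterministic(self, small_swin, rng):
        x = rng.standard_normal((1, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(small_swin(x), small_swin(x))

    def test_window_size_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            OrganNetConfig(window_input_size=100, encoder_steps=4)

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            build_organ_net(OrganNetConfig(backend="mystery"))

    def test_cnn_fallback_builds_and_runs(self, rng):
        net = build_organ_net(OrganNetConfig(backend="cnn", seed=2))
        x = rng.standard_normal((1, 32, 32, 32)).astype(np.float32)
        y = net(x)
        assert y.shape == (1, 32, 32, 32)

    def test_swin_gradcheck(self):
        from renalseg.nn import dice_ce_loss
        cfg = OrganNetConfig(encoder_steps=2, transformer_blocks_per_step=2,
                             window_input_size=8, base_channels=4, window_size=2,
                             num_heads=2, backend="swin", seed=5, dtype="float64")
        net = build_organ_net(cfg)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 8, 8, 8))
        t = (rng.random((8, 8, 8)) > 0.5).astype(float)
        net.zero_grad()
        p = net(x, train=True)
        _, g = dice_ce_loss(p[0], t, return_grad=True)
        gx = net.backward(g[None])
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (0, 3, 5, 2)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = (dice_ce_loss(net(xp)[0], t) - dice_ce_loss(net(xm)[0], t)) / (2 * eps)
            assert gx[idx] == pytest.approx(num, rel=1e-3, abs=1e-8)


class TestSegmentKidney:
    def _constant_net(self, value):
        class Fixed:
            def __call__(self, x, train=False):
                return np.full_like(x, value)
        return Fixed()

    def test_saturated_negative_head_gives_empty_mask(self, desk_case, rng):
        _, vol, _ = desk_case
        net = build_organ_net(OrganNetConfig(backend="cnn", seed=3))
        net.head.bias.data[...] = -50.0  # sigmoid saturates to ~0
        mask = segment_kidney(vol, net, (64, 64, 64))
        assert mask.data.sum() == 0

    def test_threshold_one_gives_empty_mask(self, desk_case):
        _, vol, _ = desk_case
        mask = segment_kidney(vol, self._constant_net(0.999), (32, 32, 32),
                              threshold=1.0)
        assert mask.data.sum() == 0

    def test_small_volume_padded_and_cropped_back(self, rng):
        from renalseg.grids import CtVolume
        vol = CtVolume(data=rng.normal(size=(20, 20, 20)).astype(np.float32),
                       spacing=(1, 1, 1))
        mask = segment_kidney(vol, self._constant_net(0.9), (32, 32, 32))
        assert mask.data.shape == (20, 20, 20)
        assert np.all(mask.data == 1)

    def test_blending_weights_cover_whole_volume(self, rng):
        data = rng.normal(size=(40, 40, 40)).astype(np.float32)
        prob = sliding_window_predict(data, self._constant_net(0.7), (32, 32, 32))
        np.testing.assert_allclose(prob, 0.7, atol=1e-5)


class TestVoiGeometry:
    def test_40_voxel_box_expands_to_50(self):
        voi = expand_box((10, 10, 10), (50, 50, 50), (100, 100, 100), 0.25)
        assert voi.extent == (50, 50, 50)
        assert voi.start == (5, 5, 5)
        assert voi.stop == (55, 55, 55)

    def test_expansion_clipped_at_grid_edge(self):
        voi = expand_box((0, 0, 0), (40, 40, 40), (45, 45, 45), 0.25)
        assert voi.start == (0, 0, 0)  # left margin clipped at 0
        assert voi.stop == (45, 45, 45)  # right margin clipped at the grid edge

    def test_exactly_two_vois_with_noise_blob(self):
        data = np.zeros((60, 60, 30), np.int16)
        data[5:20, 10:25, 5:20] = 1  # kidney 1: 3375 voxels
        data[35:50, 10:25, 5:20] = 1  # kidney 2
        data[28:30, 50:52, 25:27] = 1  # 8-voxel noise blob, below minimum
        mask = LabelMask(data=data, spacing=(1, 1, 1))
        vois = extract_vois(mask, min_component_voxels=50)
        assert len(vois) == 2
        assert all(v.source_extent == (15, 15, 15) for v in vois)
        assert all(v.extent == (19, 19, 19) for v in vois)  # round(15*1.25)

    def test_empty_mask_yields_no_vois(self):
        mask = LabelMask(data=np.zeros((20, 20, 20), np.int16), spacing=(1, 1, 1))
        assert extract_vois(mask) == []

    def test_at_most_two_components_kept(self):
        data = np.zeros((80, 20, 20), np.int16)
        for i, size in enumerate((10, 8, 6)):  # three large components
            data[i * 25:i * 25 + size, 5:5 + size, 5:5 + size] = 1
        mask = LabelMask(data=data, spacing=(1, 1, 1))
        vois = extract_vois(mask, min_component_voxels=50)
        assert len(vois) == 2

    def test_vois_deterministic_given_mask(self, desk_case):
        _, _, mask = desk_case
        kidney = mask.with_data((mask.data >= 1).astype(np.int16))
        a = extract_vois(kidney)
        b = extract_vois(kidney)
        assert [(v.start, v.stop) for v in a] == [(v.start, v.stop) for v in b]

    def test_gt_tumor_voxels_covered_by_expanded_vois(self):
        # the coverage property that justifies the coarse-to-fine design
        from renalseg.phantom import generate_phantom, random_spec
        for seed in range(10):
            gen = np.random.default_rng(seed)
            spec = random_spec(gen, preset="desk", difficulty="easy",
                               exophytic_prob=0.3)
            _, mask = generate_phantom(spec, gen)
            kidney = mask.with_data((mask.data >= 1).astype(np.int16))
            vois = extract_vois(kidney)
            covered = np.zeros(mask.data.shape, bool)
            for v in vois:
                covered[v.slices] = True
            tumor = mask.data == 2
            assert covered[tumor].all(), f"seed {seed}: tumor voxel outside VOIs"

    def test_crop_preserves_interior_tumor_voxels(self, desk_case):
        _, _, mask = desk_case
        kidney = mask.with_data((mask.data >= 1).astype(np.int16))
        vois = extract_vois(kidney)
        n_inside = sum(int((crop(mask, v).data == 2).sum()) for v in vois)
        assert n_inside >= int((mask.data == 2).sum())  # >= handles overlap
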
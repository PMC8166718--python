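"""The 3D-convolution front: shape chain, zero padding, parameter counts."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumenseg.core_models import InstanceSegSpec, ResUNetSpec, build_resunet
from lumenseg.errors import ConfigError, ShapeError
from lumenseg.image_io import BoundaryPolicy, Frame, make_triplets
from lumenseg.temporal_extension import (ExtendedModel, TemporalExtensionSpec,
                                         extend_model, predict_triplet,
                                         temporal_front, triplet_to_input)


def _raw_triplet(p, q, rng=None, fill=None):
    """Triplet stand-in without the Frame size floor, for small-p,q sweeps."""
    if fill is not None:
        frames = [SimpleNamespace(pixels=np.full((p, q, 3), fill, np.float32))
                  for _ in range(3)]
    else:
        frames = [SimpleNamespace(
            pixels=rng.random((p, q, 3)).astype(np.float32)) for _ in range(3)]
    return SimpleNamespace(frames=frames, center_index=1)


class TestSpec:
    def test_r_fixed_at_three(self):
        with pytest.raises(ConfigError):
            TemporalExtensionSpec(n_k=4, r=5)

    def test_kernel_spatial_fixed(self):
        with pytest.raises(ConfigError):
            TemporalExtensionSpec(n_k=4, kernel_spatial=(1, 1))

    def test_nk_positive(self):
        with pytest.raises(ConfigError):
            TemporalExtensionSpec(n_k=0)


class TestTemporalFront:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(p=st.integers(3, 40), q=st.integers(3, 40), n_k=st.integers(1, 8))
    def test_shape_chain(self, p, q, n_k):
        """(r,p,q,n_c) -> (1,p-2,q-2,n_k) -> (p,q,n_k) for any p,q >= 3."""
        rng = np.random.default_rng(p * 1000 + q * 10 + n_k)
        spec = TemporalExtensionSpec(n_k=n_k)
        w = rng.standard_normal((n_k, 3, 3, 3, 3)).astype(np.float32)
        res = temporal_front(_raw_triplet(p, q, rng), spec, w)
        assert res.raw.shape == (1, p - 2, q - 2, n_k)
        assert res.features.shape == (p, q, n_k)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(p=st.integers(3, 30), q=st.integers(3, 30))
    def test_border_ring_exactly_zero(self, p, q):
        rng = np.random.default_rng(p * 100 + q)
        spec = TemporalExtensionSpec(n_k=4)
        w = rng.standard_normal((4, 3, 3, 3, 3)).astype(np.float32)
        feats = temporal_front(_raw_triplet(p, q, rng), spec, w,
                               bias=rng.standard_normal(4)).features
        assert np.all(feats[0] == 0) and np.all(feats[-1] == 0)
        assert np.all(feats[:, 0] == 0) and np.all(feats[:, -1] == 0)

    def test_zero_input_zero_bias_gives_zero(self):
        spec = TemporalExtensionSpec(n_k=2, activation="linear")
        w = np.ones((2, 3, 3, 3, 3), np.float32)
        res = temporal_front(_raw_triplet(10, 10, fill=0.0), spec, w)
        assert np.all(res.raw == 0) and np.all(res.features == 0)

    def test_zero_weights_bias_broadcast(self):
        """All-zero kernels + linear activation: the interior is the bias."""
        spec = TemporalExtensionSpec(n_k=2, activation="linear")
        w = np.zeros((2, 3, 3, 3, 3), np.float32)
        bias = np.array([0.5, -0.25], np.float32)
        res = temporal_front(_raw_triplet(8, 9,
                                          rng=np.random.default_rng(0)),
                             spec, w, bias=bias)
        np.testing.assert_allclose(res.features[1:-1, 1:-1],
                                   np.broadcast_to(bias, (6, 7, 2)))

    def test_too_small_frames_rejected(self):
        spec = TemporalExtensionSpec(n_k=2)
        w = np.zeros((2, 3, 3, 3, 3), np.float32)
        with pytest.raises(ShapeError):
            temporal_front(_raw_triplet(2, 2, fill=0.0), spec, w)

    def test_matches_engine_front_convolution(self, rng):
        """Functional front equals the extended model's conv layer."""
        spec = TemporalExtensionSpec(n_k=4, activation="linear")
        model = extend_model(ResUNetSpec(depth=2, base_filters=8,
                                         input_shape=(16, 16, 3)), spec, seed=3)
        triplet = _raw_triplet(16, 16, rng)
        # engine layout (n_k, r*n_c, 3, 3) -> functional (n_k, r, 3, 3, n_c)
        w = model.front.weight.data.reshape(4, 3, 3, 3, 3).transpose(0, 1, 3, 4, 2)
        res = temporal_front(triplet, spec, w, bias=model.front.bias.data)
        from lumenseg import nn
        x = triplet_to_input(triplet)[None]
        h = model.front(nn.Tensor(x)).data[0]
        np.testing.assert_allclose(res.raw[0], h, atol=1e-5)


class TestExtendModel:
    def test_added_parameter_count(self):
        """n_k kernels of size (r x 3 x 3) over n_c channels plus biases:
        for n_k = 3, n_c = 3 that is 3*(3*3*3*3) + 3 = 246."""
        core_spec = ResUNetSpec(depth=2, base_filters=8, input_shape=(16, 16, 3))
        spec = TemporalExtensionSpec(n_k=3)
        model = extend_model(core_spec, spec, seed=0)
        assert model.front_parameter_count() == 246
        assert model.num_parameters() == (model.core.num_parameters() + 246)

    def test_fixed_channel_core_rejects_other_nk(self):
        ispec = InstanceSegSpec(input_size=16)
        with pytest.raises(ConfigError):
            extend_model(ispec, TemporalExtensionSpec(n_k=5))

    def test_fixed_channel_core_accepts_three(self):
        model = extend_model(InstanceSegSpec(input_size=16),
                             TemporalExtensionSpec(n_k=3))
        assert model.model_tag == "M2"

    def test_resunet_extension_forward(self, rng):
        model = extend_model(ResUNetSpec(depth=2, base_filters=8,
                                         input_shape=(16, 16, 3)),
                             TemporalExtensionSpec(n_k=8), seed=0)
        x = rng.random((2, 16, 16, 9)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (2, 16, 16)
        assert probs.min() > 0 and probs.max() < 1


class TestPredictTriplet:
    @pytest.fixture
    def model(self):
        return extend_model(ResUNetSpec(depth=2, base_filters=8,
                                        input_shape=(16, 16, 3)),
                            TemporalExtensionSpec(n_k=8), seed=0)

    def _triplet(self, rng):
        frames = [Frame(rng.random((16, 16, 3)).astype(np.float32), t=i,
                        video_id="v") for i in range(3)]
        return make_triplets(frames, BoundaryPolicy.DROP_EDGES)[0]

    def test_deterministic(self, model, rng):
        t = self._triplet(rng)
        np.testing.assert_array_equal(predict_triplet(model, t).pixels,
                                      predict_triplet(model, t).pixels)

    def test_map_indexed_by_center(self, model, rng):
        t = self._triplet(rng)
        pm = predict_triplet(model, t)
        assert pm.t == t.center_index == 1
        assert pm.pixels.shape == (16, 16)

    def test_single_frame_model_rejected(self, rng):
        core = build_resunet(ResUNetSpec(depth=2, base_filters=8,
                                         input_shape=(16, 16, 3)))
        with pytest.raises(ShapeError):
            predict_triplet(core, self._triplet(rng))
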
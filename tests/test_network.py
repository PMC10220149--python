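"""Architecture contracts: shapes, parameter counts, gradients, stitching."""

import numpy as np
import pytest

from jetsr.models import (
    MAGNITUDE_SCALE, NetworkSpec, build, count_parameters, predict_volume,
)
from jetsr.nn import Adam, Conv1x1, Conv3d, Module, Upsample3d
from jetsr.nn.blocks import CSPBlock, DenseBlock, ResBlock
from jetsr.nn.layers import upsample_matrix
from jetsr.nn.ops import conv3d_forward, conv3d_forward_numpy


def tiny_spec(variant="res", **kw):
    kw.setdefault("channels", 4)
    kw.setdefault("lr_blocks", 2)
    kw.setdefault("hr_blocks", 1)
    kw.setdefault("growth_rate", 2)
    kw.setdefault("head_depth", 1)
    return NetworkSpec(variant=variant, **kw)


class TestShapes:
    @pytest.mark.parametrize("variant", ["res", "dense", "csp"])
    def test_twelve_cube_in_fortyeight_cube_out(self, variant, rng):
        model = build(tiny_spec(variant))
        x = rng.normal(size=(2, 6, 12, 12, 12)).astype(np.float32)
        y = model.forward(x)
        assert y.shape == (2, 3, 48, 48, 48)
        assert np.isfinite(y).all()

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(in_patch=12, out_patch=24, upsample_factor=4)
        with pytest.raises(ValueError):
            NetworkSpec(variant="transformer")


class TestParameterCounts:
    def test_single_conv_layer_count(self, rng):
        conv = Conv3d(64, 64, rng)
        assert sum(p.size for p in conv.params()) == 27 * 64 * 64 + 64

    def test_res_variant_closed_form(self):
        # independent arithmetic: branches + 1x1 merge + 12 res blocks +
        # upsample conv + three 2-conv heads at 64 channels
        C = 64
        conv = lambda ci, co: 27 * ci * co + co
        expected = (
            2 * (conv(3, C) + conv(C, C))      # velocity + magnitude branches
            + (2 * C * C + C)                  # 1x1 merge
            + 12 * 2 * conv(C, C)              # 8 LR + 4 HR res blocks
            + conv(C, C)                       # post-upsample conv
            + 3 * (conv(C, C) + conv(C, 1))    # output heads
        )
        model = build(NetworkSpec(variant="res"))
        assert count_parameters(model) == expected == 3_343_619

    def test_res_reported_as_3_34_million(self):
        n = count_parameters(build(NetworkSpec(variant="res")))
        assert round(n / 1e6, 2) == 3.34

    def test_variant_ordering_res_dense_csp(self):
        counts = {
            v: count_parameters(build(NetworkSpec(variant=v)))
            for v in ("res", "dense", "csp")
        }
        assert counts["res"] > counts["dense"] > counts["csp"]

    def test_empty_model_counts_zero(self):
        class Empty(Module):
            pass

        assert count_parameters(Empty()) == 0


class TestNumericalBehaviour:
    def test_zeroed_heads_null_output(self, rng):
        model = build(tiny_spec())
        for head in model.heads:
            for p in head.modules[-1].params():
                p.value[...] = 0.0
        x = rng.normal(size=(1, 6, 12, 12, 12)).astype(np.float32)
        assert np.all(model.forward(x) == 0.0)

    def test_numba_conv_matches_numpy_oracle(self, rng):
        x = rng.normal(size=(2, 5, 6, 7, 8)).astype(np.float32)
        W = rng.normal(size=(3, 3, 3, 5, 4)).astype(np.float32) * 0.1
        b = rng.normal(size=4).astype(np.float32)
        got = conv3d_forward(x, W, b)
        ref = conv3d_forward_numpy(x, W, b)
        assert np.allclose(got, ref, atol=1e-4)

    def test_upsample_matrix_partition_of_unity(self):
        U = upsample_matrix(12, 4)
        assert U.shape == (48, 12)
        assert np.allclose(U.sum(axis=1), 1.0)   # constants are preserved

    def test_upsample_backward_is_adjoint(self, rng):
        up = Upsample3d(4)
        x = rng.normal(size=(1, 2, 5, 5, 5))
        y = rng.normal(size=(1, 2, 20, 20, 20))
        ux = up.forward(x, train=True)
        uty = up.backward(y)
        assert np.allclose((ux * y).sum(), (x * uty).sum(), rtol=1e-10)


def _param_gradcheck(module, x, rng, n_checks=6, eps=1e-6, rtol=1e-5):
    """Central-difference check of a module's parameter gradients (f64)."""
    y = module.forward(x, train=True)
    dy = rng.normal(size=y.shape)
    for p in module.params():
        p.grad[...] = 0.0
    module.backward(dy)
    for p in module.params():
        flat = p.value.ravel()
        idxs = rng.choice(flat.size, size=min(n_checks, flat.size),
                          replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            lp = (module.forward(x, train=True) * dy).sum()
            flat[i] = orig - eps
            lm = (module.forward(x, train=True) * dy).sum()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert p.grad.ravel()[i] == pytest.approx(num, rel=rtol, abs=1e-7), p.name


class TestGradients:
    @pytest.mark.parametrize("layer_cls", [Conv3d, Conv1x1])
    def test_conv_layers(self, layer_cls, rng):
        layer = layer_cls(3, 4, rng, dtype=np.float64)
        x = rng.normal(size=(2, 3, 4, 4, 4))
        _param_gradcheck(layer, x, rng)

    @pytest.mark.parametrize("block_cls", [ResBlock, DenseBlock, CSPBlock])
    def test_blocks(self, block_cls, rng):
        block = block_cls(4, rng) if block_cls is ResBlock else \
            block_cls(4, rng, growth=2, depth=2)
        for p in block.params():
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        x = rng.normal(size=(1, 4, 4, 4, 4))
        _param_gradcheck(block, x, rng)

    def test_whole_network_directional_derivative(self, rng):
        # f64 end-to-end: gradient of a scalar loss along a random parameter
        # direction matches finite differences
        spec = tiny_spec(in_patch=4, out_patch=16)
        model = build(spec)
        for p in model.params():
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        x = rng.normal(size=(1, 6, 4, 4, 4))
        target = rng.normal(size=(1, 3, 16, 16, 16))

        def loss():
            return float(((model.forward(x, train=True) - target) ** 2).sum())

        for p in model.params():
            p.grad[...] = 0.0
        pred = model.forward(x, train=True)
        model.backward(2.0 * (pred - target))
        dirs = [rng.normal(size=p.value.shape) for p in model.params()]
        analytic = sum(float((p.grad * d).sum())
                       for p, d in zip(model.params(), dirs))
        eps = 1e-6
        for p, d in zip(model.params(), dirs):
            p.value += eps * d
        lp = loss()
        for p, d in zip(model.params(), dirs):
            p.value -= 2 * eps * d
        lm = loss()
        numeric = (lp - lm) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=1e-5)


class _TrilinearStub(Module):
    """Linear model: trilinear-upsample the velocity channels."""

    def __init__(self):
        self.up = Upsample3d(4)

    def forward(self, x, train=False):
        return self.up.forward(np.ascontiguousarray(x[:, :3]), train)


class TestPredictVolume:
    def _lr_sample(self, rng, shape=(24, 24, 24)):
        from jetsr.mri import Acquisition, LRSample

        # smooth synthetic LR field
        xs = [np.linspace(0, np.pi, s) for s in shape]
        base = np.sin(xs[0])[:, None, None] * np.cos(xs[1])[None, :, None] \
            * np.cos(xs[2])[None, None, :]
        vel = np.stack([base, 0.5 * base, -0.3 * base], axis=-1).astype(np.float32)
        mag = np.full(shape + (3,), 100.0, dtype=np.float32)
        acq = Acquisition(venc=(1.5, 1.2, 0.9), snr_db=16.0, intensity=100.0)
        return LRSample(velocity=vel, magnitude=mag,
                        mask=np.ones(shape, bool), acquisition=acq)

    def test_output_shape_4x(self, rng):
        model = build(tiny_spec())
        sr = predict_volume(model, self._lr_sample(rng))
        assert sr.shape == (96, 96, 96, 3)
        assert np.isfinite(sr).all()

    def test_linear_stub_equals_global_upsampling(self, rng):
        # patchwise prediction + stitching of a trilinear stub reproduces
        # global trilinear upsampling exactly (stripped interiors only use
        # in-patch support), and VENC normalisation cancels for linear maps
        lr = self._lr_sample(rng)
        sr = predict_volume(_TrilinearStub(), lr)
        U = upsample_matrix(24, 4)
        full = lr.velocity
        for ax in range(3):
            full = np.moveaxis(
                np.tensordot(U, full, axes=([1], [ax])), 0, ax)
        assert np.allclose(sr, full, atol=1e-4)

    def test_venc_change_invariant_for_linear_model(self, rng):
        from dataclasses import replace

        lr = self._lr_sample(rng)
        sr1 = predict_volume(_TrilinearStub(), lr)
        acq2 = replace(lr.acquisition, venc=(3.0, 2.4, 1.8))
        lr2 = replace(lr, acquisition=acq2)
        sr2 = predict_volume(_TrilinearStub(), lr2)
        assert np.allclose(sr1, sr2, atol=1e-4)


class TestCheckpointRoundTrip:
    def test_save_load_preserves_weights(self, rng, tmp_path):
        from jetsr.models import load_checkpoint, save_checkpoint

        model = build(tiny_spec(seed=3))
        save_checkpoint(model, tmp_path / "model.npz", extra={"note": "t"})
        loaded = load_checkpoint(tmp_path / "model.npz")
        x = rng.normal(size=(1, 6, 12, 12, 12)).astype(np.float32)
        assert np.array_equal(model.forward(x), loaded.forward(x))
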
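"""Architecture contracts: shapes, ranges, determinism, attention behavior,
gradient flow, ablations, checkpointing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaseg import NetConfig, ProbMask, binarize, build, load_checkpoint, save_checkpoint
from gaseg import autograd as ag
from gaseg.autograd import Tensor
from gaseg.errors import ConfigError, ShapeError
from gaseg.net import AttentionGate2D, AxialCollapse

TINY_CFG = NetConfig(input_dims=(8, 16, 8), levels=2, base_channels=2, seed=0)


def _fwd(net, cfg, seed=0):
    rng = np.random.default_rng(seed)
    vol = rng.standard_normal(cfg.input_dims).astype(np.float32)
    return net.predict_proba(vol)


class TestBuildAndForward:
    def test_output_dims_follow_input(self):
        net = build(TINY_CFG)
        p = _fwd(net, TINY_CFG)
        assert p.grid.shape == (16, 8)
        assert 0.0 <= p.grid.min() and p.grid.max() <= 1.0

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ConfigError):
            NetConfig(input_dims=(8, 12, 8), levels=3, base_channels=2)

    def test_same_seed_identical_parameters(self):
        a, b = build(TINY_CFG), build(TINY_CFG)
        assert a.checksum() == b.checksum()
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_different_seed_differs(self):
        other = NetConfig(**{**TINY_CFG.__dict__, "seed": 1})
        assert build(TINY_CFG).checksum() != build(other).checksum()

    def test_inference_deterministic(self):
        net = build(TINY_CFG)
        p1, p2 = _fwd(net, TINY_CFG, 3), _fwd(net, TINY_CFG, 3)
        np.testing.assert_array_equal(p1.grid, p2.grid)

    def test_zero_final_layer_gives_half(self):
        net = build(TINY_CFG)
        net.zero_final_layer()
        p = _fwd(net, TINY_CFG)
        np.testing.assert_array_equal(p.grid, np.full((16, 8), 0.5, np.float32))

    def test_z_equal_one_input_works(self):
        cfg = NetConfig(input_dims=(1, 16, 8), levels=2, base_channels=2, seed=0)
        p = _fwd(build(cfg), cfg)
        assert p.grid.shape == (16, 8)

    @pytest.mark.parametrize("attention,residual", [(False, False), (True, False),
                                                    (False, True)])
    def test_ablations_keep_contracts(self, attention, residual):
        cfg = NetConfig(input_dims=(8, 16, 8), levels=2, base_channels=2,
                        use_attention=attention, use_residual=residual, seed=0)
        p = _fwd(build(cfg), cfg)
        assert p.grid.shape == (16, 8)
        assert 0.0 <= p.grid.min() and p.grid.max() <= 1.0

    def test_nir_second_channel(self, rng):
        cfg = NetConfig(input_dims=(8, 16, 8), levels=2, base_channels=2,
                        in_channels=2, seed=0)
        net = build(cfg)
        vol = rng.standard_normal(cfg.input_dims).astype(np.float32)
        nir = rng.random(cfg.mask_dims).astype(np.float32)
        p = net.predict_proba(vol, nir)
        assert p.grid.shape == (16, 8)
        with pytest.raises(ShapeError):
            net.predict_proba(vol)  # nIR required when configured

    def test_wrong_input_dims_rejected(self, rng):
        net = build(TINY_CFG)
        with pytest.raises(ShapeError):
            net.predict_proba(rng.random((8, 16, 4)).astype(np.float32))


class TestAxialCollapse:
    def test_zero_logits_reduce_to_plain_mean(self, rng):
        layer = AxialCollapse(np.random.default_rng(0), channels=3,
                              use_attention=True)
        x = rng.standard_normal((2, 3, 5, 4, 6)).astype(np.float32)
        out = layer(Tensor(x))
        expected = layer.mix(Tensor(x.mean(axis=2)))
        np.testing.assert_allclose(out.data, expected.data, atol=1e-5)

    def test_z1_degenerates_to_identity_slice(self, rng):
        layer = AxialCollapse(np.random.default_rng(0), channels=2,
                              use_attention=True)
        x = rng.standard_normal((1, 2, 1, 4, 4)).astype(np.float32)
        out = layer(Tensor(x))
        expected = layer.mix(Tensor(x[:, :, 0]))
        np.testing.assert_allclose(out.data, expected.data, atol=1e-6)

    @given(st.integers(1, 6), st.integers(1, 5), st.integers(1, 5))
    def test_spatial_dims_preserved(self, z, x, y):
        layer = AxialCollapse(np.random.default_rng(0), channels=2,
                              use_attention=True)
        data = np.random.default_rng(7).standard_normal((1, 2, z, x, y)).astype(np.float32)
        assert layer(Tensor(data)).data.shape == (1, 2, x, y)


class TestAttentionGate:
    def test_forced_alpha_limits(self, rng):
        gate = AttentionGate2D(np.random.default_rng(0), c_skip=3, c_gate=4)
        skip = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
        gating = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
        # alpha -> 1: large positive psi bias; output equals skip
        gate.psi.w.data[:] = 0.0
        gate.psi.b.data[:] = 50.0
        out = gate(Tensor(skip), Tensor(gating))
        np.testing.assert_allclose(out.data, skip, atol=1e-5)
        # alpha -> 0
        gate.psi.b.data[:] = -50.0
        out = gate(Tensor(skip), Tensor(gating))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-5)

    @given(st.integers(0, 10))
    def test_gate_never_amplifies(self, seed):
        rng = np.random.default_rng(seed)
        gate = AttentionGate2D(np.random.default_rng(3), c_skip=2, c_gate=2)
        skip = rng.standard_normal((1, 2, 4, 5)).astype(np.float32)
        gating = rng.standard_normal((1, 2, 4, 5)).astype(np.float32)
        out = gate(Tensor(skip), Tensor(gating))
        assert np.all(np.abs(out.data) <= np.abs(skip) + 1e-6)

    def test_spatial_mismatch_rejected(self, rng):
        gate = AttentionGate2D(np.random.default_rng(0), c_skip=2, c_gate=2)
        with pytest.raises(ShapeError):
            gate(Tensor(rng.random((1, 2, 4, 4)).astype(np.float32)),
                 Tensor(rng.random((1, 2, 3, 3)).astype(np.float32)))


class TestGradientFlow:
    def test_every_parameter_gets_nonzero_gradient(self, rng):
        """No dead branches: every weight is reached by at least one of a
        handful of random batches (a single batch can leave a ReLU unit
        inactive by chance)."""
        from gaseg.train import _batch_loss

        cfg = NetConfig(input_dims=(16, 16, 16), levels=2, base_channels=2, seed=0)
        net = build(cfg)
        params = net.parameters()
        touched = [np.zeros_like(p.data, bool) for p in params]
        for _ in range(5):
            vol = rng.standard_normal((2, 1) + cfg.input_dims).astype(np.float32)
            t = (rng.random((2, 16, 16)) > 0.5).astype(np.float32)
            for p in params:
                p.grad = None
            loss = _batch_loss(net.forward_batch(vol), t, (1.0, 1.0))
            loss.backward()
            for m, p in zip(touched, params):
                if p.grad is not None:
                    m |= p.grad != 0
            if all(m.all() for m in touched):
                break
        for i, m in enumerate(touched):
            assert m.any(), f"parameter {i} never received any gradient"
        # dead ReLU units may zero single entries, but never most of the net
        assert sum(m.sum() for m in touched) >= 0.5 * sum(m.size for m in touched)


class TestBinarize:
    def test_tie_maps_to_lesion(self):
        p = ProbMask(np.full((2, 2), 0.5, np.float32))
        assert binarize(p, 0.5).grid.sum() == 4
        assert binarize(p, 0.9).grid.sum() == 0

    def test_idempotent_on_binary(self):
        p = ProbMask(np.array([[0.0, 1.0], [1.0, 0.0]], np.float32))
        once = binarize(p, 0.5)
        twice = binarize(ProbMask(once.grid.astype(np.float32)), 0.5)
        np.testing.assert_array_equal(once.grid, twice.grid)

    def test_bad_threshold(self):
        with pytest.raises(ConfigError):
            binarize(ProbMask(np.zeros((2, 2), np.float32)), 1.0)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        net = build(TINY_CFG)
        vol = rng.standard_normal(TINY_CFG.input_dims).astype(np.float32)
        before = net.predict_proba(vol).grid
        save_checkpoint(net, tmp_path / "net.ckpt")
        restored = load_checkpoint(tmp_path / "net.ckpt")
        assert restored.config == net.config
        np.testing.assert_array_equal(restored.predict_proba(vol).grid, before)
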
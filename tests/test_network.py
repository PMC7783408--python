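"""Architecture contracts: shapes, probabilities, gradients, receptive field."""

import numpy as np
import pytest

from lesionseg.errors import InvalidConfigError
from lesionseg.losses import loss_and_logit_grad, total_loss
from lesionseg.network import (
    NetworkConfig,
    build_network,
    count_parameters,
    match_parameters,
    receptive_field,
)


@pytest.fixture(scope="module")
def tiny_model():
    return build_network(NetworkConfig(levels=2, encoder_width=2), seed=0)


def test_config_invariants():
    cfg = NetworkConfig()
    assert cfg.levels == 3 and cfg.encoder_width == 32 and cfg.decoder_width == 64
    with pytest.raises(InvalidConfigError):
        NetworkConfig(levels=0)
    with pytest.raises(InvalidConfigError):
        NetworkConfig(encoder_width=32, decoder_width=48)
    with pytest.raises(InvalidConfigError):
        NetworkConfig(block_type="plain")


def test_output_shape_matches_input_on_divisible_grid(tiny_model):
    x = np.random.default_rng(0).normal(size=(16, 16, 8)).astype(np.float32)
    z = tiny_model.forward_logits(x)
    assert z.shape == (2, 16, 16, 8)


def test_output_shape_matches_input_on_non_divisible_grid(tiny_model):
    """18 slices with two poolings forces internal padding; output is cropped
    back to the input geometry."""
    x = np.random.default_rng(0).normal(size=(20, 20, 18)).astype(np.float32)
    z = tiny_model.forward_logits(x)
    assert z.shape == (2, 20, 20, 18)


def test_softmax_probabilities_normalized(tiny_model):
    x = np.random.default_rng(1).normal(size=(16, 16, 8)).astype(np.float32)
    p = tiny_model.predict_probs(x)
    assert np.all(p >= 0) and np.all(p <= 1)
    np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-5)


def test_resnet_block_with_zero_convs_is_identity():
    """With conv weights and biases zeroed and BatchNorm affine at identity,
    the residual path makes the block the identity map."""
    from lesionseg.network import ResNetBlock

    rng = np.random.default_rng(0)
    block = ResNetBlock(3, rng)
    for unit in (block.u1, block.u2):
        unit.conv.w.value[...] = 0.0
        unit.conv.b.value[...] = 0.0
    x = rng.normal(size=(3, 6, 6, 6)).astype(np.float32)
    y = block.forward(x, training=False)
    np.testing.assert_allclose(y, x, atol=1e-6)


def test_full_model_gradients_match_finite_differences(tiny_model):
    """Backprop through the whole graph (residuals, skips, pooling,
    upsampling, batch norm) agrees with central finite differences."""
    m = tiny_model
    rng = np.random.default_rng(1)
    x = rng.normal(size=(8, 8, 8)).astype(np.float32)
    t = (rng.random((8, 8, 8)) > 0.7).astype(float)

    def loss_train():
        z = m.forward_logits(x, training=True)
        q = 1.0 / (1.0 + np.exp(-(z[1] - z[0])))
        return total_loss(t, q).total

    z = m.forward_logits(x, training=True)
    _, g = loss_and_logit_grad(t, z)
    for p in m.parameters():
        p.zero_grad()
    m.backward(g)

    params = m.parameters()
    idx_rng = np.random.default_rng(2)
    checked = 0
    for p_i in idx_rng.choice(len(params), size=12, replace=False):
        par = params[p_i]
        flat = par.value.ravel()
        i = int(idx_rng.integers(flat.size))
        eps = 1e-3
        orig = flat[i]
        flat[i] = orig + eps
        lp = loss_train()
        flat[i] = orig - eps
        lm = loss_train()
        flat[i] = orig
        num = (lp - lm) / (2 * eps)
        ana = par.grad.ravel()[i]
        # float32 forward passes limit finite-difference accuracy
        assert ana == pytest.approx(num, rel=0.05, abs=2e-4)
        checked += 1
    assert checked == 12


class TestParameterCount:
    def test_single_bottleneck_closed_form(self):
        """A 1^3 conv 32->64 with bias holds 32*64 + 64 = 2112 weights."""
        from lesionseg.engine import Conv3d

        conv = Conv3d(32, 64, 1, np.random.default_rng(0))
        assert sum(p.value.size for p in conv.parameters()) == 2112

    def test_invariant_to_input_size(self, tiny_model):
        n = count_parameters(tiny_model)
        tiny_model.forward_logits(np.zeros((8, 8, 8), dtype=np.float32))
        assert count_parameters(tiny_model) == n

    def test_width_ordering(self):
        counts = {
            w: count_parameters(build_network(NetworkConfig(encoder_width=w)))
            for w in (28, 32, 36)
        }
        assert counts[28] < counts[32] < counts[36]


class TestMatchParameters:
    def test_reference_matches_itself(self):
        cfg = NetworkConfig(levels=2, encoder_width=8)
        ref = build_network(cfg)
        matched = match_parameters(cfg, ref, max_width=24)
        assert matched.encoder_width == 8

    def test_halved_depth_widened_to_closest_count(self):
        base = build_network(NetworkConfig(levels=2, encoder_width=8))
        target = count_parameters(base)
        variant = NetworkConfig(levels=1, encoder_width=8)
        matched = match_parameters(variant, base, max_width=32)
        err_matched = abs(count_parameters(build_network(matched)) - target)
        # exhaustive scan oracle
        errs = {
            w: abs(
                count_parameters(build_network(NetworkConfig(levels=1, encoder_width=w)))
                - target
            )
            for w in range(1, 33)
        }
        assert err_matched == min(errs.values())

    def test_widening_never_decreases_count(self):
        counts = [
            count_parameters(build_network(NetworkConfig(levels=1, encoder_width=w)))
            for w in range(2, 12)
        ]
        assert all(b > a for a, b in zip(counts, counts[1:]))

    def test_densenet_growth_matched_to_baseline(self):
        base = build_network(NetworkConfig(levels=2, encoder_width=8))
        variant = NetworkConfig(levels=2, encoder_width=8, block_type="densenet")
        matched = match_parameters(variant, base, max_width=32)
        err = abs(count_parameters(build_network(matched)) - count_parameters(base))
        # within one growth step of the target
        step = abs(
            count_parameters(
                build_network(
                    NetworkConfig(
                        levels=2, encoder_width=8, block_type="densenet",
                        growth_rate=matched.growth_rate + 1,
                    )
                )
            )
            - count_parameters(build_network(matched))
        )
        assert err <= step


class TestReceptiveField:
    @staticmethod
    def _linear_positive(model):
        """Positive conv weights, zero biases: with BatchNorm at its identity
        running stats the whole network is linear with positive coefficients,
        so dependency is visible as an exactly nonzero output."""
        for p in model.parameters():
            if p.value.ndim == 5:
                p.value[...] = np.abs(p.value) + 0.05
        return model

    @staticmethod
    def _oracle_extent(model, grid, out_index, axis=0):
        hits = []
        center = [g // 2 for g in grid]
        center[axis] = out_index
        for i in range(grid[axis]):
            x = np.zeros(grid, dtype=np.float32)
            pos = [g // 2 for g in grid]
            pos[axis] = i
            x[tuple(pos)] = 1.0
            z = model.forward_logits(x, training=False)
            if z[(0, *center)] != 0.0:
                hits.append(i)
        return max(hits) - min(hits) + 1

    def test_single_and_stacked_convs(self):
        """One 3^3 convolution sees 3 voxels; two stacked see 5."""
        from lesionseg.engine import Conv3d

        rng = np.random.default_rng(0)
        c1 = Conv3d(1, 1, 3, rng)
        c2 = Conv3d(1, 1, 3, rng)
        for c in (c1, c2):
            c.w.value[...] = np.abs(c.w.value) + 0.1
            c.b.value[...] = 0.0
        x = np.zeros((1, 9, 9, 9), dtype=np.float32)
        x[0, 4, 4, 4] = 1.0
        one = c1.forward(x, training=False)
        extent1 = np.flatnonzero(one[0].sum(axis=(1, 2)))
        assert len(extent1) == 3
        two = c2.forward(one, training=False)
        extent2 = np.flatnonzero(two[0].sum(axis=(1, 2)))
        assert len(extent2) == 5

    @pytest.mark.parametrize("levels,grid", [(1, (40, 12, 12)), (2, (72, 12, 12))])
    def test_agrees_with_perturbation_oracle(self, levels, grid):
        cfg = NetworkConfig(levels=levels, encoder_width=2)
        model = self._linear_positive(build_network(cfg, seed=3))
        period = 2**levels
        calc = 0
        emp = 0
        base = (grid[0] // 2 // period) * period
        for off in range(period):
            from lesionseg.network import _input_support

            s = _input_support(cfg, off)
            calc = max(calc, max(s) - min(s) + 1)
            emp = max(emp, self._oracle_extent(model, grid, base + off))
        assert receptive_field(cfg)[0] == calc
        assert calc == emp

    def test_halved_depth_shrinks_receptive_field(self):
        rf3 = receptive_field(NetworkConfig(levels=3))[0]
        rf2 = receptive_field(NetworkConfig(levels=2))[0]
        assert rf2 < rf3
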
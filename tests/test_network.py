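import numpy as np
import pytest

from cfanet.encoder import DimensionError
from cfanet.metrics import soft_dice_loss
from cfanet.network import (
    CFANet,
    DecoderBlock,
    NetworkConfig,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
)
from cfanet.nn import functional as F
from cfanet.nn.autograd import Tensor
from cfanet.nn.layers import Conv2d


# --- independent parameter enumeration (pure arithmetic, no Module walk) ---

def _conv(cin, cout, k, bias):
    return cin * cout * k * k + (cout if bias else 0)


def _cbr(cin, cout, k):
    return _conv(cin, cout, k, False) + 2 * cout


def _basic_block(cin, cout, downsample):
    n = _cbr(cin, cout, 3) + _cbr(cout, cout, 3)
    if downsample:
        n += _cbr(cin, cout, 1)
    return n


def _encoder_total():
    total = _cbr(3, 64, 7)
    for cin, cout, depth in [(64, 64, 3), (64, 128, 4), (128, 256, 6), (256, 512, 3)]:
        total += _basic_block(cin, cout, cin != cout)
        total += (depth - 1) * _basic_block(cout, cout, False)
    return total


def _cff_level(channels):
    c0 = channels[0]
    total = sum(_cbr(c, c0, 1) for c in channels)       # 1x1 channel unify
    total += sum(_cbr(len(channels) * c0, c0, k) for k in (1, 3, 5))
    total += _conv(3 * c0, c0, 1, True)                 # final projection
    return total


def _ecsa_total(c=512, r=16):
    return _conv(c, c // r, 1, True) + _conv(c // r, c, 1, True) + _conv(2, 1, 7, True)


def _decoder_total(ladder=(512, 256, 128, 64, 64, 32), num_classes=1):
    total = sum(_cbr(ladder[i], ladder[i + 1], 3) for i in range(5))
    return total + _conv(ladder[5], num_classes, 1, True)


def expected_total(use_cff=True, use_ecsa=True):
    total = _encoder_total() + _decoder_total()
    if use_cff:
        total += sum(_cff_level(ch) for ch in
                     [(64, 128, 256), (128, 256, 512), (256, 512)])
    if use_ecsa:
        total += _ecsa_total()
    return total


class TestParameterCount:
    def test_linear_map_example(self):
        layer = Conv2d(10, 5, 1, bias=True)
        assert sum(p.data.size for p in layer.parameters()) == 55

    def test_conv_bn_example(self):
        from cfanet.nn.layers import ConvBNReLU
        unit = ConvBNReLU(64, 64, 3)
        assert sum(p.data.size for p in unit.parameters()) == 36_992

    def test_default_config_matches_enumeration_oracle(self):
        assert count_parameters() == expected_total()

    def test_default_config_rounds_to_30M(self):
        assert count_parameters(as_millions=True) == 30

    def test_ablations_match_oracle_and_are_monotone(self):
        full = count_parameters(NetworkConfig())
        no_cff = count_parameters(NetworkConfig(use_cff=False))
        no_ecsa = count_parameters(NetworkConfig(use_ecsa=False))
        baseline = count_parameters(NetworkConfig(use_cff=False, use_ecsa=False))
        assert no_cff == expected_total(use_cff=False)
        assert no_ecsa == expected_total(use_ecsa=False)
        assert baseline == expected_total(use_cff=False, use_ecsa=False)
        assert baseline < no_cff < full
        assert baseline < no_ecsa < full
        assert len({full, no_cff, no_ecsa, baseline}) == 4

    def test_count_is_pure_function_of_config(self):
        assert count_parameters(NetworkConfig(seed=1)) == count_parameters(
            NetworkConfig(seed=99)
        )


class TestDecoderBlock:
    def test_skip_sum_shapes(self, rng):
        block = DecoderBlock(512, 256, rng=rng)
        x = Tensor(rng.standard_normal((1, 512, 8, 8)).astype(np.float32))
        skip = Tensor(rng.standard_normal((1, 256, 16, 16)).astype(np.float32))
        assert block(x, skip).shape == (1, 256, 16, 16)

    def test_no_skip_pure_upsample(self, rng):
        block = DecoderBlock(64, 64, rng=rng)
        x = Tensor(rng.standard_normal((1, 64, 64, 64)).astype(np.float32))
        assert block(x).shape == (1, 64, 128, 128)

    def test_wrong_skip_shape_names_both(self, rng):
        block = DecoderBlock(64, 32, rng=rng)
        x = Tensor(np.zeros((1, 64, 8, 8), dtype=np.float32))
        skip = Tensor(np.zeros((1, 32, 12, 12), dtype=np.float32))
        with pytest.raises(DimensionError, match=r"12.*16|16.*12"):
            block(x, skip)


class TestForward:
    def test_logits_shape(self, default_net):
        out = default_net(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert out.shape == (1, 1, 64, 64)

    @pytest.mark.parametrize("h,w", [(32, 32), (64, 96)])
    def test_output_dims_equal_input_dims(self, default_net, h, w):
        out = default_net(np.zeros((1, 3, h, w), dtype=np.float32))
        assert out.shape == (1, 1, h, w)

    def test_baseline_is_plain_u_shape(self, rng):
        net = CFANet(NetworkConfig(use_cff=False, use_ecsa=False, seed=0))
        assert net.cff is None and net.ecsa is None
        out = net(rng.standard_normal((1, 3, 32, 32)).astype(np.float32))
        assert out.shape == (1, 1, 32, 32)

    def test_inference_deterministic(self, default_net, rng):
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(
            default_net.predict_proba(x), default_net.predict_proba(x)
        )

    def test_seeded_init_reproducible(self, rng):
        a = CFANet(NetworkConfig(seed=5))
        b = CFANet(NetworkConfig(seed=5))
        x = rng.standard_normal((1, 3, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_non_divisible_input_rejected(self, default_net):
        with pytest.raises(DimensionError):
            default_net(np.zeros((1, 3, 60, 64), dtype=np.float32))


def test_gradient_reaches_every_parameter(rng):
    net = CFANet(NetworkConfig(seed=3))
    net.train()
    x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
    target = (rng.random((2, 1, 64, 64)) < 0.01).astype(np.float32)
    probs = F.sigmoid(net(Tensor(x)))
    loss = soft_dice_loss(probs, target)
    loss.backward()
    dead = [name for name, p in net.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert dead == []


def test_checkpoint_roundtrip(tmp_path, rng):
    net = CFANet(NetworkConfig(seed=11))
    x = rng.standard_normal((1, 3, 32, 32)).astype(np.float32)
    before = net.predict_proba(x)
    path = tmp_path / "model.npz"
    save_checkpoint(path, net, extra={"note": "test"})
    restored, meta = load_checkpoint(path)
    assert meta["note"] == "test"
    assert restored.config == net.config
    np.testing.assert_array_equal(before, restored.predict_proba(x))


def test_checkpoint_missing_file(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_checkpoint(tmp_path / "absent.npz")


def test_config_validation():
    with pytest.raises(ValueError):
        NetworkConfig(decoder_ladder=(512, 256, 128))
    with pytest.raises(ValueError):
        NetworkConfig(num_classes=0)
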
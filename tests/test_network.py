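"""Unit and property tests for the network core: activations, layer forward
passes against brute-force oracles, shape schedules, exact gradients, and the
gradient-descent update."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from empick import network as net
from empick.cli import gradient_check
from conftest import brute_force_conv, brute_force_pool


# ---------------------------------------------------------------------------
# sigmoid
# ---------------------------------------------------------------------------

def test_sigmoid_fixed_points():
    assert net.sigmoid(0.0) == 0.5
    assert net.sigmoid(math.log(3)) == pytest.approx(0.75, abs=1e-12)


@given(st.floats(-700, 700))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_sigmoid_symmetry_and_stability(x):
    assert net.sigmoid(x) + net.sigmoid(-x) == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= net.sigmoid(x) <= 1.0  # saturates smoothly, never overflows


@given(st.floats(-36, 35))
@settings(deadline=None, max_examples=60, derandomize=True)
def test_sigmoid_open_interval_and_monotonicity(x):
    # strictly inside (0,1) until double precision saturates (|x| ~ 36.7)
    assert 0.0 < net.sigmoid(x) < 1.0
    assert net.sigmoid(x + 1.0) > net.sigmoid(x)


# ---------------------------------------------------------------------------
# layer forward passes vs brute-force oracles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_in,n_out,side,k", [
    (1, 1, 8, 3), (2, 3, 8, 3), (3, 2, 16, 5), (1, 2, 10, 1), (2, 1, 5, 5),
])
def test_conv_forward_matches_nested_loop_oracle(rng, n_in, n_out, side, k):
    x = rng.normal(size=(n_in, side, side))
    w = rng.normal(size=(n_out, n_in, k, k))
    b = rng.normal(size=n_out)
    spec = net.ConvLayerSpec(n_in, n_out, k)
    out = net.conv_forward(x, spec, w, b)
    ref = brute_force_conv(x, w, b, net.sigmoid)
    assert out.shape == (n_out, side - k + 1, side - k + 1)
    assert np.abs(out - ref).max() < 1e-10


def test_conv_forward_zero_kernel_gives_half(rng):
    x = rng.normal(size=(1, 6, 6))
    spec = net.ConvLayerSpec(1, 1, 1)
    out = net.conv_forward(x, spec, np.zeros((1, 1, 1, 1)), np.zeros(1))
    assert np.all(out == 0.5)


def test_conv_forward_respects_connection_table(rng):
    """Maps outside M_j must not contribute to output map j."""
    x = rng.normal(size=(2, 8, 8))
    w = rng.normal(size=(2, 2, 3, 3))
    b = rng.normal(size=2)
    spec = net.ConvLayerSpec(2, 2, 3, connections=((0,), (0, 1)))
    out = net.conv_forward(x, spec, w, b)
    w_masked = w * spec.mask()[:, :, None, None]
    ref = brute_force_conv(x, w_masked, b, net.sigmoid)
    assert np.abs(out - ref).max() < 1e-10


def test_conv_forward_published_box_to_first_layer_shape(rng):
    """A 272-px box with a 51-px kernel yields 222-px feature maps."""
    x = rng.normal(size=(1, 272, 272))
    spec = net.ConvLayerSpec(1, 1, 51)
    out = net.conv_forward(x, spec, rng.normal(size=(1, 1, 51, 51)),
                           np.zeros(1))
    assert out.shape == (1, 222, 222)


@pytest.mark.parametrize("side,p", [(8, 2), (12, 3), (6, 6), (9, 1)])
def test_pool_forward_matches_nested_loop_oracle(rng, side, p):
    x = rng.normal(size=(2, side, side))
    out = net.pool_forward(x, net.PoolLayerSpec(p, p))
    assert np.abs(out - brute_force_pool(x, p, p)).max() < 1e-10


def test_pool_forward_examples():
    const = np.full((1, 6, 6), 3.7)
    assert np.all(net.pool_forward(const, net.PoolLayerSpec(2, 2)) == 3.7)
    block = np.array([[[1.0, 2.0], [3.0, 4.0]]])
    assert net.pool_forward(block, net.PoolLayerSpec(2, 2))[0, 0, 0] == 2.5
    with pytest.raises(net.ConfigurationError):
        net.pool_forward(np.zeros((1, 7, 7)), net.PoolLayerSpec(2, 2))


@given(st.integers(1, 4), st.integers(1, 3))
@settings(deadline=None, max_examples=20, derandomize=True)
def test_pool_forward_conserves_global_mean(blocks, p):
    rng = np.random.default_rng(blocks * 10 + p)
    x = rng.normal(size=(1, blocks * p, blocks * p))
    out = net.pool_forward(x, net.PoolLayerSpec(p, p))
    assert out.mean() == pytest.approx(x.mean(), abs=1e-12)


def test_output_forward_oracle_and_examples(rng):
    x = rng.normal(size=(3, 4, 4))
    w = rng.normal(size=48)
    ref = net.sigmoid(float(x.ravel() @ w) + 0.3)
    assert net.output_forward(x, w, 0.3) == pytest.approx(ref, abs=1e-12)
    assert net.output_forward(x, np.zeros(48), 0.0) == 0.5
    with pytest.raises(net.ConfigurationError):
        net.output_forward(x, np.zeros(47), 0.0)


# ---------------------------------------------------------------------------
# schedules and the full forward pass
# ---------------------------------------------------------------------------

def _chain_sides(box_side, schedule):
    """Independent shape calculator: fold the schedule from the box side."""
    sides = []
    side = box_side
    for idx, (_, printed) in enumerate(schedule):
        if idx % 2 == 0:
            k = side - printed + 1
            assert 1 <= k <= side
            side = side - k + 1
        else:
            assert side % printed == 0
            side = printed
        sides.append(side)
    return sides


PUBLISHED = {
    "klh": (272, [222, 74, 54, 27, 18, 9]),
    "19s": (160, [141, 47, 38, 19, 16, 8]),
    "26s": (150, [120, 60, 46, 23, 14, 7]),
    "inflammasome": (112, [98, 49, 40, 20, 14, 7]),
}


@pytest.mark.parametrize("name", list(PUBLISHED))
def test_published_schedules_reproduce_map_sizes(name):
    box, sides = PUBLISHED[name]
    cfg = net.SCHEDULES[name]
    assert cfg.box_side == box
    assert cfg.map_sides() == sides
    assert _chain_sides(cfg.box_side, cfg.schedule) == sides
    cfg.layers()  # consistent shape arithmetic end to end


def test_klh_output_layer_feature_count():
    assert net.SCHEDULES["klh"].layers()[-1].n_features == 12 * 9 * 9


def test_parameter_count_matches_independent_calculator():
    cfg = net.SCHEDULES["klh"]
    # independent count from the printed schedule: kernels forced by shape
    kernels = [(1, 6, 51), (6, 12, 21), (12, 12, 10)]
    expected = sum(ci * co * k * k + co for ci, co, k in kernels) + (972 + 1)
    assert net.count_parameters(cfg) == expected
    state = net.init_network(cfg, seed=0)
    assert state.flat_parameters().size == expected


def test_inconsistent_schedule_rejected():
    with pytest.raises(net.ConfigurationError):
        net.NetworkConfig(box_side=64, schedule=((6, 56), (6, 29), (12, 24),
                                                 (12, 12), (12, 8), (12, 4)))
    with pytest.raises(net.ConfigurationError):
        net.NetworkConfig(box_side=64, schedule=((6, 70), (6, 28), (12, 24),
                                                 (12, 12), (12, 8), (12, 4)))


def test_network_forward_deterministic_and_bounded(tiny_state, rng):
    box = rng.normal(size=(8, 8))
    s1 = net.network_forward(box, tiny_state)
    s2 = net.network_forward(box, tiny_state)
    assert s1 == s2
    assert 0.0 < s1 < 1.0


def test_network_forward_zero_head_is_half(rng):
    state = net.init_network(net.SCHEDULES["tiny8"], seed=3)
    state.out_weights[:] = 0.0
    state.out_bias = 0.0
    for _ in range(3):
        assert net.network_forward(rng.normal(size=(8, 8)), state) == 0.5


def test_forward_batch_matches_single(tiny_state, rng):
    boxes = rng.normal(size=(5, 8, 8))
    batch = net.forward_batch(boxes, tiny_state)
    singles = [net.network_forward(b, tiny_state) for b in boxes]
    assert np.allclose(batch, singles, atol=1e-12)


def test_forward_rejects_wrong_box_size(tiny_state):
    with pytest.raises(ValueError):
        net.network_forward(np.zeros((9, 9)), tiny_state)


# ---------------------------------------------------------------------------
# loss, gradients, update
# ---------------------------------------------------------------------------

def test_loss_examples():
    assert net.loss([0.2, 0.9], [0.2, 0.9]) == 0.0
    assert net.loss([0.0], [1.0]) == 0.5
    assert net.loss([0.0, 1.0], [1.0, 1.0]) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        net.loss([], [])


def test_backprop_matches_finite_differences():
    """Exact-gradient audit on the tiny eight-layer network."""
    assert gradient_check(seed=0) <= 1e-5
    assert gradient_check(seed=7) <= 1e-5


def test_backprop_mean_invariant_under_batch_duplication(tiny_state, rng):
    boxes = rng.normal(size=(3, 8, 8))
    t = np.array([1.0, 0.0, 1.0])
    g1 = net.backprop_gradients(boxes, t, tiny_state).flat()
    g2 = net.backprop_gradients(np.concatenate([boxes, boxes]),
                                np.concatenate([t, t]), tiny_state).flat()
    assert np.allclose(g1, g2, atol=1e-12)


def test_sgd_update_properties(tiny_state, rng):
    boxes = rng.normal(size=(4, 8, 8))
    t = rng.integers(0, 2, 4).astype(float)
    g = net.backprop_gradients(boxes, t, tiny_state)

    zero = net.backprop_gradients(boxes, net.forward_batch(boxes, tiny_state),
                                  tiny_state)  # targets == outputs
    same = net.sgd_update(tiny_state, zero, eta=1.0)
    assert np.allclose(same.flat_parameters(), tiny_state.flat_parameters(),
                       atol=1e-12)

    full = net.sgd_update(tiny_state, g, eta=1.0)
    half = net.sgd_update(tiny_state, g, eta=0.5)
    p0 = tiny_state.flat_parameters()
    assert np.allclose(half.flat_parameters() - p0,
                       0.5 * (full.flat_parameters() - p0), atol=1e-12)

    with pytest.raises(net.ConfigurationError):
        net.sgd_update(tiny_state, g, eta=0.0)


def test_small_step_does_not_increase_loss(tiny_state, rng):
    boxes = rng.normal(size=(6, 8, 8))
    t = rng.integers(0, 2, 6).astype(float)
    before = net.loss(net.forward_batch(boxes, tiny_state), t)
    g = net.backprop_gradients(boxes, t, tiny_state)
    after_state = net.sgd_update(tiny_state, g, eta=1e-2)
    after = net.loss(net.forward_batch(boxes, after_state), t)
    assert after <= before + 1e-12


def test_targets_equal_outputs_give_zero_gradient(tiny_state, rng):
    boxes = rng.normal(size=(3, 8, 8))
    y = net.forward_batch(boxes, tiny_state)
    g = net.backprop_gradients(boxes, y, tiny_state)
    assert np.abs(g.flat()).max() == 0.0


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_init_seeded_determinism_and_range():
    cfg = net.SCHEDULES["tiny8"]
    a = net.init_network(cfg, seed=11)
    b = net.init_network(cfg, seed=11)
    assert np.array_equal(a.flat_parameters(), b.flat_parameters())
    p = a.flat_parameters()
    assert p.min() >= 0.0 and p.max() < 1.0  # uniform [0,1) per default scheme
    c = net.init_network(cfg, seed=12)
    assert not np.array_equal(p, c.flat_parameters())


def test_init_symmetric_scheme_is_fan_in_bounded():
    cfg = net.SCHEDULES["tiny8"]
    s = net.init_network(cfg, seed=5, scheme="symmetric")
    for w, spec in zip(s.conv_weights, [l for l in cfg.layers()
                                        if isinstance(l, net.ConvLayerSpec)]):
        a = 1.0 / math.sqrt(spec.n_in_maps * spec.kernel_side ** 2)
        assert np.abs(w).max() <= a
    for b in s.conv_biases:
        assert np.all(b == 0.0)
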
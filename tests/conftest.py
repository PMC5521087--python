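import numpy as np
import pytest

from empick import network as net


@pytest.fixture(scope="session")
def tiny_state():
    """A seeded eight-layer network on 8-px boxes, 2 maps per conv layer."""
    return net.init_network(net.SCHEDULES["tiny8"], seed=0, scheme="symmetric")


@pytest.fixture(scope="session")
def tiny16_state():
    """A seeded eight-layer network on 16-px boxes (used for scan tests)."""
    return net.init_network(net.SCHEDULES["tiny16"], seed=1, scheme="symmetric")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_conv(stack, weights, bias, activation):
    """Direct nested-loop valid cross-correlation oracle."""
    n_out, n_in, k, _ = weights.shape
    H = stack.shape[1]
    out_side = H - k + 1
    out = np.zeros((n_out, out_side, out_side))
    b = np.broadcast_to(np.asarray(bias, float).ravel(), (n_out,)) \
        if np.asarray(bias).size == 1 else np.asarray(bias, float)
    for o in range(n_out):
        for i in range(out_side):
            for j in range(out_side):
                s = b[o]
                for c in range(n_in):
                    for u in range(k):
                        for v in range(k):
                            s += stack[c, i + u, j + v] * weights[o, c, u, v]
                out[o, i, j] = activation(s)
    return out


def brute_force_pool(stack, p, q):
    """Direct nested-loop block-average oracle."""
    n, H, W = stack.shape
    out = np.zeros((n, H // p, W // q))
    for c in range(n):
        for i in range(H // p):
            for j in range(W // q):
                s = 0.0
                for u in range(p):
                    for v in range(q):
                        s += stack[c, i * p + u, j * q + v]
                out[c, i, j] = s / (p * q)
    return out
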
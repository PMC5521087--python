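"""Eight-layer convolutional network for particle/non-particle classification.

The network alternates three convolutional layers (C1, C3, C5) with three
average-subsampling layers (S2, S4, S6) between the input plane and a fully
connected sigmoid output unit.  Convolutions are *valid* cross-correlations
with unit stride and shared kernels; subsampling is a plain non-overlapping
block average with no learnable parameters and no activation.  Everything —
forward pass, exact gradients, and the gradient-descent update — is written
directly in numpy; there is no autodiff anywhere on this path, which is why
the test suite audits every gradient against central finite differences.

Layer geometry is specified the way the field tabulates it: a list of
``(n_maps, map_side)`` pairs for C1..S6.  Kernel sides and pool sizes are
derived from the printed map sides (kernel = in - out + 1, pool = in / out)
and validated, so a schedule is internally consistent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.fft import irfft2, rfft2

__all__ = [
    "sigmoid",
    "relu",
    "ConvLayerSpec",
    "PoolLayerSpec",
    "OutputLayerSpec",
    "NetworkConfig",
    "NetworkState",
    "SCHEDULES",
    "conv_forward",
    "pool_forward",
    "output_forward",
    "network_forward",
    "forward_batch",
    "loss",
    "backprop_gradients",
    "sgd_update",
    "init_network",
    "count_parameters",
]


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def sigmoid(x):
    """Logistic activation 1 / (1 + exp(-x)), computed stably for any x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def relu(x):
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def _activation_pair(name: str) -> tuple[Callable, Callable]:
    """Return (f, f') where the derivative is expressed in terms of f(x)."""
    if name == "sigmoid":
        return sigmoid, lambda a: a * (1.0 - a)
    if name == "relu":
        return relu, lambda a: (a > 0).astype(float)
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# layer specs and configuration
# ---------------------------------------------------------------------------

class ConfigurationError(ValueError):
    """Raised when a layer schedule or parameter set is internally inconsistent."""


@dataclass(frozen=True)
class ConvLayerSpec:
    """A shared-kernel convolutional layer.

    ``connections[j]`` lists the input-map indices feeding output map j
    (the connection table M_j); ``None`` means full connectivity, the
    default reading when no sparse table is given.
    """

    n_in_maps: int
    n_out_maps: int
    kernel_side: int
    connections: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self):
        if self.kernel_side < 1:
            raise ConfigurationError("kernel_side must be >= 1")
        if self.n_in_maps < 1 or self.n_out_maps < 1:
            raise ConfigurationError("map counts must be >= 1")
        if self.connections is not None:
            if len(self.connections) != self.n_out_maps:
                raise ConfigurationError("one connection set per output map required")
            for mj in self.connections:
                if len(mj) == 0:
                    raise ConfigurationError("every connection set must be non-empty")
                if any(i < 0 or i >= self.n_in_maps for i in mj):
                    raise ConfigurationError("connection indexes out of range")

    def mask(self) -> np.ndarray:
        """Boolean (n_out, n_in) connectivity mask."""
        if self.connections is None:
            return np.ones((self.n_out_maps, self.n_in_maps), dtype=bool)
        m = np.zeros((self.n_out_maps, self.n_in_maps), dtype=bool)
        for j, mj in enumerate(self.connections):
            m[j, list(mj)] = True
        return m

    def out_side(self, in_side: int) -> int:
        if self.kernel_side > in_side:
            raise ConfigurationError(
                f"kernel {self.kernel_side} larger than input side {in_side}"
            )
        return in_side - self.kernel_side + 1


@dataclass(frozen=True)
class PoolLayerSpec:
    """Non-overlapping block average over pool_rows x pool_cols tiles."""

    pool_rows: int
    pool_cols: int

    def __post_init__(self):
        if self.pool_rows < 1 or self.pool_cols < 1:
            raise ConfigurationError("pool sizes must be >= 1")

    def out_side(self, in_side: int) -> int:
        if in_side % self.pool_rows or in_side % self.pool_cols:
            raise ConfigurationError(
                f"input side {in_side} not divisible by pool "
                f"{self.pool_rows}x{self.pool_cols}"
            )
        # square maps: both axes must agree
        if in_side // self.pool_rows != in_side // self.pool_cols:
            raise ConfigurationError("non-square pooling of square maps")
        return in_side // self.pool_rows


@dataclass(frozen=True)
class OutputLayerSpec:
    """Fully connected scalar output over the flattened last feature stack."""

    n_features: int

    def __post_init__(self):
        if self.n_features < 1:
            raise ConfigurationError("output layer needs at least one feature")


@dataclass(frozen=True)
class NetworkConfig:
    """Full eight-layer schedule: input, C1,S2,C3,S4,C5,S6, output.

    ``schedule`` holds (n_maps, map_side) for C1..S6 exactly as such tables
    are printed; kernel and pool sizes are derived from it.

    normalize_input : standardize each input box to zero mean / unit variance
        before the first layer (raw-intensity mode when False).
    shared_bias : one bias per conv layer instead of one per output map.
    activation : hidden-layer activation; the output unit is always sigmoid
        so scores stay in (0, 1).
    """

    box_side: int
    schedule: tuple[tuple[int, int], ...]
    activation: str = "sigmoid"
    normalize_input: bool = True
    shared_bias: bool = False
    connections: tuple[tuple[tuple[int, ...], ...] | None, ...] = (None, None, None)

    def __post_init__(self):
        if len(self.schedule) != 6:
            raise ConfigurationError("schedule must list C1,S2,C3,S4,C5,S6")
        if len(self.connections) != 3:
            raise ConfigurationError("one connection table (or None) per conv layer")
        _activation_pair(self.activation)
        self.layers()  # validate shape arithmetic eagerly

    def layers(self) -> list[ConvLayerSpec | PoolLayerSpec | OutputLayerSpec]:
        """Materialize layer specs from the printed map-size schedule."""
        specs: list[ConvLayerSpec | PoolLayerSpec | OutputLayerSpec] = []
        in_maps, in_side = 1, self.box_side
        for idx, (n_maps, side) in enumerate(self.schedule):
            if idx % 2 == 0:  # convolutional layer
                k = in_side - side + 1
                if k < 1:
                    raise ConfigurationError(
                        f"layer C{idx + 1}: output side {side} exceeds input {in_side}"
                    )
                spec = ConvLayerSpec(in_maps, n_maps, k, self.connections[idx // 2])
                if spec.out_side(in_side) != side:
                    raise ConfigurationError("inconsistent conv schedule")
            else:  # subsampling layer
                if n_maps != in_maps:
                    raise ConfigurationError(
                        f"layer S{idx + 1}: pooling cannot change the map count "
                        f"({in_maps} -> {n_maps})"
                    )
                if side < 1 or in_side % side:
                    raise ConfigurationError(
                        f"layer S{idx + 1}: side {in_side} not divisible into {side}"
                    )
                p = in_side // side
                spec = PoolLayerSpec(p, p)
                if spec.out_side(in_side) != side:
                    raise ConfigurationError("inconsistent pool schedule")
            specs.append(spec)
            in_maps, in_side = n_maps, side
        specs.append(OutputLayerSpec(in_maps * in_side * in_side))
        return specs

    def map_sides(self) -> list[int]:
        return [side for _, side in self.schedule]


def _schedule(box, sides, maps=(6, 6, 12, 12, 12, 12)):
    return NetworkConfig(box_side=box, schedule=tuple(zip(maps, sides)))


#: Published per-dataset layer schedules plus the package's desk-scale default
#: (same 6/12-map grammar at 64-pixel boxes, used by the synthetic pipeline).
SCHEDULES: dict[str, NetworkConfig] = {
    "klh": _schedule(272, (222, 74, 54, 27, 18, 9)),
    "19s": _schedule(160, (141, 47, 38, 19, 16, 8)),
    "26s": _schedule(150, (120, 60, 46, 23, 14, 7)),
    "inflammasome": _schedule(112, (98, 49, 40, 20, 14, 7)),
    "desk64": _schedule(64, (56, 28, 24, 12, 8, 4)),
    "tiny16": _schedule(16, (12, 6, 4, 2, 2, 1), maps=(2, 2, 4, 4, 4, 4)),
    "tiny8": _schedule(8, (6, 3, 2, 1, 1, 1), maps=(2, 2, 2, 2, 2, 2)),
}


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """All learnable parameters of a configured network.

    conv_weights[c] has shape (n_out, n_in, k, k); entries outside the
    connection table are identically zero and stay zero through training.
    conv_biases[c] has shape (n_out,) (per-map bias, the default) or (1,)
    (per-layer shared bias).
    """

    config: NetworkConfig
    conv_weights: list[np.ndarray]
    conv_biases: list[np.ndarray]
    out_weights: np.ndarray
    out_bias: float
    rng_seed: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            config=self.config,
            conv_weights=[w.copy() for w in self.conv_weights],
            conv_biases=[b.copy() for b in self.conv_biases],
            out_weights=self.out_weights.copy(),
            out_bias=float(self.out_bias),
            rng_seed=self.rng_seed,
        )

    # flat views used by the finite-difference audit and the optimizer tests
    def flat_parameters(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.conv_weights, self.conv_biases):
            parts.append(w.ravel())
            parts.append(b.ravel())
        parts.append(self.out_weights.ravel())
        parts.append(np.array([self.out_bias]))
        return np.concatenate(parts)

    def set_flat_parameters(self, flat: np.ndarray) -> None:
        i = 0
        for c, (w, b) in enumerate(zip(self.conv_weights, self.conv_biases)):
            self.conv_weights[c] = flat[i : i + w.size].reshape(w.shape).copy()
            i += w.size
            self.conv_biases[c] = flat[i : i + b.size].reshape(b.shape).copy()
            i += b.size
        self.out_weights = flat[i : i + self.out_weights.size].copy()
        i += self.out_weights.size
        self.out_bias = float(flat[i])


def count_parameters(config: NetworkConfig) -> int:
    """Number of learnable parameters implied by the schedule (masked
    connections excluded)."""
    n = 0
    for spec in config.layers():
        if isinstance(spec, ConvLayerSpec):
            n += int(spec.mask().sum()) * spec.kernel_side ** 2
            n += 1 if config.shared_bias else spec.n_out_maps
        elif isinstance(spec, OutputLayerSpec):
            n += spec.n_features + 1
    return n


def init_network(
    config: NetworkConfig, seed: int, scheme: str = "uniform01"
) -> NetworkState:
    """Draw all weights and biases from the given seed.

    scheme="uniform01" draws every parameter uniformly from [0, 1).
    scheme="symmetric" draws from U[-a, a] with a = 1/sqrt(fan-in), which
    avoids the sigmoid saturation that all-positive weights cause in the
    deeper layers (see docs/methods.md); biases start at 0.
    """
    rng = np.random.default_rng(seed)
    conv_w, conv_b = [], []
    specs = config.layers()
    for spec in specs:
        if isinstance(spec, ConvLayerSpec):
            shape = (spec.n_out_maps, spec.n_in_maps, spec.kernel_side, spec.kernel_side)
            mask = spec.mask()
            fan_in = mask.sum(axis=1).max() * spec.kernel_side ** 2
            if scheme == "uniform01":
                w = rng.uniform(0.0, 1.0, size=shape)
            elif scheme == "symmetric":
                a = 1.0 / math.sqrt(fan_in)
                w = rng.uniform(-a, a, size=shape)
            else:
                raise ConfigurationError(f"unknown init scheme {scheme!r}")
            w *= mask[:, :, None, None]
            nb = 1 if config.shared_bias else spec.n_out_maps
            if scheme == "uniform01":
                b = rng.uniform(0.0, 1.0, size=nb)
            else:
                b = np.zeros(nb)
            conv_w.append(w)
            conv_b.append(b)
        elif isinstance(spec, OutputLayerSpec):
            if scheme == "uniform01":
                ow = rng.uniform(0.0, 1.0, size=spec.n_features)
                ob = float(rng.uniform(0.0, 1.0))
            else:
                a = 1.0 / math.sqrt(spec.n_features)
                ow = rng.uniform(-a, a, size=spec.n_features)
                ob = 0.0
    return NetworkState(config, conv_w, conv_b, ow, ob, rng_seed=seed)


# ---------------------------------------------------------------------------
# single-sample layer operations (the reference API)
# ---------------------------------------------------------------------------

def _check_stack(inputs: np.ndarray) -> np.ndarray:
    x = np.asarray(inputs, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("feature stack must be (n_maps, H, W)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in feature stack")
    return x


def _conv_batch(x: np.ndarray, weights: np.ndarray, bias: np.ndarray,
                act: Callable) -> tuple[np.ndarray, np.ndarray]:
    """Batched valid cross-correlation + bias + activation.

    x (B, C, H, W); weights (O, C, k, k); bias (O,) or (1,).
    Computed as a circular FFT convolution with the flipped kernel; the
    valid region (the last Ho x Wo block) is free of wrap-around, so the
    result equals the direct nested-loop cross-correlation to double-
    precision FFT roundoff (~1e-13 relative), which the oracle tests check.
    Returns (activations (B, O, Ho, Wo), the input spectrum for backprop).
    """
    B, C, H, W = x.shape
    O, _, k, _ = weights.shape
    xf = rfft2(x, s=(H, W))                            # (B, C, H, W//2+1)
    kf = rfft2(weights[:, :, ::-1, ::-1], s=(H, W))    # (O, C, H, W//2+1)
    pre = irfft2(np.einsum("bcxy,ocxy->boxy", xf, kf), s=(H, W))
    pre = pre[:, :, k - 1 :, k - 1 :]
    pre = pre + bias.reshape(1, -1, 1, 1)
    return act(pre), xf


def conv_forward(inputs: np.ndarray, layer: ConvLayerSpec,
                 weights: np.ndarray, bias: np.ndarray,
                 activation: Callable = sigmoid) -> np.ndarray:
    """Convolutional layer: activation(sum over connected input maps of the
    valid cross-correlation with the shared kernel, plus the map's bias).

    inputs: (n_in, H, W); weights: (n_out, n_in, k, k) with non-connected
    entries zero; bias: (n_out,) or (1,).  Output side is H - k + 1.
    """
    x = _check_stack(inputs)
    if x.shape[0] != layer.n_in_maps:
        raise ConfigurationError(
            f"expected {layer.n_in_maps} input maps, got {x.shape[0]}"
        )
    if weights.shape != (layer.n_out_maps, layer.n_in_maps,
                         layer.kernel_side, layer.kernel_side):
        raise ConfigurationError("weight shape does not match layer spec")
    layer.out_side(x.shape[1])
    out, _ = _conv_batch(x[None], weights * layer.mask()[:, :, None, None],
                         np.asarray(bias, dtype=float).ravel(), activation)
    return out[0]


def pool_forward(inputs: np.ndarray, layer: PoolLayerSpec) -> np.ndarray:
    """Average-subsampling: non-overlapping block means, one output map per
    input map, no parameters, no activation."""
    x = _check_stack(inputs)
    n, H, W = x.shape
    p, q = layer.pool_rows, layer.pool_cols
    if H % p or W % q:
        raise ConfigurationError(f"map {H}x{W} not divisible by pool {p}x{q}")
    return x.reshape(n, H // p, p, W // q, q).mean(axis=(2, 4))


def output_forward(inputs: np.ndarray, weights: np.ndarray, bias: float,
                   activation: Callable = sigmoid) -> float:
    """Fully connected scalar head: activation(w . flat(features) + b)."""
    x = _check_stack(inputs).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if x.size != w.size:
        raise ConfigurationError(
            f"output layer expects {w.size} features, got {x.size}"
        )
    return float(activation(float(x @ w) + bias))


# ---------------------------------------------------------------------------
# full network, batched
# ---------------------------------------------------------------------------

def _normalize_boxes(boxes: np.ndarray) -> np.ndarray:
    mean = boxes.mean(axis=(1, 2), keepdims=True)
    std = boxes.std(axis=(1, 2), keepdims=True)
    return (boxes - mean) / np.maximum(std, 1e-12)


def forward_batch(boxes: np.ndarray, state: NetworkState,
                  keep_cache: bool = False):
    """Forward pass for a (B, side, side) batch of boxes.

    Returns scores (B,) in (0, 1); with keep_cache=True also the per-layer
    activations and patch matrices needed for backpropagation.
    """
    cfg = state.config
    boxes = np.asarray(boxes, dtype=float)
    if boxes.ndim == 2:
        boxes = boxes[None]
    if boxes.shape[1] != cfg.box_side or boxes.shape[2] != cfg.box_side:
        raise ValueError(
            f"boxes must be {cfg.box_side}x{cfg.box_side}, got {boxes.shape[1:]}"
        )
    if cfg.normalize_input:
        boxes = _normalize_boxes(boxes)
    act, _ = _activation_pair(cfg.activation)

    x = boxes[:, None]  # (B, 1, side, side)
    stacks = [x]
    spectra = []
    ci = 0
    for spec in cfg.layers():
        if isinstance(spec, ConvLayerSpec):
            x, xf = _conv_batch(x, state.conv_weights[ci],
                                state.conv_biases[ci], act)
            spectra.append(xf if keep_cache else None)
            ci += 1
        elif isinstance(spec, PoolLayerSpec):
            B, n, H, W = x.shape
            p, q = spec.pool_rows, spec.pool_cols
            x = x.reshape(B, n, H // p, p, W // q, q).mean(axis=(3, 5))
        else:
            flat = x.reshape(x.shape[0], -1)
            pre = flat @ state.out_weights + state.out_bias
            y = sigmoid(pre)  # output unit is always sigmoid
        stacks.append(x)
    y = np.atleast_1d(y)
    if keep_cache:
        return y, stacks, spectra
    return y


def network_forward(box: np.ndarray, state: NetworkState) -> float:
    """Score a single box through C1->S2->C3->S4->C5->S6->output."""
    return float(forward_batch(np.asarray(box, dtype=float)[None], state)[0])


def loss(outputs: Sequence[float], targets: Sequence[float]) -> float:
    """Squared-error objective: mean over samples of half the squared
    residual, E_N = (1/2N) sum ||t_n - y_n||^2."""
    y = np.asarray(outputs, dtype=float).ravel()
    t = np.asarray(targets, dtype=float).ravel()
    if y.size == 0 or y.size != t.size:
        raise ValueError("outputs and targets must be equal-length, non-empty")
    return float(np.mean(0.5 * (t - y) ** 2))


@dataclass
class Gradients:
    """Mean gradients dE_N/dw, shaped exactly like the parameters."""

    conv_weights: list[np.ndarray]
    conv_biases: list[np.ndarray]
    out_weights: np.ndarray
    out_bias: float

    def flat(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.conv_weights, self.conv_biases):
            parts.append(w.ravel())
            parts.append(b.ravel())
        parts.append(self.out_weights.ravel())
        parts.append(np.array([self.out_bias]))
        return np.concatenate(parts)


def _zero_gradients(state: NetworkState) -> Gradients:
    return Gradients(
        [np.zeros_like(w) for w in state.conv_weights],
        [np.zeros_like(b) for b in state.conv_biases],
        np.zeros_like(state.out_weights),
        0.0,
    )


def backprop_gradients(boxes: np.ndarray, targets: Sequence[float],
                       state: NetworkState, chunk: int = 64,
                       return_outputs: bool = False):
    """Exact gradient of the squared-error objective over the batch.

    Shared kernels accumulate gradient over every spatial application;
    average pooling distributes gradient uniformly with weight 1/(MN).
    Large batches are processed in chunks so the working set stays small;
    the result is the exact mean gradient either way.  With
    return_outputs=True also returns the forward-pass outputs, which the
    training loop reuses to track the objective without a second pass.
    """
    boxes = np.asarray(boxes, dtype=float)
    if boxes.ndim == 2:
        boxes = boxes[None]
    t_all = np.asarray(targets, dtype=float).ravel()
    if boxes.shape[0] != t_all.size:
        raise ValueError("one target per box required")
    N = boxes.shape[0]
    total = _zero_gradients(state)
    outputs = np.empty(N)
    for lo in range(0, N, chunk):
        g, y = _backprop_chunk(boxes[lo : lo + chunk], t_all[lo : lo + chunk],
                               state)
        outputs[lo : lo + y.size] = y
        for c in range(len(total.conv_weights)):
            total.conv_weights[c] += g.conv_weights[c]
            total.conv_biases[c] += g.conv_biases[c]
        total.out_weights += g.out_weights
        total.out_bias += g.out_bias
    for c in range(len(total.conv_weights)):
        total.conv_weights[c] /= N
        total.conv_biases[c] /= N
    total.out_weights /= N
    total.out_bias /= N
    if return_outputs:
        return total, outputs
    return total


def _backprop_chunk(boxes: np.ndarray, t: np.ndarray,
                    state: NetworkState) -> tuple[Gradients, np.ndarray]:
    """Sum (not mean) of per-sample gradients for one chunk."""
    cfg = state.config
    _, dact = _activation_pair(cfg.activation)
    y, stacks, spectra = forward_batch(boxes, state, keep_cache=True)

    specs = cfg.layers()
    grads = _zero_gradients(state)

    # output unit: dE/dpre = (y - t) * y(1-y)  [sigmoid head]
    d_pre = (y - t) * y * (1.0 - y)                      # (B,)
    last_stack = stacks[-2]                              # S6 activations
    flat = last_stack.reshape(last_stack.shape[0], -1)
    grads.out_weights = d_pre @ flat
    grads.out_bias = float(d_pre.sum())
    delta = (d_pre[:, None] * state.out_weights).reshape(last_stack.shape)

    ci = len(state.conv_weights) - 1
    for li in range(len(specs) - 2, -1, -1):
        spec = specs[li]
        x_in = stacks[li]
        if isinstance(spec, PoolLayerSpec):
            p, q = spec.pool_rows, spec.pool_cols
            delta = np.repeat(np.repeat(delta, p, axis=2), q, axis=3) / (p * q)
        elif isinstance(spec, ConvLayerSpec):
            a = stacks[li + 1]                           # (B, O, Ho, Wo)
            d_pre_map = delta * dact(a)
            B, O, Ho, Wo = d_pre_map.shape
            k = spec.kernel_side
            H, W = x_in.shape[2], x_in.shape[3]
            mask = spec.mask()[:, :, None, None]
            # dW: valid correlation of the layer input with the delta map,
            # via the cached input spectrum (wrap-free in the region read).
            df_r = rfft2(d_pre_map[:, :, ::-1, ::-1], s=(H, W))
            dw_full = irfft2(np.einsum("bcxy,boxy->ocxy", spectra[ci], df_r),
                             s=(H, W))
            dw = dw_full[:, :, Ho - 1 : Ho - 1 + k, Wo - 1 : Wo - 1 + k]
            grads.conv_weights[ci] = dw * mask
            if state.conv_biases[ci].size == 1:
                grads.conv_biases[ci] = np.array([d_pre_map.sum()])
            else:
                grads.conv_biases[ci] = d_pre_map.sum(axis=(0, 2, 3))
            if li > 0:  # no gradient needed past the input plane
                # dX: full convolution of the delta map with the kernel
                # (exact: the linear convolution length Ho+k-1 equals H).
                w = state.conv_weights[ci] * mask
                df = rfft2(d_pre_map, s=(H, W))
                wf = rfft2(w, s=(H, W))
                delta = irfft2(np.einsum("boxy,ocxy->bcxy", df, wf), s=(H, W))
            ci -= 1
    return grads, y


def sgd_update(state: NetworkState, gradients: Gradients,
               eta: float = 1.0) -> NetworkState:
    """One gradient-descent step w(t+1) = w(t) - eta * dE_N/dw (eta defaults
    to 1, the value used throughout training here)."""
    if eta <= 0:
        raise ConfigurationError("learning rate must be positive")
    new = state.copy()
    for c in range(len(new.conv_weights)):
        new.conv_weights[c] -= eta * gradients.conv_weights[c]
        new.conv_biases[c] -= eta * gradients.conv_biases[c]
    new.out_weights = new.out_weights - eta * gradients.out_weights
    new.out_bias = float(new.out_bias - eta * gradients.out_bias)
    return new
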
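"""Training-set assembly, rotation augmentation, and the training loop.

Labeled boxes (target 1 for particles, 0 for non-particles) are augmented by
the three 90-degree rotations, then the network is trained by full-batch
gradient descent on the squared-error objective, with held-out accuracy at
score threshold 0.5 checked after every epoch as the stopping signal.  The
training set can be grown between rounds with verified false positives and
missed particles (recursive training-set optimization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import network as net
from .network import NetworkConfig, NetworkState

__all__ = [
    "BoxOrigin",
    "TrainingSample",
    "TrainingSet",
    "TrainingReport",
    "augment_rotations",
    "evaluate_accuracy",
    "train",
    "refresh_training_set",
]


@dataclass(frozen=True)
class BoxOrigin:
    """Where a training box came from: micrograph id, corner coordinates and
    the augmentation rotation applied (degrees, one of 0/90/180/270)."""

    micrograph_id: str
    x: int
    y: int
    rotation: int = 0

    def __post_init__(self):
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError("rotation must be one of 0, 90, 180, 270")

    def key(self) -> tuple:
        """Identity of the underlying boxed region, rotation ignored."""
        return (self.micrograph_id, self.x, self.y)


@dataclass
class TrainingSample:
    box: np.ndarray
    target: int
    origin: BoxOrigin | None = None

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        if self.target not in (0, 1):
            raise ValueError("target must be 0 or 1")


@dataclass
class TrainingSet:
    samples: list[TrainingSample]
    n_positive_originals: int
    n_negative_originals: int

    def __len__(self) -> int:
        return len(self.samples)

    def boxes(self) -> np.ndarray:
        return np.stack([s.box for s in self.samples])

    def targets(self) -> np.ndarray:
        return np.array([s.target for s in self.samples], dtype=float)

    def origin_keys(self) -> set:
        return {s.origin.key() for s in self.samples if s.origin is not None}


@dataclass
class TrainingReport:
    epoch_losses: list[float] = field(default_factory=list)
    epoch_accuracies: list[float] = field(default_factory=list)
    test_accuracy: float = float("nan")
    stopped_reason: str = ""


def _rotated(sample: TrainingSample, k: int) -> TrainingSample:
    box = np.rot90(sample.box, k)
    origin = None
    if sample.origin is not None:
        origin = replace(sample.origin, rotation=(sample.origin.rotation + 90 * k) % 360)
    return TrainingSample(box=box, target=sample.target, origin=origin)


def augment_rotations(originals: Sequence[TrainingSample]) -> TrainingSet:
    """Quadruple the set with exact 90/180/270-degree rotations.

    Targets and origins are carried through; only square boxes rotate onto
    the same grid, so non-square boxes are rejected.  Warns when the
    positive/negative originals are unbalanced by more than 10% of the set,
    since training assumes roughly equal class counts.
    """
    originals = list(originals)
    if not originals:
        raise ValueError("no training samples given")
    for s in originals:
        if s.box.ndim != 2 or s.box.shape[0] != s.box.shape[1]:
            raise ValueError("augmentation requires square boxes")
    n_pos = sum(1 for s in originals if s.target == 1)
    n_neg = len(originals) - n_pos
    if abs(n_pos - n_neg) > 0.1 * len(originals):
        warnings.warn(
            f"unbalanced training set: {n_pos} positives vs {n_neg} negatives",
            stacklevel=2,
        )
    samples = []
    for s in originals:
        for k in range(4):
            samples.append(_rotated(s, k))
    return TrainingSet(samples, n_pos, n_neg)


def _rotation_averaged_scores(boxes: np.ndarray, state: NetworkState,
                              chunk: int = 64) -> np.ndarray:
    """Mean network output over the four 90-degree rotations of each box."""
    boxes = np.asarray(boxes, dtype=float)
    out = np.zeros(boxes.shape[0])
    for lo in range(0, boxes.shape[0], chunk):
        b = boxes[lo : lo + chunk]
        four = np.stack([net.forward_batch(np.ascontiguousarray(
            np.rot90(b, k, axes=(1, 2))), state) for k in range(4)])
        # sort before averaging: the orbit scores are then combined in a
        # value-determined order, so the average is bit-identical for any
        # 90-degree rotation of the input box
        four.sort(axis=0)
        out[lo : lo + b.shape[0]] = four.mean(axis=0)
    return out


def evaluate_accuracy(state: NetworkState, samples: TrainingSet,
                      threshold: float = 0.5) -> float:
    """Fraction of samples classified correctly at the given score threshold.

    Scores are rotation-averaged, matching the recognition stage; a score
    equal to the threshold counts as a positive prediction.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if len(samples) == 0:
        raise ValueError("empty evaluation set")
    scores = _rotation_averaged_scores(samples.boxes(), state)
    pred = (scores >= threshold).astype(int)
    return float(np.mean(pred == samples.targets().astype(int)))


def train(
    train_set: TrainingSet,
    test_set: TrainingSet,
    config: NetworkConfig,
    eta: float = 1.0,
    max_epochs: int = 200,
    target_accuracy: float = 0.95,
    seed: int = 0,
    batch_size: int | None = None,
    init: str = "symmetric",
    initial_state: NetworkState | None = None,
) -> tuple[NetworkState, TrainingReport]:
    """Gradient-descent training with held-out accuracy as stopping signal.

    Full-batch by default (the objective's sum runs over the whole set, so
    sample order is irrelevant); pass batch_size for seeded mini-batch SGD.
    Training stops once held-out accuracy at threshold 0.5 reaches
    target_accuracy (default 0.95) or after max_epochs.  Train and test sets
    must not share any originating boxed region.
    """
    if len(train_set) == 0 or len(test_set) == 0:
        raise ValueError("train and test sets must be non-empty")
    overlap = train_set.origin_keys() & test_set.origin_keys()
    if overlap:
        raise ValueError(f"train/test sets share {len(overlap)} box origins")

    state = initial_state.copy() if initial_state is not None \
        else net.init_network(config, seed=seed, scheme=init)
    rng = np.random.default_rng(seed + 1)
    boxes, targets = train_set.boxes(), train_set.targets()
    report = TrainingReport()

    for _ in range(max_epochs):
        # the epoch objective is tracked from the backprop forward passes:
        # exact E_N (pre-update) in full-batch mode, the running mean of the
        # per-batch values in mini-batch mode
        if batch_size is None:
            grads, y = net.backprop_gradients(boxes, targets, state,
                                              return_outputs=True)
            state = net.sgd_update(state, grads, eta)
            report.epoch_losses.append(net.loss(y, targets))
        else:
            order = rng.permutation(len(targets))
            batch_losses = []
            for lo in range(0, len(order), batch_size):
                idx = order[lo : lo + batch_size]
                grads, y = net.backprop_gradients(boxes[idx], targets[idx],
                                                  state, return_outputs=True)
                batch_losses.append(net.loss(y, targets[idx]))
                state = net.sgd_update(state, grads, eta)
            report.epoch_losses.append(float(np.mean(batch_losses)))
        acc = evaluate_accuracy(state, test_set, threshold=0.5)
        report.epoch_accuracies.append(acc)
        if acc >= target_accuracy:
            report.stopped_reason = "target_accuracy"
            break
    else:
        report.stopped_reason = "max_epochs"
    report.test_accuracy = report.epoch_accuracies[-1]
    return state, report


def refresh_training_set(
    current: TrainingSet, verified_additions: Sequence[TrainingSample]
) -> TrainingSet:
    """Grow the training set with verified picks from new micrographs.

    Verified false positives enter with target 0, missed true particles with
    target 1; only the new originals are augmented (by the same factor of
    four).  Additions whose origin already appears in the set are dropped
    with a warning.
    """
    additions = list(verified_additions)
    if not additions:
        return current
    seen = current.origin_keys()
    fresh, dropped = [], 0
    batch_keys: set = set()
    for s in additions:
        k = s.origin.key() if s.origin is not None else None
        if k is not None and (k in seen or k in batch_keys):
            dropped += 1
            continue
        if k is not None:
            batch_keys.add(k)
        fresh.append(s)
    if dropped:
        warnings.warn(f"dropped {dropped} duplicate training additions",
                      stacklevel=2)
    if not fresh:
        return current
    with warnings.catch_warnings():
        # verified additions are naturally lopsided (mostly false positives)
        warnings.filterwarnings("ignore", message="unbalanced training set")
        aug = augment_rotations(fresh)
    n_pos = sum(1 for s in fresh if s.target == 1)
    return TrainingSet(
        samples=current.samples + aug.samples,
        n_positive_originals=current.n_positive_originals + n_pos,
        n_negative_originals=current.n_negative_originals + (len(fresh) - n_pos),
    )
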
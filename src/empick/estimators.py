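"""scikit-learn style estimators wrapping the network and the picker.

``CNNParticleClassifier`` is a binary classifier over square boxes
(fit/predict/predict_proba, get_params/set_params, fitted attributes with a
trailing underscore) so it composes with sklearn model selection.
``ParticlePicker`` calibrates the picking threshold at the F2 maximum on
labeled micrographs and then picks particles from new ones.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import evaluation, network as net, recognition, training
from .network import SCHEDULES, NetworkConfig

__all__ = ["CNNParticleClassifier", "ParticlePicker"]


class CNNParticleClassifier(ClassifierMixin, BaseEstimator):
    """Eight-layer convolutional particle/non-particle classifier.

    Parameters
    ----------
    schedule : str or tuple of (n_maps, map_side)
        A named layer schedule (one of ``empick.network.SCHEDULES``) or an
        explicit six-entry C1..S6 table; "desk64" is the 64-pixel default.
    box_side : int or None
        Required only with an explicit schedule tuple; ignored for named
        schedules.
    activation : str
        Hidden activation ("sigmoid" or "relu"); the output unit is always
        sigmoid.
    eta : float
        Learning rate of the gradient update (default 1).
    max_epochs, target_accuracy : training loop bounds; training stops when
        held-out accuracy at threshold 0.5 reaches target_accuracy.
    batch_size : None for full-batch gradient descent, else mini-batch size.
    init : "symmetric" (fan-in scaled, the trainable default) or "uniform01".
    validation_fraction : share of the originals held out for the accuracy
        stopping signal (split before augmentation, so no rotated copy of a
        validation box leaks into training).
    augment : quadruple the training data with 90/180/270-degree rotations.
    random_state : seed for initialization, splitting and batching.

    Attributes
    ----------
    state_ : NetworkState — the trained weights and biases.
    report_ : TrainingReport — per-epoch losses, held-out accuracies.
    classes_ : array([0, 1]).
    """

    def __init__(self, schedule="desk64", box_side=None, activation="sigmoid",
                 normalize_input=True, shared_bias=False, eta=1.0,
                 max_epochs=60, target_accuracy=0.95, batch_size=32,
                 init="symmetric", validation_fraction=0.25, augment=True,
                 random_state=0):
        self.schedule = schedule
        self.box_side = box_side
        self.activation = activation
        self.normalize_input = normalize_input
        self.shared_bias = shared_bias
        self.eta = eta
        self.max_epochs = max_epochs
        self.target_accuracy = target_accuracy
        self.batch_size = batch_size
        self.init = init
        self.validation_fraction = validation_fraction
        self.augment = augment
        self.random_state = random_state

    # -- configuration ----------------------------------------------------
    def _make_config(self) -> NetworkConfig:
        if isinstance(self.schedule, str):
            base = SCHEDULES[self.schedule]
            return NetworkConfig(
                box_side=base.box_side, schedule=base.schedule,
                activation=self.activation,
                normalize_input=self.normalize_input,
                shared_bias=self.shared_bias)
        if self.box_side is None:
            raise ValueError("box_side is required with an explicit schedule")
        return NetworkConfig(
            box_side=self.box_side, schedule=tuple(tuple(p) for p in self.schedule),
            activation=self.activation, normalize_input=self.normalize_input,
            shared_bias=self.shared_bias)

    def _boxes(self, X, side) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:  # flattened rows
            X = X.reshape(X.shape[0], side, side)
        if X.ndim != 3 or X.shape[1] != side or X.shape[2] != side:
            raise ValueError(f"X must be (n, {side}, {side}) boxes")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        config = self._make_config()
        X = self._boxes(X, config.box_side)
        y = np.asarray(y).ravel().astype(int)
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("targets must be 0 (non-particle) or 1 (particle)")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = config.box_side ** 2

        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(X.shape[0])
        n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if tr_idx.size == 0:
            raise ValueError("not enough samples to split off a validation set")

        def to_samples(idx, tag):
            return [training.TrainingSample(
                        box=X[i], target=int(y[i]),
                        origin=training.BoxOrigin(tag, i, 0))
                    for i in idx]

        tr = to_samples(tr_idx, "fit")
        va = to_samples(val_idx, "fit")
        if self.augment:
            train_set = training.augment_rotations(tr)
        else:
            train_set = training.TrainingSet(
                tr, sum(s.target for s in tr), sum(1 - s.target for s in tr))
        # validation scoring is rotation-averaged, so augmenting the
        # validation set would only repeat each sample's identical score
        val_set = training.TrainingSet(
            va, sum(s.target for s in va), sum(1 - s.target for s in va))

        self.state_, self.report_ = training.train(
            train_set, val_set, config, eta=self.eta,
            max_epochs=self.max_epochs, target_accuracy=self.target_accuracy,
            seed=self.random_state, batch_size=self.batch_size, init=self.init)
        return self

    def decision_function(self, X):
        """Rotation-averaged network scores in (0, 1)."""
        self._check_fitted()
        X = self._boxes(X, self.state_.config.box_side)
        return training._rotation_averaged_scores(X, self.state_)

    def predict_proba(self, X):
        p1 = self.decision_function(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0.5).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "state_"):
            raise AttributeError("this CNNParticleClassifier is not fitted yet")


class ParticlePicker(BaseEstimator):
    """Threshold-calibrated particle picker over a trained classifier.

    fit() traces the precision-recall curve on labeled micrographs and sets
    the picking threshold at the F2 maximum; predict() raster-scans new
    micrographs and returns the selected candidates.

    Parameters: classifier (a fitted CNNParticleClassifier or a raw
    NetworkState), stride (raster step, px), nms_radius (local-maximum
    radius, px, default box_side/2), std_k (pixel-std band half-width in
    candidate-population sigmas; None disables the filter), beta (F-measure
    weight, default 2), thresholds (calibration grid, default 50 values in
    (0,1)), match_tolerance (hit distance, px, default box_side/4).

    Attributes: threshold_, curve_ (PRCurve from calibration).
    """

    def __init__(self, classifier=None, stride=4, nms_radius=None,
                 std_k=2.0, beta=2.0, thresholds=None, match_tolerance=None):
        self.classifier = classifier
        self.stride = stride
        self.nms_radius = nms_radius
        self.std_k = std_k
        self.beta = beta
        self.thresholds = thresholds
        self.match_tolerance = match_tolerance

    def _state(self):
        if self.classifier is None:
            raise ValueError("ParticlePicker needs a trained classifier")
        if isinstance(self.classifier, net.NetworkState):
            return self.classifier
        self.classifier._check_fitted()
        return self.classifier.state_

    def fit(self, micrographs, truths):
        """Calibrate the threshold at the F2 peak over labeled micrographs.

        truths[i] lists the ground-truth box corner coordinates of
        micrographs[i].
        """
        state = self._state()
        self.curve_ = evaluation.pr_curve(
            micrographs, truths, state, thresholds=self.thresholds,
            beta=self.beta, tolerance=self.match_tolerance,
            stride=self.stride, nms_radius=self.nms_radius, std_k=self.std_k)
        self.threshold_ = evaluation.select_threshold(self.curve_)
        return self

    def predict(self, micrograph, threshold=None):
        """Pick particles from one micrograph; returns a Candidate list."""
        state = self._state()
        if threshold is None:
            if not hasattr(self, "threshold_"):
                raise AttributeError(
                    "no threshold: fit() the picker or pass threshold=")
            threshold = self.threshold_
        return recognition.pick(
            micrograph, state, threshold=threshold, stride=self.stride,
            nms_radius=self.nms_radius, std_k=self.std_k)
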
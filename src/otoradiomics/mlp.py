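"""Multi-layer-perceptron classifier on principal-component scores.

One hidden layer of 500 ReLU units trained with Adam at learning rate 0.001,
full-batch gradients, and early stopping on an internal stratified
validation split carved from the training data (never the test set).
scikit-learn's ``MLPClassifier`` provides the optimizer; for two classes its
single logistic output unit yields the same class-1 probability as a
two-unit softmax head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier

__all__ = ["MLPConfig", "TrainedModel", "train", "predict_proba"]


@dataclass
class MLPConfig:
    """Classifier hyperparameters (study defaults)."""

    hidden_units: int = 500
    learning_rate: float = 0.001
    max_epochs: int = 1000
    patience: int = 20
    validation_fraction: float = 0.1
    early_stopping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class TrainedModel:
    """Fitted network plus its training history."""

    estimator: MLPClassifier
    config: MLPConfig
    loss_curve: tuple[float, ...]
    validation_scores: tuple[float, ...]
    stop_epoch: int

    @property
    def weights(self) -> list[np.ndarray]:
        return list(self.estimator.coefs_)

    @property
    def biases(self) -> list[np.ndarray]:
        return list(self.estimator.intercepts_)


def train(scores: np.ndarray, labels: np.ndarray, config: MLPConfig | None = None) -> TrainedModel:
    """Train the MLP on component scores.  Deterministic given config.seed."""
    config = config or MLPConfig()
    x = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2:
        raise ValueError("scores must be 2D (samples x components)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite inputs")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    est = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.max_epochs,
        early_stopping=config.early_stopping,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.patience,
        # full-batch gradients (minus the internal validation split)
        batch_size=len(y) - (int(np.ceil(len(y) * config.validation_fraction))
                             if config.early_stopping else 0),
        random_state=config.seed,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", category=ConvergenceWarning)
        est.fit(x, y)
    val_scores = tuple(est.validation_scores_) if config.early_stopping else ()
    return TrainedModel(
        estimator=est,
        config=config,
        loss_curve=tuple(est.loss_curve_),
        validation_scores=val_scores,
        stop_epoch=int(est.n_iter_),
    )


def predict_proba(model: TrainedModel, scores: np.ndarray) -> np.ndarray:
    """Class probability matrix, columns ordered (control=0, patient=1)."""
    x = np.asarray(scores, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != model.estimator.coefs_[0].shape[0]:
        raise ValueError(
            f"dimension mismatch: model expects {model.estimator.coefs_[0].shape[0]} "
            f"inputs, got {x.shape}"
        )
    return model.estimator.predict_proba(x)
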
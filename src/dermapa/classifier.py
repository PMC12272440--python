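"""Per-sample spectral classification with a small 1D convolutional network.

One model instance is trained per sample, on that sample's own K-means
generated training spectra only -- there is no cross-sample transfer, which
sidesteps inter-individual spectral variability entirely.  The network
convolves across the wavelength axis of a single pixel spectrum at a time
and outputs the probability that the pixel is tumorous; a probability in
[0, 0.5] reads as healthy and above 0.5 as non-healthy.  The convolution
kernel is kept wide enough (odd widths in [3, 15] samples) not to latch onto
spectral noise, yet narrow enough to preserve the one distinguishing
feature expected of melanoma spectra: a steeper rise toward short
wavelengths.

Spectra are standardized per wavelength with statistics fit on the training
set alone (stored in the model); this conditions the optimisation while
preserving the inter-class amplitude contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._convnet import ConvNet1D, TrainingHistory
from .core_io import PAVolume
from .labeling import (BACKGROUND, HEALTHY, NONHEALTHY, UNLABELED, LabelMap,
                       TrainingSet)

__all__ = [
    "ClassifierSpec", "SpectralConvNetClassifier", "TrainedClassifier",
    "ProbabilityMap", "train_classifier", "predict_map", "classify",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of the per-sample spectral network.

    Defaults: conv(16 filters, kernel 9) -> ReLU -> maxpool(2) ->
    conv(32, kernel 5) -> ReLU -> global average pool -> dense(16, ReLU) ->
    dense(1, sigmoid); Adam 1e-3, batch 32, up to 200 epochs with early
    stopping (patience 20) on a 20% validation split.
    """

    conv_filters: tuple[int, ...] = (16, 32)
    kernel_sizes: tuple[int, ...] = (9, 5)
    pool_sizes: tuple[int, ...] = (2, 1)
    dense_units: tuple[int, ...] = (16,)
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    min_delta: float = 1e-4
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for k in self.kernel_sizes:
            if k % 2 == 0 or not (3 <= k <= 15):
                raise ValueError("kernel widths must be odd and within [3, 15]")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in (0, 1)")


class SpectralConvNetClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style estimator around the numpy 1D conv net.

    ``fit(X, y)`` takes an ``(n, n_wavelengths)`` spectra matrix and binary
    labels; fitted attributes are ``net_`` (the trained network), ``scale_``
    / ``mean_`` (per-wavelength standardization fit on the training data)
    and ``history_``.  ``predict_proba`` returns calibrated-range
    probabilities in [0, 1]; ``predict`` applies the 0.5 cut with ties
    (p == 0.5) going to the healthy class.
    """

    def __init__(
        self,
        conv_filters=(16, 32),
        kernel_sizes=(9, 5),
        pool_sizes=(2, 1),
        dense_units=(16,),
        learning_rate=1e-3,
        batch_size=32,
        max_epochs=200,
        patience=20,
        min_delta=1e-4,
        validation_fraction=0.2,
        random_state=0,
    ):
        self.conv_filters = conv_filters
        self.kernel_sizes = kernel_sizes
        self.pool_sizes = pool_sizes
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_spectra, n_wavelengths)")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean_) / self.scale_
        self.net_ = ConvNet1D(
            input_len=X.shape[1],
            conv_filters=self.conv_filters,
            kernel_sizes=self.kernel_sizes,
            pool_sizes=self.pool_sizes,
            dense_units=self.dense_units,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            min_delta=self.min_delta,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
        )
        self.history_ = self.net_.fit(Xs, y.astype(float))
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"spectra have {X.shape[1]} wavelengths, model expects "
                f"{self.n_features_in_}"
            )
        p1 = self.net_.predict_proba((X - self.mean_) / self.scale_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


@dataclass
class TrainedClassifier:
    """A fitted per-sample model: spec, weights, scaler and history."""

    spec: ClassifierSpec
    estimator: SpectralConvNetClassifier
    history: TrainingHistory
    n_wavelengths: int
    seed: int

    def predict_proba(self, spectra: np.ndarray) -> np.ndarray:
        """Tumor probability in [0, 1] for each spectrum."""
        return self.estimator.predict_proba(np.asarray(spectra, dtype=float))[:, 1]


@dataclass
class ProbabilityMap:
    """Per-pixel tumor probability on the sample grid.

    ``prob`` is NaN on background pixels (they carry no probability);
    ``valid`` marks pixels with a defined probability.
    """

    prob: np.ndarray
    valid: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.prob.shape != self.valid.shape:
            raise ValueError("prob and valid shapes differ")
        p = self.prob[self.valid]
        if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise ValueError("probabilities must lie in [0, 1]")


def train_classifier(ts: TrainingSet, spec: ClassifierSpec | None = None) -> TrainedClassifier:
    """Train a per-sample model on a balanced training set.

    Requires at least 20 points per class; training is deterministic given
    the spec seed (initialisation, shuffling and validation split all derive
    from it).
    """
    spec = spec or ClassifierSpec()
    if ts.n_per_class < 20:
        raise ValueError(
            f"need >= 20 training points per class, got {ts.n_per_class}"
        )
    est = SpectralConvNetClassifier(
        conv_filters=spec.conv_filters,
        kernel_sizes=spec.kernel_sizes,
        pool_sizes=spec.pool_sizes,
        dense_units=spec.dense_units,
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        max_epochs=spec.max_epochs,
        patience=spec.patience,
        min_delta=spec.min_delta,
        validation_fraction=spec.validation_fraction,
        random_state=spec.seed,
    )
    est.fit(ts.spectra, ts.labels)
    return TrainedClassifier(spec=spec, estimator=est, history=est.history_,
                             n_wavelengths=ts.spectra.shape[1], seed=spec.seed)


def predict_map(model: TrainedClassifier, pa: PAVolume,
                label_map: LabelMap) -> ProbabilityMap:
    """Predict a tumor probability for every non-background pixel.

    Cluster-labeled pixels are predicted too (useful for map comparison),
    but :func:`classify` leaves their final class to the clustering; the
    network decides only the unlabeled band.
    """
    if pa.data.shape[3] != model.n_wavelengths:
        raise ValueError(
            f"volume has {pa.data.shape[3]} wavelengths, model expects "
            f"{model.n_wavelengths}"
        )
    if label_map.labels.shape != pa.spatial_shape:
        raise ValueError("label map and volume shapes do not match")
    valid = label_map.labels != BACKGROUND
    prob = np.full(pa.spatial_shape, np.nan)
    if valid.any():
        prob[valid] = model.predict_proba(pa.data[valid])
    return ProbabilityMap(prob=prob, valid=valid, threshold=0.5)


def classify(pmap: ProbabilityMap, label_map: LabelMap,
             threshold: float = 0.5) -> LabelMap:
    """Resolve the unlabeled band into healthy / non-healthy.

    Pixels with p <= threshold become healthy (the 0-0.5 interval is
    inclusive), p > threshold non-healthy; pixels already labeled by the
    clustering keep their cluster label.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    final = label_map.copy()
    unl = final.labels == UNLABELED
    if unl.any():
        p = pmap.prob[unl]
        if np.isnan(p).any():
            raise ValueError("unlabeled pixels lack predicted probabilities")
        final.labels[unl] = np.where(p > threshold, NONHEALTHY, HEALTHY)
    return final


# --------------------------------------------------------------------------
# model serialization (spec + scaler + weights + seed in one npz)
# --------------------------------------------------------------------------

def save_model(model: TrainedClassifier, path: str | Path) -> Path:
    path = Path(path)
    payload = {f"w__{k}": v for k, v in model.estimator.net_.get_weights().items()}
    payload["mean"] = model.estimator.mean_
    payload["scale"] = model.estimator.scale_
    payload["spec_json"] = np.frombuffer(
        json.dumps(asdict(model.spec)).encode(), dtype=np.uint8)
    payload["n_wavelengths"] = np.array([model.n_wavelengths])
    np.savez(path, **payload)
    return path


def load_model(path: str | Path) -> TrainedClassifier:
    with np.load(path) as fh:
        spec_dict = json.loads(bytes(fh["spec_json"]).decode())
        for key in ("conv_filters", "kernel_sizes", "pool_sizes", "dense_units"):
            spec_dict[key] = tuple(spec_dict[key])
        spec = ClassifierSpec(**spec_dict)
        n_wavelengths = int(fh["n_wavelengths"][0])
        est = SpectralConvNetClassifier(
            conv_filters=spec.conv_filters, kernel_sizes=spec.kernel_sizes,
            pool_sizes=spec.pool_sizes, dense_units=spec.dense_units,
            learning_rate=spec.learning_rate, batch_size=spec.batch_size,
            max_epochs=spec.max_epochs, patience=spec.patience,
            min_delta=spec.min_delta,
            validation_fraction=spec.validation_fraction, random_state=spec.seed,
        )
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = n_wavelengths
        est.mean_ = fh["mean"]
        est.scale_ = fh["scale"]
        est.net_ = ConvNet1D(
            input_len=n_wavelengths, conv_filters=spec.conv_filters,
            kernel_sizes=spec.kernel_sizes, pool_sizes=spec.pool_sizes,
            dense_units=spec.dense_units, seed=spec.seed,
        )
        est.net_.set_weights({k[3:]: fh[k] for k in fh.files if k.startswith("w__")})
        est.history_ = TrainingHistory()
    return TrainedClassifier(spec=spec, estimator=est, history=est.history_,
                             n_wavelengths=n_wavelengths, seed=spec.seed)
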
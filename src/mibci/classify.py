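"""The three classifier families and their training protocol.

Two compact convolutional networks operating on band-passed, rescaled raw
windows — one whose first learnable layer is a full-channel spatial filter
(the load-bearing architectural choice for multichannel motor imagery), one
whose first layer filters each channel independently in time — and a
frequency-domain route: Welch-PSD features into an SVM with a cubic
polynomial kernel. Training follows a fixed protocol: batch size 64, at most
200 epochs, early stopping when validation accuracy stalls for 20 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from mibci import nn
from mibci.features import FeatureMatrix
from mibci.preprocess import EpochSet
from mibci.simulate import CLASSES


class FingerprintMismatchError(RuntimeError):
    """Inputs do not match the preprocessing the model was trained with."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture + training hyperparameters for one classifier family."""

    family: str  # spatial_cnn | standard_cnn | psda_svm
    channels: int = 6
    samples: int = 1000
    n_classes: int = 4
    hyper: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("spatial_cnn", "standard_cnn", "psda_svm"):
            raise ValueError(f"unknown family {self.family!r}")


_CNN_DEFAULTS = {
    "spatial_filters": 12,
    "temporal_filters": 24,
    "kernel": 16,
    "pool": 4,
    "dropout": 0.25,
    "batch_size": 64,
    "max_epochs": 200,
    "patience": 20,
    "lr": 1e-3,
}


def build_spatial_cnn(
    channels: int = 6, samples: int = 1000, n_classes: int = 4, **hyper: Any
) -> ModelSpec:
    """Spatial-first CNN: layer 1 mixes ALL channels into virtual channels.

    Stack: spatial convolution (kernel channels×1, F1 maps) → BN → ELU →
    two temporal blocks (same-padded convolution, BN, ELU, average pool,
    dropout) → dense softmax. Pool sizes leave a non-empty time axis down to
    1 s windows at 250 Hz.
    """
    if samples < 64:
        raise ValueError(f"samples must be >= 64, got {samples}")
    h = {**_CNN_DEFAULTS, **hyper}
    return ModelSpec("spatial_cnn", channels, samples, n_classes, h)


def build_standard_cnn(
    channels: int = 6, samples: int = 1000, n_classes: int = 4, **hyper: Any
) -> ModelSpec:
    """Temporal-first CNN: layer 1 has spatial extent 1 (no channel mixing).

    Identical budget and block structure to the spatial CNN except the first
    learnable layer is a depthwise temporal convolution, isolating the
    presence/absence of an initial full-channel spatial kernel.
    """
    if samples < 64:
        raise ValueError(f"samples must be >= 64, got {samples}")
    h = {**_CNN_DEFAULTS, **hyper}
    return ModelSpec("standard_cnn", channels, samples, n_classes, h)


def instantiate_cnn(spec: ModelSpec, seed: int = 0) -> nn.Network:
    """Build the network with seeded weight initialization.

    Both families share the temporal trunk: a band-forming temporal
    convolution whose activations are squared and average-pooled
    (instantaneous band power — the quantity ERD/ERS modulates) and
    log-compressed, then a second temporal block (convolution, BN, ELU,
    pooling) over the power envelope, then a dense softmax. They differ only
    in layer 1: a full-channel spatial convolution versus per-channel
    (depthwise) temporal filters.
    """
    rng = np.random.default_rng(seed)
    h = spec.hyper
    f1, f2 = h["spatial_filters"], h["temporal_filters"]
    k, drop = h["kernel"], h["dropout"]
    p1, p2 = h["pool"] * 2, h["pool"]
    t = spec.samples
    layers: list[nn.Layer] = []
    if spec.family == "spatial_cnn":
        # virtual channels from a full-channel spatial filter, then a trunk
        # of dense temporal convolutions over all maps
        layers += [
            nn.SpatialConv(spec.channels, f1, rng),
            nn.BatchNorm(f1),
            nn.TemporalConv(f1, f2, k, rng),
            nn.BatchNorm(f2),
            nn.Square(),
            nn.AvgPool(p1),
            nn.Log(),
            nn.Dropout(drop),
            nn.TemporalConv(f2, f2, max(k // 2, 2), rng),
            nn.BatchNorm(f2),
            nn.ELU(),
            nn.AvgPool(p2),
            nn.Dropout(drop),
        ]
        width = f2
    else:
        # image-style CNN with 1×k kernels: every convolution has spatial
        # extent 1, so channels stay separate until the dense readout
        mult = max(1, f1 // spec.channels) * 2
        width = spec.channels * mult
        layers += [
            nn.DepthwiseTemporalConv(spec.channels, mult, k, rng),
            nn.BatchNorm(width),
            nn.DepthwiseTemporalConv(width, 1, k, rng),
            nn.BatchNorm(width),
            nn.Square(),
            nn.AvgPool(p1),
            nn.Log(),
            nn.Dropout(drop),
            nn.DepthwiseTemporalConv(width, 1, max(k // 2, 2), rng),
            nn.BatchNorm(width),
            nn.ELU(),
            nn.AvgPool(p2),
            nn.Dropout(drop),
        ]
    t = (t // p1) // p2
    if t < 1:
        raise ValueError("pooling exhausted the time axis")
    layers += [nn.Flatten(), nn.Dense(width * t, spec.n_classes, rng)]
    net = nn.Network(layers)
    if net.n_params() >= 10**6:
        raise ValueError("parameter budget exceeded")
    return net


@dataclass
class TrainedClassifier:
    """A fitted model plus the preprocessing fingerprint needed to apply it.

    ``fingerprint`` records fs, band, window length and rescale flag;
    :func:`predict` refuses inputs that disagree with it.
    """

    family: str
    model: Any  # nn.Network or sklearn Pipeline
    spec: ModelSpec | None
    fingerprint: dict[str, Any]
    label_map: tuple[str, ...]
    history: list[float] = field(default_factory=list)

    def _check(self, fs: float, window_length_s: float) -> None:
        if abs(fs - self.fingerprint["fs"]) > 1e-9:
            raise FingerprintMismatchError(
                f"model trained at fs={self.fingerprint['fs']}, got {fs}"
            )
        if abs(window_length_s - self.fingerprint["window_length_s"]) > 1e-9:
            raise FingerprintMismatchError(
                f"model trained on {self.fingerprint['window_length_s']} s windows, "
                f"got {window_length_s} s"
            )


def _encode(labels: np.ndarray, label_map: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(label_map)}
    try:
        return np.asarray([index[l] for l in labels])
    except KeyError as e:
        raise ValueError(f"unknown class label {e.args[0]!r}") from None


def _label_map_for(labels: np.ndarray) -> tuple[str, ...]:
    present = set(labels.tolist())
    ordered = [c for c in CLASSES if c in present]
    ordered += sorted(present - set(CLASSES))
    return tuple(ordered)


def train_cnn(
    spec: ModelSpec,
    train: EpochSet,
    val: EpochSet,
    seed: int = 0,
    rescaled: bool = True,
) -> TrainedClassifier:
    """Fit a CNN spec on rescaled windows with early stopping.

    ``val`` drives the stopping rule; the best-validation-epoch parameters
    are returned. Deterministic given ``seed``.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty train or validation split")
    if set(train.labels.tolist()) != set(val.labels.tolist()):
        raise ValueError("train and validation label sets differ")
    label_map = _label_map_for(train.labels)
    y_train = _encode(train.labels, label_map)
    y_val = _encode(val.labels, label_map)
    net = instantiate_cnn(spec, seed)
    h = spec.hyper
    res = net.fit(
        train.windows,
        y_train,
        val.windows,
        y_val,
        batch_size=h["batch_size"],
        max_epochs=h["max_epochs"],
        patience=h["patience"],
        lr=h["lr"],
        seed=seed + 1,
    )
    return TrainedClassifier(
        family=spec.family,
        model=net,
        spec=spec,
        fingerprint={
            "fs": train.fs,
            "window_length_s": train.window_spec.length_s,
            "rescaled": rescaled,
            "band": (4.0, 33.0),
        },
        label_map=label_map,
        history=res.history,
    )


def train_svm_psda(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    C: float = 1.0,
    degree: int = 3,
    coef0: float = 1.0,
) -> TrainedClassifier:
    """Cubic-polynomial-kernel SVM on PSDA features (one-vs-one multiclass).

    The kernel is the conventional inhomogeneous cubic ``(γ⟨x, x'⟩ + 1)³``
    (``coef0=1``); the homogeneous variant (``coef0=0``) discards all
    lower-order terms and classifies these features poorly. Feature
    standardization is fitted on the training data only and stored with the
    model.
    """
    y = features.labels if labels is None else np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least two classes to train an SVM")
    label_map = _label_map_for(y)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="poly",
                    degree=degree,
                    C=C,
                    coef0=coef0,
                    decision_function_shape="ovr",
                ),
            ),
        ]
    )
    pipe.fit(features.X, _encode(y, label_map))
    return TrainedClassifier(
        family="psda_svm",
        model=pipe,
        spec=None,
        fingerprint={
            "fs": features.fs,
            "window_length_s": features.window_length_s,
            "rescaled": True,
            "band": (float(features.freqs[0]), float(features.freqs[-1])),
        },
        label_map=label_map,
    )


def predict(
    clf: TrainedClassifier, data: EpochSet | FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class scores for each window.

    Scores are softmax probabilities for the CNNs and one-vs-rest decision
    values for the SVM. Argmax ties break toward the lowest class index.
    """
    if clf.family in ("spatial_cnn", "standard_cnn"):
        if not isinstance(data, EpochSet):
            raise FingerprintMismatchError("CNN families predict on EpochSet windows")
        clf._check(data.fs, data.window_spec.length_s)
        scores = clf.model.predict_proba(data.windows)
    else:
        if not isinstance(data, FeatureMatrix):
            raise FingerprintMismatchError("psda_svm predicts on a FeatureMatrix")
        clf._check(data.fs, data.window_length_s)
        scores = clf.model.decision_function(data.X)
        if scores.ndim == 1:  # binary
            scores = np.stack([-scores, scores], axis=1)
    idx = scores.argmax(axis=1)
    labels = np.asarray([clf.label_map[i] for i in idx], dtype=object)
    return labels, scores
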
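"""3D convolutional classifier for labeled brain volumes.

The default architecture is a VGG-style stack of five convolutional layers
(filter schedule 11/5/3/3/3, stride 4 on the first layer) each followed by
2x2x2 max pooling, a global-average-pooling (GAP) layer, and a two-node
softmax output.  GAP acts as a structural regularizer: each final feature map
is collapsed to its spatial mean before classification, which keeps the head
small and ties class evidence to whole feature maps.  A three-layer
fully-connected head is available as a configuration option.

Labels follow the disease-study convention: 1 is the disease (positive)
class, 0 is control.  Sensitivity and specificity are reported with the
disease class as positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .augment import AugmentationConfig, augment_dataset
from .synthetic import ValidationError


class ConfigurationError(ValueError):
    """Architecture/input mismatch; the message names the offending layer."""


#: (filter_size, stride_xy, stride_z, out_channels) per convolutional layer.
DEFAULT_CONV_SPECS = ((11, 4, 4, 16), (5, 1, 1, 32), (3, 1, 1, 64),
                      (3, 1, 1, 64), (3, 1, 1, 64))


@dataclass(frozen=True)
class ArchitectureConfig:
    conv_specs: tuple[tuple[int, int, int, int], ...] = DEFAULT_CONV_SPECS
    n_maxpool: int = 5
    gap: bool = True
    n_output: int = 2
    #: hidden widths of the fully-connected head used when gap=False
    fc_widths: tuple[int, int] = (128, 64)
    #: first conv is 'valid', deeper convs 'same' so small grids survive
    first_padding: str = "valid"

    def __post_init__(self):
        if self.n_output < 2:
            raise ValidationError(f"n_output must be >= 2, got {self.n_output}")
        if self.n_maxpool > len(self.conv_specs):
            raise ValidationError("n_maxpool cannot exceed the number of conv layers")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 8


@dataclass
class EvalMetrics:
    """Accuracy, sensitivity, specificity, AUC — disease class positive.

    A metric whose defining class is absent from the evaluation set is
    reported as None (missing), never as 0.
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    n: int = 0
    fold: int | None = None

    def as_dict(self):
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc, "n": self.n}


class VolumeClassifier:
    """A trained (or untrained) network over single-channel 3D volumes."""

    def __init__(self, net: nn.Sequential, input_shape, cfg: ArchitectureConfig):
        self.net = net
        self.input_shape = tuple(input_shape)
        self.cfg = cfg

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def forward_logits(self, volumes: np.ndarray) -> np.ndarray:
        x = np.asarray(volumes, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        return self.net.forward(x[:, None], train=False)

    def predict_proba(self, volumes: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Per-class probabilities, rows summing to 1."""
        x = np.asarray(volumes, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        out = []
        for i in range(0, len(x), batch_size):
            out.append(nn.softmax(self.net.forward(x[i:i + batch_size, None])))
        return np.concatenate(out)

    def predict_disease_probability(self, volumes, batch_size: int = 32):
        return self.predict_proba(volumes, batch_size=batch_size)[:, 1]


def build_classifier(cfg: ArchitectureConfig | None = None,
                     input_shape=(91, 109, 91), seed: int = 0) -> VolumeClassifier:
    """Assemble the network and validate the layer schedule against the grid.

    Raises ``ConfigurationError`` naming the first layer whose (valid)
    convolution does not fit the incoming spatial extent.
    """
    cfg = cfg or ArchitectureConfig()
    rng = np.random.default_rng(seed)
    layers: list[nn.layers.Layer] = []
    spatial = tuple(int(s) for s in input_shape)
    channels = 1
    for i, (k, sxy, sz, out_ch) in enumerate(cfg.conv_specs):
        padding = cfg.first_padding if i == 0 else "same"
        conv = nn.Conv3D(channels, out_ch, k, stride=(sxy, sxy, sz),
                         padding=padding, rng=rng, name=f"conv{i + 1}")
        try:
            spatial = conv.out_shape(spatial)
        except ValueError as e:
            raise ConfigurationError(str(e)) from e
        layers.append(conv)
        layers.append(nn.ReLU())
        if i < cfg.n_maxpool:
            layers.append(nn.MaxPool3D())
            spatial = tuple(-(-s // 2) for s in spatial)  # ceil-mode pooling
        channels = out_ch
    if cfg.gap:
        layers.append(nn.GlobalAveragePool())
        feat = channels
        layers.append(nn.Dense(feat, cfg.n_output, rng))
    else:
        layers.append(nn.Flatten())
        feat = channels * int(np.prod(spatial))
        for w in cfg.fc_widths:
            layers.append(nn.Dense(feat, w, rng))
            layers.append(nn.ReLU())
            feat = w
        layers.append(nn.Dense(feat, cfg.n_output, rng))
    return VolumeClassifier(nn.Sequential(layers), input_shape, cfg)


def train_classifier(model: VolumeClassifier, volumes, labels,
                     train_cfg: TrainConfig | None = None, seed: int = 0):
    """Train in place with Adam on softmax cross-entropy.

    Returns ``(model, log)`` where ``log`` is the per-epoch mean loss.  With
    ``epochs=0`` the model is returned untouched.  Deterministic for a fixed
    seed (pure numpy backend).
    """
    train_cfg = train_cfg or TrainConfig()
    volumes = np.asarray(volumes, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValidationError("training requires at least two classes present")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.net.params(), lr=train_cfg.learning_rate)
    log: list[float] = []
    n = len(volumes)
    for _ in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, train_cfg.batch_size):
            idx = order[i:i + train_cfg.batch_size]
            logits = model.net.forward(volumes[idx][:, None], train=True)
            loss, grad = nn.cross_entropy_grad(logits, labels[idx])
            model.net.backward(grad)
            opt.step()
            losses.append(loss)
        log.append(float(np.mean(losses)))
    return model, log


def evaluate(model: VolumeClassifier, volumes, labels) -> EvalMetrics:
    """Accuracy, sensitivity (TP/(TP+FN)), specificity (TN/(TN+FP)), rank AUC."""
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be binary (0=control, 1=disease)")
    proba = model.predict_disease_probability(volumes)
    pred = (proba >= 0.5).astype(int)
    accuracy = float((pred == labels).mean())
    pos, neg = labels == 1, labels == 0
    sensitivity = float(pred[pos].mean()) if pos.any() else None
    specificity = float(1 - pred[neg].mean()) if neg.any() else None
    auc = float(roc_auc_score(labels, proba)) if pos.any() and neg.any() else None
    return EvalMetrics(accuracy, sensitivity, specificity, auc, n=len(labels))


def save_classifier(model: VolumeClassifier, path):
    """Persist weights + architecture to an .npz archive."""
    import json

    cfg = model.cfg
    meta = json.dumps({
        "conv_specs": [list(c) for c in cfg.conv_specs],
        "n_maxpool": cfg.n_maxpool, "gap": cfg.gap, "n_output": cfg.n_output,
        "fc_widths": list(cfg.fc_widths), "first_padding": cfg.first_padding,
        "input_shape": list(model.input_shape)})
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.net.params())}
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_classifier(path) -> VolumeClassifier:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    cfg = ArchitectureConfig(
        conv_specs=tuple(tuple(c) for c in meta["conv_specs"]),
        n_maxpool=meta["n_maxpool"], gap=meta["gap"], n_output=meta["n_output"],
        fc_widths=tuple(meta["fc_widths"]), first_padding=meta["first_padding"])
    model = build_classifier(cfg, input_shape=tuple(meta["input_shape"]))
    model.net.load_state(arrays)
    return model


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator):
    """Fold index per sample; per-class shuffled round-robin assignment."""
    folds = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < k:
            raise ValidationError(
                f"class {c} has {len(members)} members, fewer than k={k}")
        perm = rng.permutation(members)
        folds[perm] = np.arange(len(perm)) % k
    return folds


def crossvalidate(volumes, labels, k: int = 5, seed: int = 0, *,
                  cfg: ArchitectureConfig | None = None,
                  train_cfg: TrainConfig | None = None,
                  augment_cfg: AugmentationConfig | None = None,
                  subject_ids=None):
    """Stratified k-fold cross-validation with leak-free augmentation.

    Augmentation (when requested) runs inside each training fold only, so no
    augmented copy of a held-out subject ever reaches training.  Fold
    assignment and training order are canonicalized by subject id, making the
    result invariant to the ordering of the input arrays.

    Returns ``(per_fold_metrics, mean_metrics)``.
    """
    volumes = np.asarray(volumes, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(len(volumes))]
    subject_ids = np.asarray(subject_ids)
    order = np.argsort(subject_ids, kind="stable")
    volumes, labels, subject_ids = volumes[order], labels[order], subject_ids[order]

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, k, rng)
    per_fold = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        tr_vols, tr_labels = volumes[train], labels[train]
        tr_ids = list(subject_ids[train])
        if augment_cfg is not None:
            tr_vols, tr_labels, tr_ids = augment_dataset(
                tr_vols, tr_labels, augment_cfg, seed=seed + fold,
                subject_ids=tr_ids)
        assert set(tr_ids).isdisjoint(subject_ids[test])
        model = build_classifier(cfg, input_shape=volumes.shape[1:],
                                 seed=seed + fold)
        train_classifier(model, tr_vols, tr_labels, train_cfg, seed=seed + fold)
        m = evaluate(model, volumes[test], labels[test])
        m.fold = fold
        per_fold.append(m)

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    mean = EvalMetrics(
        accuracy=_mean([m.accuracy for m in per_fold]),
        sensitivity=_mean([m.sensitivity for m in per_fold]),
        specificity=_mean([m.specificity for m in per_fold]),
        auc=_mean([m.auc for m in per_fold]),
        n=len(labels))
    return per_fold, mean
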
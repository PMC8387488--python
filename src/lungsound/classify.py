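"""Classifier heads over frozen features, and the two-stage decision scheme.

Two heads are provided:

* ``cnn_one_layer`` (primary): a single 3x3 convolution (64 filters, ReLU)
  over the feature map, global average pooling, and a linear softmax layer,
  trained with Adam on class-weighted cross-entropy. Inverse-frequency class
  weights counter the strong normal-class imbalance of the emulated corpus.
* ``svm`` (comparison): flattened, standardized features into a linear-kernel
  SVM; pseudo-probabilities from a softmax over the decision scores.

The two-stage scheme first separates normal from abnormal, then assigns
abnormal segments to crackle/wheeze/rhonchus; composite probabilities follow
the product rule P(class) = P(abnormal) * P(class | abnormal). A flat 4-class
mode is also available.

Training is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .extract import FeatureMap

__all__ = [
    "TASK_CLASSES",
    "TrainConfig",
    "ClassifierHead",
    "PredictionSet",
    "DegenerateLabelsError",
    "NotTrainedError",
    "to_binary_labels",
    "train_head",
    "predict",
    "two_stage_predict",
    "aggregate_to_recording",
]

TASK_CLASSES = {
    "binary_normal_abnormal": ("normal", "abnormal"),
    "three_class_abnormal": ("crackle", "wheeze", "rhonchus"),
    "four_class_flat": ("normal", "crackle", "wheeze", "rhonchus"),
}


class DegenerateLabelsError(ValueError):
    """Fewer than two classes present in the training labels."""


class NotTrainedError(RuntimeError):
    """Prediction requested from an untrained head."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    n_filters: int = 64
    class_weighting: bool = True


@dataclass
class PredictionSet:
    """Per-segment probability vectors and hard labels for one task."""

    probs: np.ndarray  # (N, C), rows sum to 1
    labels: list[str]
    class_names: tuple[str, ...]
    segment_ids: list[str] = field(default_factory=list)


def to_binary_labels(labels) -> list[str]:
    """Collapse 4-class labels to the normal/abnormal dichotomy."""
    return ["normal" if lab == "normal" else "abnormal" for lab in labels]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _as_tensor_batch(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, np.ndarray):
        return features, [""] * len(features)
    if features and isinstance(features[0], FeatureMap):
        return (
            np.stack([f.tensor for f in features]),
            [f.segment_id for f in features],
        )
    return np.stack(features), [""] * len(features)


def _im2col_same(t: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N, H*W, 9C) patches for a same-padded 3x3 conv."""
    n, h, w, c = t.shape
    tp = np.pad(t, ((0, 0), (1, 1), (1, 1), (0, 0)))
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(tp, (3, 3), axis=(1, 2))  # (N, H, W, C, 3, 3)
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(n, h * w, 9 * c)


class _OneLayerCNN:
    """Numpy implementation: 3x3 conv (ReLU) -> GAP -> linear softmax.

    Patch matrices are built per minibatch so wide feature maps (e.g. 2048
    channels) never materialize an (N, positions, 9C) array at once.
    """

    def __init__(self, in_channels: int, n_classes: int, cfg: TrainConfig):
        rng = np.random.default_rng(cfg.seed)
        k = 9 * in_channels
        self.w1 = rng.standard_normal((k, cfg.n_filters)) * np.sqrt(2.0 / k)
        self.b1 = np.zeros(cfg.n_filters)
        self.w2 = rng.standard_normal((cfg.n_filters, n_classes)) * np.sqrt(
            1.0 / cfg.n_filters
        )
        self.b2 = np.zeros(n_classes)
        self.cfg = cfg

    def _forward(self, cols: np.ndarray):
        a = np.maximum(cols @ self.w1 + self.b1, 0.0)  # (N, P, F)
        g = a.mean(axis=1)  # (N, F)
        return a, g, _softmax(g @ self.w2 + self.b2)

    def predict_proba(self, t: np.ndarray, chunk: int = 16) -> np.ndarray:
        out = []
        for start in range(0, len(t), chunk):
            out.append(self._forward(_im2col_same(t[start : start + chunk]))[2])
        return np.concatenate(out)

    def fit(self, t, y_idx, weights, val=None):
        cfg = self.cfg
        n = len(t)
        n_classes = self.w2.shape[1]
        y1h = np.eye(n_classes)[y_idx]
        rng = np.random.default_rng(cfg.seed + 1)
        # Adam state
        params = ["w1", "b1", "w2", "b2"]
        m = {q: np.zeros_like(getattr(self, q)) for q in params}
        v = {q: np.zeros_like(getattr(self, q)) for q in params}
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        step = 0
        best = (-1.0, None)
        # cache patches up-front only when the array stays modest
        cols_all = _im2col_same(t) if t.shape[3] * n * t.shape[1] * t.shape[2] * 9 < 4e7 else None
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = cols_all[idx] if cols_all is not None else _im2col_same(t[idx])
                yb, wb = y1h[idx], weights[idx]
                p = xb.shape[1]
                a, g, probs = self._forward(xb)
                dlogits = (probs - yb) * wb[:, None] / len(idx)
                grads = {
                    "w2": g.T @ dlogits,
                    "b2": dlogits.sum(axis=0),
                }
                dg = dlogits @ self.w2.T  # (B, F)
                da = (dg[:, None, :] / p) * (a > 0)
                grads["w1"] = xb.reshape(-1, xb.shape[2]).T @ da.reshape(
                    -1, da.shape[2]
                )
                grads["b1"] = da.sum(axis=(0, 1))
                step += 1
                for q in params:
                    m[q] = b1m * m[q] + (1 - b1m) * grads[q]
                    v[q] = b2m * v[q] + (1 - b2m) * np.square(grads[q])
                    mh = m[q] / (1 - b1m**step)
                    vh = v[q] / (1 - b2m**step)
                    setattr(
                        self,
                        q,
                        getattr(self, q) - cfg.learning_rate * mh / (np.sqrt(vh) + eps),
                    )
            if val is not None:
                acc = float(
                    np.mean(self.predict_proba(val[0]).argmax(axis=1) == val[1])
                )
                if acc > best[0]:
                    best = (acc, {q: getattr(self, q).copy() for q in params})
        if val is not None and best[1] is not None:
            for q, arr in best[1].items():
                setattr(self, q, arr)
        return self


@dataclass
class ClassifierHead:
    """A trained (or trainable) classification head for one task."""

    kind: str  # cnn_one_layer | svm
    task: str
    train_config: TrainConfig
    classes: tuple[str, ...] = ()
    trained: bool = False
    _model: object = field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in ("cnn_one_layer", "svm"):
            raise ValueError(f"unknown head kind {self.kind!r}")
        if self.task not in TASK_CLASSES:
            raise ValueError(f"unknown task {self.task!r}")
        if not self.classes:
            self.classes = TASK_CLASSES[self.task]


def train_head(
    kind: str,
    task: str,
    features,
    labels,
    config: TrainConfig | None = None,
    validation=None,
) -> ClassifierHead:
    """Train a head on feature maps.

    ``validation``: optional (features, labels) pair; the CNN head then keeps
    the parameters of the epoch with the best validation accuracy.
    """
    cfg = config or TrainConfig()
    head = ClassifierHead(kind, task, cfg)
    classes = head.classes
    labels = list(labels)
    bad = set(labels) - set(classes)
    if bad:
        raise ValueError(f"labels {sorted(bad)} outside task classes {classes}")
    if len(set(labels)) < 2:
        raise DegenerateLabelsError(
            f"need at least 2 classes in training labels, got {set(labels)}"
        )
    t, _ = _as_tensor_batch(features)
    y_idx = np.array([classes.index(lab) for lab in labels])
    if cfg.class_weighting:
        # sklearn-style "balanced": w_c = n / (n_present_classes * freq_c)
        freq = np.bincount(y_idx, minlength=len(classes)).astype(float)
        present = freq > 0
        w_class = np.zeros(len(classes))
        w_class[present] = len(y_idx) / (present.sum() * freq[present])
        weights = w_class[y_idx]
    else:
        weights = np.ones(len(y_idx))
    if kind == "cnn_one_layer":
        model = _OneLayerCNN(t.shape[3], len(classes), cfg)
        val = None
        if validation is not None:
            vt, _ = _as_tensor_batch(validation[0])
            vy = np.array([classes.index(lab) for lab in validation[1]])
            val = (vt, vy)
        model.fit(t, y_idx, weights, val=val)
    else:
        flat = t.reshape(len(t), -1)
        model = make_pipeline(
            StandardScaler(),
            LinearSVC(C=1.0, class_weight="balanced" if cfg.class_weighting else None,
                      random_state=cfg.seed, max_iter=5000),
        )
        model.fit(flat, y_idx)
    head._model = model
    head.trained = True
    return head


def predict(head: ClassifierHead, features) -> PredictionSet:
    """Probabilities and argmax labels (ties break to the lowest class index)."""
    if not head.trained:
        raise NotTrainedError("head must be trained before prediction")
    t, seg_ids = _as_tensor_batch(features)
    if head.kind == "cnn_one_layer":
        probs = head._model.predict_proba(t)
    else:
        scores = head._model.decision_function(t.reshape(len(t), -1))
        if scores.ndim == 1:  # binary decision axis -> two-column scores
            scores = np.column_stack([-scores, scores])
        probs = _softmax(scores)
    idx = probs.argmax(axis=1)
    return PredictionSet(
        probs=probs,
        labels=[head.classes[i] for i in idx],
        class_names=head.classes,
        segment_ids=seg_ids,
    )


def two_stage_predict(
    stage1: ClassifierHead, stage2: ClassifierHead, features
) -> PredictionSet:
    """Normal-vs-abnormal gate, then abnormal subtype; product-rule composite.

    Composite probabilities over (normal, crackle, wheeze, rhonchus):
    P(normal) from stage 1; P(c) = P(abnormal) * P(c | abnormal) for each
    abnormal class, so the vector sums to one.
    """
    if stage1.task != "binary_normal_abnormal" or stage2.task != "three_class_abnormal":
        raise ValueError("stage1 must be the binary head, stage2 the 3-class head")
    p1 = predict(stage1, features)
    p2 = predict(stage2, features)
    i_norm = stage1.classes.index("normal")
    i_abn = 1 - i_norm
    classes = TASK_CLASSES["four_class_flat"]
    n = len(p1.probs)
    probs = np.empty((n, 4))
    probs[:, 0] = p1.probs[:, i_norm]
    for j, cls in enumerate(classes[1:]):
        probs[:, j + 1] = p1.probs[:, i_abn] * p2.probs[:, stage2.classes.index(cls)]
    gate_normal = p1.probs[:, i_norm] >= p1.probs[:, i_abn]
    labels = [
        "normal" if gate_normal[i] else p2.labels[i] for i in range(n)
    ]
    return PredictionSet(probs, labels, classes, p1.segment_ids)


def aggregate_to_recording(
    preds: PredictionSet, segment_to_recording: dict
) -> pd.DataFrame:
    """Mean segment probability vector per recording, then argmax.

    Raises KeyError for a segment without a parent recording.
    """
    rec_ids = []
    for sid in preds.segment_ids:
        if sid not in segment_to_recording:
            raise KeyError(f"segment {sid!r} has no parent recording")
        rec_ids.append(segment_to_recording[sid])
    df = pd.DataFrame(preds.probs, columns=list(preds.class_names))
    df["recording_id"] = rec_ids
    agg = df.groupby("recording_id", sort=True).mean()
    agg["label"] = [
        preds.class_names[i] for i in agg[list(preds.class_names)].to_numpy().argmax(axis=1)
    ]
    return agg.reset_index()
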
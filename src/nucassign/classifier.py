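"""Two-layer feed-forward purine/pyrimidine classifier on residue descriptors.

Architecture: 403 inputs -> fully connected 403 (ReLU) -> dropout ->
fully connected 2 (log-softmax).  Training minimizes the negative
log-likelihood with the ADAM optimizer; inference is deterministic
(dropout disabled).  Separate weight sets are trained per modality
(cryo-EM and MX maps differ in fine detail); both are instances of the
same architecture.  Implemented directly in numpy so trained models load
without a deep-learning runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .descriptor import CLOUD_SIZE, PURINE, PYRIMIDINE, ResidueDescriptor

CLASS_ORDER = (PURINE, PYRIMIDINE)   # output index 0, 1


@dataclass
class TrainingConfig:
    epochs: int = 1000
    batch_size: int = 20
    learning_rate: float = 1e-5
    dropout_p: float = 0.5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")


@dataclass
class LabeledDescriptor:
    descriptor: ResidueDescriptor
    label: str                      # PURINE | PYRIMIDINE

    def __post_init__(self):
        if self.label not in CLASS_ORDER:
            raise ValueError(f"label must be one of {CLASS_ORDER}")


@dataclass
class ClassifierModel:
    W1: np.ndarray                  # (403, 403)
    b1: np.ndarray                  # (403,)
    W2: np.ndarray                  # (2, 403)
    b2: np.ndarray                  # (2,)
    modality: str = "EM"            # "EM" | "MX"
    training_meta: dict = field(default_factory=dict)

    def log_proba(self, X: np.ndarray) -> np.ndarray:
        """Log-softmax class probabilities, rows = examples."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.W1.shape[1]:
            raise ValueError(f"descriptor length {X.shape[1]} != {self.W1.shape[1]}")
        h = np.maximum(X @ self.W1.T + self.b1, 0.0)
        logits = h @ self.W2.T + self.b2
        m = logits.max(axis=1, keepdims=True)
        return logits - (m + np.log(np.exp(logits - m).sum(axis=1, keepdims=True)))


def _zero_model(modality: str = "EM") -> ClassifierModel:
    return ClassifierModel(W1=np.zeros((CLOUD_SIZE, CLOUD_SIZE)), b1=np.zeros(CLOUD_SIZE),
                           W2=np.zeros((2, CLOUD_SIZE)), b2=np.zeros(2), modality=modality)


def _stack(data: list[LabeledDescriptor]):
    X = np.array([d.descriptor.values for d in data])
    y = np.array([CLASS_ORDER.index(d.label) for d in data])
    return X, y


def train_classifier(data: list[LabeledDescriptor],
                     config: TrainingConfig | None = None,
                     modality: str = "EM") -> ClassifierModel:
    """Train the MLP with ADAM on the negative log-likelihood.

    A seeded validation split is held out; train/validation accuracies
    are recorded every 10 epochs in ``training_meta``.  Identical data,
    config and seed give bit-identical weights.
    """
    config = config or TrainingConfig()
    X, y = _stack(data)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("training requires >= 2 examples of each class")
    rng = np.random.default_rng(config.seed)
    n = len(X)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, yt = X[train_idx], y[train_idx]
    Xv, yv = X[val_idx], y[val_idx]

    d_in = X.shape[1]
    # seeded Glorot-style uniform init
    lim1 = np.sqrt(6.0 / (d_in + d_in))
    lim2 = np.sqrt(6.0 / (d_in + 2))
    W1 = rng.uniform(-lim1, lim1, (d_in, d_in))
    b1 = np.zeros(d_in)
    W2 = rng.uniform(-lim2, lim2, (2, d_in))
    b2 = np.zeros(2)

    params = [W1, b1, W2, b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    p_drop = config.dropout_p
    history = []
    step = 0

    def accuracy(Xa, ya):
        model = ClassifierModel(W1=W1, b1=b1, W2=W2, b2=b2)
        return float((model.log_proba(Xa).argmax(1) == ya).mean())

    n_train = len(Xt)
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = Xt[idx], yt[idx]
            bs = len(xb)
            # forward
            z1 = xb @ W1.T + b1
            h = np.maximum(z1, 0.0)
            if p_drop > 0:
                mask = (rng.random(h.shape) >= p_drop) / (1.0 - p_drop)
                hd = h * mask
            else:
                mask = None
                hd = h
            logits = hd @ W2.T + b2
            mx = logits.max(1, keepdims=True)
            logZ = mx + np.log(np.exp(logits - mx).sum(1, keepdims=True))
            probs = np.exp(logits - logZ)
            # backward (NLL)
            dlogits = probs
            dlogits[np.arange(bs), yb] -= 1.0
            dlogits /= bs
            gW2 = dlogits.T @ hd
            gb2 = dlogits.sum(0)
            dh = dlogits @ W2
            if mask is not None:
                dh = dh * mask
            dz1 = dh * (z1 > 0)
            gW1 = dz1.T @ xb
            gb1 = dz1.sum(0)
            step += 1
            for p, g, m_, v_ in zip(params, [gW1, gb1, gW2, gb2], m_t, v_t):
                m_ *= beta1
                m_ += (1 - beta1) * g
                v_ *= beta2
                v_ += (1 - beta2) * g * g
                mhat = m_ / (1 - beta1 ** step)
                vhat = v_ / (1 - beta2 ** step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        if epoch % 10 == 0 or epoch == config.epochs - 1:
            history.append({"epoch": epoch,
                            "train_acc": accuracy(Xt, yt),
                            "val_acc": accuracy(Xv, yv)})
    meta = {
        "config": {"epochs": config.epochs, "batch_size": config.batch_size,
                   "learning_rate": config.learning_rate, "dropout_p": config.dropout_p,
                   "validation_fraction": config.validation_fraction, "seed": config.seed},
        "n_train": int(n_train), "n_val": int(n_val),
        "history": history,
        "final_train_acc": history[-1]["train_acc"],
        "final_val_acc": history[-1]["val_acc"],
    }
    return ClassifierModel(W1=W1, b1=b1, W2=W2, b2=b2,
                           modality=modality, training_meta=meta)


def predict_base_class(model: ClassifierModel,
                       descriptor: ResidueDescriptor | np.ndarray):
    """(log p_purine, log p_pyrimidine) for one descriptor."""
    values = descriptor.values if isinstance(descriptor, ResidueDescriptor) else descriptor
    lp = model.log_proba(np.asarray(values, float)[None, :])[0]
    return float(lp[0]), float(lp[1])


def evaluate(model: ClassifierModel, data: list[LabeledDescriptor]) -> float:
    """Fraction of argmax-correct predictions."""
    if not data:
        raise ValueError("empty evaluation set")
    X, y = _stack(data)
    return float((model.log_proba(X).argmax(1) == y).mean())


def save_model(model: ClassifierModel, path) -> None:
    np.savez(path, W1=model.W1, b1=model.b1, W2=model.W2, b2=model.b2,
             modality=np.array(model.modality),
             meta=np.array(json.dumps(model.training_meta)))


def load_model(path) -> ClassifierModel:
    with np.load(path, allow_pickle=False) as z:
        return ClassifierModel(W1=z["W1"], b1=z["b1"], W2=z["W2"], b2=z["b2"],
                               modality=str(z["modality"]),
                               training_meta=json.loads(str(z["meta"])))
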
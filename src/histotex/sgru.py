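"""Stacked gated recurrent unit (SGRU) classification head.

Each GRU layer computes, per time step t (sigma = logistic sigmoid):

    u_t = sigma(Wu h_{t-1} + Uu x_t + bu)        update gate
    r_t = sigma(Wr h_{t-1} + Ur x_t + br)        reset gate
    c_t = tanh(Wc (r_t * h_{t-1}) + Uc x_t + bc) candidate state
    h_t = u_t * c_t + (1 - u_t) * h_{t-1}

Layer 1 consumes the embedded input sequence e_1..e_t; each higher layer
consumes the hidden state of the layer below at the same time step.  The
top layer's final hidden state maps through an affine head and softmax to
class probabilities.

An image's fixed-length feature vector is turned into the input sequence
by deterministic chunking in index order (:func:`featuremap_to_sequence`).

Training is plain mini-batch SGD on the cross-entropy loss with gradients
derived analytically (backpropagation through time across the stack);
dropout acts on the inter-layer hidden states only and is disabled at
inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRULayerParams",
    "SGRUClassifier",
    "TrainConfig",
    "gru_cell_step",
    "sgru_forward",
    "featuremap_to_sequence",
    "train_classifier",
    "softmax",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class GRULayerParams:
    """One GRU layer's weights: W* recurrent (H x H), U* input (H x I),
    b* biases (H), for the update (u), reset (r) and candidate (c) paths."""

    Wu: np.ndarray
    Wr: np.ndarray
    Wc: np.ndarray
    Uu: np.ndarray
    Ur: np.ndarray
    Uc: np.ndarray
    bu: np.ndarray
    br: np.ndarray
    bc: np.ndarray

    def __post_init__(self) -> None:
        h = self.Wu.shape[0]
        i = self.Uu.shape[1]
        for name in ("Wu", "Wr", "Wc"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must be ({h}, {h})")
        for name in ("Uu", "Ur", "Uc"):
            if getattr(self, name).shape != (h, i):
                raise ValueError(f"{name} must be ({h}, {i})")
        for name in ("bu", "br", "bc"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must be ({h},)")
        for name in ("Wu", "Wr", "Wc", "Uu", "Ur", "Uc", "bu", "br", "bc"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def hidden_size(self) -> int:
        return self.Wu.shape[0]

    @property
    def input_size(self) -> int:
        return self.Uu.shape[1]

    @classmethod
    def init(cls, hidden: int, inp: int, rng: np.random.Generator) -> "GRULayerParams":
        s = 1.0 / np.sqrt(hidden)
        def w(r, c):
            return rng.uniform(-s, s, size=(r, c))
        return cls(
            Wu=w(hidden, hidden), Wr=w(hidden, hidden), Wc=w(hidden, hidden),
            Uu=w(hidden, inp), Ur=w(hidden, inp), Uc=w(hidden, inp),
            bu=np.zeros(hidden), br=np.zeros(hidden), bc=np.zeros(hidden),
        )

    def copy(self) -> "GRULayerParams":
        return GRULayerParams(**{
            k: getattr(self, k).copy()
            for k in ("Wu", "Wr", "Wc", "Uu", "Ur", "Uc", "bu", "br", "bc")
        })


def gru_cell_step(
    x: np.ndarray, h_prev: np.ndarray, params: GRULayerParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One GRU step; returns (update gate, reset gate, candidate, new hidden).

    Accepts a single vector or a (batch, dim) array; the arithmetic is the
    same either way, so batching never changes per-sample values.
    """
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, h_prev {h_prev.shape}, "
            f"layer expects input {params.input_size}, hidden {params.hidden_size}"
        )
    u = _sigmoid(h_prev @ params.Wu.T + x @ params.Uu.T + params.bu)
    r = _sigmoid(h_prev @ params.Wr.T + x @ params.Ur.T + params.br)
    c = np.tanh((r * h_prev) @ params.Wc.T + x @ params.Uc.T + params.bc)
    h_new = u * c + (1.0 - u) * h_prev
    return u, r, c, h_new


def featuremap_to_sequence(vector: np.ndarray, chunk: int) -> np.ndarray:
    """Split a feature vector into an ordered (t, chunk) sequence.

    Chunks are taken in index order; concatenating them reproduces the
    vector exactly.  The length must divide evenly.
    """
    vec = np.asarray(vector, dtype=float).ravel()
    if chunk < 1 or chunk > vec.size:
        raise ValueError(f"chunk size {chunk} invalid for vector of length {vec.size}")
    if vec.size % chunk != 0:
        raise ValueError(f"vector length {vec.size} is not divisible by chunk {chunk}")
    return vec.reshape(vec.size // chunk, chunk)


def sgru_forward(
    sequence: np.ndarray,
    stack: list[GRULayerParams],
    head_w: np.ndarray,
    head_b: np.ndarray,
) -> np.ndarray:
    """Class probabilities for one input sequence (t, input_size).

    Runs each layer left to right with h_0 = 0; layer i >= 2 consumes the
    hidden states of layer i-1.  The top layer's final hidden state feeds
    the affine softmax head.  Probabilities sum to 1.
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 2 or seq.shape[0] == 0:
        raise ValueError(f"expected a nonempty (t, input) sequence, got shape {seq.shape}")
    if not stack:
        raise ValueError("stack must contain at least one layer")
    inputs = seq
    for params in stack:
        h = np.zeros(params.hidden_size)
        hs = []
        for t in range(inputs.shape[0]):
            _, _, _, h = gru_cell_step(inputs[t], h, params)
            hs.append(h)
        inputs = np.stack(hs)
    logits = head_w @ inputs[-1] + head_b
    return softmax(logits)


@dataclass(frozen=True)
class TrainConfig:
    """SGRU training hyperparameters (defaults: lr 0.01, dropout 0.5,
    batch 5, 50 epochs, 2-layer stack)."""

    learning_rate: float = 0.01
    dropout: float = 0.5
    batch_size: int = 5
    hidden_size: int = 16
    layers: int = 2
    epochs: int = 50
    seq_len: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.learning_rate):
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1 or self.hidden_size < 1 or self.layers < 1:
            raise ValueError("batch_size, hidden_size and layers must be >= 1")
        if self.epochs < 0 or self.seq_len < 1:
            raise ValueError("epochs must be >= 0 and seq_len >= 1")


class SGRUClassifier:
    """Stacked GRU + affine softmax head over chunked feature vectors."""

    def __init__(self, feature_length: int, n_classes: int,
                 config: TrainConfig | None = None, seed: int = 0) -> None:
        self.config = config or TrainConfig()
        if feature_length % self.config.seq_len != 0:
            raise ValueError(
                f"feature length {feature_length} not divisible by "
                f"seq_len {self.config.seq_len}"
            )
        self.feature_length = feature_length
        self.n_classes = n_classes
        self.chunk = feature_length // self.config.seq_len
        rng = np.random.default_rng(seed)
        h = self.config.hidden_size
        self.stack = [
            GRULayerParams.init(h, self.chunk if i == 0 else h, rng)
            for i in range(self.config.layers)
        ]
        s = 1.0 / np.sqrt(h)
        self.head_w = rng.uniform(-s, s, size=(n_classes, h))
        self.head_b = np.zeros(n_classes)

    # ---- forward -------------------------------------------------------

    def _sequences(self, features: np.ndarray) -> np.ndarray:
        feats = np.atleast_2d(np.asarray(features, dtype=float))
        return np.stack([featuremap_to_sequence(f, self.chunk) for f in feats])

    def _forward_batch(self, seqs: np.ndarray, dropout_rng: np.random.Generator | None):
        """Batched forward; returns (probs, caches) with caches kept for
        backprop.  seqs is (B, T, chunk)."""
        B, T, _ = seqs.shape
        p = self.config.dropout
        caches: list[list[dict]] = [[None] * T for _ in self.stack]
        inputs = seqs  # (B, T, I)
        for li, params in enumerate(self.stack):
            h = np.zeros((B, params.hidden_size))
            outs = np.empty((B, T, params.hidden_size))
            for t in range(T):
                x = inputs[:, t, :]
                mask = None
                if li > 0 and dropout_rng is not None and p > 0.0:
                    mask = (dropout_rng.random(x.shape) >= p) / (1.0 - p)
                    x = x * mask
                u, r, c, h_new = gru_cell_step(x, h, params)
                caches[li][t] = {"x": x, "mask": mask, "h_prev": h,
                                 "u": u, "r": r, "c": c}
                outs[:, t, :] = h_new
                h = h_new
            inputs = outs
        h_top = inputs[:, -1, :]
        logits = h_top @ self.head_w.T + self.head_b
        return softmax(logits, axis=1), h_top, caches

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        probs, _, _ = self._forward_batch(self._sequences(features), None)
        return probs

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.predict_proba(features).argmax(axis=1)

    # ---- backward ------------------------------------------------------

    def _zero_grads(self):
        gs = []
        for params in self.stack:
            gs.append({k: np.zeros_like(getattr(params, k))
                       for k in ("Wu", "Wr", "Wc", "Uu", "Ur", "Uc", "bu", "br", "bc")})
        return gs

    @staticmethod
    def _cell_backward(dh: np.ndarray, cache: dict, params: GRULayerParams, g: dict):
        x, h_prev = cache["x"], cache["h_prev"]
        u, r, c = cache["u"], cache["r"], cache["c"]
        du = dh * (c - h_prev)
        dc = dh * u
        dh_prev = dh * (1.0 - u)
        dc_pre = dc * (1.0 - c * c)
        g["Wc"] += dc_pre.T @ (r * h_prev)
        g["Uc"] += dc_pre.T @ x
        g["bc"] += dc_pre.sum(axis=0)
        d_rh = dc_pre @ params.Wc
        dr = d_rh * h_prev
        dh_prev = dh_prev + d_rh * r
        dx = dc_pre @ params.Uc
        du_pre = du * u * (1.0 - u)
        g["Wu"] += du_pre.T @ h_prev
        g["Uu"] += du_pre.T @ x
        g["bu"] += du_pre.sum(axis=0)
        dh_prev = dh_prev + du_pre @ params.Wu
        dx = dx + du_pre @ params.Uu
        dr_pre = dr * r * (1.0 - r)
        g["Wr"] += dr_pre.T @ h_prev
        g["Ur"] += dr_pre.T @ x
        g["br"] += dr_pre.sum(axis=0)
        dh_prev = dh_prev + dr_pre @ params.Wr
        dx = dx + dr_pre @ params.Ur
        return dx, dh_prev

    def _train_step(self, seqs: np.ndarray, labels: np.ndarray,
                    dropout_rng: np.random.Generator) -> float:
        B, T, _ = seqs.shape
        probs, h_top, caches = self._forward_batch(seqs, dropout_rng)
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), labels] = 1.0
        loss = -np.mean(np.log(np.clip(probs[np.arange(B), labels], 1e-300, None)))
        dlogits = (probs - onehot) / B
        g_head_w = dlogits.T @ h_top
        g_head_b = dlogits.sum(axis=0)
        grads = self._zero_grads()
        L = len(self.stack)
        # dh_time[l]: gradient wrt h_t^l arriving from the t+1 recurrence
        dh_time = [np.zeros((B, p.hidden_size)) for p in self.stack]
        for t in range(T - 1, -1, -1):
            d_from_above = None
            for li in range(L - 1, -1, -1):
                dh = dh_time[li].copy()
                if li == L - 1 and t == T - 1:
                    dh += dlogits @ self.head_w
                if d_from_above is not None:
                    dh += d_from_above
                dx, dh_prev = self._cell_backward(dh, caches[li][t], self.stack[li],
                                                  grads[li])
                dh_time[li] = dh_prev
                if li > 0:
                    mask = caches[li][t]["mask"]
                    d_from_above = dx if mask is None else dx * mask
                else:
                    d_from_above = None
        lr = self.config.learning_rate
        for params, g in zip(self.stack, grads):
            for k, gv in g.items():
                getattr(params, k)[...] -= lr * gv
        self.head_w -= lr * g_head_w
        self.head_b -= lr * g_head_b
        return float(loss)

    # ---- serialization -------------------------------------------------

    def save(self, path) -> None:
        """Serialize all parameters plus shape metadata to one .npz container."""
        arrays = {"head_w": self.head_w, "head_b": self.head_b,
                  "meta": np.array([self.feature_length, self.n_classes,
                                    self.config.hidden_size, self.config.layers,
                                    self.config.seq_len])}
        for i, params in enumerate(self.stack):
            for k in ("Wu", "Wr", "Wc", "Uu", "Ur", "Uc", "bu", "br", "bc"):
                arrays[f"layer{i}_{k}"] = getattr(params, k)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SGRUClassifier":
        data = np.load(path)
        feat, ncls, hidden, layers, seq_len = (int(v) for v in data["meta"])
        model = cls(feat, ncls,
                    TrainConfig(hidden_size=hidden, layers=layers, seq_len=seq_len))
        model.head_w = data["head_w"]
        model.head_b = data["head_b"]
        for i in range(layers):
            for k in ("Wu", "Wr", "Wc", "Uu", "Ur", "Uc", "bu", "br", "bc"):
                getattr(model.stack[i], k)[...] = data[f"layer{i}_{k}"]
        return model


def _accuracy(model: SGRUClassifier, feats: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(model.predict(feats) == labels))


def train_classifier(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    config: TrainConfig | None = None,
    n_classes: int | None = None,
    seed: int = 0,
) -> tuple[SGRUClassifier, dict]:
    """Fit an SGRU classifier by mini-batch SGD on cross-entropy.

    Deterministic given ``seed`` (initialization, shuffling and dropout all
    derive from it).  Returns the model and a history dict with per-epoch
    train/val accuracy and loss.  ``epochs = 0`` returns the untouched
    initialization.
    """
    config = config or TrainConfig()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0 or X.shape[0] != y.shape[0]:
        raise ValueError("train set must be a nonempty (n, d) matrix with n labels")
    K = n_classes if n_classes is not None else int(y.max()) + 1
    rng = np.random.default_rng(seed)
    model = SGRUClassifier(X.shape[1], K, config, seed=int(rng.integers(2**31)))
    shuffle_rng = np.random.default_rng(int(rng.integers(2**31)))
    dropout_rng = np.random.default_rng(int(rng.integers(2**31)))
    history = {"train_acc": [], "val_acc": [], "train_loss": [], "val_loss": []}
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(X.shape[0])
        losses = []
        for start in range(0, X.shape[0], config.batch_size):
            idx = order[start:start + config.batch_size]
            seqs = model._sequences(X[idx])
            losses.append(model._train_step(seqs, y[idx], dropout_rng))
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(_accuracy(model, X, y))
        if val_features is not None and len(val_features):
            vy = np.asarray(val_labels, dtype=int)
            probs = model.predict_proba(val_features)
            vloss = -np.mean(np.log(np.clip(probs[np.arange(len(vy)), vy],
                                            1e-300, None)))
            history["val_loss"].append(float(vloss))
            history["val_acc"].append(_accuracy(model, np.asarray(val_features), vy))
    return model, history
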
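"""A small differentiable text classifier with an explicit embedding layer.

Architecture: token embedding table -> mean pool over non-padding tokens ->
affine map to k logits, optionally through one tanh hidden layer
(``arch="mlp"``). The model is written directly in numpy with hand-derived
backpropagation; this keeps training bit-reproducible on one CPU and gives
closed forms for every gradient the difficulty and attribution analyses
need:

* linear head:  d logit_p / d e_i = w_p / n            (identical per token)
* mlp head:     d logit_p / d e_i = W1^T [(1 - tanh^2 a) * W2_p] / n

where e_i is token i's embedding, n the number of non-padding tokens and
a the hidden pre-activation. The mlp head is the default for analyses that
need token- or input-dependent gradients (a linear mean-pool model has the
same logit gradient at every token position).

Training is cross-entropy with Adam; K snapshots are captured at evenly
spaced epochs, the last one always being the final model.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import softmax

from .reverse_coding import PAD_ID, SentenceRecord

__all__ = [
    "ModelConfig",
    "TextClassifier",
    "Checkpoint",
    "CheckpointSet",
    "train_with_checkpoints",
    "predict_logits",
    "predict_proba_batch",
    "token_gradients",
    "embed_record",
    "logit_from_embeddings",
    "gradient_from_embeddings",
    "save_checkpoints",
    "load_checkpoints",
]


@dataclass(frozen=True)
class ModelConfig:
    d: int = 32                 # embedding width
    hidden: int = 64            # hidden units (mlp head only)
    arch: str = "mlp"           # "mlp" | "linear"
    epochs: int = 30
    K: int = 5                  # checkpoints captured, last = final model
    learning_rate: float = 0.01
    weight_decay: float = 1e-3  # L2; embedding rows decay only when touched
    init_scale: float = 0.25    # embedding init sd; also the scale at which
                                # never-trained (unknown-word) rows remain
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ("mlp", "linear"):
            raise ValueError(f"unknown architecture: {self.arch!r}")
        if self.K < 1 or self.epochs < self.K:
            raise ValueError("need 1 <= K <= epochs")


class TextClassifier:
    """Embedding -> mean pool -> (tanh hidden) -> affine logits."""

    def __init__(self, vocab_size: int, k: int, config: ModelConfig,
                 params: dict[str, np.ndarray] | None = None):
        if k < 2:
            raise ValueError("need at least 2 classes")
        self.vocab_size = int(vocab_size)
        self.k = int(k)
        self.config = config
        if params is not None:
            self.params = params
        else:
            rng = np.random.default_rng([config.seed, 10])
            d, h = config.d, config.hidden
            self.params = {"E": rng.normal(0.0, config.init_scale, size=(vocab_size, d))}
            if config.arch == "linear":
                self.params["W"] = rng.normal(0.0, 1.0 / np.sqrt(d), size=(k, d))
                self.params["b"] = np.zeros(k)
            else:
                self.params["W1"] = rng.normal(0.0, 1.0 / np.sqrt(d), size=(h, d))
                self.params["b1"] = np.zeros(h)
                self.params["W2"] = rng.normal(0.0, 1.0 / np.sqrt(h), size=(k, h))
                self.params["b2"] = np.zeros(k)

    def copy(self) -> "TextClassifier":
        return TextClassifier(
            self.vocab_size, self.k, self.config,
            params={n: p.copy() for n, p in self.params.items()},
        )

    # -- forward ------------------------------------------------------------

    def _pool(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        counts = mask.sum(axis=1, keepdims=True)
        if (counts == 0).any():
            raise ValueError("a sequence consists only of padding tokens")
        emb = self.params["E"][ids] * mask[..., None]
        return emb.sum(axis=1) / counts

    def logits_from_pooled(self, H: np.ndarray) -> np.ndarray:
        if self.config.arch == "linear":
            return H @ self.params["W"].T + self.params["b"]
        t = np.tanh(H @ self.params["W1"].T + self.params["b1"])
        return t @ self.params["W2"].T + self.params["b2"]

    def forward(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return self.logits_from_pooled(self._pool(ids, mask))


@dataclass(frozen=True)
class Checkpoint:
    epoch: int
    model: TextClassifier
    is_final: bool = False


@dataclass
class CheckpointSet:
    """Ordered training snapshots; the last snapshot is the final model."""

    checkpoints: list[Checkpoint]

    def __post_init__(self):
        epochs = [c.epoch for c in self.checkpoints]
        if epochs != sorted(set(epochs)):
            raise ValueError("checkpoint epochs must be strictly increasing")
        if self.checkpoints and not self.checkpoints[-1].is_final:
            raise ValueError("last checkpoint must be the final model")

    def __len__(self) -> int:
        return len(self.checkpoints)

    def __iter__(self):
        return iter(self.checkpoints)

    @property
    def final(self) -> TextClassifier:
        return self.checkpoints[-1].model


def _batchify(records: Sequence[SentenceRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = max(r.n_tokens for r in records)
    ids = np.full((len(records), L), PAD_ID, dtype=np.int64)
    for i, r in enumerate(records):
        ids[i, : r.n_tokens] = r.token_ids
    mask = ids != PAD_ID
    # Defensive: a genuine pad id inside the sentence is still masked out.
    labels = np.array([r.label_index for r in records], dtype=np.int64)
    return ids, mask, labels


def train_with_checkpoints(
    train: Sequence[SentenceRecord],
    config: ModelConfig,
    vocab_size: int | None = None,
    n_classes: int | None = None,
) -> tuple[TextClassifier, CheckpointSet]:
    """Cross-entropy training with K evenly spaced snapshots.

    Fully deterministic given ``config.seed``. ``vocab_size``/``n_classes``
    default to the maxima observed in the training records; pass them
    explicitly when the evaluation data may contain higher indices.
    """
    if not train:
        raise ValueError("empty training data")
    ids, mask, labels = _batchify(train)
    if np.unique(labels).size < 2:
        raise ValueError("training data contain a single class")
    if vocab_size is None:
        vocab_size = int(ids.max()) + 1
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    model = TextClassifier(vocab_size, n_classes, config)
    rng = np.random.default_rng([config.seed, 11])

    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    snap_epochs = sorted(set(int(round(e)) for e in
                             np.linspace(config.epochs / config.K, config.epochs, config.K)))
    snap_epochs[-1] = config.epochs
    snaps: list[Checkpoint] = []

    n = len(train)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            bids, bmask, by = ids[sel], mask[sel], labels[sel]
            counts = bmask.sum(axis=1, keepdims=True)
            H = (model.params["E"][bids] * bmask[..., None]).sum(axis=1) / counts

            if config.arch == "linear":
                logits = H @ model.params["W"].T + model.params["b"]
            else:
                a = H @ model.params["W1"].T + model.params["b1"]
                t = np.tanh(a)
                logits = t @ model.params["W2"].T + model.params["b2"]

            p = softmax(logits, axis=1)
            dlogits = p
            dlogits[np.arange(len(by)), by] -= 1.0
            dlogits /= len(by)

            grads: dict[str, np.ndarray] = {}
            if config.arch == "linear":
                grads["W"] = dlogits.T @ H
                grads["b"] = dlogits.sum(axis=0)
                dH = dlogits @ model.params["W"]
            else:
                grads["W2"] = dlogits.T @ t
                grads["b2"] = dlogits.sum(axis=0)
                da = (dlogits @ model.params["W2"]) * (1.0 - t * t)
                grads["W1"] = da.T @ H
                grads["b1"] = da.sum(axis=0)
                dH = da @ model.params["W1"]

            gE = np.zeros_like(model.params["E"])
            contrib = (dH / counts)[:, None, :] * bmask[..., None]
            np.add.at(gE, bids.ravel(), contrib.reshape(-1, contrib.shape[-1]))
            gE[PAD_ID] = 0.0
            if config.weight_decay:
                # Sparse decay: only embedding rows present in this batch
                # (vocabulary rows never seen in training keep their init).
                rows = np.unique(bids[bmask])
                gE[rows] += config.weight_decay * model.params["E"][rows]
                for name in grads:
                    grads[name] += config.weight_decay * model.params[name]
            grads["E"] = gE

            step += 1
            for name, g in grads.items():
                m[name] = beta1 * m[name] + (1 - beta1) * g
                v[name] = beta2 * v[name] + (1 - beta2) * g * g
                mhat = m[name] / (1 - beta1 ** step)
                vhat = v[name] / (1 - beta2 ** step)
                model.params[name] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

        if epoch in snap_epochs:
            snaps.append(Checkpoint(epoch=epoch, model=model.copy(),
                                    is_final=epoch == config.epochs))

    return model, CheckpointSet(snaps)


def predict_logits(model: TextClassifier, record: SentenceRecord) -> np.ndarray:
    """Logit vector z(x) for one tokenized sentence."""
    ids = np.array([i for i in record.token_ids if i != PAD_ID])
    if ids.size == 0:
        raise ValueError("record contains no non-padding tokens")
    if ids.max() >= model.vocab_size:
        raise ValueError("token id outside the model vocabulary")
    H = model.params["E"][ids].mean(axis=0, keepdims=True)
    return model.logits_from_pooled(H)[0]


def predict_proba_batch(
    model: TextClassifier, records: Sequence[SentenceRecord]
) -> np.ndarray:
    ids, mask, _ = _batchify(records)
    return softmax(model.forward(ids, mask), axis=1)


def embed_record(model: TextClassifier, record: SentenceRecord) -> np.ndarray:
    """Non-padding token embeddings of a record, shape (n_tokens, d)."""
    ids = np.array([i for i in record.token_ids if i != PAD_ID])
    if ids.size == 0:
        raise ValueError("record contains no non-padding tokens")
    return model.params["E"][ids].copy()


def logit_from_embeddings(model: TextClassifier, X: np.ndarray, p: int) -> float:
    """Pre-softmax logit of class p for an explicit embedding matrix."""
    if not 0 <= p < model.k:
        raise ValueError(f"class index {p} outside [0, {model.k})")
    H = X.mean(axis=0, keepdims=True)
    return float(model.logits_from_pooled(H)[0, p])


def gradient_from_embeddings(model: TextClassifier, X: np.ndarray, p: int) -> np.ndarray:
    """d logit_p / d X, shape like X, for an explicit embedding matrix."""
    if not 0 <= p < model.k:
        raise ValueError(f"class index {p} outside [0, {model.k})")
    n = X.shape[0]
    if model.config.arch == "linear":
        g_h = model.params["W"][p]
    else:
        h = X.mean(axis=0)
        t = np.tanh(model.params["W1"] @ h + model.params["b1"])
        g_h = model.params["W1"].T @ ((1.0 - t * t) * model.params["W2"][p])
    return np.tile(g_h / n, (n, 1))


def token_gradients(model: TextClassifier, record: SentenceRecord, p: int) -> np.ndarray:
    """Gradient of the class-p logit w.r.t. each non-padding token embedding.

    Returns S of shape (non-padding tokens, d): S[i] = d z_p / d e_i.
    """
    X = embed_record(model, record)
    return gradient_from_embeddings(model, X, p)


# ---------------------------------------------------------------------------
# Serialization: versioned directory with a JSON manifest
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_checkpoints(directory, checkpoints: CheckpointSet) -> None:
    """Write snapshots as per-parameter .npy files plus a JSON manifest.

    Plain .npy files (unlike zipped .npz archives) carry no timestamps, so
    a rerun under the same seed reproduces the directory byte for byte.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    final = checkpoints.final
    files = []
    for ck in checkpoints:
        sub = directory / f"checkpoint_epoch{ck.epoch:04d}"
        sub.mkdir(exist_ok=True)
        hashes = {}
        for name, arr in sorted(ck.model.params.items()):
            np.save(sub / f"{name}.npy", arr)
            hashes[name] = _sha256(sub / f"{name}.npy")
        files.append(
            {"epoch": ck.epoch, "dir": sub.name, "is_final": ck.is_final,
             "params": sorted(ck.model.params), "sha256": hashes}
        )
    manifest = {
        "format_version": FORMAT_VERSION,
        "vocab_size": final.vocab_size,
        "k": final.k,
        "config": asdict(final.config),
        "checkpoints": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_checkpoints(directory) -> CheckpointSet:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    config = ModelConfig(**manifest["config"])
    snaps = []
    for entry in manifest["checkpoints"]:
        sub = directory / entry["dir"]
        params = {name: np.load(sub / f"{name}.npy") for name in entry["params"]}
        model = TextClassifier(manifest["vocab_size"], manifest["k"], config, params=params)
        snaps.append(Checkpoint(epoch=entry["epoch"], model=model,
                                is_final=entry["is_final"]))
    return CheckpointSet(snaps)
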
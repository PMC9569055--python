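"""The hierarchical neural network scoring circRNA-disease pairs.

Architecture: two independent three-layer ReLU towers project a
circRNA's fused-similarity row and a disease's fused-similarity row into
high-order feature vectors CH and DH of length N; the element-wise
product CD = CH * DH captures multiplicative feature co-occurrence; the
concatenation [CH; CD; DH] feeds a three-layer classifier head
(ReLU, ReLU, sigmoid) that outputs the association probability.

Training minimises binary cross-entropy with an L2 penalty on all
weights, by mini-batch adaptive moment estimation (Adam).  The network
is implemented directly on NumPy arrays with hand-derived gradients: it
is small (a few hundred thousand parameters), runs comfortably on one
CPU core, and every source of randomness (initialisation, shuffling)
is driven by a single seed, so training is bitwise reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataio import SimilarityMatrix
from .errors import ParameterError, TrainingError

__all__ = [
    "ModelConfig",
    "MspcdModel",
    "tower_forward",
    "interact_and_concat",
    "head_forward",
    "init_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_SUPPORTED_HIGHORDER = (8, 16, 32, 64, 128)
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the towers, head and optimiser.

    highorder_dim is the length N of the high-order feature vectors; the
    supported sweep grid is {8, 16, 32, 64, 128}.  Hidden widths taper
    geometrically toward N on the tower side and from 3N toward the
    scalar output on the head side.
    """

    highorder_dim: int = 64
    tower_hidden: tuple[int, int] = (256, 128)
    head_hidden: tuple[int, int] = (128, 64)
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 200
    l2: float = 1e-4
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.highorder_dim < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ParameterError("dimensions, batch size and epochs must be positive")
        if self.learning_rate <= 0 or self.l2 < 0:
            raise ParameterError("learning rate must be positive, l2 non-negative")
        if not (0.0 <= self.dropout < 1.0):
            raise ParameterError("dropout must lie in [0, 1)")
        if self.highorder_dim not in _SUPPORTED_HIGHORDER:
            warnings.warn(
                f"highorder_dim {self.highorder_dim} is outside the usual grid "
                f"{_SUPPORTED_HIGHORDER}", stacklevel=2,
            )

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("tower_hidden", "head_hidden"):
            if key in d:
                d[key] = tuple(d[key])
        return ModelConfig(**d)


Layers = list[tuple[np.ndarray, np.ndarray]]  # [(W: (in, out), b: (out,)), ...]


@dataclass
class MspcdModel:
    """Trained parameters of both towers and the classifier head."""

    tower_c: Layers
    tower_d: Layers
    head: Layers
    config: ModelConfig
    input_dims: tuple[int, int]
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        nc, nd = self.input_dims
        n = self.config.highorder_dim
        h1, h2 = self.config.tower_hidden
        g1, g2 = self.config.head_hidden
        expect = {
            "circRNA tower": (self.tower_c, [nc, h1, h2, n]),
            "disease tower": (self.tower_d, [nd, h1, h2, n]),
            "head": (self.head, [3 * n, g1, g2, 1]),
        }
        for what, (layers, dims) in expect.items():
            for k, (w, b) in enumerate(layers):
                if w.shape != (dims[k], dims[k + 1]) or b.shape != (dims[k + 1],):
                    raise ParameterError(
                        f"{what} layer {k + 1} has shape {w.shape}, "
                        f"expected {(dims[k], dims[k + 1])}"
                    )


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def tower_forward(x: np.ndarray, params: Layers) -> np.ndarray:
    """Three fully connected ReLU layers; accepts a vector or a batch."""
    h = np.atleast_2d(np.asarray(x, dtype=float))
    if h.shape[1] != params[0][0].shape[0]:
        raise ParameterError(
            f"input width {h.shape[1]} does not match tower input "
            f"{params[0][0].shape[0]}"
        )
    for w, b in params:
        h = _relu(h @ w + b)
    return h[0] if np.ndim(x) == 1 else h


def interact_and_concat(ch: np.ndarray, dh: np.ndarray) -> np.ndarray:
    """[CH; CH*DH; DH] — the pair representation fed to the head."""
    ch = np.asarray(ch, dtype=float)
    dh = np.asarray(dh, dtype=float)
    if ch.shape != dh.shape:
        raise ParameterError("high-order vectors must have equal length")
    return np.concatenate([ch, ch * dh, dh], axis=-1)


def head_forward(vg: np.ndarray, params: Layers) -> np.ndarray:
    """ReLU, ReLU, then a sigmoid unit giving the association score."""
    h = np.atleast_2d(np.asarray(vg, dtype=float))
    if h.shape[1] != params[0][0].shape[0]:
        raise ParameterError(
            f"pair vector width {h.shape[1]} does not match head input "
            f"{params[0][0].shape[0]}"
        )
    for w, b in params[:-1]:
        h = _relu(h @ w + b)
    w, b = params[-1]
    out = _sigmoid(h @ w + b)[..., 0]
    return float(out[0]) if np.ndim(vg) == 1 else out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _init_layers(rng: np.random.Generator, dims: Sequence[int]) -> Layers:
    return [
        (_glorot(rng, dims[k], dims[k + 1]), np.zeros(dims[k + 1]))
        for k in range(len(dims) - 1)
    ]


def init_model(config: ModelConfig, nc: int, nd: int) -> MspcdModel:
    """Glorot-uniform initialisation of all layers, fully seeded."""
    rng = np.random.default_rng(config.seed)
    n = config.highorder_dim
    h1, h2 = config.tower_hidden
    g1, g2 = config.head_hidden
    return MspcdModel(
        tower_c=_init_layers(rng, [nc, h1, h2, n]),
        tower_d=_init_layers(rng, [nd, h1, h2, n]),
        head=_init_layers(rng, [3 * n, g1, g2, 1]),
        config=config,
        input_dims=(nc, nd),
    )


def _forward_cache(
    model: MspcdModel,
    xc: np.ndarray,
    xd: np.ndarray,
    drop_rng: np.random.Generator | None = None,
    p: float = 0.0,
):
    """Full forward pass keeping activations for backprop.

    With dropout active (training only), inverted dropout is applied to
    the hidden tower layers and hidden head layers — not to the
    high-order outputs CH/DH, whose element-wise product carries the
    pair interaction.
    """

    def maybe_drop(h: np.ndarray) -> np.ndarray:
        if drop_rng is None or p == 0.0:
            return h
        mask = drop_rng.random(h.shape) >= p
        return h * mask / (1.0 - p)

    acts_c = [xc]
    for k, (w, b) in enumerate(model.tower_c):
        h = _relu(acts_c[-1] @ w + b)
        acts_c.append(maybe_drop(h) if k < len(model.tower_c) - 1 else h)
    acts_d = [xd]
    for k, (w, b) in enumerate(model.tower_d):
        h = _relu(acts_d[-1] @ w + b)
        acts_d.append(maybe_drop(h) if k < len(model.tower_d) - 1 else h)
    ch, dh = acts_c[-1], acts_d[-1]
    vg = np.concatenate([ch, ch * dh, dh], axis=1)
    acts_h = [vg]
    for w, b in model.head[:-1]:
        acts_h.append(maybe_drop(_relu(acts_h[-1] @ w + b)))
    w, b = model.head[-1]
    logits = (acts_h[-1] @ w + b)[:, 0]
    return acts_c, acts_d, acts_h, logits


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # stable: max(z,0) - z*y + log1p(exp(-|z|))
    return float(
        np.mean(np.maximum(logits, 0.0) - logits * y + np.log1p(np.exp(-np.abs(logits))))
    )


def _backward(model: MspcdModel, acts_c, acts_d, acts_h, logits, y, p: float = 0.0):
    """Hand-derived gradients of mean BCE w.r.t. every layer parameter.

    Stored activations already carry the inverted-dropout mask, so the
    ReLU derivative factor is ``(a > 0) / (1 - p)`` on dropped layers.
    """
    batch = y.shape[0]
    n = model.config.highorder_dim
    keep = 1.0 - p
    grads_h: Layers = [None] * len(model.head)  # type: ignore[list-item]
    dz = (_sigmoid(logits) - y)[:, None] / batch
    w, _ = model.head[-1]
    grads_h[-1] = (acts_h[-1].T @ dz, dz.sum(axis=0))
    dh_prev = dz @ w.T
    for k in range(len(model.head) - 2, -1, -1):
        dz = dh_prev * (acts_h[k + 1] > 0) / keep
        grads_h[k] = (acts_h[k].T @ dz, dz.sum(axis=0))
        dh_prev = dz @ model.head[k][0].T
    dvg = dh_prev
    ch, dh = acts_c[-1], acts_d[-1]
    dch = dvg[:, :n] + dvg[:, n : 2 * n] * dh
    ddh = dvg[:, 2 * n :] + dvg[:, n : 2 * n] * ch

    def tower_grads(layers: Layers, acts, dtop) -> Layers:
        grads: Layers = [None] * len(layers)  # type: ignore[list-item]
        d = dtop
        for k in range(len(layers) - 1, -1, -1):
            scale = 1.0 if k == len(layers) - 1 else keep  # no dropout on CH/DH
            dz = d * (acts[k + 1] > 0) / scale
            grads[k] = (acts[k].T @ dz, dz.sum(axis=0))
            d = dz @ layers[k][0].T
        return grads

    return tower_grads(model.tower_c, acts_c, dch), tower_grads(
        model.tower_d, acts_d, ddh
    ), grads_h


def train(
    cv: SimilarityMatrix,
    dv: SimilarityMatrix,
    samples,
    config: ModelConfig,
) -> MspcdModel:
    """Fit the network on labelled (circRNA, disease) index pairs.

    *samples* is any object exposing integer ``pairs`` of shape (n, 2)
    and binary ``labels`` of shape (n,) — typically a
    :class:`~mspcd.evaluation.PairDataset`.  Feature vectors are the raw
    rows of the fused similarity matrices; the loss is mean binary
    cross-entropy plus ``l2 * sum(W**2)`` over all weight matrices.
    Returns the trained model with a per-epoch training-loss trace.
    """
    pairs = np.asarray(samples.pairs, dtype=int)
    labels = np.asarray(samples.labels, dtype=float)
    if pairs.size == 0:
        raise TrainingError("empty training set")
    if len(np.unique(labels)) < 2:
        raise TrainingError("training labels contain a single class")
    if pairs[:, 0].max() >= cv.n or pairs[:, 1].max() >= dv.n or pairs.min() < 0:
        raise ParameterError("sample indices fall outside the similarity matrices")

    model = init_model(config, cv.n, dv.n)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5B]))
    flat = (
        [p for p in model.tower_c]
        + [p for p in model.tower_d]
        + [p for p in model.head]
    )
    params = [arr for pair in flat for arr in pair]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    xc_all = cv.values
    xd_all = dv.values
    n_samples = pairs.shape[0]
    bs = min(config.batch_size, n_samples)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n_samples)
        epoch_loss = 0.0
        for start in range(0, n_samples, bs):
            idx = order[start : start + bs]
            xc = xc_all[pairs[idx, 0]]
            xd = xd_all[pairs[idx, 1]]
            y = labels[idx]
            acts_c, acts_d, acts_h, logits = _forward_cache(
                model, xc, xd, drop_rng=rng, p=config.dropout
            )
            loss = _bce_from_logits(logits, y)
            gc, gd, gh = _backward(
                model, acts_c, acts_d, acts_h, logits, y, p=config.dropout
            )
            grads = [arr for pair in (gc + gd + gh) for arr in pair]
            step += 1
            for k, (p, g) in enumerate(zip(params, grads)):
                if config.l2 > 0 and p.ndim == 2:  # weights only, not biases
                    g = g + 2.0 * config.l2 * p
                m_t[k] = beta1 * m_t[k] + (1 - beta1) * g
                v_t[k] = beta2 * v_t[k] + (1 - beta2) * g * g
                mhat = m_t[k] / (1 - beta1**step)
                vhat = v_t[k] / (1 - beta2**step)
                p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n_samples)
    model.loss_trace = trace
    return model


def predict(
    model: MspcdModel,
    cv: SimilarityMatrix,
    dv: SimilarityMatrix,
    pairs: Sequence[tuple[int, int]] | np.ndarray,
    batch_size: int = 4096,
) -> np.ndarray:
    """Association scores in (0, 1) for (circRNA index, disease index)
    pairs, order preserved; independent of the internal batching."""
    arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if arr.size and (
        arr.min() < 0 or arr[:, 0].max() >= cv.n or arr[:, 1].max() >= dv.n
    ):
        raise ParameterError("pair indices fall outside the similarity matrices")
    out = np.empty(arr.shape[0], dtype=float)
    for start in range(0, arr.shape[0], batch_size):
        chunk = arr[start : start + batch_size]
        ch = tower_forward(cv.values[chunk[:, 0]], model.tower_c)
        dh = tower_forward(dv.values[chunk[:, 1]], model.tower_d)
        out[start : start + batch_size] = head_forward(
            interact_and_concat(ch, dh), model.head
        )
    return out


def save_model(model: MspcdModel, path: str | Path) -> None:
    """Serialise weights and config into one .npz archive (versioned)."""
    arrays: dict[str, np.ndarray] = {}
    for tag, layers in (("c", model.tower_c), ("d", model.tower_d), ("h", model.head)):
        for k, (w, b) in enumerate(layers):
            arrays[f"{tag}{k}_w"] = w
            arrays[f"{tag}{k}_b"] = b
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "input_dims": list(model.input_dims),
        "loss_trace": model.loss_trace,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with Path(path).open("wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | Path) -> MspcdModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ParameterError(
                f"unsupported checkpoint version {meta['format_version']}"
            )

        def layers(tag: str) -> Layers:
            out: Layers = []
            k = 0
            while f"{tag}{k}_w" in data:
                out.append((data[f"{tag}{k}_w"], data[f"{tag}{k}_b"]))
                k += 1
            return out

        return MspcdModel(
            tower_c=layers("c"),
            tower_d=layers("d"),
            head=layers("h"),
            config=ModelConfig.from_dict(meta["config"]),
            input_dims=tuple(meta["input_dims"]),
            loss_trace=list(meta["loss_trace"]),
        )
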
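"""Frame classifiers: mean-amplitude baseline, CRNN and CDNN.

All three consume the same standardized frame tensors (sequence x bins x
columns; 200 x 15 x 4 for a 2-s fragment at the default analysis
parameters) and emit one bowel-sound probability per 10-ms frame.

* baseline — the score of a frame is the mean of its standardized dB block
  over the 0-1500 Hz band; a frame is a sound when the score exceeds a fixed
  cutoff. No training; the reference point every learned model must beat.
* CRNN — a small convolutional stack applied identically to every frame
  (30 filters 3x3, then 60 filters 4x2, valid padding, ReLU; 15x4 -> 10x1)
  flattened to 600 features, then a bidirectional GRU (80 units, ReLU
  candidate activation, reset-after gating) over the 200-frame sequence and
  a per-frame sigmoid unit. 342,281 trainable parameters.
* CDNN — per-frame flatten (60) -> dense 120 (ReLU), then the feature
  vectors of the 9 adjacent frames (+-4, zero-padded at sequence edges) are
  concatenated and classified by dense 100 (ReLU) -> sigmoid unit. 115,521
  trainable parameters. No recurrence: context comes from the concatenation.

Training minimizes per-frame binary cross-entropy with Adam at its
conventional defaults; the retained checkpoint is the epoch with the best
validation accuracy. Optional augmentation adds Gaussian noise to the
standardized spectrogram values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .spectro import FrameTensor

__all__ = [
    "BaselineConfig",
    "ModelSpec",
    "TrainConfig",
    "FramePredictions",
    "baseline_classify",
    "build_model",
    "augment",
    "train",
    "predict",
    "save_model",
    "load_model",
]


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineConfig:
    """Cutoff on the mean standardized-dB amplitude of a frame block."""

    cutoff: float = 0.07

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters shared by the two networks."""

    kind: str = "cdnn"
    seq_len: int = 200
    n_bins: int = 15
    cols: int = 4
    conv1_filters: int = 30
    conv1_size: tuple[int, int] = (3, 3)
    conv2_filters: int = 60
    conv2_size: tuple[int, int] = (4, 2)
    gru_units: int = 80
    dense1: int = 120
    context: int = 9
    dense2: int = 100
    dropout: float = 0.4

    def __post_init__(self) -> None:
        if self.kind not in ("crnn", "cdnn"):
            raise ValueError(f"kind must be 'crnn' or 'cdnn', got {self.kind!r}")
        if self.context % 2 != 1:
            raise ValueError(f"context must be odd, got {self.context}")
        for name in ("seq_len", "n_bins", "cols", "gru_units", "dense1", "dense2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    augmentation_sigma: float | None = None
    augmentation_copies: int = 5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class FramePredictions:
    """Per-frame probabilities with the binary decisions they imply."""

    probabilities: np.ndarray = field(repr=False)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "probabilities", np.asarray(self.probabilities, dtype=np.float64)
        )

    @property
    def decisions(self) -> np.ndarray:
        return (self.probabilities > self.threshold).astype(np.int8)


# --------------------------------------------------------------------------
# baseline
# --------------------------------------------------------------------------


def baseline_classify(frames: FrameTensor | np.ndarray, cfg: BaselineConfig) -> FramePredictions:
    """Threshold the mean standardized amplitude of each frame block.

    The decision is ``mean > cutoff``; the reported probability is a sigmoid
    of the margin (score - cutoff) so that the decisions/probability contract
    of :class:`FramePredictions` holds at the 0.5 threshold.
    """
    if isinstance(frames, FrameTensor):
        if not frames.standardized:
            raise ContractError("baseline_classify requires standardized frames")
        blocks = frames.blocks
    else:
        blocks = np.asarray(frames)
    scores = blocks.reshape(blocks.shape[0], -1).mean(axis=1)
    probs = 1.0 / (1.0 + np.exp(-(scores - cfg.cutoff)))
    return FramePredictions(probabilities=probs, threshold=0.5)


# --------------------------------------------------------------------------
# neural models
# --------------------------------------------------------------------------


def _conv2d_valid(x: Tensor, w: Tensor, b: Tensor, kh: int, kw: int,
                  c_out: int) -> Tensor:
    """Valid 2-D convolution as a sum of shifted matrix products.

    x: (N, H, W, Cin); w: (kh*kw, Cin, Cout); b: (Cout,).
    """
    n, h, wd, c_in = x.shape
    ho, wo = h - kh + 1, wd - kw + 1
    out = None
    for di in range(kh):
        for dj in range(kw):
            patch = x[:, di : di + ho, dj : dj + wo, :]
            term = patch.reshape(n * ho * wo, c_in) @ w[di * kw + dj]
            out = term if out is None else out + term
    return out.reshape(n, ho, wo, c_out) + b


class _GRULayer:
    """Fused bidirectional GRU with hand-written backpropagation through time.

    Reset-after ("double bias") gating, as in cuDNN-compatible
    implementations: each gate has separate input and recurrent biases, and
    the reset gate multiplies the already-biased recurrent candidate term.
    The candidate activation is ReLU; gates are sigmoids. Writing the layer
    as one graph node keeps backward memory proportional to (batch x units)
    per timestep instead of materialising per-step gradient buffers of the
    whole input sequence.
    """

    def __init__(self, units: int, in_features: int, rng: np.random.Generator):
        self.units = units
        u, f = units, in_features
        self.params: dict[str, Tensor] = {}
        for d in ("fwd", "bwd"):
            self.params[f"gru_{d}_W"] = Tensor(
                nn.glorot_uniform(rng, (f, 3 * u), f, 3 * u), requires_grad=True)
            self.params[f"gru_{d}_U"] = Tensor(
                nn.orthogonal(rng, u, 3 * u), requires_grad=True)
            self.params[f"gru_{d}_bW"] = Tensor(np.zeros(3 * u), requires_grad=True)
            self.params[f"gru_{d}_bU"] = Tensor(np.zeros(3 * u), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        u = self.units
        p = self.params
        caches = {}
        outs = {}
        for d, order in (("fwd", range(T)), ("bwd", range(T - 1, -1, -1))):
            W, U = p[f"gru_{d}_W"].data, p[f"gru_{d}_U"].data
            bW, bU = p[f"gru_{d}_bW"].data, p[f"gru_{d}_bU"].data
            h = np.zeros((B, u))
            cache, hs = [], np.empty((B, T, u))
            gx_all = x.data @ W + bW  # (B,T,3u) — input projection is time-parallel
            for t in order:
                gh = h @ U + bU
                pre_g = gx_all[:, t] + gh
                z = _sig(pre_g[:, :u])
                r = _sig(pre_g[:, u : 2 * u])
                pre_h = gx_all[:, t, 2 * u :] + r * gh[:, 2 * u :]
                hh = np.maximum(pre_h, 0.0)
                h_prev = h
                h = z * h_prev + (1.0 - z) * hh
                hs[:, t] = h
                cache.append((t, h_prev, z, r, hh, gh[:, 2 * u :], pre_h > 0))
            caches[d] = cache
            outs[d] = hs

        parents = [x] + [p[f"gru_{d}_{k}"] for d in ("fwd", "bwd")
                         for k in ("W", "U", "bW", "bU")]
        out = Tensor(np.concatenate([outs["fwd"], outs["bwd"]], axis=2), parents)

        def bwd(g):
            gx_total = np.zeros_like(x.data)
            grads = []
            for i, d in enumerate(("fwd", "bwd")):
                gd = g[:, :, i * u : (i + 1) * u]
                W, U = p[f"gru_{d}_W"].data, p[f"gru_{d}_U"].data
                dW = np.zeros_like(W)
                dU = np.zeros_like(U)
                dbW = np.zeros(3 * u)
                dbU = np.zeros(3 * u)
                dh_next = np.zeros((B, u))
                dgx = np.zeros((B, T, 3 * u))
                for t, h_prev, z, r, hh, ghh, relu_mask in reversed(caches[d]):
                    dh = gd[:, t] + dh_next
                    dz = dh * (h_prev - hh)
                    da = dh * (1.0 - z) * relu_mask  # through ReLU candidate
                    dr = da * ghh
                    dgz = dz * z * (1.0 - z)
                    dgr = dr * r * (1.0 - r)
                    dgh = np.concatenate([dgz, dgr, da * r], axis=1)
                    dgx[:, t, :2 * u] = np.concatenate([dgz, dgr], axis=1)
                    dgx[:, t, 2 * u :] = da
                    dU += h_prev.T @ dgh
                    dbU += dgh.sum(axis=0)
                    dh_next = dh * z + dgh @ U.T
                dW = x.data.reshape(B * T, F).T @ dgx.reshape(B * T, 3 * u)
                dbW = dgx.sum(axis=(0, 1))
                gx_total += dgx @ W.T
                grads.extend([dW, dU, dbW, dbU])
            return tuple([gx_total] + grads)

        out._bwd = bwd
        return out


def _sig(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _ModelBase:
    spec: ModelSpec
    params: dict[str, Tensor]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Probabilities for a batch (n, T, bins, cols) -> (n, T)."""
        chunks = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            chunks.append(_sig(logits.data))
        return np.concatenate(chunks, axis=0)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data[...] = weights[k]


class CRNN(_ModelBase):
    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        k1h, k1w = spec.conv1_size
        k2h, k2w = spec.conv2_size
        f1, f2 = spec.conv1_filters, spec.conv2_filters
        self.params = {
            "conv1_w": Tensor(nn.glorot_uniform(rng, (k1h * k1w, 1, f1),
                                                k1h * k1w, f1), requires_grad=True),
            "conv1_b": Tensor(np.zeros(f1), requires_grad=True),
            "conv2_w": Tensor(nn.glorot_uniform(rng, (k2h * k2w, f1, f2),
                                                k2h * k2w * f1, f2), requires_grad=True),
            "conv2_b": Tensor(np.zeros(f2), requires_grad=True),
        }
        h_out = spec.n_bins - k1h + 1 - k2h + 1
        w_out = spec.cols - k1w + 1 - k2w + 1
        self.flat_features = h_out * w_out * f2
        if h_out <= 0 or w_out <= 0:
            raise ValueError("convolution kernels do not fit the frame block")
        self.gru = _GRULayer(spec.gru_units, self.flat_features, rng)
        self.params.update(self.gru.params)
        self.params["out_w"] = Tensor(
            nn.glorot_uniform(rng, (2 * spec.gru_units, 1), 2 * spec.gru_units, 1),
            requires_grad=True)
        self.params["out_b"] = Tensor(np.zeros(1), requires_grad=True)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        s = self.spec
        B, T = x.shape[0], x.shape[1]
        t = Tensor(x.reshape(B * T, s.n_bins, s.cols, 1))
        t = _conv2d_valid(t, self.params["conv1_w"], self.params["conv1_b"],
                          *s.conv1_size, s.conv1_filters).relu()
        t = _conv2d_valid(t, self.params["conv2_w"], self.params["conv2_b"],
                          *s.conv2_size, s.conv2_filters).relu()
        t = t.reshape(B, T, self.flat_features)
        t = nn.dropout(t, s.dropout, rng, train)
        t = self.gru(t)
        t = nn.dropout(t, s.dropout, rng, train)
        logits = t.reshape(B * T, 2 * s.gru_units) @ self.params["out_w"] + self.params["out_b"]
        return logits.reshape(B, T)


class CDNN(_ModelBase):
    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        flat = spec.n_bins * spec.cols
        self.params = {
            "dense1_w": Tensor(nn.glorot_uniform(rng, (flat, spec.dense1),
                                                 flat, spec.dense1), requires_grad=True),
            "dense1_b": Tensor(np.zeros(spec.dense1), requires_grad=True),
            "dense2_w": Tensor(nn.glorot_uniform(rng, (spec.context * spec.dense1, spec.dense2),
                                                 spec.context * spec.dense1, spec.dense2),
                               requires_grad=True),
            "dense2_b": Tensor(np.zeros(spec.dense2), requires_grad=True),
            "out_w": Tensor(nn.glorot_uniform(rng, (spec.dense2, 1), spec.dense2, 1),
                            requires_grad=True),
            "out_b": Tensor(np.zeros(1), requires_grad=True),
        }

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        s = self.spec
        B, T = x.shape[0], x.shape[1]
        flat = s.n_bins * s.cols
        t = Tensor(x.reshape(B * T, flat))
        t = (t @ self.params["dense1_w"] + self.params["dense1_b"]).relu()
        t = t.reshape(B, T, s.dense1)
        t = _concat_context(t, s.context)
        t = nn.dropout(t, s.dropout, rng, train)
        t = t.reshape(B * T, s.context * s.dense1)
        t = (t @ self.params["dense2_w"] + self.params["dense2_b"]).relu()
        logits = t @ self.params["out_w"] + self.params["out_b"]
        return logits.reshape(B, T)


def _concat_context(x: Tensor, context: int) -> Tensor:
    """Concatenate each frame's vector with its +-(context//2) neighbours,
    zero vectors standing in beyond the sequence edges."""
    B, T, F = x.shape
    half = context // 2
    padded_data = np.zeros((B, T + 2 * half, F))
    padded_data[:, half : half + T] = x.data
    padded = Tensor(padded_data, (x,))
    padded._bwd = lambda g: (g[:, half : half + T],)
    return nn.concat([padded[:, off : off + T] for off in range(context)], axis=2)


def build_model(spec: ModelSpec, seed: int = 0) -> _ModelBase:
    """Instantiate a CRNN or CDNN with reproducible initial weights."""
    return CRNN(spec, seed) if spec.kind == "crnn" else CDNN(spec, seed)


# --------------------------------------------------------------------------
# augmentation / training
# --------------------------------------------------------------------------


def augment(x: np.ndarray, y: np.ndarray, sigma: float, copies: int = 5,
            seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Enlarge a training set with noisy replicas.

    Per input sequence, ``copies`` replicas with i.i.d. Gaussian(0, sigma^2)
    added to the standardized spectrogram values; labels copied unchanged;
    originals retained first. Output size = (copies + 1) * input size.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    reps = [x]
    for _ in range(copies):
        reps.append(x + rng.normal(0.0, sigma, x.shape))
    return np.concatenate(reps, axis=0), np.concatenate([y] * (copies + 1), axis=0)


def train(model: _ModelBase, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray], cfg: TrainConfig):
    """Minimize per-frame binary cross-entropy with Adam.

    ``train_set``/``val_set`` are (X, y) with X of shape (n, T, bins, cols)
    and y of shape (n, T). Per-epoch validation metrics are recorded and the
    weights retained at the end are those of the best epoch by validation
    accuracy. Returns the history (list of per-epoch dicts).
    """
    from .evaluation import confusion

    x_tr, y_tr = train_set
    x_val, y_val = val_set
    if x_tr.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    if len(np.unique(y_tr)) < 2:
        import warnings

        warnings.warn("training labels contain a single class", stacklevel=2)
    if cfg.augmentation_sigma is not None:
        x_tr, y_tr = augment(x_tr, y_tr, cfg.augmentation_sigma,
                             cfg.augmentation_copies, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history: list[dict] = []
    best_acc, best_weights = -np.inf, model.get_weights()
    n = x_tr.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x_tr[idx], train=True, rng=rng)
            loss = nn.bce_with_logits(logits.reshape(idx.size * x_tr.shape[1]),
                                      y_tr[idx].reshape(-1))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data) * idx.size
        probs = model.predict_proba(x_val)
        decisions = (probs > cfg.threshold).astype(np.int8)
        res = confusion(decisions.reshape(-1), y_val.reshape(-1))
        rec = {"epoch": epoch, "loss": total_loss / n,
               "val_accuracy": res.accuracy, "val_precision": res.precision,
               "val_sensitivity": res.sensitivity, "val_specificity": res.specificity}
        history.append(rec)
        if res.accuracy is not None and res.accuracy > best_acc:
            best_acc = res.accuracy
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return history


def predict(model: _ModelBase, frames: FrameTensor | np.ndarray,
            threshold: float = 0.5) -> FramePredictions:
    """One probability per frame of a (standardized) frame tensor."""
    if isinstance(frames, FrameTensor):
        if not frames.standardized:
            raise ContractError("predict requires frames standardized with the "
                                "training-time statistics")
        x = frames.blocks[None, ...]
    else:
        x = np.asarray(frames)
        if x.ndim == 3:
            x = x[None, ...]
    if x.shape[2] != model.spec.n_bins or x.shape[3] != model.spec.cols:
        raise ContractError(
            f"frame blocks {x.shape[2]}x{x.shape[3]} do not match the model's "
            f"{model.spec.n_bins}x{model.spec.cols}")
    probs = model.predict_proba(x)
    return FramePredictions(probabilities=probs.reshape(-1) if probs.shape[0] == 1
                            else probs, threshold=threshold)


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def save_model(model: _ModelBase, path: str | Path, norm_mean: float | None = None,
               norm_std: float | None = None, threshold: float = 0.5) -> None:
    """Store architecture, weights and the training-time standardization."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    meta = {"spec": asdict(model.spec), "norm_mean": norm_mean,
            "norm_std": norm_std, "threshold": threshold}
    (d / "model.json").write_text(json.dumps(meta, indent=2))
    np.savez(d / "weights.npz", **model.get_weights())


def load_model(path: str | Path):
    """Inverse of :func:`save_model`; returns (model, metadata dict)."""
    d = Path(path)
    meta = json.loads((d / "model.json").read_text())
    spec_kw = dict(meta["spec"])
    for k in ("conv1_size", "conv2_size"):
        spec_kw[k] = tuple(spec_kw[k])
    model = build_model(ModelSpec(**spec_kw))
    with np.load(d / "weights.npz") as z:
        model.set_weights({k: z[k] for k in z.files})
    return model, meta
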
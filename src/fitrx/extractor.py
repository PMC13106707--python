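"""1D-CNN + multi-head self-attention feature extractor, in NumPy.

Maps the N x 15 x 4 fitness sequence tensor to a 256-dimensional pooled
embedding z. Three strided convolutions (filters 64/128/256, kernel 5,
stride 2, ReLU, "same"-with-stride zero padding) shorten the lap axis
15 -> 8 -> 4 -> 2 while deepening the channels; eight 32-dimensional
scaled dot-product attention heads re-weight the two remaining positions,
are projected back, added residually and layer-normalized; global average
pooling over time yields z.

Training minimizes a weighted sum of four per-metric cross-entropies —
each the loss of an auxiliary softmax head on a forward pass where every
input channel except that metric's is zero-masked — plus an attention
entropy regularizer (lambda = 0.1) and an L2 penalty (1e-4) on all
trainable weights, with Adam and early stopping on validation loss.
Gradients are hand-derived and checked against finite differences in the
test suite. The auxiliary head is used only during training; downstream
classification consumes z.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

LN_EPS = 1e-5
_METRIC_CHANNELS = ("run_3000m", "pull_ups", "sit_ups", "shuttle")


@dataclass(frozen=True)
class ExtractorConfig:
    conv_filters: tuple[int, ...] = (64, 128, 256)
    kernel: int = 5
    stride: int = 2
    heads: int = 8
    attn_dropout: float = 0.3
    lambda_attn: float = 0.1
    metric_weights: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2)
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    l2: float = 1e-4
    hidden_noise: float = 0.05
    patience: int = 10
    max_epochs: int = 100
    batch_size: int = 128
    n_classes: int = 4
    seed: int = 42

    def __post_init__(self) -> None:
        if self.d % self.heads != 0:
            raise ValueError(f"model width {self.d} not divisible by heads={self.heads}")
        if abs(sum(self.metric_weights) - 1.0) > 1e-9:
            raise ValueError("metric loss weights must sum to 1")
        for name in ("attn_dropout",):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.hidden_noise < 0 or self.l2 < 0 or self.lambda_attn < 0:
            raise ValueError("rates and penalties must be non-negative")

    @property
    def d(self) -> int:
        return self.conv_filters[-1]

    @property
    def head_dim(self) -> int:
        return self.d // self.heads


def conv_output_lengths(t: int, n_layers: int, stride: int) -> list[int]:
    """Sequence lengths after each strided conv: ceil division per layer."""
    out = []
    for _ in range(n_layers):
        t = math.ceil(t / stride)
        if t < 1:
            raise ValueError("sequence collapsed below length 1")
        out.append(t)
    return out


def _pad_amounts(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    l_out = math.ceil(length / stride)
    total = max((l_out - 1) * stride + kernel - length, 0)
    return l_out, total // 2, total - total // 2


def _im2col(x: np.ndarray, kernel: int, stride: int) -> tuple[np.ndarray, tuple]:
    """(N, L, C) -> (N, L_out, kernel*C) with ceil 'same' zero padding."""
    n, length, c = x.shape
    l_out, pl, pr = _pad_amounts(length, kernel, stride)
    xp = np.zeros((n, length + pl + pr, c), dtype=x.dtype)
    xp[:, pl : pl + length, :] = x
    cols = np.empty((n, l_out, kernel * c), dtype=x.dtype)
    for t in range(l_out):
        cols[:, t, :] = xp[:, t * stride : t * stride + kernel, :].reshape(n, kernel * c)
    return cols, (length, pl, kernel, stride, c)


def _col2im(dcols: np.ndarray, meta: tuple) -> np.ndarray:
    length, pl, kernel, stride, c = meta
    n, l_out, _ = dcols.shape
    dxp = np.zeros((n, pl + (l_out - 1) * stride + kernel, c), dtype=dcols.dtype)
    for t in range(l_out):
        dxp[:, t * stride : t * stride + kernel, :] += dcols[:, t, :].reshape(n, kernel, c)
    return dxp[:, pl : pl + length, :]


def _softmax(s: np.ndarray) -> np.ndarray:
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def attention_sparsity_penalty(a: np.ndarray) -> float:
    """Mean Shannon entropy (nats) of the attention rows.

    Averaged over samples, heads and query positions; zero iff every row
    is one-hot, maximal (ln T') for uniform rows.
    """
    a = np.asarray(a, dtype=float)
    if (a < -1e-12).any():
        raise ValueError("attention weights must be non-negative")
    rows = a.sum(axis=-1)
    if np.abs(rows - 1.0).max() > 1e-4:
        raise ValueError("attention rows must sum to 1")
    safe = np.maximum(a, 1e-300)
    ent = -(a * np.log(safe)).sum(axis=-1)
    return float(ent.mean())


def total_loss(
    per_metric_losses: Sequence[float],
    attention: np.ndarray,
    metric_weights: Sequence[float] = (0.4, 0.2, 0.2, 0.2),
    lambda_attn: float = 0.1,
) -> float:
    """Weighted per-metric loss plus the attention entropy regularizer.

    total = 0.4 L_3000m + 0.2 L_pull + 0.2 L_sit + 0.2 L_shuttle
            + lambda * mean row entropy of the attention map.
    """
    losses = [float(v) for v in per_metric_losses]
    if len(losses) != 4:
        raise ValueError("expected 4 per-metric losses")
    if any(not math.isfinite(v) for v in losses):
        raise FloatingPointError("non-finite per-metric loss — training failure")
    data = sum(w * v for w, v in zip(metric_weights, losses))
    return data + lambda_attn * attention_sparsity_penalty(attention)


class Extractor:
    """The network: parameters, forward passes and (internal) backprop."""

    def __init__(self, config: ExtractorConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.params = self._init_params(rng)
        self.history: dict = {}

    # -- initialization ----------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        p: dict[str, np.ndarray] = {}
        c_in = 4
        for i, c_out in enumerate(cfg.conv_filters):
            fan_in = cfg.kernel * c_in
            p[f"W{i}"] = rng.normal(0.0, math.sqrt(2.0 / fan_in), (cfg.kernel, c_in, c_out))
            p[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        d = cfg.d
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[name] = rng.normal(0.0, math.sqrt(1.0 / d), (d, d))
        p["gamma"] = np.ones(d)
        p["beta"] = np.zeros(d)
        p["Wh"] = rng.normal(0.0, math.sqrt(1.0 / d), (d, cfg.n_classes))
        p["bh"] = np.zeros(cfg.n_classes)
        return p

    # -- forward pieces (public, eval mode) --------------------------------
    def conv_forward(self, x: np.ndarray) -> np.ndarray:
        """Strided conv stack: (N, 15, 4) -> (N, T', d), ReLU outputs."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[2] != 4:
            raise ValueError(f"expected N x T x 4 tensor, got {x.shape}")
        h = x
        for i in range(len(self.config.conv_filters)):
            h = self._conv_layer(h, i)[0]
        return h

    def _conv_layer(self, h, i):
        cfg = self.config
        w = self.params[f"W{i}"]
        cols, meta = _im2col(h, cfg.kernel, cfg.stride)
        pre = cols @ w.reshape(-1, w.shape[2]) + self.params[f"b{i}"]
        return np.maximum(pre, 0.0), (cols, meta, pre)

    def attention_forward(
        self, h: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Multi-head attention + residual + LayerNorm.

        Returns (H_attn of shape (N, T', d), attention map (N, h, T', T')).
        Dropout on the attention probabilities is active only in training.
        """
        out, a, _ = self._attention(h, train=train, rng=rng)
        return out, a

    def _attention(self, h, train, rng):
        cfg = self.config
        n, t, d = h.shape
        if d != cfg.d:
            raise ValueError(f"attention width {d} != model width {cfg.d}")
        nh, dh = cfg.heads, cfg.head_dim
        p = self.params

        def split(x):  # (N,T,d) -> (N,h,T,dh)
            return x.reshape(n, t, nh, dh).transpose(0, 2, 1, 3)

        q, k, v = split(h @ p["Wq"]), split(h @ p["Wk"]), split(h @ p["Wv"])
        s = q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh)
        a = _softmax(s)
        if train and cfg.attn_dropout > 0:
            mask = (rng.random(a.shape) >= cfg.attn_dropout) / (1.0 - cfg.attn_dropout)
        else:
            mask = np.ones_like(a)
        ad = a * mask
        o = ad @ v                                      # (N,h,T,dh)
        concat = o.transpose(0, 2, 1, 3).reshape(n, t, d)
        proj = concat @ p["Wo"]
        r = h + proj
        mu = r.mean(axis=-1, keepdims=True)
        var = r.var(axis=-1, keepdims=True)
        xhat = (r - mu) / np.sqrt(var + LN_EPS)
        out = p["gamma"] * xhat + p["beta"]
        cache = dict(h=h, q=q, k=k, v=v, a=a, mask=mask, ad=ad, concat=concat,
                     xhat=xhat, var=var)
        return out, a, cache

    def pool(self, h_attn: np.ndarray) -> np.ndarray:
        """Global average pooling over the time axis -> z (N, d)."""
        h_attn = np.asarray(h_attn, dtype=float)
        if h_attn.ndim != 3 or h_attn.shape[1] < 1:
            raise ValueError("expected non-empty (N, T', d) input")
        return h_attn.mean(axis=1)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode embedding of the full (unmasked) input."""
        h = self.conv_forward(x)
        h_attn, _ = self.attention_forward(h)
        return self.pool(h_attn)

    def embed_views(self, x: np.ndarray) -> np.ndarray:
        """Classification embedding: z averaged over the four channel-masked
        views of the input.

        The network only ever sees channel-masked inputs during training (the
        per-metric loss), so the masked views are its calibrated operating
        regime; averaging their pooled features keeps z at 256 dimensions
        while staying on the training distribution. The unmasked embed() is
        retained for inspection.
        """
        zs = [self.embed(mask_channels(x, m)) for m in range(4)]
        return np.mean(zs, axis=0)

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        z = self.embed(x)
        return z @ self.params["Wh"] + self.params["bh"]

    # -- one masked pass: loss + gradients ---------------------------------
    def _pass(self, x, y, w_ce, w_ent, train, rng):
        """Forward + backward for one (already masked) batch.

        Returns (ce, entropy, grads). Loss contribution of this pass is
        w_ce * ce + w_ent * entropy; grads are scaled accordingly.
        """
        cfg = self.config
        p = self.params
        n = x.shape[0]
        h = x
        conv_caches = []
        for i in range(len(cfg.conv_filters)):
            h, cache = self._conv_layer(h, i)
            conv_caches.append((h, cache))
        h_attn, a, ac = self._attention(h, train=train, rng=rng)
        noisy = h_attn
        if train and cfg.hidden_noise > 0:
            noisy = h_attn + rng.normal(0.0, cfg.hidden_noise, size=h_attn.shape)
        z = noisy.mean(axis=1)
        logits = z @ p["Wh"] + p["bh"]
        probs = _softmax(logits)
        ce = -float(np.mean(np.log(np.maximum(probs[np.arange(n), y], 1e-300))))
        safe_a = np.maximum(a, 1e-300)
        ent = float(-(a * np.log(safe_a)).sum(axis=-1).mean())

        # ---- backward ----
        g: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= w_ce / n
        g["Wh"] = z.T @ dlogits
        g["bh"] = dlogits.sum(axis=0)
        dz = dlogits @ p["Wh"].T
        t_prime = h_attn.shape[1]
        dout = np.repeat(dz[:, None, :], t_prime, axis=1) / t_prime

        # LayerNorm backward
        xhat, var = ac["xhat"], ac["var"]
        g["gamma"] = (dout * xhat).sum(axis=(0, 1))
        g["beta"] = dout.sum(axis=(0, 1))
        dxhat = dout * p["gamma"]
        inv = 1.0 / np.sqrt(var + LN_EPS)
        dr = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        dh = dr.copy()                       # residual branch
        dproj = dr
        g["Wo"] = ac["concat"].reshape(-1, cfg.d).T @ dproj.reshape(-1, cfg.d)
        dconcat = dproj @ p["Wo"].T
        nh, dh_dim = cfg.heads, cfg.head_dim
        do = dconcat.reshape(n, t_prime, nh, dh_dim).transpose(0, 2, 1, 3)
        dad = do @ ac["v"].transpose(0, 1, 3, 2)
        dv = ac["ad"].transpose(0, 1, 3, 2) @ do
        da = dad * ac["mask"]
        if w_ent != 0.0:
            rows = a.shape[0] * a.shape[1] * a.shape[2]
            da = da + w_ent * (-(np.log(safe_a) + 1.0)) / rows
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        scale = 1.0 / math.sqrt(dh_dim)
        dq = ds @ ac["k"] * scale
        dk = ds.transpose(0, 1, 3, 2) @ ac["q"] * scale

        def merge(x4):  # (N,h,T,dh) -> (N,T,d)
            return x4.transpose(0, 2, 1, 3).reshape(n, t_prime, cfg.d)

        hin = ac["h"].reshape(-1, cfg.d)
        for name, dx in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
            dflat = merge(dx).reshape(-1, cfg.d)
            g[name] = hin.T @ dflat
            dh += (dflat @ p[name].T).reshape(n, t_prime, cfg.d)

        # conv stack backward
        dcur = dh
        for i in reversed(range(len(cfg.conv_filters))):
            relu_out, (cols, meta, pre) = conv_caches[i]
            dpre = dcur * (pre > 0)
            w = p[f"W{i}"]
            g[f"W{i}"] = (
                cols.reshape(-1, cols.shape[2]).T @ dpre.reshape(-1, dpre.shape[2])
            ).reshape(w.shape)
            g[f"b{i}"] = dpre.sum(axis=(0, 1))
            dcols = dpre @ w.reshape(-1, w.shape[2]).T
            dcur = _col2im(dcols, meta)
        return ce, ent, g


def mask_channels(x: np.ndarray, keep: int) -> np.ndarray:
    """Zero every input channel except `keep` (0=laps, 1=pull, 2=sit, 3=shuttle)."""
    out = np.zeros_like(x)
    out[:, :, keep] = x[:, :, keep]
    return out


def batch_loss_and_grads(
    model: Extractor, x: np.ndarray, y: np.ndarray,
    train: bool = True, rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Custom loss over the four channel-masked passes, with gradients.

    loss = sum_m w_m CE_m + lambda_attn * mean_m entropy_m + l2 * sum ||W||^2.
    """
    cfg = model.config
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    ces, ents = [], []
    for m in range(4):
        ce, ent, g = model._pass(
            mask_channels(x, m), y,
            w_ce=cfg.metric_weights[m], w_ent=cfg.lambda_attn / 4.0,
            train=train, rng=rng,
        )
        ces.append(ce)
        ents.append(ent)
        for k in grads:
            grads[k] += g[k]
    if any(not math.isfinite(c) for c in ces):
        raise FloatingPointError("non-finite per-metric loss — training failure")
    loss = sum(w * c for w, c in zip(cfg.metric_weights, ces))
    loss += cfg.lambda_attn * float(np.mean(ents))
    if cfg.l2 > 0:
        for k, v in model.params.items():
            loss += cfg.l2 * float((v ** 2).sum())
            grads[k] += 2.0 * cfg.l2 * v
    return loss, grads


def _evaluate_loss(model: Extractor, x: np.ndarray, y: np.ndarray) -> float:
    cfg = model.config
    ces, ents = [], []
    for m in range(4):
        xm = mask_channels(x, m)
        h = model.conv_forward(xm)
        h_attn, a = model.attention_forward(h)
        z = model.pool(h_attn)
        logits = z @ model.params["Wh"] + model.params["bh"]
        probs = _softmax(logits)
        ces.append(-float(np.mean(np.log(np.maximum(probs[np.arange(len(y)), y], 1e-300)))))
        ents.append(attention_sparsity_penalty(a))
    return float(
        sum(w * c for w, c in zip(cfg.metric_weights, ces))
        + cfg.lambda_attn * np.mean(ents)
    )


def train_extractor(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: ExtractorConfig,
) -> tuple[Extractor, dict]:
    """Adam training with early stopping on the validation loss.

    Stops after `patience` consecutive epochs without strict improvement
    and restores the weights of the best validation epoch. One integer
    seed drives init, shuffling, dropout and hidden noise.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    x_train = np.asarray(x_train, dtype=float)
    x_val = np.asarray(x_val, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)

    root = np.random.SeedSequence(config.seed)
    init_ss, shuffle_ss, noise_ss = root.spawn(3)
    model = Extractor(config, rng=np.random.default_rng(init_ss))
    shuffle_rng = np.random.default_rng(shuffle_ss)
    noise_rng = np.random.default_rng(noise_ss)

    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    best_val = math.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_epoch = 0
    bad = 0
    history: dict = {"train_loss": [], "val_loss": []}

    n = len(x_train)
    bs = min(config.batch_size, n)
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            loss, grads = batch_loss_and_grads(
                model, x_train[idx], y_train[idx], train=True, rng=noise_rng
            )
            epoch_loss += loss
            n_batches += 1
            step += 1
            b1c = 1.0 - config.beta1 ** step
            b2c = 1.0 - config.beta2 ** step
            for k, gk in grads.items():
                m_state[k] = config.beta1 * m_state[k] + (1 - config.beta1) * gk
                v_state[k] = config.beta2 * v_state[k] + (1 - config.beta2) * gk ** 2
                model.params[k] -= config.lr * (m_state[k] / b1c) / (
                    np.sqrt(v_state[k] / b2c) + 1e-8
                )
        val = _evaluate_loss(model, x_val, y_val)
        history["train_loss"].append(epoch_loss / n_batches)
        history["val_loss"].append(val)
        if val < best_val:
            best_val = val
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    model.params = best_params
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = epoch
    model.history = history
    return model, history


# ---------------------------------------------------------------------------
# checkpoint i/o
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: Extractor, path) -> None:
    header = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "history": model.history,
    }
    arrays = {k: v for k, v in model.params.items()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Extractor:
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    header = json.loads(bytes(data["__header__"]).decode())
    cfg_dict = header["config"]
    for key in ("conv_filters", "metric_weights"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = Extractor(ExtractorConfig(**cfg_dict))
    model.params = {k: data[k] for k in data.files if k != "__header__"}
    model.history = header.get("history", {})
    return model
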
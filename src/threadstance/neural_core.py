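"""Numeric building blocks of the debate/stance networks.

Two layers of code live here:

* pure reference operations (:func:`conv_feature_map`,
  :func:`max_over_time`, :func:`highway`, :func:`lstm_step`,
  :func:`label_distribution`, :func:`sequence_nll`) written for clarity
  in float64 — these are the contract the trainable path is tested
  against; and

* :class:`DebateNet` / :class:`StanceNet`, vectorized forward/backward
  implementations used for training by stochastic gradient descent.

The post encoder is a word-level CNN: word-embedding columns form a
d x l matrix, filters of widths 2..5 produce tanh feature maps, and
max-over-time pooling keeps one scalar per filter.  The debate network
passes the pooled vector through a highway layer and an LSTM running
over the posts of a thread, so each post's label distribution depends
on the whole preceding discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid

__all__ = [
    "ConvFilter",
    "FilterBank",
    "HighwayParams",
    "LSTMParams",
    "LSTMState",
    "SoftmaxParams",
    "conv_feature_map",
    "max_over_time",
    "encode_post",
    "highway",
    "lstm_step",
    "label_distribution",
    "sequence_nll",
    "NetConfig",
    "DebateNet",
    "StanceNet",
    "sgd_update",
    "numeric_gradients",
    "gradient_check",
]

LOG_CLIP = 1e-12

GATE_ORDER = ("i", "f", "o", "g")


# ---------------------------------------------------------------------------
# Parameter containers (reference path)
# ---------------------------------------------------------------------------


@dataclass
class ConvFilter:
    """One convolution kernel H (d x k) with scalar bias b."""

    H: np.ndarray
    b: float

    @property
    def width(self) -> int:
        return int(self.H.shape[1])


@dataclass
class FilterBank:
    filters: list[ConvFilter]

    def __len__(self) -> int:
        return len(self.filters)

    @property
    def max_width(self) -> int:
        return max(f.width for f in self.filters)


@dataclass
class HighwayParams:
    A_H: np.ndarray
    b_H: np.ndarray
    A_T: np.ndarray
    b_T: np.ndarray
    activation: str = "tanh"


@dataclass
class LSTMParams:
    """Per-gate parameters U^j (m x h), V^j (m x m), b^j (m) for j in i,f,o,g."""

    U: dict[str, np.ndarray]
    V: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    @property
    def m(self) -> int:
        return int(self.U["i"].shape[0])


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray

    @staticmethod
    def zero(m: int) -> "LSTMState":
        return LSTMState(np.zeros(m), np.zeros(m))


@dataclass
class SoftmaxParams:
    """One weight vector z^j (length m) and bias b^j per label."""

    Z: np.ndarray  # (n_labels, m)
    b: np.ndarray  # (n_labels,)


# ---------------------------------------------------------------------------
# Reference operations
# ---------------------------------------------------------------------------


def conv_feature_map(W: np.ndarray, filt: ConvFilter) -> np.ndarray:
    """Feature map f[i] = tanh(<W[:, i:i+k-1], H> + b), Frobenius inner product."""
    d, l = W.shape
    k = filt.width
    if filt.H.shape[0] != d:
        raise ValueError("filter and post matrix disagree on embedding dim")
    if l < k:
        raise ValueError(f"post length {l} shorter than filter width {k}")
    out = np.empty(l - k + 1)
    for i in range(l - k + 1):
        out[i] = np.tanh(float(np.sum(W[:, i : i + k] * filt.H)) + filt.b)
    return out


def max_over_time(f: np.ndarray) -> float:
    """Max-over-time pooling: the largest feature-map entry."""
    f = np.asarray(f)
    if f.size == 0:
        raise ValueError("empty feature map")
    return float(np.max(f))


def encode_post(
    tokens: list[str],
    emb,
    bank: FilterBank,
    oov_vector: np.ndarray | None = None,
) -> np.ndarray:
    """Pooled CNN representation l^p of a post (length = number of filters).

    Unknown words map to ``oov_vector`` (zeros when not given); posts
    shorter than the widest filter are zero-padded on the right.
    """
    if len(bank) == 0:
        raise ValueError("empty filter bank")
    d = emb.dim
    if oov_vector is None:
        oov_vector = np.zeros(d)
    cols = []
    for t in tokens:
        v = emb.vector(t)
        cols.append(oov_vector if v is None else v)
    l = max(len(cols), bank.max_width)
    W = np.zeros((d, l))
    for j, c in enumerate(cols):
        W[:, j] = c
    return np.array([max_over_time(conv_feature_map(W, f)) for f in bank.filters])


def highway(l: np.ndarray, params: HighwayParams) -> np.ndarray:
    """Highway layer z = t * g(A_H l + b_H) + (1 - t) * l, t = sigma(A_T l + b_T)."""
    if params.A_H.shape[1] != l.shape[0]:
        raise ValueError("highway dimension mismatch")
    g = np.tanh if params.activation == "tanh" else _named_activation(params.activation)
    t = sigmoid(params.A_T @ l + params.b_T)
    return t * g(params.A_H @ l + params.b_H) + (1.0 - t) * l


def _named_activation(name: str):
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    raise ValueError(f"unknown activation {name!r}")


def lstm_step(x: np.ndarray, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One LSTM step: gated update of the memory cell and hidden state."""
    if params.U["i"].shape[1] != x.shape[0]:
        raise ValueError("lstm input dimension mismatch")
    i = sigmoid(params.U["i"] @ x + params.V["i"] @ state.h + params.b["i"])
    f = sigmoid(params.U["f"] @ x + params.V["f"] @ state.h + params.b["f"])
    o = sigmoid(params.U["o"] @ x + params.V["o"] @ state.h + params.b["o"])
    g = np.tanh(params.U["g"] @ x + params.V["g"] @ state.h + params.b["g"])
    c = f * state.c + i * g
    h = o * np.tanh(c)
    return LSTMState(h, c)


def label_distribution(h: np.ndarray, params: SoftmaxParams) -> np.ndarray:
    """Softmax label probabilities from a hidden vector, overflow-safe."""
    logits = params.Z @ h + params.b
    logits = logits - np.max(logits)
    e = np.exp(logits)
    return e / e.sum()


def sequence_nll(prob_seq, labels, classes=None) -> float:
    """Negative log-likelihood of the true labels over a post sequence.

    ``labels`` may be integer class indices, or label objects together
    with the ``classes`` ordering.  Probabilities are clipped at 1e-12
    so an impossible gold label yields a large finite loss.
    """
    if len(prob_seq) != len(labels):
        raise ValueError("probability sequence and label sequence differ in length")
    if classes is not None:
        labels = [classes.index(y) for y in labels]
    loss = 0.0
    for p, y in zip(prob_seq, labels):
        loss -= float(np.log(max(float(p[int(y)]), LOG_CLIP)))
    return loss


# ---------------------------------------------------------------------------
# Trainable networks
# ---------------------------------------------------------------------------


def _init(rng: np.random.Generator, *shape, scale: float = 0.1) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


@dataclass
class NetConfig:
    embedding_dim: int = 50
    filter_widths: tuple[int, ...] = (2, 3, 4, 5)
    filters_per_width: int = 100
    hidden_dim: int = 100
    n_classes: int = 2
    use_highway: bool = True
    seed: int = 0

    @property
    def n_filters(self) -> int:
        return self.filters_per_width * len(self.filter_widths)


class _CNNEncoder:
    """Vectorized CNN post encoder over an embedding table with OOV column.

    ``E`` has one column per vocabulary word plus a final trainable OOV
    column; padding positions are zero columns outside the table.
    """

    def __init__(self, params: dict[str, np.ndarray], cfg: NetConfig):
        self.params = params
        self.cfg = cfg

    @staticmethod
    def init_params(cfg: NetConfig, vocab_size: int, rng: np.random.Generator,
                    embedding_init: np.ndarray | None = None) -> dict[str, np.ndarray]:
        d = cfg.embedding_dim
        E = _init(rng, d, vocab_size + 1)
        if embedding_init is not None:
            if embedding_init.shape != (d, vocab_size):
                raise ValueError("embedding_init shape mismatch")
            E[:, :vocab_size] = embedding_init
        p = {"E": E}
        for k in cfg.filter_widths:
            p[f"H{k}"] = _init(rng, cfg.filters_per_width, d, k,
                               scale=1.0 / np.sqrt(d * k))
            p[f"bH{k}"] = np.zeros(cfg.filters_per_width)
        return p

    def forward(self, ids: np.ndarray):
        """Encode one post given token column ids (-1 marks padding)."""
        cfg, p = self.cfg, self.params
        d = cfg.embedding_dim
        k_max = max(cfg.filter_widths)
        L = max(len(ids), k_max)
        padded = np.full(L, -1, dtype=np.intp)
        padded[: len(ids)] = ids
        W = np.zeros((d, L))
        valid = padded >= 0
        W[:, valid] = p["E"][:, padded[valid]]

        pooled_parts, cache_parts = [], []
        for k in cfg.filter_widths:
            # windows: (L-k+1, d*k)
            win = np.lib.stride_tricks.sliding_window_view(W, (d, k))
            X = win.reshape(L - k + 1, d * k)
            Hf = p[f"H{k}"].reshape(cfg.filters_per_width, d * k)
            F = np.tanh(X @ Hf.T + p[f"bH{k}"])  # (P, n)
            arg = F.argmax(axis=0)
            pooled = F[arg, np.arange(F.shape[1])]
            pooled_parts.append(pooled)
            cache_parts.append((k, X, arg, pooled))
        lvec = np.concatenate(pooled_parts)
        cache = (padded, valid, W.shape[1], cache_parts)
        return lvec, cache

    def backward(self, dl: np.ndarray, cache, grads: dict[str, np.ndarray]) -> None:
        cfg, p = self.cfg, self.params
        d = cfg.embedding_dim
        padded, valid, L, cache_parts = cache
        dW = np.zeros((d, L))
        offset = 0
        for k, X, arg, pooled in cache_parts:
            n = cfg.filters_per_width
            dpool = dl[offset : offset + n]
            offset += n
            dpre = dpool * (1.0 - pooled**2)  # through tanh at the argmax
            Xa = X[arg]  # (n, d*k)
            grads[f"H{k}"] += (dpre[:, None] * Xa).reshape(n, d, k)
            grads[f"bH{k}"] += dpre
            dwin = (dpre[:, None] * p[f"H{k}"].reshape(n, d * k)).reshape(n, d, k)
            cols = arg[:, None] + np.arange(k)[None, :]  # (n, k)
            np.add.at(dW, (slice(None), cols), dwin.transpose(1, 0, 2))
        ids = padded[valid]
        np.add.at(grads["E"], (slice(None), ids), dW[:, valid])


class _Highway:
    def __init__(self, params: dict[str, np.ndarray]):
        self.params = params

    @staticmethod
    def init_params(h: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        return {
            "A_H": _init(rng, h, h, scale=1.0 / np.sqrt(h)),
            "b_H": np.zeros(h),
            "A_T": _init(rng, h, h, scale=1.0 / np.sqrt(h)),
            # slight negative bias so the carry path dominates initially
            "b_T": np.full(h, -1.0),
        }

    def forward(self, l: np.ndarray):
        p = self.params
        g = np.tanh(p["A_H"] @ l + p["b_H"])
        t = sigmoid(p["A_T"] @ l + p["b_T"])
        z = t * g + (1.0 - t) * l
        return z, (l, g, t)

    def backward(self, dz: np.ndarray, cache, grads) -> np.ndarray:
        p = self.params
        l, g, t = cache
        dt = dz * (g - l)
        dg = dz * t
        dl = dz * (1.0 - t)
        da_h = dg * (1.0 - g**2)
        grads["A_H"] += np.outer(da_h, l)
        grads["b_H"] += da_h
        dl += p["A_H"].T @ da_h
        da_t = dt * t * (1.0 - t)
        grads["A_T"] += np.outer(da_t, l)
        grads["b_T"] += da_t
        dl += p["A_T"].T @ da_t
        return dl


class _LSTM:
    """Stacked-gate LSTM (gate order i, f, o, g) with backprop through time."""

    def __init__(self, params: dict[str, np.ndarray], m: int):
        self.params = params
        self.m = m

    @staticmethod
    def init_params(h: int, m: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        b = np.zeros(4 * m)
        b[m : 2 * m] = 1.0  # forget-gate bias: remember by default
        return {
            "U": _init(rng, 4 * m, h, scale=1.0 / np.sqrt(h)),
            "V": _init(rng, 4 * m, m, scale=1.0 / np.sqrt(m)),
            "b_l": b,
        }

    def forward(self, x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray):
        p, m = self.params, self.m
        a = p["U"] @ x + p["V"] @ h_prev + p["b_l"]
        i = sigmoid(a[:m])
        f = sigmoid(a[m : 2 * m])
        o = sigmoid(a[2 * m : 3 * m])
        g = np.tanh(a[3 * m :])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        return h, c, (x, h_prev, c_prev, i, f, o, g, tc)

    def backward(self, dh, dc, cache, grads):
        p, m = self.params, self.m
        x, h_prev, c_prev, i, f, o, g, tc = cache
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        da = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            do * o * (1.0 - o),
            dg * (1.0 - g**2),
        ])
        grads["U"] += np.outer(da, x)
        grads["V"] += np.outer(da, h_prev)
        grads["b_l"] += da
        dx = p["U"].T @ da
        dh_prev = p["V"].T @ da
        dc_prev = dc * f
        return dx, dh_prev, dc_prev

    def to_reference(self) -> LSTMParams:
        """Expose the stacked parameters as per-gate reference params."""
        m = self.m
        sl = {j: slice(n * m, (n + 1) * m) for n, j in enumerate(GATE_ORDER)}
        return LSTMParams(
            U={j: self.params["U"][sl[j]] for j in GATE_ORDER},
            V={j: self.params["V"][sl[j]] for j in GATE_ORDER},
            b={j: self.params["b_l"][sl[j]] for j in GATE_ORDER},
        )


def _softmax_init(m: int, n_classes: int, rng) -> dict[str, np.ndarray]:
    return {"Z": _init(rng, n_classes, m, scale=1.0 / np.sqrt(m)),
            "b_s": np.zeros(n_classes)}


class DebateNet:
    """CNN post encoder + highway + LSTM + per-post softmax over a thread."""

    def __init__(self, cfg: NetConfig, vocab_size: int,
                 embedding_init: np.ndarray | None = None):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params = _CNNEncoder.init_params(cfg, vocab_size, rng, embedding_init)
        if cfg.use_highway:
            self.params.update(_Highway.init_params(cfg.n_filters, rng))
        self.params.update(_LSTM.init_params(cfg.n_filters, cfg.hidden_dim, rng))
        self.params.update(_softmax_init(cfg.hidden_dim, cfg.n_classes, rng))
        self.encoder = _CNNEncoder(self.params, cfg)
        self.highway = _Highway(self.params) if cfg.use_highway else None
        self.lstm = _LSTM(self.params, cfg.hidden_dim)

    # -- forward ----------------------------------------------------------
    def forward_thread(self, thread_ids: list[np.ndarray]):
        """Label distributions for each post of a thread, in order."""
        m = self.cfg.hidden_dim
        h = np.zeros(m)
        c = np.zeros(m)
        probs = []
        caches = []
        for ids in thread_ids:
            lvec, enc_cache = self.encoder.forward(ids)
            if self.highway is not None:
                z, hw_cache = self.highway.forward(lvec)
            else:
                z, hw_cache = lvec, None
            h, c, lstm_cache = self.lstm.forward(z, h, c)
            logits = self.params["Z"] @ h + self.params["b_s"]
            logits = logits - logits.max()
            e = np.exp(logits)
            p = e / e.sum()
            probs.append(p)
            caches.append((enc_cache, hw_cache, lstm_cache, h, p))
        return probs, caches

    # -- loss & gradients -------------------------------------------------
    def loss_and_grads(self, thread_ids: list[np.ndarray], label_ids: list[int]):
        probs, caches = self.forward_thread(thread_ids)
        loss = sequence_nll(probs, label_ids)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        m = self.cfg.hidden_dim
        dh_next = np.zeros(m)
        dc_next = np.zeros(m)
        for t in range(len(thread_ids) - 1, -1, -1):
            enc_cache, hw_cache, lstm_cache, h, p = caches[t]
            dlogits = p.copy()
            dlogits[label_ids[t]] -= 1.0
            grads["Z"] += np.outer(dlogits, h)
            grads["b_s"] += dlogits
            dh = self.params["Z"].T @ dlogits + dh_next
            dz, dh_next, dc_next = self.lstm.backward(dh, dc_next, lstm_cache, grads)
            if self.highway is not None:
                dl = self.highway.backward(dz, hw_cache, grads)
            else:
                dl = dz
            self.encoder.backward(dl, enc_cache, grads)
        return loss, grads

    def predict_thread(self, thread_ids: list[np.ndarray]) -> np.ndarray:
        probs, _ = self.forward_thread(thread_ids)
        return np.array(probs)


class StanceNet:
    """CNN post encoder + softmax; posts are classified independently."""

    def __init__(self, cfg: NetConfig, vocab_size: int,
                 embedding_init: np.ndarray | None = None):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params = _CNNEncoder.init_params(cfg, vocab_size, rng, embedding_init)
        self.params.update(_softmax_init(cfg.n_filters, cfg.n_classes, rng))
        self.encoder = _CNNEncoder(self.params, cfg)

    def forward_post(self, ids: np.ndarray):
        lvec, cache = self.encoder.forward(ids)
        logits = self.params["Z"] @ lvec + self.params["b_s"]
        logits = logits - logits.max()
        e = np.exp(logits)
        p = e / e.sum()
        return p, (cache, lvec, p)

    def loss_and_grads(self, ids: np.ndarray, label_id: int):
        p, (cache, lvec, _) = self.forward_post(ids)
        loss = -float(np.log(max(float(p[label_id]), LOG_CLIP)))
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogits = p.copy()
        dlogits[label_id] -= 1.0
        grads["Z"] += np.outer(dlogits, lvec)
        grads["b_s"] += dlogits
        dl = self.params["Z"].T @ dlogits
        self.encoder.backward(dl, cache, grads)
        return loss, grads

    def predict_post(self, ids: np.ndarray) -> np.ndarray:
        p, _ = self.forward_post(ids)
        return p


# ---------------------------------------------------------------------------
# SGD and gradient checking
# ---------------------------------------------------------------------------


def sgd_update(params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
               lr: float, clip: float = 5.0) -> None:
    """In-place SGD step with global-norm gradient clipping."""
    norm = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))
    scale = lr if norm <= clip or norm == 0.0 else lr * clip / norm
    for k, g in grads.items():
        params[k] -= scale * g


def gradient_check(analytic: dict[str, np.ndarray],
                   numeric: dict[str, np.ndarray]) -> float:
    """Worst norm-relative error between two gradient sets.

    Per parameter array: ||a - n|| / max(||a||, ||n||, 1e-12).  The
    norm form avoids spurious blow-ups on entries whose true gradient
    is at the round-off floor of central differences.
    """
    worst = 0.0
    for k, a in analytic.items():
        n = numeric[k]
        denom = max(float(np.linalg.norm(a)), float(np.linalg.norm(n)), 1e-12)
        worst = max(worst, float(np.linalg.norm(a - n)) / denom)
    return worst


def numeric_gradients(loss_fn, params: dict[str, np.ndarray],
                      eps: float = 1e-6) -> dict[str, np.ndarray]:
    """Central-difference gradients of ``loss_fn()`` w.r.t. every array."""
    out = {}
    for name, arr in params.items():
        g = np.zeros_like(arr)
        flat = arr.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_fn()
            flat[i] = orig - eps
            lm = loss_fn()
            flat[i] = orig
            gflat[i] = (lp - lm) / (2 * eps)
        out[name] = g
    return out
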
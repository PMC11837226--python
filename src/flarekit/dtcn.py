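"""Dilated temporal convolutional network for 3-class flaring ethograms.

Sequence-to-sequence classifier built from "dilation blocks": two dilated
1-D convolutions (kernel 9, 32 channels), each followed by a leaky ReLU and
dropout (p = 0.1), with a residual skip (1x1 projection when channel counts
differ) combined before a final leaky ReLU.  Two blocks feed a dense +
softmax head producing per-frame class probabilities.  Training uses
class-weighted cross-entropy (weight N/N_i for class i), Adam at 1e-4,
fixed-length sequence chunking with a 90/10 random split and early stopping
on validation loss.

Implemented directly on NumPy (forward and backward passes are explicit)
so the package has no deep-learning runtime dependency; training sizes here
are small enough that this is fast on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (DEFAULT_FRAME_RATE, Ethogram, FeatureSeries,
                   FLARE_CLASSES, subseed)

log = logging.getLogger(__name__)

LEAKY_SLOPE = 0.01
N_CLASSES = 3


@dataclass
class ClassifierSpec:
    n_blocks: int = 2
    channels: int = 32
    kernel_size: int = 9
    dropout_p: float = 0.1
    dilations: tuple | None = None       # default: 2**(block index) = (1, 2)
    sequence_length: int = 1000
    batch_size: int = 8
    train_fraction: float = 0.9
    patience: int = 20
    learning_rate: float = 1e-4
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.dilations is None:
            self.dilations = tuple(2 ** k for k in range(self.n_blocks))
        if len(self.dilations) != self.n_blocks:
            raise ValueError("need one dilation per block")
        for name in ("n_blocks", "channels", "kernel_size", "sequence_length",
                     "batch_size", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")


@dataclass
class ClassWeights:
    weights: np.ndarray     # per-class, 0 for absent classes
    total: int              # N = sum of counts


def class_weights(label_counts) -> ClassWeights:
    """Inverse-frequency loss weights: w_i = N / N_i, 0 for absent classes."""
    counts = np.asarray(label_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all class counts are zero")
    w = np.zeros_like(counts)
    present = counts > 0
    w[present] = total / counts[present]
    return ClassWeights(weights=w, total=int(total))


# --------------------------------------------------------------------------
# layers

def _conv1d_forward(x, W, b, dilation):
    """Dilated 1-D convolution with symmetric zero padding (same length).

    x: (B, Cin, T); W: (Cout, Cin, K); returns (y, cols) where cols is the
    gathered (B, Cin, K, T) view reused by the backward pass.
    """
    B, Cin, T = x.shape
    K = W.shape[2]
    pad = dilation * (K - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.empty((B, Cin, K, T), dtype=x.dtype)
    for k in range(K):
        cols[:, :, k, :] = xp[:, :, k * dilation:k * dilation + T]
    y = np.einsum("ock,bckt->bot", W, cols, optimize=True) + b[None, :, None]
    return y, cols


def _conv1d_backward(dy, cols, W, dilation, T):
    """Gradients of the dilated convolution; returns (dx, dW, db)."""
    K = W.shape[2]
    pad = dilation * (K - 1) // 2
    dW = np.einsum("bot,bckt->ock", dy, cols, optimize=True)
    db = dy.sum(axis=(0, 2))
    dcols = np.einsum("ock,bot->bckt", W, dy, optimize=True)
    B, Cin = dcols.shape[0], dcols.shape[1]
    dxp = np.zeros((B, Cin, T + 2 * pad), dtype=dy.dtype)
    for k in range(K):
        dxp[:, :, k * dilation:k * dilation + T] += dcols[:, :, k, :]
    return dxp[:, :, pad:pad + T], dW, db


def _lrelu(x):
    return np.where(x >= 0, x, LEAKY_SLOPE * x)


def _lrelu_grad(x):
    return np.where(x >= 0, 1.0, LEAKY_SLOPE)


class DTCN:
    """The network: parameters, forward pass and explicit gradients."""

    def __init__(self, spec: ClassifierSpec, n_features: int):
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        self.spec = spec
        self.n_features = n_features
        rng = np.random.default_rng(subseed(spec.seed, 0xD7C4))
        self.params = {}
        ch = spec.channels
        K = spec.kernel_size
        in_ch = n_features
        for bidx in range(spec.n_blocks):
            self._init_conv(rng, f"b{bidx}_c1", ch, in_ch, K)
            self._init_conv(rng, f"b{bidx}_c2", ch, ch, K)
            if in_ch != ch:
                self._init_conv(rng, f"b{bidx}_proj", ch, in_ch, 1)
            in_ch = ch
        self._init_conv(rng, "dense", N_CLASSES, ch, 1)
        # input standardization, set at training time
        self.input_mean = np.zeros(n_features)
        self.input_std = np.ones(n_features)

    def _init_conv(self, rng, name, cout, cin, k):
        scale = np.sqrt(2.0 / (cin * k))
        self.params[f"{name}_W"] = rng.normal(0.0, scale, size=(cout, cin, k))
        self.params[f"{name}_b"] = np.zeros(cout)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def standardize(self, x):
        return (x - self.input_mean[None, :, None]) / self.input_std[None, :, None]

    def forward(self, x, train: bool = False, drop_rng=None):
        """x: (B, n_features, T) raw features -> (probs, cache)."""
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature channels, got {x.shape[1]}")
        spec = self.spec
        p = self.params
        h = self.standardize(np.asarray(x, dtype=np.float64))
        T = h.shape[2]
        cache = {"T": T, "blocks": []}
        for bidx in range(spec.n_blocks):
            d = spec.dilations[bidx]
            blk = {"input": h, "dilation": d}
            a1, blk["cols1"] = _conv1d_forward(h, p[f"b{bidx}_c1_W"],
                                               p[f"b{bidx}_c1_b"], d)
            blk["a1"] = a1
            r1 = _lrelu(a1)
            r1, blk["mask1"] = self._dropout(r1, train, drop_rng)
            a2, blk["cols2"] = _conv1d_forward(r1, p[f"b{bidx}_c2_W"],
                                               p[f"b{bidx}_c2_b"], d)
            blk["a2"] = a2
            r2 = _lrelu(a2)
            r2, blk["mask2"] = self._dropout(r2, train, drop_rng)
            if f"b{bidx}_proj_W" in p:
                res, blk["cols_proj"] = _conv1d_forward(
                    h, p[f"b{bidx}_proj_W"], p[f"b{bidx}_proj_b"], 1)
            else:
                res, blk["cols_proj"] = h, None
            s = r2 + res
            blk["s"] = s
            h = _lrelu(s)
            cache["blocks"].append(blk)
        logits, cache["cols_dense"] = _conv1d_forward(h, p["dense_W"],
                                                      p["dense_b"], 1)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache["probs"] = probs
        return probs, cache

    def _dropout(self, x, train, rng):
        pdrop = self.spec.dropout_p
        if not train or pdrop == 0.0:
            return x, None
        mask = (rng.random(x.shape) >= pdrop) / (1.0 - pdrop)
        return x * mask, mask

    def loss_and_grads(self, x, labels, weights, train=True, drop_rng=None):
        """Weighted cross-entropy loss and parameter gradients.

        labels: (B, T) int; weights: per-class array (uniform weights give
        the unweighted cross-entropy exactly).
        """
        probs, cache = self.forward(x, train=train, drop_rng=drop_rng)
        B, C, T = probs.shape
        w = np.asarray(weights, dtype=float)[labels]          # (B, T)
        idx_b, idx_t = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
        p_true = probs[idx_b, labels, idx_t]
        denom = B * T
        loss = float((w * -np.log(np.maximum(p_true, 1e-300))).sum() / denom)

        onehot = np.zeros_like(probs)
        onehot[idx_b, labels, idx_t] = 1.0
        dlogits = (probs - onehot) * w[:, None, :] / denom

        grads = {k: None for k in self.params}
        p = self.params
        dh, grads["dense_W"], grads["dense_b"] = _conv1d_backward(
            dlogits, cache["cols_dense"], p["dense_W"], 1, T)
        for bidx in reversed(range(self.spec.n_blocks)):
            blk = cache["blocks"][bidx]
            d = blk["dilation"]
            ds = dh * _lrelu_grad(blk["s"])
            dr2 = ds if blk["mask2"] is None else ds * blk["mask2"]
            da2 = dr2 * _lrelu_grad(blk["a2"])
            dr1, grads[f"b{bidx}_c2_W"], grads[f"b{bidx}_c2_b"] = \
                _conv1d_backward(da2, blk["cols2"], p[f"b{bidx}_c2_W"], d, T)
            if blk["mask1"] is not None:
                dr1 = dr1 * blk["mask1"]
            da1 = dr1 * _lrelu_grad(blk["a1"])
            dh_conv, grads[f"b{bidx}_c1_W"], grads[f"b{bidx}_c1_b"] = \
                _conv1d_backward(da1, blk["cols1"], p[f"b{bidx}_c1_W"], d, T)
            if blk["cols_proj"] is not None:
                dres, grads[f"b{bidx}_proj_W"], grads[f"b{bidx}_proj_b"] = \
                    _conv1d_backward(ds, blk["cols_proj"],
                                     p[f"b{bidx}_proj_W"], 1, T)
            else:
                dres = ds
            dh = dh_conv + dres
        return loss, grads


def build_dtcn(spec: ClassifierSpec, n_features: int) -> DTCN:
    """Construct the network for a given feature-channel count."""
    return DTCN(spec, n_features)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def chunk_sequences(features_list, labels_list, sequence_length: int):
    """Chunk aligned feature/label records into fixed-length sequences.

    Features may be FeatureSeries or (T, C) arrays; labels Ethogram or (T,)
    int arrays.  The remainder of each record shorter than one sequence is
    dropped (and logged).  Returns X (N, C, L), Y (N, L).
    """
    xs, ys = [], []
    dropped = 0
    for feats, labs in zip(features_list, labels_list):
        F = (feats.data.to_numpy(dtype=float) if isinstance(feats, FeatureSeries)
             else np.asarray(feats, dtype=float))
        L = labs.labels if isinstance(labs, Ethogram) else np.asarray(labs)
        if len(F) != len(L):
            raise ValueError("features and labels must be aligned")
        n_seq = len(F) // sequence_length
        dropped += len(F) - n_seq * sequence_length
        for i in range(n_seq):
            sl = slice(i * sequence_length, (i + 1) * sequence_length)
            xs.append(F[sl].T)
            ys.append(np.asarray(L[sl], dtype=int))
    if dropped:
        log.info("chunking dropped %d remainder frames", dropped)
    if not xs:
        raise ValueError("no complete sequences after chunking")
    return np.stack(xs), np.stack(ys)


def train_dtcn(model: DTCN, features_list, labels_list,
               spec: ClassifierSpec | None = None,
               max_epochs: int | None = None):
    """Train with Adam, early stopping on validation loss.

    Sequences are split train/validation at the sequence level with the run
    seed; class weights (N/N_i) come from the training split.  Training
    stops after ``patience`` epochs without a new validation minimum; the
    parameters at the validation-loss minimum are restored.  Returns
    (model, history) with per-epoch train/val losses.
    """
    spec = spec or model.spec
    if max_epochs is None:
        max_epochs = spec.max_epochs
    X, Y = chunk_sequences(features_list, labels_list, spec.sequence_length)
    n_seq = len(X)
    if n_seq < 2:
        raise ValueError("need at least 2 sequences (train + validation)")
    rng = np.random.default_rng(subseed(spec.seed, 0x5EED))
    order = rng.permutation(n_seq)
    n_train = min(max(int(round(spec.train_fraction * n_seq)), 1), n_seq - 1)
    tr, va = order[:n_train], order[n_train:]
    Xtr, Ytr, Xva, Yva = X[tr], Y[tr], X[va], Y[va]

    # standardize inputs on training statistics
    flat = Xtr.transpose(1, 0, 2).reshape(Xtr.shape[1], -1)
    model.input_mean = flat.mean(axis=1)
    model.input_std = np.maximum(flat.std(axis=1), 1e-8)

    counts = np.bincount(Ytr.ravel(), minlength=N_CLASSES)
    cw = class_weights(counts)
    history = {"train_loss": [], "val_loss": [],
               "class_counts": counts.tolist(),
               "class_weights": cw.weights.tolist(),
               "n_train_sequences": int(n_train),
               "n_val_sequences": int(n_seq - n_train)}

    drop_rng = np.random.default_rng(subseed(spec.seed, 0xD809))
    opt = _Adam(model.params, spec.learning_rate)
    best_loss = np.inf
    best_params = model.copy_params()
    best_epoch = -1
    since_best = 0

    for epoch in range(max_epochs):
        perm = rng.permutation(n_train)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n_train, spec.batch_size):
            bidx = perm[start:start + spec.batch_size]
            loss, grads = model.loss_and_grads(Xtr[bidx], Ytr[bidx], cw.weights,
                                               train=True, drop_rng=drop_rng)
            opt.step(model.params, grads)
            ep_loss += loss
            n_batches += 1
        val_loss = evaluate_loss(model, Xva, Yva, cw.weights)
        history["train_loss"].append(ep_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = model.copy_params()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= spec.patience:
                break
    if best_epoch >= 0:
        model.set_params(best_params)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = None if best_epoch < 0 else float(best_loss)
    return model, history


def evaluate_loss(model: DTCN, X, Y, weights, batch_size: int = 8) -> float:
    """Mean weighted cross-entropy over a sequence set, dropout disabled."""
    total, n = 0.0, 0
    for start in range(0, len(X), batch_size):
        xb, yb = X[start:start + batch_size], Y[start:start + batch_size]
        probs, _ = model.forward(xb, train=False)
        B, _, T = probs.shape
        idx_b, idx_t = np.meshgrid(np.arange(B), np.arange(T), indexing="ij")
        w = np.asarray(weights)[yb]
        p_true = probs[idx_b, yb, idx_t]
        total += float((w * -np.log(np.maximum(p_true, 1e-300))).sum())
        n += B * T
    return total / max(n, 1)


def predict_ethogram(model: DTCN, features,
                     frame_rate: float = DEFAULT_FRAME_RATE) -> Ethogram:
    """Per-frame argmax of predicted class probabilities.

    Ties break toward the lower class index (none < partial < full).
    """
    if isinstance(features, FeatureSeries):
        frame_rate = features.frame_rate
        F = features.data.to_numpy(dtype=float)
    else:
        F = np.asarray(features, dtype=float)
    if F.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} channels, got {F.shape[1]}")
    probs, _ = model.forward(F.T[None], train=False)
    labels = np.argmax(probs[0], axis=0)       # first max -> lower index wins
    return Ethogram(labels=labels.astype(np.int8), frame_rate=frame_rate,
                    provenance="predicted")


@dataclass
class EvaluationReport:
    per_class: dict                 # name -> {precision, recall, f1} or None
    macro_f1: float
    proportion_flaring_pred: float
    proportion_flaring_true: float

    @property
    def proportion_flaring_abs_diff(self) -> float:
        return abs(self.proportion_flaring_pred - self.proportion_flaring_true)


def evaluate(pred: Ethogram, truth: Ethogram) -> EvaluationReport:
    """Per-class precision/recall/F1 (harmonic mean) plus the comparison of
    the proportion of time spent flaring (partial + full combined).

    A class absent from both prediction and truth is reported as None and
    excluded from the macro average.
    """
    if len(pred) != len(truth):
        raise ValueError("prediction and truth must have equal length")
    yp = pred.labels
    yt = truth.labels
    per_class = {}
    f1s = []
    for cls_id, name in enumerate(FLARE_CLASSES):
        tp = int(((yp == cls_id) & (yt == cls_id)).sum())
        fp = int(((yp == cls_id) & (yt != cls_id)).sum())
        fn = int(((yp != cls_id) & (yt == cls_id)).sum())
        if tp + fp + fn == 0:
            per_class[name] = None
            continue
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[name] = {"precision": prec, "recall": rec, "f1": f1}
        f1s.append(f1)
    macro = float(np.mean(f1s)) if f1s else float("nan")
    return EvaluationReport(per_class=per_class, macro_f1=macro,
                            proportion_flaring_pred=float(pred.binary.mean()),
                            proportion_flaring_true=float(truth.binary.mean()))


def dataset_frame_total(n_videos: int, duration_s: float,
                        frame_rate: float = DEFAULT_FRAME_RATE) -> int:
    """Bookkeeping: total frames in a set of equal-length recordings."""
    return int(round(n_videos * duration_s * frame_rate))
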
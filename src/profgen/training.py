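"""Training the profile generator: RMSE cost, Adam, dropout, random-start crops.

The cost is the root mean square error between the softmax output and the
teacher profile over all (site, residue-type) entries of a mini-batch, with
padded positions masked out. Regularisation is unit dropout on the embedding
output (between the input layer and the LSTM layer) with inverted scaling at
train time, active only in training passes. Each epoch learns a random
subsample of the training pool; within a sequence, the starting site is not
confined to the N-terminus but drawn at random, so the model cannot overfit
site-specific features of sequence starts.

Backpropagation through time is derived analytically (see ``loss_and_gradients``),
and its correctness against central finite differences is part of the test
suite. Reference hyperparameters: batch size 200, epoch subsample 40 000,
5000 epochs, dropout 0.5, validation set 20 000 — every experiment in this
package runs scaled-down versions of the same loop.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence as TypingSequence, Tuple

import numpy as np

from .alphabet import N_AA, PAD_INDEX, encode
from .lstm import LSTMParams, ModelParams, init_params, sigmoid, softmax_rows
from .types import ProfileMatrix, Sequence

__all__ = [
    "TrainingConfig",
    "TrainingReport",
    "rmse_loss",
    "crop_random_start",
    "sample_epoch",
    "loss_and_gradients",
    "train",
    "validate",
]

Pair = Tuple[Sequence, ProfileMatrix]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of a training run (defaults = reference configuration)."""

    batch_size: int = 200
    epoch_subsample: int = 40000
    max_epochs: int = 5000
    dropout_ratio: float = 0.5
    validation_size: int = 20000
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    seed: int = 0
    crop: bool = True
    crop_max_len: int = 1000
    dtype: str = "float64"  # "float32" roughly halves time and memory


@dataclass
class TrainingReport:
    """Learning-curve record and final parameters of one run."""

    params: ModelParams
    train_losses: List[float] = field(default_factory=list)
    val_losses: List[float] = field(default_factory=list)
    n_updates: int = 0
    wall_time: float = 0.0


def rmse_loss(pred, target) -> float:
    """Root mean square error over all N x 20 entries; zero iff equal."""
    a = pred.matrix if isinstance(pred, ProfileMatrix) else np.asarray(pred, dtype=float)
    b = target.matrix if isinstance(target, ProfileMatrix) else np.asarray(target, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def crop_random_start(
    seq: Sequence, target: ProfileMatrix, max_len: int, rng: np.random.Generator
) -> Pair:
    """Crop both sequence and profile from a uniformly random start site.

    Returns positions s..min(N, s+max_len-1) of both, kept aligned; the
    cropped profile rows are the teacher rows of the same absolute sites.
    """
    if target.n != seq.n:
        raise ValueError("profile rows must match sequence length")
    s = int(rng.integers(0, seq.n))
    end = min(seq.n, s + max_len)
    return (
        Sequence(seq.id, seq.residues[s:end]),
        ProfileMatrix(target.matrix[s:end], source=target.source),
    )


def sample_epoch(dataset: TypingSequence[Pair], k: int, rng: np.random.Generator) -> List[Pair]:
    """Uniform subsample without replacement defining one epoch."""
    if k > len(dataset):
        raise ValueError(f"cannot draw {k} items from a dataset of {len(dataset)}")
    idx = rng.choice(len(dataset), size=k, replace=False)
    return [dataset[i] for i in idx]


# ---------------------------------------------------------------------------
# batched forward/backward
# ---------------------------------------------------------------------------


def _batch_arrays(pairs: TypingSequence[Pair], dtype) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-pad a list of pairs to (X, targets, mask) arrays."""
    lengths = [p[0].n for p in pairs]
    b, t_max = len(pairs), max(lengths)
    x = np.full((b, t_max), PAD_INDEX, dtype=np.int64)
    tgt = np.zeros((b, t_max, N_AA), dtype=dtype)
    mask = np.zeros((b, t_max), dtype=bool)
    for i, (seq, prof) in enumerate(pairs):
        n = seq.n
        x[i, :n] = encode(seq.residues)
        tgt[i, :n] = prof.matrix
        mask[i, :n] = True
    return x, tgt, mask


def _forward(params: ModelParams, x: np.ndarray, drop_mask: Optional[np.ndarray]):
    """Batched forward pass caching every gate activation for backprop."""
    b, t_max = x.shape
    h = params.hidden_size
    lstm = params.lstm
    e = params.embed_table[x]  # (B, T, d)
    if drop_mask is not None:
        e = e * drop_mask
    a_in = e @ lstm.w_in  # (B, T, 4H)
    gates_i = np.empty((b, t_max, h), dtype=e.dtype)
    gates_f = np.empty_like(gates_i)
    gates_z = np.empty_like(gates_i)
    gates_o = np.empty_like(gates_i)
    cells = np.empty_like(gates_i)
    tanh_c = np.empty_like(gates_i)
    outs = np.empty_like(gates_i)
    h_prev = np.zeros((b, h), dtype=e.dtype)
    c_prev = np.zeros((b, h), dtype=e.dtype)
    for t in range(t_max):
        a = a_in[:, t] + h_prev @ lstm.w_rec + lstm.bias
        gi = sigmoid(a[:, :h])
        gf = sigmoid(a[:, h : 2 * h])
        gz = np.tanh(a[:, 2 * h : 3 * h])
        go = sigmoid(a[:, 3 * h :])
        c = gf * c_prev + gi * gz
        tc = np.tanh(c)
        v = go * tc
        gates_i[:, t], gates_f[:, t], gates_z[:, t], gates_o[:, t] = gi, gf, gz, go
        cells[:, t], tanh_c[:, t], outs[:, t] = c, tc, v
        h_prev, c_prev = v, c
    logits = outs @ params.fc_weight + params.fc_bias
    probs = softmax_rows(logits)
    cache = dict(
        e=e, i=gates_i, f=gates_f, z=gates_z, o=gates_o,
        c=cells, tc=tanh_c, v=outs, p=probs,
    )
    return probs, cache


def _masked_rmse(probs: np.ndarray, tgt: np.ndarray, mask: np.ndarray) -> Tuple[float, np.ndarray, int]:
    diff = (probs - tgt) * mask[..., None]
    n_entries = int(mask.sum()) * N_AA
    loss = float(np.sqrt((diff**2).sum() / n_entries))
    return loss, diff, n_entries


def _backward(
    params: ModelParams,
    x: np.ndarray,
    tgt: np.ndarray,
    mask: np.ndarray,
    cache: dict,
    drop_mask: Optional[np.ndarray],
) -> Tuple[float, Dict[str, np.ndarray]]:
    lstm = params.lstm
    h = params.hidden_size
    b, t_max = x.shape
    probs = cache["p"]
    loss, diff, n_entries = _masked_rmse(probs, tgt, mask)
    grads = {k: np.zeros_like(a) for k, a in params.arrays().items()}
    if loss == 0.0:
        return loss, grads
    dp = diff / (n_entries * loss)
    # softmax backward (rows are independent)
    dlogits = probs * (dp - (dp * probs).sum(axis=-1, keepdims=True))
    v = cache["v"]
    grads["fc_weight"] = v.reshape(-1, h).T @ dlogits.reshape(-1, N_AA)
    grads["fc_bias"] = dlogits.sum(axis=(0, 1))
    dv_out = dlogits @ params.fc_weight.T  # (B, T, H)

    da_all = np.empty((b, t_max, 4 * h), dtype=v.dtype)
    dh_next = np.zeros((b, h), dtype=v.dtype)
    dc_next = np.zeros((b, h), dtype=v.dtype)
    gi, gf, gz, go = cache["i"], cache["f"], cache["z"], cache["o"]
    cells, tanh_c = cache["c"], cache["tc"]
    for t in range(t_max - 1, -1, -1):
        dh = dv_out[:, t] + dh_next
        dc = dc_next + dh * go[:, t] * (1.0 - tanh_c[:, t] ** 2)
        c_prev = cells[:, t - 1] if t > 0 else np.zeros((b, h), dtype=v.dtype)
        da = da_all[:, t]
        da[:, :h] = dc * gz[:, t] * gi[:, t] * (1.0 - gi[:, t])
        da[:, h : 2 * h] = dc * c_prev * gf[:, t] * (1.0 - gf[:, t])
        da[:, 2 * h : 3 * h] = dc * gi[:, t] * (1.0 - gz[:, t] ** 2)
        da[:, 3 * h :] = dh * tanh_c[:, t] * go[:, t] * (1.0 - go[:, t])
        dh_next = da @ lstm.w_rec.T
        dc_next = dc * gf[:, t]

    e = cache["e"]
    d = e.shape[-1]
    grads["w_in"] = e.reshape(-1, d).T @ da_all.reshape(-1, 4 * h)
    h_prev = np.zeros_like(v)
    h_prev[:, 1:] = v[:, :-1]
    grads["w_rec"] = h_prev.reshape(-1, h).T @ da_all.reshape(-1, 4 * h)
    grads["bias"] = da_all.sum(axis=(0, 1))
    de = da_all @ lstm.w_in.T
    if drop_mask is not None:
        de = de * drop_mask
    d_embed = grads["embed_table"]
    np.add.at(d_embed, x.reshape(-1), de.reshape(-1, d))
    d_embed[PAD_INDEX] = 0.0  # padding embedding is pinned to zero
    return loss, grads


def loss_and_gradients(
    params: ModelParams,
    pairs: TypingSequence[Pair],
    drop_mask: Optional[np.ndarray] = None,
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Batch RMSE loss and its analytic gradients w.r.t. every parameter array.

    ``drop_mask``, when given, multiplies the embedding output (shape
    B x T x d); passing an inverted-dropout mask reproduces a training pass.
    """
    dtype = params.dtype
    x, tgt, mask = _batch_arrays(pairs, dtype)
    _, cache = _forward(params, x, drop_mask)
    return _backward(params, x, tgt, mask, cache, drop_mask)


class _Adam:
    def __init__(self, params: ModelParams, cfg: TrainingConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(a) for k, a in params.arrays().items()}
        self.v = {k: np.zeros_like(a) for k, a in params.arrays().items()}
        self.t = 0

    def step(self, params: ModelParams, grads: Dict[str, np.ndarray]) -> None:
        cfg = self.cfg
        self.t += 1
        b1t = 1.0 - cfg.beta1**self.t
        b2t = 1.0 - cfg.beta2**self.t
        for k, a in params.arrays().items():
            g = grads[k]
            self.m[k] = cfg.beta1 * self.m[k] + (1.0 - cfg.beta1) * g
            self.v[k] = cfg.beta2 * self.v[k] + (1.0 - cfg.beta2) * g * g
            a -= cfg.learning_rate * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + cfg.epsilon)


def _batches(pairs: List[Pair], batch_size: int) -> List[List[Pair]]:
    """Sort-by-length bucketing to limit padding waste."""
    ordered = sorted(pairs, key=lambda p: p[0].n)
    return [ordered[i : i + batch_size] for i in range(0, len(ordered), batch_size)]


def validate(params: ModelParams, pairs: TypingSequence[Pair], batch_size: int = 200) -> float:
    """Mean per-pair RMSE with dropout inactive."""
    if not pairs:
        raise ValueError("validation set is empty")
    dtype = params.dtype
    losses = []
    for chunk in _batches(list(pairs), batch_size):
        x, tgt, mask = _batch_arrays(chunk, dtype)
        probs, _ = _forward(params, x, None)
        sq = ((probs - tgt) ** 2 * mask[..., None]).sum(axis=(1, 2))
        n = mask.sum(axis=1) * N_AA
        losses.extend(np.sqrt(sq / n).tolist())
    return float(np.mean(losses))


def train(
    dataset: TypingSequence[Pair],
    config: TrainingConfig,
    embed_dim: int = 400,
    hidden_size: int = 3200,
    init: Optional[ModelParams] = None,
) -> TrainingReport:
    """Mini-batch Adam on the RMSE cost; fully reproducible given config.seed.

    The validation split (``config.validation_size`` pairs) is held out of
    the training pool; both learning curves are recorded per epoch.
    """
    if len(dataset) <= config.validation_size:
        raise ValueError("dataset must be larger than the validation split")
    dtype = np.float32 if config.dtype == "float32" else np.float64
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    val_pairs = [dataset[i] for i in order[: config.validation_size]]
    pool = [dataset[i] for i in order[config.validation_size :]]

    params = init.copy() if init is not None else init_params(
        embed_dim, hidden_size, rng=rng, dtype=dtype
    )
    opt = _Adam(params, config)
    report = TrainingReport(params=params)
    started = time.perf_counter()
    keep = 1.0 - config.dropout_ratio
    k = min(config.epoch_subsample, len(pool))

    for _epoch in range(config.max_epochs):
        epoch_pairs = sample_epoch(pool, k, rng)
        if config.crop:
            epoch_pairs = [
                crop_random_start(s, p, config.crop_max_len, rng) for s, p in epoch_pairs
            ]
        epoch_losses = []
        for batch in _batches(epoch_pairs, config.batch_size):
            x, tgt, mask = _batch_arrays(batch, dtype)
            drop = None
            if config.dropout_ratio > 0.0:
                drop = (
                    rng.random((x.shape[0], x.shape[1], embed_dim)) < keep
                ).astype(dtype) / keep
            _, cache = _forward(params, x, drop)
            loss, grads = _backward(params, x, tgt, mask, cache, drop)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at update {opt.t + 1}"
                )
            opt.step(params, grads)
            epoch_losses.append(loss)
        report.train_losses.append(float(np.mean(epoch_losses)))
        report.val_losses.append(validate(params, val_pairs, config.batch_size))
    report.n_updates = opt.t
    report.wall_time = time.perf_counter() - started
    return report
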
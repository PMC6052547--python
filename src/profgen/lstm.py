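"""Forward model: word embedding -> forget-gate LSTM -> softmax head.

The generator maps an amino-acid sequence to an N x 20 profile one site at a
time. Each residue is embedded as a dense d-dimensional vector, fed through a
single LSTM layer with input, forget and output gates around a constant-error
memory cell, and the LSTM output at each position is projected by a fully
connected layer to 20 logits whose softmax is the predicted probability
column for that site. The recurrent state is initialised to the null vector
at the N-terminus, so position t sees exactly residues 1..t — the model is
causal by construction.

Gate equations, with u the embedded input, h the previous unit output and
c the memory cell (``∘`` elementwise):

    i = σ(u W_i + h R_i + b_i)          input gate
    f = σ(u W_f + h R_f + b_f)          forget gate
    z = τ(u W_z + h R_z + b_z)          candidate
    o = σ(u W_o + h R_o + b_o)          output gate
    c' = f ∘ c + i ∘ z
    v  = o ∘ τ(c'),   h' = v

The reference configuration is d = 400 and H = 3200 gate units; every
operation also works at arbitrary scaled-down dimensions.

``truncated_forward`` implements the memory-reset mode: with reset length L,
the profile column at position t is computed from a fresh null state over the
window of the previous L sites including the current one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .alphabet import AA_ORDER, N_AA, PAD_INDEX, encode
from .types import ProfileMatrix, Sequence

__all__ = [
    "LSTMParams",
    "ModelParams",
    "RecurrentState",
    "init_params",
    "embed",
    "lstm_step",
    "forward_profile",
    "truncated_forward",
    "reset_step_count",
    "get_step_count",
    "save_model",
    "load_model",
]

GATES = ("input", "forget", "candidate", "output")

# global invocation counter for the linear-work property
_STEP_COUNT = 0


def reset_step_count() -> None:
    global _STEP_COUNT
    _STEP_COUNT = 0


def get_step_count() -> int:
    return _STEP_COUNT


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-sided formulation
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax_rows(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class LSTMParams:
    """Gate parameters, stored stacked as [input | forget | candidate | output].

    ``w_in`` is d x 4H (weights on the embedded input), ``w_rec`` is H x 4H
    (weights on the fed-back unit output) and ``bias`` is 4H.
    """

    w_in: np.ndarray
    w_rec: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        d, four_h = self.w_in.shape
        if four_h % 4 or self.w_rec.shape != (four_h // 4, four_h) or self.bias.shape != (four_h,):
            raise ValueError("inconsistent LSTM parameter shapes")

    @property
    def hidden_size(self) -> int:
        return self.w_in.shape[1] // 4

    def gate(self, name: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(W_g, R_g, b_g) view for gate g in {input, forget, candidate, output}."""
        g = GATES.index(name)
        h = self.hidden_size
        sl = slice(g * h, (g + 1) * h)
        return self.w_in[:, sl], self.w_rec[:, sl], self.bias[sl]


@dataclass
class ModelParams:
    """Learned state of the profile generator.

    ``embed_table`` has 21 rows: the 20 residues in alphabet order plus the
    padding symbol, whose row is pinned to zero.
    """

    embed_table: np.ndarray  # (21, d)
    lstm: LSTMParams
    fc_weight: np.ndarray  # (H, 20)
    fc_bias: np.ndarray  # (20,)

    def __post_init__(self):
        if self.embed_table.shape[0] != N_AA + 1:
            raise ValueError("embedding table must have 21 rows (20 residues + padding)")
        d = self.embed_table.shape[1]
        h = self.lstm.hidden_size
        if self.lstm.w_in.shape[0] != d:
            raise ValueError("embedding dim does not match LSTM input dim")
        if self.fc_weight.shape != (h, N_AA) or self.fc_bias.shape != (N_AA,):
            raise ValueError("fully connected head shape mismatch")

    @property
    def embed_dim(self) -> int:
        return self.embed_table.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.lstm.hidden_size

    @property
    def dtype(self) -> np.dtype:
        return self.embed_table.dtype

    def arrays(self) -> dict:
        """Named views of all trainable arrays (embedding row 21 stays zero)."""
        return {
            "embed_table": self.embed_table,
            "w_in": self.lstm.w_in,
            "w_rec": self.lstm.w_rec,
            "bias": self.lstm.bias,
            "fc_weight": self.fc_weight,
            "fc_bias": self.fc_bias,
        }

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.embed_table.copy(),
            LSTMParams(self.lstm.w_in.copy(), self.lstm.w_rec.copy(), self.lstm.bias.copy()),
            self.fc_weight.copy(),
            self.fc_bias.copy(),
        )


@dataclass
class RecurrentState:
    """hidden = previous unit output fed back; cell = constant-error memory."""

    hidden: np.ndarray
    cell: np.ndarray

    @classmethod
    def null(cls, h: int, dtype=np.float64) -> "RecurrentState":
        return cls(np.zeros(h, dtype=dtype), np.zeros(h, dtype=dtype))


def _orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def init_params(
    embed_dim: int = 400,
    hidden_size: int = 3200,
    rng: Optional[np.random.Generator] = None,
    dtype=np.float64,
    forget_bias: float = 1.0,
) -> ModelParams:
    """Random initial parameters.

    Embedding rows are uniform(-0.1, 0.1); input weights use Glorot-uniform
    scaling; recurrent weights are orthogonal per gate block; the forget-gate
    bias starts positive (default 1.0) so memory is retained early in
    training — the standard recipe for learning long dependencies.
    """
    rng = np.random.default_rng() if rng is None else rng
    d, h = embed_dim, hidden_size
    embed_table = rng.uniform(-0.1, 0.1, size=(N_AA + 1, d))
    embed_table[PAD_INDEX] = 0.0
    lim = np.sqrt(6.0 / (d + h))
    w_in = rng.uniform(-lim, lim, size=(d, 4 * h))
    w_rec = np.concatenate([_orthogonal(h, rng) for _ in GATES], axis=1)
    bias = np.zeros(4 * h)
    bias[h : 2 * h] = forget_bias
    fc_lim = np.sqrt(6.0 / (h + N_AA))
    fc_weight = rng.uniform(-fc_lim, fc_lim, size=(h, N_AA))
    fc_bias = np.zeros(N_AA)
    return ModelParams(
        embed_table.astype(dtype),
        LSTMParams(w_in.astype(dtype), w_rec.astype(dtype), bias.astype(dtype)),
        fc_weight.astype(dtype),
        fc_bias.astype(dtype),
    )


def embed(residue: str, params: ModelParams) -> np.ndarray:
    """The embedding row for one residue symbol ('-' denotes padding)."""
    if residue == "-":
        return params.embed_table[PAD_INDEX]
    if residue not in AA_ORDER:
        raise KeyError(f"unknown residue symbol {residue!r}")
    return params.embed_table[AA_ORDER.index(residue)]


def lstm_step(
    u: np.ndarray, state: RecurrentState, params: LSTMParams
) -> Tuple[np.ndarray, RecurrentState]:
    """One LSTM update; pure function of (u, state, params).

    Returns the unit output v and the new state (hidden' = v, cell' updated
    through the constant-error carousel).
    """
    global _STEP_COUNT
    _STEP_COUNT += 1
    h = params.hidden_size
    if u.shape[-1] != params.w_in.shape[0]:
        raise ValueError(
            f"input dim {u.shape[-1]} does not match LSTM input dim {params.w_in.shape[0]}"
        )
    if state.hidden.shape[-1] != h:
        raise ValueError("state size does not match LSTM hidden size")
    a = u @ params.w_in + state.hidden @ params.w_rec + params.bias
    i = sigmoid(a[..., :h])
    f = sigmoid(a[..., h : 2 * h])
    z = np.tanh(a[..., 2 * h : 3 * h])
    o = sigmoid(a[..., 3 * h :])
    cell = f * state.cell + i * z
    v = o * np.tanh(cell)
    return v, RecurrentState(v, cell)


def forward_profile(seq: Sequence, params: ModelParams) -> ProfileMatrix:
    """Predict the full profile of a sequence from the null initial state.

    Row t is softmax(v_t W_fc + b_fc) where v_t is the LSTM output after
    consuming residues 1..t. Every row sums to 1.
    """
    if seq.n == 0:
        raise ValueError("cannot predict a profile for an empty sequence")
    idx = encode(seq.residues)
    state = RecurrentState.null(params.hidden_size, dtype=params.dtype)
    rows = np.empty((seq.n, N_AA), dtype=params.dtype)
    for t, j in enumerate(idx):
        v, state = lstm_step(params.embed_table[j], state, params.lstm)
        rows[t] = v @ params.fc_weight + params.fc_bias
    return ProfileMatrix(softmax_rows(rows), source="predicted")


def truncated_forward(seq: Sequence, params: ModelParams, memory_length: int) -> ProfileMatrix:
    """Memory-reset prediction: row t uses only the previous ``memory_length``
    sites including site t, each window re-run from the null state.

    With memory_length >= N this reproduces ``forward_profile`` bit for bit.
    """
    if memory_length < 1:
        raise ValueError("memory length must be >= 1")
    if seq.n == 0:
        raise ValueError("cannot predict a profile for an empty sequence")
    if memory_length >= seq.n:
        return forward_profile(seq, params)
    idx = encode(seq.residues)
    rows = np.empty((seq.n, N_AA), dtype=params.dtype)
    for t in range(seq.n):
        start = max(0, t - memory_length + 1)
        state = RecurrentState.null(params.hidden_size, dtype=params.dtype)
        for j in idx[start : t + 1]:
            v, state = lstm_step(params.embed_table[j], state, params.lstm)
        rows[t] = v @ params.fc_weight + params.fc_bias
    return ProfileMatrix(softmax_rows(rows), source="predicted")


MODEL_FORMAT_VERSION = 1


def save_model(params: ModelParams, path) -> None:
    """Serialize parameters to a single versioned .npz container."""
    np.savez(
        path,
        format_version=np.array(MODEL_FORMAT_VERSION),
        **params.arrays(),
    )


def load_model(path) -> ModelParams:
    with np.load(path) as z:
        version = int(z["format_version"])
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        return ModelParams(
            z["embed_table"],
            LSTMParams(z["w_in"], z["w_rec"], z["bias"]),
            z["fc_weight"],
            z["fc_bias"],
        )
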
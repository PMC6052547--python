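"""Synthetic teacher: context-dependent ground truth for (sequence, profile) pairs.

Real training targets for a de novo profile generator come from iterative
database searches; at desk scale this module stands in with a generative rule
whose context dependence is known and controllable. Each site t carries a
hidden environment state e_t drawn from ``n_states`` possibilities; every
state owns a fixed 20-dim probability column (drawn once from a symmetric
Dirichlet), the target profile row at t is the column of e_t, and the residue
at t is sampled from that row.

The environment assignment is a *deterministic* function of the residues
preceding the site, never of future residues, so the teacher is causal in the
same sense as the left-to-right generator and the Bayes-optimal predictor is
exactly the teacher rule:

* local context: e_t hashes the previous ``context_k`` residues into a state;
* persistence: with hash-derived pseudo-probability ``rho`` the previous
  environment is kept, producing longer run lengths (the hash keeps the
  assignment a pure function of the prefix);
* long-range pairing mode: when ``pair_offset`` Δ is set, e_t at t ≥ Δ is
  determined by the residue at t−Δ — the analogue of a β-strand partner
  residue constraining the local environment from far away in sequence.
  Sites t < Δ share one fixed state.

The default configuration keeps ``rho`` at 0 so the dependency range is
exactly ``context_k`` (or Δ), which makes truncated-memory experiments sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence as TypingSequence, Tuple

import numpy as np

from .alphabet import AA_ORDER, N_AA, encode
from .types import ProfileMatrix, Sequence

__all__ = [
    "TeacherConfig",
    "TeacherModel",
    "make_teacher",
    "sample_pair",
    "sample_dataset",
    "make_timing_sequences",
]

_MASK32 = 0xFFFFFFFF


def _mix(values, salt: int) -> int:
    """Deterministic 32-bit hash of a residue-index tuple."""
    h = (salt * 0x9E3779B9 + 0x85EBCA6B) & _MASK32
    for v in values:
        h = ((h ^ (int(v) + 0x9E3779B9)) * 2654435761) & _MASK32
        h ^= h >> 16
    return h


@dataclass(frozen=True)
class TeacherConfig:
    """Study conditions for the synthetic teacher.

    n_states: number of hidden environment states.
    context_k: the environment at site t is a hash of residues t−k..t−1.
    rho: pseudo-probability of persisting the previous site's environment
        (hash-derived, so the assignment stays a pure function of the prefix).
    pair_offset: optional Δ — long-range mode, environment at t determined by
        the residue at t−Δ (context_k is ignored past Δ when 0).
    emission_concentration: symmetric Dirichlet α for the state columns;
        smaller α gives sharper, more mutually distinct columns.
    length_range: inclusive uniform range for sampled sequence lengths.
    """

    n_states: int = 4
    context_k: int = 2
    rho: float = 0.0
    pair_offset: Optional[int] = None
    emission_concentration: float = 0.5
    length_range: Tuple[int, int] = (50, 100)
    seed: int = 0


@dataclass
class TeacherModel:
    """Frozen ground-truth rule mapping sequence context to profile columns."""

    columns: np.ndarray  # n_states x 20
    config: TeacherConfig
    _salt_env: int = field(default=0)
    _salt_persist: int = field(default=0)

    def environment(self, prefix_indices: np.ndarray, t: int) -> int:
        """Hidden state at site t given the residues before t (as indices).

        Pure function of ``prefix_indices[:t]``; recursion through the
        persistence rule only ever consults earlier sites.
        """
        cfg = self.config
        if cfg.pair_offset is not None:
            if t < cfg.pair_offset:
                return _mix((), self._salt_env) % cfg.n_states
            window = list(prefix_indices[max(0, t - cfg.context_k) : t]) if cfg.context_k else []
            window.append(prefix_indices[t - cfg.pair_offset])
            return _mix(window, self._salt_env) % cfg.n_states
        base = _mix(prefix_indices[max(0, t - cfg.context_k) : t], self._salt_env) % cfg.n_states
        if cfg.rho > 0.0 and t > 0:
            u = _mix(prefix_indices[max(0, t - cfg.context_k - 1) : t], self._salt_persist)
            if u / 2**32 < cfg.rho:
                return self.environment(prefix_indices, t - 1)
        return base

    def target_profile(self, seq: Sequence) -> ProfileMatrix:
        """Exact teacher profile for an existing sequence."""
        idx = encode(seq.residues)
        states = [self.environment(idx, t) for t in range(len(idx))]
        return ProfileMatrix(self.columns[states], source="teacher")


def make_teacher(config: TeacherConfig) -> TeacherModel:
    """Draw state columns from Dirichlet(α·1) under the config seed."""
    if config.n_states < 1:
        raise ValueError("n_states must be >= 1")
    if not 0.0 <= config.rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(config.seed)
    columns = rng.dirichlet(
        np.full(N_AA, config.emission_concentration), size=config.n_states
    )
    salt_env = int(rng.integers(1, 2**31))
    salt_persist = int(rng.integers(1, 2**31))
    return TeacherModel(columns, config, salt_env, salt_persist)


def sample_pair(
    teacher: TeacherModel, length: int, rng: np.random.Generator, seq_id: str = "synthetic"
) -> Tuple[Sequence, ProfileMatrix]:
    """One (sequence, exact target profile) pair of the given length.

    Residue t is sampled from the column of the environment at t; the target
    matrix holds the teacher truth (the columns themselves), not the
    empirical draw, so the Bayes ceiling of any predictor is known.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    idx = np.empty(length, dtype=np.int64)
    target = np.empty((length, N_AA))
    cum = teacher.columns.cumsum(axis=1)
    unif = rng.random(length)
    for t in range(length):
        e = teacher.environment(idx, t)
        target[t] = teacher.columns[e]
        idx[t] = np.searchsorted(cum[e], unif[t], side="right")
    residues = "".join(AA_ORDER[i] for i in idx)
    return Sequence(seq_id, residues), ProfileMatrix(target, source="teacher")


def sample_dataset(
    teacher: TeacherModel, n_pairs: int, rng: np.random.Generator
) -> List[Tuple[Sequence, ProfileMatrix]]:
    """Independent pairs with lengths uniform over the config length range."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    lo, hi = teacher.config.length_range
    lengths = rng.integers(lo, hi + 1, size=n_pairs)
    return [
        sample_pair(teacher, int(n), rng, seq_id=f"synth{i:05d}")
        for i, n in enumerate(lengths)
    ]


def make_timing_sequences(
    lengths: TypingSequence[int], rng: np.random.Generator
) -> List[Sequence]:
    """I.i.d.-uniform random sequences for scalability timing runs."""
    out = []
    for i, n in enumerate(lengths):
        if n < 1:
            raise ValueError("lengths must be >= 1")
        idx = rng.integers(0, N_AA, size=n)
        out.append(Sequence(f"timing{i:04d}_len{n}", "".join(AA_ORDER[j] for j in idx)))
    return out
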
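"""Core value types: sequences and per-site profile matrices."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alphabet import AA_ORDER, AA_INDEX, IRREGULAR, N_AA

#: sequence-length window accepted for training use
TRAIN_MIN_LEN = 50
TRAIN_MAX_LEN = 1000

#: row-normalisation tolerance for 64-bit profiles (1e-5 for 32-bit backends)
ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Sequence:
    """A named amino-acid sequence over the 20-letter alphabet."""

    id: str
    residues: str

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def validate_training_sequence(seq: Sequence) -> bool:
    """Whether a sequence qualifies as a training instance.

    True iff every residue is one of the 20 canonical letters (irregular
    symbols such as B, Z, J, U, O or X disqualify) and the length lies in
    [50, 1000].
    """
    if not (TRAIN_MIN_LEN <= seq.n <= TRAIN_MAX_LEN):
        return False
    return all(r in AA_INDEX for r in seq.residues)


@dataclass
class ProfileMatrix:
    """An N x 20 matrix of per-site amino-acid probabilities.

    Row t is the probability column for site t of the associated sequence;
    columns follow the fixed alphabet order ACDEFGHIKLMNPQRSTVWY. ``source``
    records where the profile came from: a ground-truth teacher, a model
    prediction, or conversion from an HMM profile.
    """

    matrix: np.ndarray
    source: str = "converted"  # one of {"teacher", "predicted", "converted"}

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_AA:
            raise ValueError(f"profile must be N x {N_AA}, got {self.matrix.shape}")
        if self.source not in ("teacher", "predicted", "converted"):
            raise ValueError(f"unknown profile source {self.source!r}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def validate(self, tol: float = ROW_SUM_TOL) -> None:
        """Raise ValueError unless all entries are probabilities and rows sum to 1."""
        m = self.matrix
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("profile entries must lie in [0, 1]")
        sums = m.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
        if bad.size:
            raise ValueError(
                f"profile row {bad[0]} sums to {sums[bad[0]]:.8f}, not 1 within {tol}"
            )


@dataclass
class HmmProfile:
    """Match-state emission frequencies extracted from an HMM profile file."""

    match_states: np.ndarray  # M x 20, rows are probability vectors
    name: str = ""
    consensus: Optional[str] = None

    def __post_init__(self):
        self.match_states = np.asarray(self.match_states, dtype=float)
        if self.match_states.ndim != 2 or self.match_states.shape[1] != N_AA:
            raise ValueError(
                f"match states must be M x {N_AA}, got {self.match_states.shape}"
            )

    @property
    def n_states(self) -> int:
        return self.match_states.shape[0]
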
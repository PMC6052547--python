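"""Sequence and profile file I/O.

Three text formats are handled:

* FASTA (read) — standard sequence input, via Biopython.
* HHM-style HMM profile text (read/write) — the layout used by profile-HMM
  builders: per match state a line ``<consensus> <index> <s1> .. <s20>``
  where each score is the integer ``-1000 * log2(p)`` of the emission
  probability of the amino acid in alphabet order, and ``*`` means
  probability zero. Decoded rows are renormalised to sum to 1.
* The package's ASCII PSSM dialect (read/write) — a human-readable table of
  half-bit log-odds and frequency percentages in the style of PSI-BLAST
  output, followed by a full-precision frequency block that makes the
  write/read round trip lossless.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional

import numpy as np
from Bio import SeqIO

from .alphabet import AA_ORDER, N_AA
from .types import HmmProfile, ProfileMatrix, Sequence

__all__ = [
    "ParseError",
    "read_fasta",
    "parse_hhm",
    "write_hhm",
    "hmm_to_pssm",
    "write_pssm",
    "read_pssm",
    "UNIFORM_BACKGROUND",
]

#: shipped default background frequencies (uniform 0.05 per residue type)
UNIFORM_BACKGROUND = np.full(N_AA, 1.0 / N_AA)

#: probabilities are clamped here before forming log-odds for display
LOG_ODDS_CLAMP = 1e-4


class ParseError(ValueError):
    pass


def read_fasta(path) -> List[Sequence]:
    """Read all records of a FASTA file, in file order, residues upper-cased.

    The id of each record is the header token before the first whitespace.
    Sequence data appearing before any header line is a parse error naming
    the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path.name}:{lineno}: sequence data before any FASTA header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(Sequence(rec.id, str(rec.seq).upper()))
    return records


def _decode_score(token: str) -> float:
    if token == "*":
        return 0.0
    return 2.0 ** (-int(token) / 1000.0)


def _encode_prob(p: float) -> str:
    if p <= 0.0:
        return "*"
    return str(int(round(-1000.0 * math.log2(p))))


def parse_hhm(path) -> HmmProfile:
    """Parse match-state emission frequencies from an HHM-style profile file.

    Match-state lines follow the ``HMM`` header block and carry a consensus
    residue, a 1-based state index and 20 emission scores; the record ends at
    ``//``. Scores decode as p = 2^(-score/1000) with ``*`` meaning zero, and
    each row is renormalised.
    """
    path = Path(path)
    name = ""
    rows: List[np.ndarray] = []
    consensus: List[str] = []
    in_states = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] == "NAME" and len(tokens) > 1:
                name = tokens[1]
            elif tokens[0] == "HMM":
                in_states = True
            elif tokens[0] == "//":
                break
            elif in_states and len(tokens[0]) == 1 and tokens[0].isalpha():
                if len(tokens) < 2 + N_AA:
                    raise ParseError(
                        f"{path.name}: match state {len(rows) + 1} (line {lineno}) "
                        f"has {len(tokens) - 2} emission scores, expected {N_AA}"
                    )
                try:
                    row = np.array([_decode_score(t) for t in tokens[2 : 2 + N_AA]])
                except ValueError:
                    raise ParseError(
                        f"{path.name}: match state {len(rows) + 1} (line {lineno}) "
                        "has a non-integer emission score"
                    ) from None
                total = row.sum()
                if total <= 0:
                    raise ParseError(
                        f"{path.name}: match state {len(rows) + 1} has all-zero emissions"
                    )
                rows.append(row / total)
                consensus.append(tokens[0])
    if not in_states:
        raise ParseError(f"{path.name}: no HMM header line found")
    if not rows:
        raise ParseError(f"{path.name}: no match states found")
    return HmmProfile(np.vstack(rows), name=name, consensus="".join(consensus))


def write_hhm(hmm: HmmProfile, path) -> None:
    """Write an HmmProfile in the HHM-style text layout read by parse_hhm."""
    m = hmm.match_states
    consensus = hmm.consensus or "".join(
        AA_ORDER[j] for j in np.argmax(m, axis=1)
    )
    with open(path, "w") as fh:
        fh.write(f"NAME {hmm.name or 'profile'}\n")
        fh.write(f"LENG {m.shape[0]}\n")
        fh.write("HMM  " + "  ".join(AA_ORDER) + "\n")
        for i, row in enumerate(m, start=1):
            scores = " ".join(_encode_prob(p) for p in row)
            fh.write(f"{consensus[i - 1]} {i} {scores}\n")
        fh.write("//\n")


def hmm_to_pssm(hmm: HmmProfile) -> ProfileMatrix:
    """Convert an HMM profile to a PSSM by extracting the match-state
    emission frequencies, one profile row per match state."""
    if hmm.n_states == 0:
        raise ValueError("HMM profile has no match states")
    return ProfileMatrix(hmm.match_states.copy(), source="converted")


def write_pssm(
    profile: ProfileMatrix,
    path,
    background: Optional[np.ndarray] = None,
    name: str = "profile",
) -> None:
    """Write a profile in the package's ASCII PSSM dialect.

    The display table gives, per 1-based position: the consensus residue
    (argmax), 20 half-bit log-odds values round(2*log2(p/q)) with p clamped
    to >= 1e-4, and 20 frequency percentages. A full-precision frequency
    block follows so that read_pssm reproduces the matrix within 1e-9.
    """
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if q.shape != (N_AA,):
        raise ValueError(f"background must have {N_AA} entries")
    if np.any(q <= 0):
        raise ValueError("background frequencies must be strictly positive")
    if abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    m = profile.matrix
    clamped = np.clip(m, LOG_ODDS_CLAMP, None)
    log_odds = np.rint(2.0 * np.log2(clamped / q)).astype(int)
    with open(path, "w") as fh:
        fh.write(f"# profgen PSSM: {name}\n")
        fh.write(f"# columns (alphabet order): {AA_ORDER}\n")
        fh.write("# background: " + " ".join(f"{x:.6f}" for x in q) + "\n")
        fh.write("# per position: index, consensus, 20 half-bit log-odds, 20 freq %\n")
        header = "  ".join(AA_ORDER)
        fh.write(f"      {header}   {header}\n")
        for i, row in enumerate(m):
            cons = AA_ORDER[int(np.argmax(row))]
            lo = " ".join(f"{v:3d}" for v in log_odds[i])
            pc = " ".join(f"{100.0 * p:5.1f}" for p in row)
            fh.write(f"{i + 1:5d} {cons} {lo}  {pc}\n")
        fh.write("# BEGIN FREQUENCIES (lossless)\n")
        for i, row in enumerate(m):
            fh.write(f"{i + 1} " + " ".join(f"{p:.17g}" for p in row) + "\n")
        fh.write("# END FREQUENCIES\n")


def read_pssm(path) -> ProfileMatrix:
    """Read a profile written by write_pssm (requires the lossless block)."""
    path = Path(path)
    rows = []
    in_block = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("# BEGIN FREQUENCIES"):
                in_block = True
                continue
            if line.startswith("# END FREQUENCIES"):
                in_block = False
                continue
            if in_block:
                tokens = line.split()
                rows.append([float(t) for t in tokens[1 : 1 + N_AA]])
    if not rows:
        raise ParseError(f"{path.name}: no lossless frequency block found")
    return ProfileMatrix(np.array(rows), source="converted")
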
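"""The 20-letter amino-acid alphabet and its fixed column order.

Every profile matrix, embedding table and PSSM file in this package uses the
alphabetical one-letter order ``ACDEFGHIKLMNPQRSTVWY`` for its 20 columns.
Index 20 is reserved for the padding symbol used when batching sequences of
unequal length; its embedding is pinned to the zero vector.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
N_AA = len(AA_ORDER)

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: index of the padding symbol in the embedding table
PAD_INDEX = N_AA

#: residue letters that disqualify a sequence from training use
IRREGULAR = set("BZJUOX")


def encode(residues: str) -> np.ndarray:
    """Map a residue string to an int64 index array.

    Raises
    ------
    KeyError
        If a character outside the 20-letter alphabet is present.
    """
    try:
        return np.array([AA_INDEX[r] for r in residues], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"unknown residue symbol {exc.args[0]!r}") from None


def decode(indices) -> str:
    return "".join(AA_ORDER[i] for i in indices)
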
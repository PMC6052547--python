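"""Profile format conversions: HHM match states -> PSSM -> ASCII dialect.

Builds a small HMM profile, extracts its match-state emission frequencies
into a PSSM, writes the PSI-BLAST-style ASCII file and reads it back
losslessly.
"""

import tempfile
from pathlib import Path

import numpy as np

from profgen.seqio import hmm_to_pssm, parse_hhm, read_pssm, write_hhm, write_pssm
from profgen.types import HmmProfile

rng = np.random.default_rng(0)
emissions = rng.dirichlet(np.ones(20) * 0.5, size=4)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_hhm(HmmProfile(emissions, name="demo"), tmp / "demo.hhm")
    hmm = parse_hhm(tmp / "demo.hhm")
    print(f"match states: {hmm.n_states}")
    print(f"decode error vs authored probabilities: "
          f"{np.abs(hmm.match_states - emissions).max():.2e}  (score quantization)")

    pssm = hmm_to_pssm(hmm)
    write_pssm(pssm, tmp / "demo.pssm", name="demo")
    back = read_pssm(tmp / "demo.pssm")
    print(f"PSSM round-trip error: {np.abs(back.matrix - pssm.matrix).max():.2e}  (lossless block)")
    print("\nfirst lines of the ASCII PSSM:")
    print("\n".join((tmp / "demo.pssm").read_text().splitlines()[:7]))
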
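"""Generate a PSSM for a single sequence with an untrained scaled-down model.

Shows the basic prediction path: sequence in, N x 20 probability matrix out,
every row a softmax over the 20 amino-acid types. An untrained model gives
near-uniform columns; training (examples 02-03) sharpens them.
"""

import numpy as np

from profgen.lstm import forward_profile, init_params
from profgen.types import Sequence

params = init_params(embed_dim=16, hidden_size=64, rng=np.random.default_rng(0))
seq = Sequence("demo", "MKVLAAGITGHQWERTYDDAMKVLAAGITGHQ")

profile = forward_profile(seq, params)
print(f"sequence length: {seq.n}")
print(f"profile shape:   {profile.matrix.shape}")
print(f"row sums (first 3): {profile.matrix.sum(axis=1)[:3]}")
print(f"first column (A..Y): {np.round(profile.matrix[0], 3)}")
# Each row is the predicted amino-acid probability column for that site;
# rows sum to 1 by construction of the softmax head.
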
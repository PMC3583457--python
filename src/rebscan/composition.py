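"""Amino-acid background composition shared by the simulator and profile search.

Robinson & Robinson average protein composition, the conventional background
for log-odds scoring; renormalised over the 20 standard residues.
"""

from __future__ import annotations

import numpy as np

from .records import AMINO_ACIDS

_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def background_frequencies() -> np.ndarray:
    """Background frequency of each residue, ordered as AMINO_ACIDS; sums to 1."""
    freqs = np.array([_ROBINSON[a] for a in AMINO_ACIDS], dtype=float)
    return freqs / freqs.sum()


BACKGROUND = background_frequencies()
BACKGROUND.setflags(write=False)
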
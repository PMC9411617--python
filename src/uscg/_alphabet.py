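"""Amino-acid alphabet, background frequencies and the BLOSUM62 matrix.

Internal constants shared by the aligner, the profile search and the
sequence simulator. The alphabet is the 20 standard residues plus ``X`` at
index 20; any non-standard letter (B, Z, J, U, O, ...) is encoded as ``X``,
and ``X`` scores 0 against everything, including itself.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWY"
X_INDEX = 20
ALPHABET = AA + "X"
N_SYMBOLS = 21

_AA_TO_INDEX = np.full(128, X_INDEX, dtype=np.int8)
for _i, _a in enumerate(AA):
    _AA_TO_INDEX[ord(_a)] = _i
    _AA_TO_INDEX[ord(_a.lower())] = _i

#: Robinson & Robinson background residue frequencies (BLAST's default),
#: in :data:`AA` order, renormalised to sum to 1.
BACKGROUND = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def _build_blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((N_SYMBOLS, N_SYMBOLS), dtype=np.float64)
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = mat[a, b]
    # X row/column stays 0 by construction
    return out


#: BLOSUM62 over the 21-symbol alphabet; X scores 0 against everything.
BLOSUM62 = _build_blosum62()


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as int8 alphabet indices (non-standard -> X)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _AA_TO_INDEX[raw]


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in indices)
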
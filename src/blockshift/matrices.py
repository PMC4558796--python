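"""Amino-acid alphabet, BLOSUM62 access and background frequencies.

The canonical alphabet is the 20 standard residues in alphabetical
one-letter order.  'X' (unknown) is accepted in sequences and treated as
background composition wherever residue identity matters.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)

# BLOSUM62 marginal amino-acid frequencies (standard published composition).
_BG = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

# Rounded half-bit BLOSUM62 scale factor: S = log2(q_ab/(p_a p_b)) * 2.
_BLOSUM62_LAMBDA = np.log(2.0) / 2.0


def background_frequencies() -> np.ndarray:
    """Return the 20-vector of background frequencies, normalised to sum 1."""
    v = np.array([_BG[a] for a in AMINO_ACIDS], dtype=float)
    return v / v.sum()


@lru_cache(maxsize=None)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def blosum62_array() -> np.ndarray:
    """BLOSUM62 scores as a 20x20 array over the canonical alphabet."""
    m = _blosum62()
    out = np.empty((N_AA, N_AA), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = m[a][b]
    return out


def blosum62_score(a: str, b: str) -> float:
    """Pairwise BLOSUM62 score; 'X' scored via the matrix's own X column."""
    m = _blosum62()
    return float(m[a][b])


@lru_cache(maxsize=None)
def conditional_probabilities() -> np.ndarray:
    """P(a | b) implied by BLOSUM62, as a 20x20 array indexed [a, b].

    From the log-odds definition S(a,b) = (1/lambda) ln(q_ab / p_a p_b)
    the conditional is proportional to p_a * exp(lambda * S(a,b)); each
    column is renormalised to absorb the rounding of the printed scores.
    """
    bg = background_frequencies()
    s = blosum62_array()
    cond = bg[:, None] * np.exp(_BLOSUM62_LAMBDA * s)
    cond /= cond.sum(axis=0, keepdims=True)
    return cond
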
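"""Reference-dependent alignment accuracy: the Q-score.

Q = 100 * |correctly aligned residue pairs in the test alignment| /
          |aligned residue pairs in the reference alignment|

Pairs are compared as (query_index, template_index) tuples, so the score
depends only on the aligned pair sets, never on gap placement.  The
denominator is the reference (the score is not symmetrized).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError
from .seqio import PairwiseAlignment


@dataclass(frozen=True)
class QScoreResult:
    q: float
    correct_pairs: int
    reference_pairs: int


def qscore(test: PairwiseAlignment, ref: PairwiseAlignment) -> QScoreResult:
    """Q-score of a test alignment against a reference, in [0, 100]."""
    if (test.query.residues != ref.query.residues
            or test.template.residues != ref.template.residues):
        raise InputError("test and reference alignments are over different sequences")
    ref_pairs = set(ref.pairs())
    if not ref_pairs:
        raise InputError("reference alignment has no aligned pairs")
    correct = len(ref_pairs & set(test.pairs()))
    return QScoreResult(100.0 * correct / len(ref_pairs), correct, len(ref_pairs))
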
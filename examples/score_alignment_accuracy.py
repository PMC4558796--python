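"""Q-score: fraction of reference residue pairs reproduced by a test
alignment, on the 0-100 scale.

The score depends only on which (query, template) residue pairs are
aligned, never on where gaps are drawn, and its denominator is always the
reference alignment.
"""

from blockshift import PairwiseAlignment, qscore

reference = PairwiseAlignment.from_rows("query", "template",
                                        "MKWVTF-ISLL", "MKWVTFQISLL")
test = PairwiseAlignment.from_rows("query", "template",
                                   "MKWVT-FISLL", "MKWVTFQISLL")

res = qscore(test, reference)
print(f"reference pairs: {res.reference_pairs}")
print(f"correct pairs:   {res.correct_pairs}")
print(f"Q-score:         {res.q:.1f}")
# The test alignment slides one residue of the query by a single
# position, so the pairs downstream of the gap disagree with the
# reference and the Q-score drops below 100.
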
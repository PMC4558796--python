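"""Refine a synthetic alignment whose middle helix is misaligned by +2.

Builds a noise-free synthetic case (the query equals the template, so the
true register is unambiguous), plants a two-residue shift in block 2,
runs the refiner and prints the accuracy before and after plus the
per-block decisions.
"""

from blockshift import Config, make_case, qscore, refine_alignment
from blockshift.report import render_text_report

case = make_case(seed=9, signal_strength=1.0, planted_shifts=[0, 2, 0])
cfg = Config(mode="O+G")
report = refine_alignment(case.starting_alignment, case.chain, case.sse,
                          cfg, qprof=case.qprof, tprof=case.tprof)

q_start = qscore(case.starting_alignment, case.true_alignment)
q_refined = qscore(report.refined, case.true_alignment)
print(f"Q-score vs truth before refinement: {q_start.q:.1f}")
print(f"Q-score vs truth after refinement:  {q_refined.q:.1f}")
for dec in report.decisions:
    print(f"  block {dec.block.ordinal}: {dec.shift_result}")
print()
print(render_text_report(report))
# A Q-score of 100 after refinement means every aligned residue pair of
# the reference was restored; the block-2 decision shows the accepted
# variant that undid the planted +2 shift (a -2 entry in its family).
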
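"""Plain-text and JSON rendering of a refinement report.

The text report mirrors the tool's three sections: the starting and
refined alignments with secondary-structure, residue-number and Cm1/Cm2
change lines; a block summary table; and a per-variant score table for
every evaluated block.  All residue numbers are 1-based.  Rendering is
deterministic: identical inputs yield byte-identical reports.
"""

from __future__ import annotations

import json
from typing import Optional

from .refine import BlockDecision, RefinementReport, annotate_changes
from .seqio import GAP, PairwiseAlignment


def _number_line(row: str, start_count: int = 0, every: int = 10) -> str:
    """Residue-number tick line for a gapped row (1-based, every 10th)."""
    out = [" "] * len(row)
    count = start_count
    i = 0
    while i < len(row):
        ch = row[i]
        if ch != GAP:
            count += 1
            if count % every == 0:
                label = str(count)
                if i + 1 >= len(label):
                    for k, d in enumerate(label):
                        out[i - len(label) + 1 + k] = d
        i += 1
    return "".join(out)


def _sse_line_for_row(row: str, labels: str) -> str:
    """Spread per-residue SSE labels under/over a gapped row."""
    out = []
    idx = 0
    for ch in row:
        if ch == GAP:
            out.append(" ")
        else:
            out.append(labels[idx] if idx < len(labels) else " ")
            idx += 1
    return "".join(out)


def _block_marker_line(aln: PairwiseAlignment, report: RefinementReport,
                      refined_only: bool) -> str:
    """Underscore markers beneath columns of blocks that were refined."""
    out = [" "] * len(aln)
    col_of = {}
    for col, (_, t) in enumerate(aln.columns.entries):
        if t is not None:
            col_of[t] = col
    for dec in report.decisions:
        if refined_only and (dec.kept or not dec.evaluated):
            continue
        elem = dec.block.element
        for t in range(elem.start, elem.end):
            if t in col_of:
                out[col_of[t]] = "_"
    return "".join(out)


def _alignment_section(aln: PairwiseAlignment, report: RefinementReport,
                       title: str, width: int = 60,
                       cm_lines: Optional[tuple[str, str]] = None,
                       mark_refined: bool = False) -> list[str]:
    qnum = _number_line(aln.query_row)
    tnum = _number_line(aln.template_row)
    tsse = _sse_line_for_row(aln.template_row, report.sse.labels)
    qsse = (_sse_line_for_row(aln.query_row, report.query_sse)
            if report.query_sse else None)
    marks = _block_marker_line(aln, report, refined_only=mark_refined)
    lines = [title, "=" * len(title)]
    for off in range(0, len(aln), width):
        sl = slice(off, off + width)
        if cm_lines is not None:
            lines.append(f"{'Cm1':>10} {cm_lines[0][sl]}")
            lines.append(f"{'Cm2':>10} {cm_lines[1][sl]}")
        if qsse is not None:
            lines.append(f"{'SSE':>10} {qsse[sl]}")
        lines.append(f"{'Number':>10} {qnum[sl]}")
        lines.append(f"{aln.query.id[:10]:>10} {aln.query_row[sl]}")
        lines.append(f"{aln.template.id[:10]:>10} {aln.template_row[sl]}")
        lines.append(f"{'SSE':>10} {tsse[sl]}")
        lines.append(f"{'Number':>10} {tnum[sl]}")
        lines.append(f"{'Blocks':>10} {marks[sl]}")
        lines.append("")
    return lines


def _block_segment(aln: PairwiseAlignment, dec: BlockDecision) -> tuple[str, str]:
    col_of = {}
    for col, (_, t) in enumerate(aln.columns.entries):
        if t is not None:
            col_of[t] = col
    elem = dec.block.element
    c0, c1 = col_of[elem.start], col_of[elem.end - 1] + 1
    return aln.query_row[c0:c1], aln.template_row[c0:c1]


def render_text_report(report: RefinementReport, width: int = 60) -> str:
    lines: list[str] = []
    lines.append("Alignment refinement report")
    lines.append("===========================")
    lines.append(f"Mode: {report.mode}")
    lines.append(
        f"Template-to-structure identity: {report.identity:.3f} "
        f"(threshold {report.min_identity:.2f}) -> "
        + ("refinement enabled" if report.gate_passed else
           "gate FAILED, alignment returned unchanged")
    )
    lines.append(f"Blocks refined: {report.n_refined} / "
                 f"{sum(1 for d in report.decisions if d.evaluated)} evaluated")
    lines.append("")
    lines += _alignment_section(report.starting, report, "Starting alignment",
                                width)
    cm = annotate_changes(report.starting, report.refined)
    lines += _alignment_section(report.refined, report, "Refined alignment",
                                width, cm_lines=cm, mark_refined=True)

    lines.append("Block summary")
    lines.append("=============")
    header = (f"{'No':>3} {'Start':>6} {'End':>6} {'Type':>5} "
              f"{'Frac':>6} {'Original block':<22} {'Shift result':<16} "
              f"{'Refined block':<22}")
    lines.append(header)
    for dec in report.decisions:
        elem = dec.block.element
        qorig, _ = _block_segment(report.starting, dec)
        if dec.evaluated and not dec.kept:
            qref, _ = _block_segment(report.refined, dec)
        else:
            qref = "-"
        lines.append(
            f"{dec.block.ordinal:>3} {elem.start + 1:>6} {elem.end:>6} "
            f"{'Helix' if elem.type == 'H' else 'Strand':>5} "
            f"{dec.block.nongap_fraction:>6.2f} {qorig:<22} "
            f"{dec.shift_result:<16} {qref:<22}"
        )
    lines.append("")

    for dec in report.decisions:
        if not dec.evaluated or not dec.bundles:
            continue
        lines.append(f"Scores for block {dec.block.ordinal}")
        lines.append("-" * 24)
        lines.append(f"{'Gap mode':<10} {'Shift':>6} {'Unique':>7} "
                     f"{'S_seq':>10} {'S_str':>10} {'S_comb_I':>10} "
                     f"{'S_comb_II':>10}  Chosen")
        for b in dec.bundles:
            if b.is_incumbent:
                chosen = "(incumbent)" if dec.kept else ""
            else:
                chosen = ("<== accepted"
                          if (not dec.kept and dec.chosen == (b.gap_mode, b.shift))
                          else "")
            comb1 = f"{b.s_comb_1:>10.3f}" if b.unique else f"{'.':>10}"
            comb2 = f"{b.s_comb_2:>10.3f}" if b.unique else f"{'.':>10}"
            lines.append(
                f"{b.gap_mode.value:<10} {b.shift:>+6d} "
                f"{'yes' if b.unique else 'dup':>7} "
                f"{b.s_seq:>10.3f} {b.s_str:>10.3f} {comb1} {comb2}  {chosen}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def report_to_dict(report: RefinementReport) -> dict:
    cm1, cm2 = annotate_changes(report.starting, report.refined)
    return {
        "mode": report.mode,
        "gate": {
            "identity": round(report.identity, 6),
            "threshold": report.min_identity,
            "passed": report.gate_passed,
        },
        "starting": {
            "query_row": report.starting.query_row,
            "template_row": report.starting.template_row,
        },
        "refined": {
            "query_row": report.refined.query_row,
            "template_row": report.refined.template_row,
        },
        "cm1": cm1,
        "cm2": cm2,
        "blocks": [
            {
                "ordinal": d.block.ordinal,
                "type": d.block.element.type,
                "start": d.block.element.start + 1,
                "end": d.block.element.end,
                "nongap_fraction": round(d.block.nongap_fraction, 6),
                "evaluated": d.evaluated,
                "kept": d.kept,
                "shift_result": d.shift_result,
                "candidates": [
                    {
                        "gap_mode": b.gap_mode.value,
                        "shift": b.shift,
                        "incumbent": b.is_incumbent,
                        "unique": b.unique,
                        "s_seq": round(b.s_seq, 6),
                        "s_str": round(b.s_str, 6),
                        "s_comb_I": round(b.s_comb_1, 6) if b.unique else None,
                        "s_comb_II": round(b.s_comb_2, 6) if b.unique else None,
                    }
                    for b in d.bundles
                ],
            }
            for d in report.decisions
        ],
    }


def render_json_report(report: RefinementReport) -> str:
    return json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
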
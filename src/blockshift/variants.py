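"""Candidate alignment variants for a block: gap preprocessing and shifts.

Variants come in three families named by their gap mode:

* ``Original`` — the block's current gap pattern is kept and the query
  residues are shifted by k positions relative to the template.
* ``Left`` / ``Right`` — block-internal gaps are first eliminated by
  packing the block's query residues against one side of the element
  (gaps consolidated on the opposite side), then shifted.

The shift sign convention: +k moves query residues toward the C-terminus,
so template residue t takes the query residue the family baseline assigned
to t, minus k.  Query residues entering or leaving the block window are
borrowed from or returned to the adjacent loop regions; a loop whose query
content changes is re-gapped deterministically (residues packed left
against the loop's template residues, trailing gaps right), while an
untouched loop keeps its original columns byte-for-byte.  A shift that
would consume residues committed to another element's block, or run past a
sequence end, is infeasible and simply omitted.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .blocks import AlignmentBlock, SSEAnnotation, SSElement
from .seqio import ColumnMap, PairwiseAlignment


class GapMode(str, Enum):
    ORIGINAL = "Original"
    LEFT = "Left"
    RIGHT = "Right"


@dataclass
class AlignmentVariant:
    gap_mode: GapMode
    shift: int
    pairs: list[tuple[int, int]]               # block (query, template) pairs
    alignment: Optional[PairwiseAlignment]     # realized full alignment
    feasible: bool
    unique: bool

    @property
    def signature(self) -> frozenset:
        """Canonical dedup key: the block's realized pair set."""
        return frozenset(self.pairs)

    @property
    def label(self) -> str:
        return f"{self.gap_mode.value} [{self.shift:+d}]"


def _window(aln: PairwiseAlignment, sse: SSEAnnotation,
            element: SSElement) -> tuple[int, int, int, int]:
    """Column and template bounds of the block window.

    Returns (win_col_start, win_col_end, left_template_bound,
    right_template_bound): the window spans the element plus both adjacent
    loops, bounded by the neighbouring elements (or the alignment ends).
    """
    idx = sse.elements.index(element)
    lt = sse.elements[idx - 1].end if idx > 0 else 0
    rt = (sse.elements[idx + 1].start if idx + 1 < len(sse.elements)
          else len(aln.template.residues))
    cmap = aln.columns
    col_of = {}
    for col, (_, t) in enumerate(cmap.entries):
        if t is not None:
            col_of[t] = col
    c0 = col_of[lt - 1] + 1 if lt > 0 else 0
    c1 = col_of[rt] if rt < len(aln.template.residues) else len(aln)
    return c0, c1, lt, rt


def _baseline(aln: PairwiseAlignment, element: SSElement,
              gap_mode: GapMode) -> dict[int, int]:
    """Shift-0 query assignment of the family for each template residue."""
    t2q = aln.columns.template_to_query()
    block_q = [t2q[t] for t in range(element.start, element.end) if t in t2q]
    if gap_mode is GapMode.ORIGINAL:
        return {t: t2q[t] for t in range(element.start, element.end) if t in t2q}
    if gap_mode is GapMode.LEFT:
        return {element.start + i: q for i, q in enumerate(block_q)}
    return {element.end - len(block_q) + i: q for i, q in enumerate(block_q)}


def realize_variant(aln: PairwiseAlignment, sse: SSEAnnotation,
                    block: AlignmentBlock, gap_mode: GapMode,
                    shift: int) -> Optional[AlignmentVariant]:
    """Realize one (gap mode, shift) candidate as a full valid alignment.

    Returns None when the shift is infeasible.  ``Original`` at shift 0 is
    the incumbent and reproduces the input alignment exactly.
    """
    element = block.element
    if gap_mode is GapMode.ORIGINAL and shift == 0:
        return AlignmentVariant(gap_mode, 0, list(block.pairs), aln,
                                feasible=True, unique=True)
    c0, c1, lt, rt = _window(aln, sse, element)
    entries = aln.columns.entries
    window_q = [q for q, _ in entries[c0:c1] if q is not None]
    window_q_set = set(window_q)

    base = _baseline(aln, element, gap_mode)
    if not base:
        return None
    pair_map = {t: q - shift for t, q in base.items()}
    if any(q not in window_q_set for q in pair_map.values()):
        return None  # beyond sequence ends or committed to another block
    pairs = sorted((q, t) for t, q in pair_map.items())
    qmin = pairs[0][0]
    qmax = pairs[-1][0]
    used = {q for q, _ in pairs}
    left_pool = [q for q in window_q if q < qmin]
    right_pool = [q for q in window_q if q > qmax]
    mid = deque(q for q in window_q if qmin < q < qmax and q not in used)

    cmap = aln.columns
    col_of = {}
    for col, (_, t) in enumerate(cmap.entries):
        if t is not None:
            col_of[t] = col
    blk_c0 = col_of[element.start]
    blk_c1 = col_of[element.end - 1] + 1

    def loop_columns(templates: list[int], pool: list[int],
                     orig_slice: tuple[int, int]) -> list[tuple]:
        orig = list(entries[orig_slice[0]:orig_slice[1]])
        orig_q = [q for q, _ in orig if q is not None]
        if orig_q == pool:
            return orig
        cols = []
        n = min(len(templates), len(pool))
        for i in range(n):
            cols.append((pool[i], templates[i]))
        for q in pool[n:]:
            cols.append((q, None))
        for t in templates[n:]:
            cols.append((None, t))
        return cols

    left_templates = list(range(lt, element.start))
    right_templates = list(range(element.end, rt))
    new_entries = list(entries[:c0])
    new_entries += loop_columns(left_templates, left_pool, (c0, blk_c0))
    for t in range(element.start, element.end):
        if t in pair_map:
            qv = pair_map[t]
            while mid and mid[0] < qv:
                new_entries.append((mid.popleft(), None))
            new_entries.append((qv, t))
        else:
            new_entries.append((None, t))
    assert not mid
    new_entries += loop_columns(right_templates, right_pool, (blk_c1, c1))
    new_entries += list(entries[c1:])

    qrow, trow = ColumnMap(tuple(new_entries)).rebuild_rows(
        aln.query.residues, aln.template.residues)
    realized = PairwiseAlignment(aln.query, aln.template, qrow, trow)
    return AlignmentVariant(gap_mode, shift, pairs, realized,
                            feasible=True, unique=True)


def preprocess_gaps(aln: PairwiseAlignment, sse: SSEAnnotation,
                    block: AlignmentBlock, side: GapMode) -> Optional[AlignmentVariant]:
    """Gap-mode preprocessing alone: pack block residues to one side."""
    if side not in (GapMode.LEFT, GapMode.RIGHT):
        raise ValueError("side must be GapMode.LEFT or GapMode.RIGHT")
    return realize_variant(aln, sse, block, side, 0)


def generate_variants(aln: PairwiseAlignment, sse: SSEAnnotation,
                      block: AlignmentBlock, mode: str = "O+G",
                      max_shift: int = 4,
                      include_original_family_in_og: bool = False,
                      ) -> list[AlignmentVariant]:
    """All candidate variants of a block for the given mode.

    Mode "O": the Original family at shifts -N..N excluding 0.  Mode "O+G"
    (also used by "O+G+M"): the Left and Right families at shifts -N..N
    including 0, with the untouched original block retained separately as
    the incumbent.  Infeasible shifts are omitted; duplicates (by realized
    block pair set, the incumbent's included) are marked non-unique and
    first-listed wins, with family order Original, Left, Right and
    ascending shift within a family.
    """
    shifts = range(-max_shift, max_shift + 1)
    plan: list[tuple[GapMode, int]] = []
    if mode == "O":
        plan += [(GapMode.ORIGINAL, k) for k in shifts if k != 0]
    elif mode in ("O+G", "O+G+M"):
        if include_original_family_in_og:
            plan += [(GapMode.ORIGINAL, k) for k in shifts if k != 0]
        plan += [(GapMode.LEFT, k) for k in shifts]
        plan += [(GapMode.RIGHT, k) for k in shifts]
    else:
        raise ValueError(f"unknown variant-generation mode {mode!r}")

    incumbent_sig = frozenset(block.pairs)
    seen = {incumbent_sig}
    out: list[AlignmentVariant] = []
    for gap_mode, k in plan:
        v = realize_variant(aln, sse, block, gap_mode, k)
        if v is None:
            continue
        if v.signature in seen:
            v.unique = False
        else:
            seen.add(v.signature)
        out.append(v)
    return out
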
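"""Secondary-structure elements and alignment blocks.

A block is the alignment window covering one template helix or strand plus
the query region aligned to it; blocks are the unit of refinement.  The
template's secondary structure comes from a user-supplied per-residue label
string (3-state H/S/C, or a DSSP 8-state string collapsed here); element
delineation algorithms themselves are external inputs, not reimplemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import InputError
from .seqio import PairwiseAlignment

# DSSP 8-state -> 3-state collapse: helix types to H, strand/bridge to S,
# everything else (turn, bend, coil) to C.  Note DSSP's own 'S' means bend.
DSSP_MAP = {
    "H": "H", "G": "H", "I": "H",
    "E": "S", "B": "S",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C", ".": "C",
}

# Plain 3-state files: accept either 'E' or 'S' for strand.
THREE_STATE_MAP = {
    "H": "H", "G": "H", "I": "H",
    "E": "S", "S": "S", "B": "S",
    "C": "C", "T": "C", "-": "C", " ": "C", ".": "C", "L": "C",
}

DEFAULT_MIN_LENGTH = {"H": 4, "S": 3}


@dataclass(frozen=True)
class SSElement:
    type: str       # 'H' or 'S'
    start: int      # template index, half-open interval [start, end)
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SSEAnnotation:
    labels: str                       # per-template-residue, in {H, S, C}
    elements: tuple[SSElement, ...]


def parse_sse(labels: str, alphabet_map: dict[str, str] | None = None,
              min_lengths: dict[str, int] | None = None) -> SSEAnnotation:
    """Collapse a label string to 3-state and delineate H/S elements.

    Maximal runs of H or S become elements, subject to per-type minimum
    lengths (defaults: helix 4, strand 3); shorter runs are relabelled C.
    """
    if alphabet_map is None:
        alphabet_map = THREE_STATE_MAP
    if min_lengths is None:
        min_lengths = DEFAULT_MIN_LENGTH
    collapsed = []
    for ch in labels.upper():
        state = alphabet_map.get(ch)
        if state is None:
            raise InputError(f"unknown secondary-structure label {ch!r}")
        collapsed.append(state)
    elements: list[SSElement] = []
    final = list(collapsed)
    i = 0
    n = len(collapsed)
    while i < n:
        state = collapsed[i]
        j = i
        while j < n and collapsed[j] == state:
            j += 1
        if state in ("H", "S"):
            if j - i >= min_lengths[state]:
                elements.append(SSElement(state, i, j))
            else:
                for k in range(i, j):
                    final[k] = "C"
        i = j
    return SSEAnnotation("".join(final), tuple(elements))


def read_sse_file(path: str | Path, dssp_style: bool = False,
                  min_lengths: dict[str, int] | None = None) -> SSEAnnotation:
    """Read a label string from single-line text or a FASTA-like file."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InputError(f"empty secondary-structure file {path}")
    if lines[0].startswith(">"):
        lines = lines[1:]
    labels = "".join(lines)
    amap = DSSP_MAP if dssp_style else THREE_STATE_MAP
    return parse_sse(labels, amap, min_lengths)


def read_dssp_labels(path: str | Path) -> str:
    """Extract the one-character structure column from a DSSP output file."""
    labels = []
    in_body = False
    for line in Path(path).read_text().splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_body = True
            continue
        if not in_body or len(line) < 17:
            continue
        if line[13] == "!":  # chain break marker
            continue
        labels.append(line[16] if line[16] != " " else "C")
    if not labels:
        raise InputError(f"no residue lines found in DSSP file {path}")
    return "".join(labels)


@dataclass
class AlignmentBlock:
    """One template element's alignment window in a particular alignment."""

    element: SSElement
    ordinal: int                       # 1-based, N- to C-terminus
    columns: tuple[int, int]           # half-open alignment-column interval
    pairs: list[tuple[int, int]]       # aligned (query_idx, template_idx)
    nongap_fraction: float
    evaluable: bool


def extract_blocks(aln: PairwiseAlignment, sse: SSEAnnotation,
                   min_fraction: float = 0.5) -> list[AlignmentBlock]:
    """Cut the alignment into one candidate block per template element.

    The non-gap fraction is aligned pairs over template residues of the
    element; blocks below ``min_fraction`` are marked skipped (reported but
    not refined).
    """
    if len(aln.template.residues) != len(sse.labels):
        raise InputError(
            "template length "
            f"{len(aln.template.residues)} != label string length {len(sse.labels)}"
        )
    cmap = aln.columns
    col_of_template = {}
    for col, (_, t) in enumerate(cmap.entries):
        if t is not None:
            col_of_template[t] = col
    t2q = cmap.template_to_query()
    out = []
    for ordinal, elem in enumerate(sse.elements, start=1):
        c0 = col_of_template[elem.start]
        c1 = col_of_template[elem.end - 1] + 1
        pairs = [(t2q[t], t) for t in range(elem.start, elem.end) if t in t2q]
        frac = len(pairs) / len(elem)
        out.append(AlignmentBlock(
            element=elem, ordinal=ordinal, columns=(c0, c1), pairs=pairs,
            nongap_fraction=frac, evaluable=frac >= min_fraction,
        ))
    return out
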
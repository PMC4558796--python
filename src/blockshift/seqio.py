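"""Sequence and pairwise-alignment data model plus FASTA I/O.

The central object is :class:`PairwiseAlignment`: two gapped rows (query on
top, template below) over one column axis.  Invariants enforced at
construction: equal row lengths, no gap-gap column, and each row ungaps to
its :class:`SequenceRecord`.  Internal coordinates are 0-based half-open;
rendered reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, InputError
from .matrices import AMINO_ACIDS, blosum62_array, AA_INDEX

GAP = "-"
_VALID_RESIDUES = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise InputError(f"sequence {self.id!r} is empty")
        res = self.residues.upper()
        bad = set(res) - _VALID_RESIDUES
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains illegal characters: "
                + "".join(sorted(bad))
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


def _normalise_row(row: str) -> str:
    # '.' is an A2M-dialect gap; normalise to '-' and upper-case.
    return row.upper().replace(".", GAP)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows over a common column axis (query first)."""

    query: SequenceRecord
    template: SequenceRecord
    query_row: str
    template_row: str

    def __post_init__(self):
        object.__setattr__(self, "query_row", _normalise_row(self.query_row))
        object.__setattr__(self, "template_row", _normalise_row(self.template_row))
        if len(self.query_row) != len(self.template_row):
            raise AlignmentError(
                "unequal row lengths: "
                f"{len(self.query_row)} vs {len(self.template_row)}"
            )
        for col, (q, t) in enumerate(zip(self.query_row, self.template_row)):
            if q == GAP and t == GAP:
                raise AlignmentError(f"gap-gap column at column {col}")
        if self.query_row.replace(GAP, "") != self.query.residues:
            raise AlignmentError(
                f"query row does not ungap to sequence {self.query.id!r}"
            )
        if self.template_row.replace(GAP, "") != self.template.residues:
            raise AlignmentError(
                f"template row does not ungap to sequence {self.template.id!r}"
            )

    @classmethod
    def from_rows(cls, query_id: str, template_id: str,
                  query_row: str, template_row: str) -> "PairwiseAlignment":
        qrow = _normalise_row(query_row)
        trow = _normalise_row(template_row)
        return cls(
            SequenceRecord(query_id, qrow.replace(GAP, "")),
            SequenceRecord(template_id, trow.replace(GAP, "")),
            qrow, trow,
        )

    def __len__(self) -> int:
        return len(self.query_row)

    @property
    def columns(self) -> "ColumnMap":
        return ColumnMap.from_alignment(self)

    def pairs(self) -> list[tuple[int, int]]:
        """Aligned (query_index, template_index) pairs, in column order."""
        return self.columns.pairs()

    def swapped(self) -> "PairwiseAlignment":
        """The same alignment with query and template roles exchanged."""
        return PairwiseAlignment(self.template, self.query,
                                 self.template_row, self.query_row)


@dataclass(frozen=True)
class ColumnMap:
    """Per-column (query_index | None, template_index | None) tuples."""

    entries: tuple[tuple[Optional[int], Optional[int]], ...] = field()

    @classmethod
    def from_alignment(cls, aln: PairwiseAlignment) -> "ColumnMap":
        qi = ti = 0
        entries = []
        for q, t in zip(aln.query_row, aln.template_row):
            eq = et = None
            if q != GAP:
                eq, qi = qi, qi + 1
            if t != GAP:
                et, ti = ti, ti + 1
            entries.append((eq, et))
        return cls(tuple(entries))

    def pairs(self) -> list[tuple[int, int]]:
        return [(q, t) for q, t in self.entries if q is not None and t is not None]

    def template_to_query(self) -> dict[int, int]:
        return {t: q for q, t in self.pairs()}

    def query_to_template(self) -> dict[int, int]:
        return {q: t for q, t in self.pairs()}

    def column_of_template(self, t: int) -> int:
        for col, (_, et) in enumerate(self.entries):
            if et == t:
                return col
        raise IndexError(f"template index {t} not in alignment")

    def rebuild_rows(self, query: str, template: str) -> tuple[str, str]:
        """Reconstruct the gapped rows; inverse of :meth:`from_alignment`."""
        qrow = []
        trow = []
        for q, t in self.entries:
            qrow.append(query[q] if q is not None else GAP)
            trow.append(template[t] if t is not None else GAP)
        return "".join(qrow), "".join(trow)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read plain (ungapped) FASTA records."""
    recs = [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise InputError(f"no FASTA records in {path}")
    return recs


def read_alignment_fasta(path: str | Path, query_first: bool = True) -> PairwiseAlignment:
    """Read a 2-record aligned FASTA as a validated pairwise alignment.

    The first record is the query unless ``query_first`` is False.
    """
    raw = list(SeqIO.parse(str(path), "fasta"))
    if len(raw) != 2:
        raise AlignmentError(
            f"expected exactly 2 aligned records in {path}, found {len(raw)}"
        )
    a, b = raw
    if not query_first:
        a, b = b, a
    return PairwiseAlignment.from_rows(a.id, b.id, str(a.seq), str(b.seq))


def write_alignment_fasta(aln: PairwiseAlignment, path: str | Path,
                          width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, row in ((aln.query.id, aln.query_row),
                            (aln.template.id, aln.template_row)):
            fh.write(f">{rec_id}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


def read_msa_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA MSA as (id, gapped_row) tuples."""
    rows = [(r.id, _normalise_row(str(r.seq))) for r in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise InputError(f"no records in MSA {path}")
    lengths = {len(r) for _, r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"MSA rows in {path} have unequal lengths")
    return rows


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identical aligned pairs / aligned pairs; 0.0 with no aligned pairs."""
    pairs = aln.pairs()
    if not pairs:
        return 0.0
    same = sum(
        1 for q, t in pairs if aln.query.residues[q] == aln.template.residues[t]
    )
    return same / len(pairs)


def global_align(a: SequenceRecord, b: SequenceRecord,
                 substitution_matrix: Optional[np.ndarray] = None,
                 gap_open: float = 10.0, gap_extend: float = 1.0,
                 ) -> PairwiseAlignment:
    """Global affine-gap alignment (Gotoh) of two sequences.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Ties are
    broken deterministically: diagonal > up (gap in b) > left (gap in a).
    Sequence ``a`` becomes the query row, ``b`` the template row.
    """
    if substitution_matrix is None:
        substitution_matrix = blosum62_array()
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)
    if n == 0 or m == 0:
        raise InputError("cannot align an empty sequence")

    def score(x: str, y: str) -> float:
        if x == "X" or y == "X":
            return 0.0
        return substitution_matrix[AA_INDEX[x], AA_INDEX[y]]

    NEG = -1e30
    # M: a[i-1] aligned to b[j-1]; Ix: gap in b (a consumed); Iy: gap in a.
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
    # traceback state: 0=M, 1=Ix, 2=Iy; per-cell predecessor state
    tb_M = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_Ix = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_Iy = np.zeros((n + 1, m + 1), dtype=np.int8)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(sa[i - 1], sb[j - 1])
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = int(np.argmax(prev))  # argmax prefers M on ties
            M[i, j] = prev[k] + s
            tb_M[i, j] = k
            open_x = M[i - 1, j] - gap_open
            ext_x = Ix[i - 1, j] - gap_extend
            if open_x >= ext_x:
                Ix[i, j], tb_Ix[i, j] = open_x, 0
            else:
                Ix[i, j], tb_Ix[i, j] = ext_x, 1
            open_y = M[i, j - 1] - gap_open
            ext_y = Iy[i, j - 1] - gap_extend
            if open_y >= ext_y:
                Iy[i, j], tb_Iy[i, j] = open_y, 0
            else:
                Iy[i, j], tb_Iy[i, j] = ext_y, 2

    finals = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax(finals))
    i, j = n, m
    qrow: list[str] = []
    trow: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            qrow.append(sa[i - 1])
            trow.append(sb[j - 1])
            state = int(tb_M[i, j])
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            qrow.append(sa[i - 1])
            trow.append(GAP)
            state = int(tb_Ix[i, j])
            i -= 1
        elif state == 2 and j > 0:
            qrow.append(GAP)
            trow.append(sb[j - 1])
            state = int(tb_Iy[i, j])
            j -= 1
        elif i > 0:
            state = 1
        else:
            state = 2
    return PairwiseAlignment(a, b, "".join(reversed(qrow)), "".join(reversed(trow)))


def alignment_score(aln: PairwiseAlignment,
                    substitution_matrix: Optional[np.ndarray] = None,
                    gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Affine-gap score of an existing alignment (for oracle comparisons)."""
    if substitution_matrix is None:
        substitution_matrix = blosum62_array()
    total = 0.0
    # substitution part
    for q, t in zip(aln.query_row, aln.template_row):
        if q != GAP and t != GAP:
            if q == "X" or t == "X":
                continue
            total += substitution_matrix[AA_INDEX[q], AA_INDEX[t]]
    # gap part: runs of gaps in either row
    for row in (aln.query_row, aln.template_row):
        run = 0
        for ch in row:
            if ch == GAP:
                run += 1
            else:
                if run:
                    total -= gap_open + (run - 1) * gap_extend
                run = 0
        if run:
            total -= gap_open + (run - 1) * gap_extend
    return total
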
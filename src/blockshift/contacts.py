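"""Template contact maps and the contact-energy structure score.

Contacts are template residue pairs closer than a strict distance cutoff
(default 6.5 A) under one of two definitions: distance between side-chain
centers, or minimum distance between any side-chain atoms.  Contact
energies e(a, b) are read from the bundled Miyazawa-Jernigan 1996 table or
a user-supplied 20x20 file; energies are negative for favorable pairs, so
the structure score of an aligned pair is the NEGATED sum of energies over
the query residue pairs inferred through the alignment (higher = better,
a partner aligned to a gap contributes 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import MatrixError
from .matrices import AA_INDEX, AMINO_ACIDS, N_AA
from .seqio import SequenceRecord
from .structio import StructureChain, TemplateStructureMap, side_chain_center

log = logging.getLogger(__name__)

SIDECHAIN_CENTERS = "sidechain_centers"
ANY_SIDECHAIN_ATOMS = "any_sidechain_atoms"


@dataclass(frozen=True)
class EnergyMatrix:
    """Symmetric 20x20 contact energies, alphabetical one-letter order."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (N_AA, N_AA):
            raise MatrixError(
                f"energy matrix {self.name!r} is {self.values.shape}, expected 20x20"
            )
        if not np.all(np.isfinite(self.values)):
            raise MatrixError(f"energy matrix {self.name!r} has non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            a, b = np.argwhere(~np.isclose(self.values, self.values.T))[0]
            raise MatrixError(
                f"energy matrix {self.name!r} is asymmetric, e.g. "
                f"CE({AMINO_ACIDS[a]},{AMINO_ACIDS[b]}) != "
                f"CE({AMINO_ACIDS[b]},{AMINO_ACIDS[a]})"
            )

    def energy(self, a: str, b: str) -> float:
        """e(a, b); 'X' against anything is 0 (unknown residue)."""
        if a == "X" or b == "X":
            return 0.0
        return float(self.values[AA_INDEX[a], AA_INDEX[b]])


def _parse_matrix_text(text: str, name: str) -> EnergyMatrix:
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise MatrixError(f"energy matrix file {name!r} is empty")
    header = lines[0].split()
    if len(header) != N_AA or any(len(h) != 1 for h in header):
        raise MatrixError(
            f"energy matrix {name!r}: first line must be 20 one-letter codes"
        )
    order = [h.upper() for h in header]
    if sorted(order) != sorted(AMINO_ACIDS):
        raise MatrixError(f"energy matrix {name!r}: header is not the 20 amino acids")
    if len(lines) != N_AA + 1:
        raise MatrixError(
            f"energy matrix {name!r}: expected 20 data rows, found {len(lines) - 1}"
        )
    raw = np.empty((N_AA, N_AA))
    row_letters = []
    for r, line in enumerate(lines[1:]):
        parts = line.split()
        if len(parts) != N_AA + 1:
            raise MatrixError(f"energy matrix {name!r}: malformed row {r + 1}")
        row_letters.append(parts[0].upper())
        raw[r] = [float(x) for x in parts[1:]]
    if row_letters != order:
        raise MatrixError(f"energy matrix {name!r}: row order differs from header")
    # reorder into canonical alphabetical order
    perm = [order.index(a) for a in AMINO_ACIDS]
    values = raw[np.ix_(perm, perm)]
    return EnergyMatrix(name, values)


def load_energy_matrix(name_or_path: str | Path = "MJ") -> EnergyMatrix:
    """Load the bundled "MJ" table or a whitespace-separated 20x20 file."""
    if str(name_or_path).upper() == "MJ":
        text = resources.files("blockshift.data").joinpath("mj1996.txt").read_text()
        return _parse_matrix_text(text, "MJ")
    path = Path(name_or_path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise MatrixError(f"cannot read energy matrix {path}: {exc}") from exc
    return _parse_matrix_text(text, f"custom:{path.name}")


def zero_energy_matrix() -> EnergyMatrix:
    """All-zero matrix: every structure score vanishes downstream."""
    return EnergyMatrix("zero", np.zeros((N_AA, N_AA)))


@dataclass(frozen=True)
class ContactMap:
    """Unordered template residue-index contact pairs."""

    pairs: frozenset[frozenset[int]]
    definition: str
    cutoff: float

    def partners(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for pair in self.pairs:
            i, j = sorted(pair)
            out.setdefault(i, []).append(j)
            out.setdefault(j, []).append(i)
        for v in out.values():
            v.sort()
        return out

    def __len__(self) -> int:
        return len(self.pairs)


def _sidechain_points(chain: StructureChain, idx: int) -> np.ndarray:
    res = chain.residues[idx]
    if res.sidechain_atoms:
        return np.array(list(res.sidechain_atoms.values()))
    return side_chain_center(res)[None, :]


def build_contact_map(chain: StructureChain, smap: TemplateStructureMap,
                      definition: str = SIDECHAIN_CENTERS,
                      cutoff: float = 6.5,
                      min_separation: int = 2) -> ContactMap:
    """Contacts among template residues resolved in the structure.

    A pair (i, j) of template indices is a contact iff both map into the
    structure, |i - j| >= min_separation, and the relevant distance is
    strictly below the cutoff.
    """
    if not smap.mapping:
        raise MatrixError("empty template-to-structure mapping")
    if definition not in (SIDECHAIN_CENTERS, ANY_SIDECHAIN_ATOMS):
        raise MatrixError(f"unknown contact definition {definition!r}")
    items = sorted(smap.mapping.items())           # (template_idx, struct_idx)
    pairs: set[frozenset[int]] = set()
    if definition == SIDECHAIN_CENTERS:
        centers = {t: side_chain_center(chain.residues[s]) for t, s in items}
        tlist = [t for t, _ in items]
        arr = np.array([centers[t] for t in tlist])
        d = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=-1)
        for a in range(len(tlist)):
            for b in range(a + 1, len(tlist)):
                ti, tj = tlist[a], tlist[b]
                if abs(ti - tj) >= min_separation and d[a, b] < cutoff:
                    pairs.add(frozenset((ti, tj)))
    else:
        pts = {t: _sidechain_points(chain, s) for t, s in items}
        tlist = [t for t, _ in items]
        for a in range(len(tlist)):
            for b in range(a + 1, len(tlist)):
                ti, tj = tlist[a], tlist[b]
                if abs(ti - tj) < min_separation:
                    continue
                diff = pts[ti][:, None, :] - pts[tj][None, :, :]
                if np.min(np.linalg.norm(diff, axis=-1)) < cutoff:
                    pairs.add(frozenset((ti, tj)))
    return ContactMap(frozenset(pairs), definition, cutoff)


def structure_score(block_pairs: Iterable[tuple[int, int]],
                    template_to_query: Mapping[int, int],
                    cmap: ContactMap, ce: EnergyMatrix,
                    query: SequenceRecord) -> float:
    """Contact-energy structure score of a block realization.

    For each block pair (query i' aligned to template i), every template
    contact partner p of i whose aligned query residue p' exists in the
    current full-alignment state contributes -e(aa(i'), aa(p')); partners
    aligned to gaps contribute nothing.
    """
    partners = cmap.partners()
    qres = query.residues
    total = 0.0
    for q, t in block_pairs:
        for p in partners.get(t, ()):
            pq = template_to_query.get(p)
            if pq is None:
                continue
            total -= ce.energy(qres[q], qres[pq])
    return total
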
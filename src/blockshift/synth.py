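"""Self-contained synthetic fixtures: toy structures, profiles and
alignments with planted block shifts.

The generator emulates the regime the refinement method targets: a
template of ideal alpha-helices (CA on a 2.3 A helix with 1.5 A rise and
100 degree twist; a single CB pseudo-side-chain displaced 1.0 A radially
outward, which puts the canonical i/i+3 and i/i+4 helix neighbours inside
the 6.5 A side-chain contact cutoff) joined by extended loops, a query
derived from the template under a substitution model, and a starting
alignment produced by shifting chosen blocks with the variant machinery
itself, so the planted error is exactly of the kind the refiner searches
over.  Helix sequences carry a heptad hydrophobic pattern (hydrophobic at
positions 0 and 3 mod 7) whose polar positions cycle with period 5, so no
shift of 4 or fewer residues reproduces the true register.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .blocks import SSEAnnotation, extract_blocks, parse_sse
from .config import Config
from .errors import InputError
from .matrices import AMINO_ACIDS, AA_INDEX, conditional_probabilities
from .profiles import Profile, mixed_profile
from .refine import refine_alignment
from .seqio import PairwiseAlignment, SequenceRecord, write_alignment_fasta
from .structio import Residue3D, StructureChain
from .evaluate import qscore
from .variants import GapMode, realize_variant

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

HELIX_RISE = 1.5          # A per residue along the axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # CA radius, A
CB_OFFSET = 1.0           # radial CB displacement beyond CA, A
LOOP_SPACING = 3.5        # A between consecutive loop CA positions

_HYDROPHOBIC = "LIFVM"
_POLAR = "EKSQA"
_LOOP = "SNPTQ"


def make_helix_coords(n: int, z0: float = 0.0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Ideal alpha-helix (CA, CB) coordinates for n residues."""
    if n < 1:
        raise InputError("helix length must be >= 1")
    out = []
    for i in range(n):
        theta = math.radians(HELIX_TWIST * i)
        ca = np.array([HELIX_RADIUS * math.cos(theta),
                       HELIX_RADIUS * math.sin(theta),
                       z0 + HELIX_RISE * i])
        rcb = HELIX_RADIUS + CB_OFFSET
        cb = np.array([rcb * math.cos(theta), rcb * math.sin(theta), ca[2]])
        out.append((ca, cb))
    return out


def make_loop_coords(n: int, z0: float = 0.0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Extended on-axis segment: CA spaced 3.5 A in z, CB offset in x."""
    out = []
    for i in range(n):
        ca = np.array([0.0, 0.0, z0 + LOOP_SPACING * (i + 1)])
        cb = ca + np.array([1.0, 0.0, 0.0])
        out.append((ca, cb))
    return out


@dataclass
class SyntheticCase:
    query: SequenceRecord
    template: SequenceRecord
    chain: StructureChain
    sse: SSEAnnotation
    true_alignment: PairwiseAlignment
    starting_alignment: PairwiseAlignment
    qprof: Profile
    tprof: Profile
    planted_shifts: list[int]
    seed: int


def _template_design(n_blocks: int, block_len: int, loop_len: int,
                     hydrophobic_period: int) -> tuple[str, str, list[tuple[np.ndarray, np.ndarray]]]:
    """Sequence, SSE labels and coordinates of the synthetic template."""
    seq: list[str] = []
    labels: list[str] = []
    coords: list[tuple[np.ndarray, np.ndarray]] = []
    hydro_i = polar_i = loop_i = 0
    z = 0.0

    def add_loop(n: int):
        nonlocal z, loop_i
        for ca, cb in make_loop_coords(n, z):
            seq.append(_LOOP[loop_i % len(_LOOP)])
            loop_i += 1
            labels.append("C")
            coords.append((ca, cb))
        z += LOOP_SPACING * (n + 1)

    add_loop(loop_len)
    for b in range(n_blocks):
        helix = make_helix_coords(block_len, z)
        for i, (ca, cb) in enumerate(helix):
            if i % hydrophobic_period in (0, 3):
                seq.append(_HYDROPHOBIC[hydro_i % len(_HYDROPHOBIC)])
                hydro_i += 1
            else:
                seq.append(_POLAR[polar_i % len(_POLAR)])
                polar_i += 1
            labels.append("H")
            coords.append((ca, cb))
        z += HELIX_RISE * block_len + LOOP_SPACING
        add_loop(loop_len)
    return "".join(seq), "".join(labels), coords


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute residues at the given rate under BLOSUM62 conditionals."""
    if rate <= 0:
        return seq
    cond = conditional_probabilities()
    out = list(seq)
    for i, aa in enumerate(seq):
        if rng.random() < rate:
            col = cond[:, AA_INDEX[aa]]
            out[i] = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=col)]
    return "".join(out)


def make_case(n_blocks: int = 3,
              planted_shifts: Optional[Sequence[int]] = None,
              block_len: int = 12, loop_len: int = 10,
              hydrophobic_period: int = 7,
              signal_strength: float = 0.7,
              profile_depth: float = 10.0,
              max_shift: int = 4,
              seed: int = 0) -> SyntheticCase:
    """Build a fully synthetic refinement case with known truth.

    ``signal_strength`` in (0, 1]: the query is the template substituted at
    rate 1 - signal_strength, and both profiles mix one-hot columns with
    background by the same factor.  ``planted_shifts`` gives one shift per
    block (0 = untouched); None draws each uniformly from the non-zero
    shifts up to ``max_shift``.  Deterministic given the seed.
    """
    if loop_len < 2 * max_shift:
        raise InputError("loops too short to absorb the allowed shifts")
    rng = np.random.default_rng(seed)
    tseq, labels, coords = _template_design(n_blocks, block_len, loop_len,
                                            hydrophobic_period)
    if planted_shifts is None:
        choices = [k for k in range(-max_shift, max_shift + 1) if k != 0]
        planted_shifts = [int(rng.choice(choices)) for _ in range(n_blocks)]
    planted_shifts = list(planted_shifts)
    if len(planted_shifts) != n_blocks:
        raise InputError("one planted shift per block required")
    if any(abs(k) > max_shift for k in planted_shifts):
        raise InputError("planted shifts must not exceed max_shift")

    template = SequenceRecord("template", tseq)
    qseq = _mutate(tseq, 1.0 - signal_strength, rng)
    query = SequenceRecord("query", qseq)
    residues = []
    for aa, (ca, cb) in zip(tseq, coords):
        residues.append(Residue3D(
            chain="A", seq_label="", aa=aa,
            backbone_atoms={"CA": ca}, sidechain_atoms={"CB": cb},
        ))
    for i, r in enumerate(residues, start=1):
        r.seq_label = str(i)
    chain = StructureChain("A", residues)
    sse = parse_sse(labels)
    true_aln = PairwiseAlignment(query, template, qseq, tseq)

    working = true_aln
    for ordinal, k in enumerate(planted_shifts, start=1):
        if k == 0:
            continue
        block = extract_blocks(working, sse)[ordinal - 1]
        v = realize_variant(working, sse, block, GapMode.ORIGINAL, k)
        if v is None:
            raise InputError(
                f"planted shift {k:+d} on block {ordinal} is infeasible"
            )
        working = v.alignment

    qprof = mixed_profile(query, signal_strength, depth=profile_depth)
    tprof = mixed_profile(template, signal_strength, depth=profile_depth)
    return SyntheticCase(query, template, chain, sse, true_aln, working,
                         qprof, tprof, planted_shifts, seed)


def recovery_rate(n_cases: int, config: Optional[Config] = None,
                  signal_strength: float = 1.0, n_blocks: int = 3,
                  planted_shifts: Optional[Sequence[int]] = None,
                  seed: int = 0) -> float:
    """Fraction of seeded cases fully restored to Q = 100 by refinement."""
    if n_cases < 1:
        raise InputError("n_cases must be >= 1")
    cfg = config or Config(mode="O+G")
    hits = 0
    for i in range(n_cases):
        case = make_case(n_blocks=n_blocks, planted_shifts=planted_shifts,
                         signal_strength=signal_strength,
                         max_shift=cfg.max_shift if cfg.max_shift > 0 else 4,
                         seed=seed + i)
        report = refine_alignment(case.starting_alignment, case.chain,
                                  case.sse, cfg,
                                  qprof=case.qprof, tprof=case.tprof)
        if qscore(report.refined, case.true_alignment).q == 100.0:
            hits += 1
    return hits / n_cases


def write_pdb(chain: StructureChain, path: str | Path) -> None:
    """Write a minimal single-chain PDB file (CA/CB pseudo-residues)."""
    serial = 1
    with open(path, "w") as fh:
        for i, res in enumerate(chain.residues, start=1):
            res3 = _ONE_TO_THREE.get(res.aa, "UNK")
            for name, pos in res.atoms.items():
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s}{res3:>4s} {chain.chain_id}"
                    f"{i:4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}\n"
                )
                serial += 1
        fh.write("END\n")


def write_case_dir(case: SyntheticCase, outdir: str | Path) -> None:
    """Dump a case as plain-text files (FASTA, PDB, SSE, profiles)."""
    from .profiles import dump_profile
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_alignment_fasta(case.true_alignment, out / "true.afa")
    write_alignment_fasta(case.starting_alignment, out / "starting.afa")
    with open(out / "sequences.fasta", "w") as fh:
        fh.write(f">{case.query.id}\n{case.query.residues}\n")
        fh.write(f">{case.template.id}\n{case.template.residues}\n")
    write_pdb(case.chain, out / "template.pdb")
    (out / "template.sse").write_text(case.sse.labels + "\n")
    dump_profile(case.qprof, out / "query.profile.tsv")
    dump_profile(case.tprof, out / "template.profile.tsv")
    (out / "case.txt").write_text(
        f"seed\t{case.seed}\nplanted_shifts\t"
        + ",".join(str(k) for k in case.planted_shifts) + "\n"
    )
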
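"""Block scoring, the two-filter decision rule, and the refinement loop.

Each candidate (the incumbent original block plus its variants) gets a
sequence score and a structure score; both are z-standardized across the
candidate set and combined linearly:

    S_comb_I  = w1 * z_seq + (1 - w1) * z_str
    S_comb_II = w2 * z_seq + (1 - w2) * z_str

Filter 1 selects the variant with the highest S_comb_I; if that does not
strictly exceed the incumbent's, every variant is rejected.  Filter 2
accepts the selected variant only if its S_comb_II also strictly exceeds
the incumbent's.  Ties keep the original.  Blocks are processed from the
N- to the C-terminus and an accepted variant is committed to the working
alignment before the next block is scored, so later structure scores see
earlier decisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .blocks import AlignmentBlock, SSEAnnotation, extract_blocks
from .contacts import (ANY_SIDECHAIN_ATOMS, SIDECHAIN_CENTERS, ContactMap,
                       EnergyMatrix, build_contact_map, load_energy_matrix,
                       structure_score)
from .errors import ModeError
from .profiles import Profile, profile_from_sequence, sequence_score
from .seqio import PairwiseAlignment
from .structio import StructureChain, TemplateStructureMap, map_structure_to_template
from .variants import (AlignmentVariant, GapMode, generate_variants,
                       realize_variant)

log = logging.getLogger(__name__)

MODES = ("O", "O+G", "O+G+M")


@dataclass
class ScoreBundle:
    gap_mode: GapMode
    shift: int
    s_seq: float
    s_str: float
    z_seq: float = 0.0
    z_str: float = 0.0
    s_comb_1: float = 0.0
    s_comb_2: float = 0.0
    is_incumbent: bool = False
    unique: bool = True
    variant: Optional[AlignmentVariant] = None

    @property
    def label(self) -> str:
        return f"{self.gap_mode.value} [{self.shift:+d}]"


@dataclass
class BlockDecision:
    block: AlignmentBlock
    evaluated: bool
    kept: bool
    chosen: Optional[tuple[GapMode, int]]
    bundles: list[ScoreBundle] = field(default_factory=list)

    @property
    def shift_result(self) -> str:
        if not self.evaluated:
            return "Not evaluated"
        if self.kept:
            return "No shift"
        gm, k = self.chosen
        return f"{gm.value} [{k:+d}]"


@dataclass
class RefinementReport:
    starting: PairwiseAlignment
    refined: PairwiseAlignment
    decisions: list[BlockDecision]
    sse: SSEAnnotation
    identity: float
    min_identity: float
    gate_passed: bool
    mode: str
    query_sse: Optional[str] = None   # display only; never scored

    @property
    def n_refined(self) -> int:
        return sum(1 for d in self.decisions if d.evaluated and not d.kept)


def _zscores(values: list[float]) -> list[float]:
    arr = np.asarray(values, dtype=float)
    sd = arr.std()
    if sd == 0 or len(arr) < 2:
        return [0.0] * len(arr)
    return list((arr - arr.mean()) / sd)


def standardize_and_combine(bundles: list[ScoreBundle],
                            w1: float = 0.5, w2: float = 0.5) -> None:
    """Fill z-scores and combined scores across a candidate set, in place.

    Standardization is over the given bundles (mean 0, sd 1; a degenerate
    sd of 0 maps every z to 0).
    """
    z_seq = _zscores([b.s_seq for b in bundles])
    z_str = _zscores([b.s_str for b in bundles])
    for b, zs, zt in zip(bundles, z_seq, z_str):
        b.z_seq, b.z_str = zs, zt
        b.s_comb_1 = w1 * zs + (1.0 - w1) * zt
        b.s_comb_2 = w2 * zs + (1.0 - w2) * zt


def score_candidates(block: AlignmentBlock, incumbent: AlignmentVariant,
                     variants: list[AlignmentVariant],
                     qprof: Profile, tprof: Profile,
                     cmap: ContactMap, ce: EnergyMatrix,
                     w1: float = 0.5, w2: float = 0.5) -> list[ScoreBundle]:
    """Score the incumbent and every unique variant on a common scale.

    The incumbent is always the first bundle.  Non-unique variants are
    carried along for reporting but excluded from standardization and from
    the decision.
    """
    candidates = [incumbent] + [v for v in variants if v.unique]
    bundles = []
    for v in candidates:
        t2q = v.alignment.columns.template_to_query()
        s_seq = sequence_score(v.pairs, qprof, tprof)
        s_str = structure_score(v.pairs, t2q, cmap, ce, v.alignment.query)
        bundles.append(ScoreBundle(v.gap_mode, v.shift, s_seq, s_str,
                                   is_incumbent=(v is incumbent), variant=v))
    standardize_and_combine(bundles, w1, w2)
    for v in variants:
        if not v.unique:
            t2q = v.alignment.columns.template_to_query()
            bundles.append(ScoreBundle(
                v.gap_mode, v.shift,
                sequence_score(v.pairs, qprof, tprof),
                structure_score(v.pairs, t2q, cmap, ce, v.alignment.query),
                unique=False, variant=v))
    return bundles


def two_filter_decide(block: AlignmentBlock,
                      bundles: list[ScoreBundle]) -> BlockDecision:
    """Apply the two-filter rule to a scored candidate set."""
    incumbent = next(b for b in bundles if b.is_incumbent)
    contenders = [b for b in bundles if not b.is_incumbent and b.unique]
    if not contenders:
        return BlockDecision(block, True, True, None, bundles)
    best = max(contenders, key=lambda b: b.s_comb_1)  # first wins ties
    if best.s_comb_1 <= incumbent.s_comb_1:
        return BlockDecision(block, True, True, None, bundles)
    if best.s_comb_2 <= incumbent.s_comb_2:
        return BlockDecision(block, True, True, None, bundles)
    return BlockDecision(block, True, False, (best.gap_mode, best.shift), bundles)


def refine_alignment(aln: PairwiseAlignment, chain: StructureChain,
                     sse: SSEAnnotation, config=None,
                     qprof: Optional[Profile] = None,
                     tprof: Optional[Profile] = None,
                     smap: Optional[TemplateStructureMap] = None,
                     query_sse: Optional[str] = None,
                     ) -> RefinementReport:
    """Refine every evaluable block of the alignment, N- to C-terminus.

    When the template-to-structure identity gate fails, the report carries
    the starting alignment unchanged with no block evaluated.  With
    ``config.freeze_state`` candidates are generated and scored against
    the starting alignment rather than the committed working state;
    accepted (gap mode, shift) choices are still applied sequentially.
    ``query_sse`` is carried into the report for display only.
    """
    from .config import Config  # local import to avoid a cycle
    cfg = config or Config()
    if cfg.mode not in MODES:
        if cfg.mode == "O+G+M+S":
            raise ModeError(
                "mode O+G+M+S (SVM second filter) is not implemented; "
                "use one of: " + ", ".join(MODES)
            )
        raise ModeError(f"unknown mode {cfg.mode!r}; use one of: " + ", ".join(MODES))

    if smap is None:
        smap = map_structure_to_template(aln.template, chain, cfg.min_identity)
    if qprof is None:
        qprof = profile_from_sequence(aln.query)
    if tprof is None:
        tprof = profile_from_sequence(aln.template)

    if not smap.passes_gate:
        blocks = extract_blocks(aln, sse, cfg.min_block_fraction)
        decisions = [BlockDecision(b, False, True, None) for b in blocks]
        return RefinementReport(aln, aln, decisions, sse, smap.identity,
                                cfg.min_identity, False, cfg.mode, query_sse)

    if cfg.mode == "O+G+M":
        definition = ANY_SIDECHAIN_ATOMS
        if cfg.matrix_path:
            ce = load_energy_matrix(cfg.matrix_path)
        else:
            log.info("mode O+G+M without a custom matrix: falling back to the "
                     "MJ energies over any-side-chain-atom contacts")
            ce = load_energy_matrix("MJ")
    else:
        definition = SIDECHAIN_CENTERS
        ce = load_energy_matrix(cfg.matrix_path or "MJ")
    cmap = build_contact_map(chain, smap, definition, cfg.contact_cutoff,
                             cfg.min_separation)

    working = aln
    decisions: list[BlockDecision] = []
    n_elements = len(sse.elements)
    for ordinal in range(1, n_elements + 1):
        base = aln if cfg.freeze_state else working
        block = extract_blocks(base, sse, cfg.min_block_fraction)[ordinal - 1]
        if not block.evaluable:
            decisions.append(BlockDecision(block, False, True, None))
            continue
        variants = generate_variants(
            base, sse, block, mode=cfg.mode, max_shift=cfg.max_shift,
            include_original_family_in_og=cfg.include_original_family,
        )
        incumbent = AlignmentVariant(GapMode.ORIGINAL, 0, list(block.pairs),
                                     base, feasible=True, unique=True)
        bundles = score_candidates(block, incumbent, variants, qprof, tprof,
                                   cmap, ce, cfg.w1, cfg.w2)
        decision = two_filter_decide(block, bundles)
        if not decision.kept:
            gm, k = decision.chosen
            if cfg.freeze_state:
                wblock = extract_blocks(working, sse,
                                        cfg.min_block_fraction)[ordinal - 1]
                applied = realize_variant(working, sse, wblock, gm, k)
                if applied is None:
                    log.warning("block %d: accepted %s [%+d] infeasible on "
                                "the working alignment; keeping original",
                                ordinal, gm.value, k)
                    decision = BlockDecision(block, True, True, None,
                                             decision.bundles)
                else:
                    working = applied.alignment
            else:
                chosen = next(b.variant for b in bundles
                              if b.unique and not b.is_incumbent
                              and (b.gap_mode, b.shift) == (gm, k))
                working = chosen.alignment
        decisions.append(decision)
    return RefinementReport(aln, working, decisions, sse, smap.identity,
                            cfg.min_identity, True, cfg.mode, query_sse)


def annotate_changes(starting: PairwiseAlignment,
                     refined: PairwiseAlignment) -> tuple[str, str]:
    """Cm1/Cm2 per-column change annotation over the refined alignment.

    Cm1 carries the sign of each query residue's movement (+ toward the
    C-terminus); Cm2 the magnitude, with '-' for a residue gap-aligned in
    both alignments, '*' for a residue that lost its partner, and blanks
    for columns holding only a template residue.
    """
    if (starting.query.residues != refined.query.residues
            or starting.template.residues != refined.template.residues):
        raise ValueError("alignments are not over the same sequence pair")
    start_q2t = starting.columns.query_to_template()
    ref_cols = refined.columns.entries
    cm1 = []
    cm2 = []
    for q, t in ref_cols:
        if q is None:
            cm1.append(" ")
            cm2.append(" ")
            continue
        t_start = start_q2t.get(q)
        if t_start is None and t is None:
            cm1.append(" ")
            cm2.append("-")
        elif t_start is not None and t is None:
            cm1.append(" ")
            cm2.append("*")
        elif t_start is None and t is not None:
            # newly aligned residue: movement undefined, magnitude shown as 0
            cm1.append(" ")
            cm2.append("0")
        else:
            delta = t - t_start
            cm1.append("+" if delta > 0 else ("-" if delta < 0 else " "))
            cm2.append(str(min(abs(delta), 9)))
    return "".join(cm1), "".join(cm2)
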
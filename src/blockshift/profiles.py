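"""Positional amino-acid profiles and the profile-profile sequence score.

A :class:`Profile` holds, per position of its ungapped master sequence,
effective observation counts n(a) (Henikoff position-based weighting of an
MSA, weights scaled so they sum to the profile's effective sequence number)
and pseudocount-smoothed frequencies

    p~(a) = (n(a) + tau * g(a)) / (sum_b n(b) + tau)

where g(a) is the BLOSUM62-conditional pseudocount distribution of the
column and tau = max(1, 5 ln neff).  Two profile columns are compared with
the symmetric log-odds score

    s(x, y) = 1/2 * sum_a [ n_x(a) ln(p~_y(a)/p_bg(a))
                            + n_y(a) ln(p~_x(a)/p_bg(a)) ]

which is zero when both smoothed columns equal the background and grows
when the columns share over-represented residues.  The sequence score of a
block realization is the sum of column scores over its aligned pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError
from .matrices import (AA_INDEX, AMINO_ACIDS, N_AA, background_frequencies,
                       conditional_probabilities)
from .seqio import GAP, SequenceRecord, read_msa_fasta


@dataclass
class Profile:
    master: SequenceRecord
    counts: np.ndarray        # (L, 20) effective observation counts
    freqs: np.ndarray         # (L, 20) smoothed frequencies
    neff: float               # effective sequence number (profile level)
    neff_pos: np.ndarray      # (L,) per-position effective sequence number
    background: np.ndarray    # (20,)

    @property
    def length(self) -> int:
        return len(self.master)

    def __post_init__(self):
        assert self.counts.shape == (self.length, N_AA)
        assert self.freqs.shape == (self.length, N_AA)

    def log_odds(self) -> np.ndarray:
        return np.log(self.freqs / self.background[None, :])


def _henikoff_weights(columns: list[list[str]], n_seq: int) -> np.ndarray:
    """Position-based sequence weights; gap positions do not contribute."""
    w = np.zeros(n_seq)
    for col in columns:
        present = [(k, aa) for k, aa in enumerate(col) if aa not in (GAP, "X")]
        if not present:
            continue
        kinds: dict[str, int] = {}
        for _, aa in present:
            kinds[aa] = kinds.get(aa, 0) + 1
        r = len(kinds)
        for k, aa in present:
            w[k] += 1.0 / (r * kinds[aa])
    if w.sum() == 0:
        w[:] = 1.0
    return w / w.sum()


def _column_entropy(freq: np.ndarray) -> float:
    nz = freq[freq > 0]
    return float(-(nz * np.log(nz)).sum())


def _smooth(counts: np.ndarray, neff: float, background: np.ndarray,
            pseudocount_weight: float | None) -> np.ndarray:
    """Apply BLOSUM62-conditional pseudocounts column-wise."""
    cond = conditional_probabilities()          # [a, b] = P(a|b)
    tau = pseudocount_weight
    if tau is None:
        tau = max(1.0, 5.0 * math.log(max(neff, 1.0)))
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0),
                     background[None, :])
    g = f @ cond.T                              # g(a) = sum_b f(b) P(a|b)
    freqs = (counts + tau * g) / (totals + tau)
    return freqs


def build_profile(msa: Sequence[tuple[str, str]] | str | Path, master_id: str,
                  max_seq_identity: float = 0.94,
                  min_coverage: float = 0.0,
                  pseudocount_weight: float | None = None,
                  weighting: str = "henikoff") -> Profile:
    """Build a profile from an aligned-FASTA MSA, projected onto the master.

    Near-duplicate rows (identity to the master above ``max_seq_identity``,
    master excluded) and rows covering less than ``min_coverage`` of the
    master's positions are dropped before weighting.  ``weighting="none"``
    gives every surviving row weight 1 (raw counts), for oracle comparisons.
    """
    rows = read_msa_fasta(msa) if isinstance(msa, (str, Path)) else list(msa)
    if not rows:
        raise InputError("empty MSA")
    master_rows = [r for i, r in rows if i == master_id]
    if not master_rows:
        raise InputError(f"master sequence {master_id!r} not found in MSA")
    master_row = master_rows[0]
    keep_cols = [i for i, ch in enumerate(master_row) if ch != GAP]
    master_seq = "".join(master_row[i] for i in keep_cols)

    projected: list[tuple[str, str]] = []
    for rid, row in rows:
        proj = "".join(row[i] for i in keep_cols)
        if rid == master_id and proj == master_seq:
            projected.append((rid, proj))
            continue
        cover = sum(1 for ch in proj if ch != GAP) / len(proj)
        if cover < min_coverage:
            continue
        pairs = [(a, b) for a, b in zip(master_seq, proj) if b != GAP]
        ident = (sum(1 for a, b in pairs if a == b) / len(pairs)) if pairs else 0.0
        if rid != master_id and ident > max_seq_identity:
            continue
        projected.append((rid, proj))
    if not any(rid == master_id for rid, _ in projected):
        projected.insert(0, (master_id, master_seq))

    n_seq = len(projected)
    length = len(master_seq)
    columns = [[projected[k][1][i] for k in range(n_seq)] for i in range(length)]
    if weighting == "none":
        weights = np.ones(n_seq)
        unit_weights = np.ones(n_seq) / n_seq
    elif weighting == "henikoff":
        unit_weights = _henikoff_weights(columns, n_seq)
        weights = unit_weights  # rescaled by neff below
    else:
        raise InputError(f"unknown weighting {weighting!r}")

    # first pass: unit-sum weighted frequencies -> neff
    raw = np.zeros((length, N_AA))
    for i, col in enumerate(columns):
        for k, aa in enumerate(col):
            if aa == GAP:
                continue
            if aa == "X":
                raw[i] += unit_weights[k] * background_frequencies()
            else:
                raw[i, AA_INDEX[aa]] += unit_weights[k]
    neff_pos = np.ones(length)
    for i in range(length):
        tot = raw[i].sum()
        if tot > 0:
            neff_pos[i] = math.exp(_column_entropy(raw[i] / tot))
    neff = float(math.exp(np.mean([
        _column_entropy(raw[i] / raw[i].sum()) if raw[i].sum() > 0 else 0.0
        for i in range(length)
    ])))

    if weighting == "henikoff":
        counts = raw * neff
    else:
        counts = np.zeros((length, N_AA))
        for i, col in enumerate(columns):
            for k, aa in enumerate(col):
                if aa == GAP:
                    continue
                if aa == "X":
                    counts[i] += background_frequencies()
                else:
                    counts[i, AA_INDEX[aa]] += 1.0

    bg = background_frequencies()
    freqs = _smooth(counts, neff, bg, pseudocount_weight)
    master_rec = SequenceRecord(master_id, master_seq.replace(GAP, ""))
    return Profile(master_rec, counts, freqs, neff, neff_pos, bg)


def profile_from_sequence(seq: SequenceRecord,
                          pseudocount_weight: float | None = None,
                          depth: float = 1.0) -> Profile:
    """One-hot profile from a single sequence (runs without any MSA)."""
    return mixed_profile(seq, signal=1.0, depth=depth,
                         pseudocount_weight=pseudocount_weight)


def mixed_profile(seq: SequenceRecord, signal: float, depth: float = 1.0,
                  pseudocount_weight: float | None = None) -> Profile:
    """Profile whose columns mix one-hot identity with background.

    ``signal`` in [0, 1]: 1 gives one-hot columns, 0 pure background.
    ``depth`` scales the effective observation count per column.
    """
    if not 0.0 <= signal <= 1.0:
        raise InputError("signal must be in [0, 1]")
    bg = background_frequencies()
    length = len(seq)
    counts = np.zeros((length, N_AA))
    for i, aa in enumerate(seq.residues):
        col = (1.0 - signal) * bg.copy()
        if aa == "X":
            col += signal * bg
        else:
            col[AA_INDEX[aa]] += signal
        counts[i] = depth * col
    neff_pos = np.ones(length)
    for i in range(length):
        f = counts[i] / counts[i].sum()
        neff_pos[i] = math.exp(_column_entropy(f))
    neff = float(np.exp(np.mean(np.log(neff_pos))))
    freqs = _smooth(counts, neff, bg, pseudocount_weight)
    return Profile(seq, counts, freqs, neff, neff_pos, bg)


def column_score(p: Profile, i: int, q: Profile, j: int) -> float:
    """Symmetric profile-profile log-odds score of columns i and j (nats)."""
    if not (0 <= i < p.length):
        raise IndexError(f"column {i} out of range for profile of length {p.length}")
    if not (0 <= j < q.length):
        raise IndexError(f"column {j} out of range for profile of length {q.length}")
    lp = np.log(p.freqs[i] / p.background)
    lq = np.log(q.freqs[j] / q.background)
    return 0.5 * float(p.counts[i] @ lq + q.counts[j] @ lp)


def sequence_score(block_pairs: Iterable[tuple[int, int]],
                   qprof: Profile, tprof: Profile) -> float:
    """Sum of column scores over the aligned pairs of a block realization."""
    return sum(column_score(qprof, q, tprof, t) for q, t in block_pairs)


def dump_profile(profile: Profile, path: str | Path) -> None:
    """Write a profile as tab-separated text (position, 20 counts, 20 freqs)."""
    with open(path, "w") as fh:
        fh.write("# master\t" + profile.master.id + "\t" + profile.master.residues + "\n")
        fh.write("# neff\t%.6f\n" % profile.neff)
        header = ["pos", "aa"] + [f"n_{a}" for a in AMINO_ACIDS] + [f"p_{a}" for a in AMINO_ACIDS]
        fh.write("\t".join(header) + "\n")
        for i in range(profile.length):
            row = [str(i + 1), profile.master.residues[i]]
            row += [f"{v:.6f}" for v in profile.counts[i]]
            row += [f"{v:.6f}" for v in profile.freqs[i]]
            fh.write("\t".join(row) + "\n")


def load_profile(path: str | Path) -> Profile:
    master_id = master_seq = None
    neff = 1.0
    counts_rows: list[list[float]] = []
    freq_rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# master\t"):
                _, master_id, master_seq = line.split("\t")
            elif line.startswith("# neff\t"):
                neff = float(line.split("\t")[1])
            elif line.startswith("pos\t") or not line.strip():
                continue
            else:
                parts = line.split("\t")
                vals = [float(x) for x in parts[2:]]
                counts_rows.append(vals[:N_AA])
                freq_rows.append(vals[N_AA:])
    if master_id is None or master_seq is None:
        raise InputError(f"profile file {path} lacks a master header")
    master = SequenceRecord(master_id, master_seq)
    counts = np.array(counts_rows)
    freqs = np.array(freq_rows)
    length = len(master)
    neff_pos = np.full(length, neff)
    return Profile(master, counts, freqs, neff, neff_pos, background_frequencies())
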
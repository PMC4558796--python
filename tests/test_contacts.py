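"""Contact maps, energy matrices and the structure score."""

import numpy as np
import pytest

from blockshift import (Residue3D, SequenceRecord, StructureChain,
                        build_contact_map, load_energy_matrix,
                        structure_score, zero_energy_matrix)
from blockshift.contacts import ANY_SIDECHAIN_ATOMS, SIDECHAIN_CENTERS
from blockshift.errors import MatrixError
from blockshift.matrices import AMINO_ACIDS
from blockshift.structio import TemplateStructureMap, side_chain_center


def _write_matrix(tmp_path, values):
    lines = [" ".join(AMINO_ACIDS)]
    for i, a in enumerate(AMINO_ACIDS):
        lines.append(a + " " + " ".join(f"{values[i, j]:.2f}" for j in range(20)))
    p = tmp_path / "ce.txt"
    p.write_text("\n".join(lines) + "\n")
    return p


class TestLoadEnergyMatrix:
    def test_builtin_mj_is_symmetric_and_finite(self):
        ce = load_energy_matrix("MJ")
        assert ce.values.shape == (20, 20)
        assert np.all(np.isfinite(ce.values))
        np.testing.assert_allclose(ce.values, ce.values.T)
        # favorable hydrophobic pairs are strongly negative energies
        assert ce.energy("L", "L") < ce.energy("K", "K") < 0

    def test_asymmetric_custom_rejected(self, tmp_path):
        vals = np.zeros((20, 20))
        vals[0, 1] = 1.0  # CE(A,C) != CE(C,A)
        with pytest.raises(MatrixError, match="asymmetric"):
            load_energy_matrix(_write_matrix(tmp_path, vals))

    def test_malformed_file_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("A C D\n1 2 3\n")
        with pytest.raises(MatrixError):
            load_energy_matrix(p)

    def test_custom_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(20, 20))
        vals = ((vals + vals.T) / 2).round(2)
        ce = load_energy_matrix(_write_matrix(tmp_path, vals))
        np.testing.assert_allclose(ce.values, vals)


def _chain(points, seq=None):
    """Chain with one CB pseudo-atom per residue at the given points."""
    seq = seq or "L" * len(points)
    residues = []
    for i, (aa, p) in enumerate(zip(seq, points)):
        p = np.asarray(p, dtype=float)
        residues.append(Residue3D("A", str(i + 1), aa,
                                  backbone_atoms={"CA": p},
                                  sidechain_atoms={"CB": p}))
    return StructureChain("A", residues)


def _identity_map(n):
    return TemplateStructureMap({i: i for i in range(n)}, 1.0, 0.5)


class TestBuildContactMap:
    def test_pair_inside_cutoff(self):
        chain = _chain([[0, 0, 0], [50, 0, 0], [6.4, 0, 0]])
        cmap = build_contact_map(chain, _identity_map(3), SIDECHAIN_CENTERS)
        assert cmap.pairs == frozenset({frozenset({0, 2})})

    def test_pair_outside_cutoff(self):
        chain = _chain([[0, 0, 0], [50, 0, 0], [6.6, 0, 0]])
        cmap = build_contact_map(chain, _identity_map(3), SIDECHAIN_CENTERS)
        assert len(cmap) == 0

    def test_cutoff_is_strict_to_hundredth_angstrom(self):
        """Bisection on the pair distance recovers the documented threshold."""
        def in_contact(d):
            chain = _chain([[0, 0, 0], [50, 0, 0], [d, 0, 0]])
            return len(build_contact_map(chain, _identity_map(3),
                                         SIDECHAIN_CENTERS)) == 1
        lo, hi = 5.0, 8.0
        assert in_contact(lo) and not in_contact(hi)
        while hi - lo > 1e-4:
            mid = (lo + hi) / 2
            if in_contact(mid):
                lo = mid
            else:
                hi = mid
        assert abs(hi - 6.5) < 0.01

    def test_sequence_neighbours_excluded(self):
        chain = _chain([[0, 0, 0], [4.0, 0, 0], [100, 0, 0]])
        cmap = build_contact_map(chain, _identity_map(3), SIDECHAIN_CENTERS,
                                 min_separation=2)
        assert len(cmap) == 0
        cmap = build_contact_map(chain, _identity_map(3), SIDECHAIN_CENTERS,
                                 min_separation=1)
        assert frozenset({0, 1}) in cmap.pairs

    @pytest.mark.parametrize("definition", [SIDECHAIN_CENTERS, ANY_SIDECHAIN_ATOMS])
    def test_counts_match_brute_force_scan(self, definition):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 15, size=(12, 3))
        chain = _chain(pts)
        cmap = build_contact_map(chain, _identity_map(12), definition)
        expected = set()
        for i in range(12):
            for j in range(i + 1, 12):
                if j - i >= 2 and np.linalg.norm(pts[i] - pts[j]) < 6.5:
                    expected.add(frozenset({i, j}))
        assert cmap.pairs == frozenset(expected)

    def test_unmapped_residues_dropped(self):
        chain = _chain([[0, 0, 0], [50, 0, 0], [3.0, 0, 0]])
        smap = TemplateStructureMap({0: 0, 1: 1}, 1.0, 0.5)  # residue 2 unmapped
        cmap = build_contact_map(chain, smap, SIDECHAIN_CENTERS)
        assert len(cmap) == 0

    def test_any_atom_definition_uses_minimum_distance(self):
        res_a = Residue3D("A", "1", "L", sidechain_atoms={
            "CB": np.array([0.0, 0.0, 0.0]), "CG": np.array([0.0, 0.0, 3.0])})
        res_far = Residue3D("A", "2", "L", sidechain_atoms={
            "CB": np.array([100.0, 0, 0])})
        res_b = Residue3D("A", "3", "L", sidechain_atoms={
            "CB": np.array([0.0, 0.0, 9.0])})
        chain = StructureChain("A", [res_a, res_far, res_b])
        # centers are 0 and 9 apart (no contact); closest atoms are 6 apart
        assert len(build_contact_map(chain, _identity_map(3),
                                     SIDECHAIN_CENTERS)) == 0
        cmap = build_contact_map(chain, _identity_map(3), ANY_SIDECHAIN_ATOMS)
        assert frozenset({0, 2}) in cmap.pairs


class TestStructureScore:
    def test_three_partner_pair(self):
        """A residue contacting j, k, m contributes all three pair energies."""
        pts = [[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3], [99, 99, 99], [99, 99, 0]]
        chain = _chain(pts, seq="LIKEDF")
        cmap = build_contact_map(chain, _identity_map(6), SIDECHAIN_CENTERS)
        assert cmap.partners()[0] == [2, 3]  # |i-j|>=2 filter drops residue 1
        ce = load_energy_matrix("MJ")
        query = SequenceRecord("q", "MWCHST")
        t2q = {i: i for i in range(6)}
        got = structure_score([(0, 0)], t2q, cmap, ce, query)
        expected = -(ce.energy("M", "C") + ce.energy("M", "H"))
        assert got == pytest.approx(expected)

    def test_gap_partners_contribute_zero(self):
        chain = _chain([[0, 0, 0], [50, 0, 0], [3, 0, 0]], seq="LKV")
        cmap = build_contact_map(chain, _identity_map(3), SIDECHAIN_CENTERS)
        ce = load_energy_matrix("MJ")
        query = SequenceRecord("q", "LKV")
        assert structure_score([(0, 0)], {0: 0}, cmap, ce, query) == 0.0

    def test_no_contacts_scores_zero(self):
        chain = _chain([[0, 0, 0], [50, 0, 0], [100, 0, 0]])
        cmap = build_contact_map(chain, _identity_map(3), SIDECHAIN_CENTERS)
        ce = load_energy_matrix("MJ")
        assert structure_score([(0, 0), (1, 1)], {0: 0, 1: 1}, cmap, ce,
                               SequenceRecord("q", "LLL")) == 0.0

    def test_zero_matrix_zeroes_everything(self):
        rng = np.random.default_rng(1)
        chain = _chain(rng.uniform(0, 10, size=(8, 3)))
        cmap = build_contact_map(chain, _identity_map(8), SIDECHAIN_CENTERS)
        score = structure_score([(i, i) for i in range(8)],
                                {i: i for i in range(8)}, cmap,
                                zero_energy_matrix(),
                                SequenceRecord("q", "LLLLLLLL"))
        assert score == 0.0

    def test_matches_brute_force_over_contacts(self):
        """Block score equals a double loop over all template contacts."""
        ce = load_energy_matrix("MJ")
        rng = np.random.default_rng(99)
        for trial in range(100):
            n = int(rng.integers(6, 14))
            pts = rng.uniform(0, 12, size=(n, 3))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
            qseq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
            chain = _chain(pts, seq=seq)
            cmap = build_contact_map(chain, _identity_map(n), SIDECHAIN_CENTERS)
            # random partial alignment state and block subset
            t2q = {t: t for t in range(n) if rng.random() < 0.8}
            block = [(q, t) for t, q in t2q.items() if rng.random() < 0.5]
            got = structure_score(block, t2q, cmap, ce,
                                  SequenceRecord("q", qseq))
            expected = 0.0
            block_ts = {t for _, t in block}
            for pair in cmap.pairs:
                i, j = sorted(pair)
                for x, y in ((i, j), (j, i)):
                    if x in block_ts and x in t2q and y in t2q:
                        expected -= ce.energy(qseq[t2q[x]], qseq[t2q[y]])
            assert got == pytest.approx(expected)

    def test_additive_and_order_invariant(self):
        rng = np.random.default_rng(5)
        chain = _chain(rng.uniform(0, 10, size=(10, 3)), seq="LIKEDFWHST")
        cmap = build_contact_map(chain, _identity_map(10), SIDECHAIN_CENTERS)
        ce = load_energy_matrix("MJ")
        q = SequenceRecord("q", "MWCHSTLIKE")
        t2q = {i: i for i in range(10)}
        pairs = [(i, i) for i in range(10)]
        total = structure_score(pairs, t2q, cmap, ce, q)
        assert total == pytest.approx(sum(
            structure_score([p], t2q, cmap, ce, q) for p in pairs))
        assert total == pytest.approx(
            structure_score(list(reversed(pairs)), t2q, cmap, ce, q))
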
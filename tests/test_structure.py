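import numpy as np
import pytest

from trpscan.msa import MsaMatrix
from trpscan.structure import (Residue, SeqStructMap, StructureModel,
                               distance_matrix, distogram_stats,
                               feature_select_positions, read_structure,
                               representative_coordinate, write_pdb)
from trpscan.synthetic import BundleSimSpec, simulate_bundle_ensemble

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.458   0.000   0.000  1.00  0.00           C
ATOM      5  CA APHE A   3       7.458   0.000   0.000  0.70  0.00           C
ATOM      6  CA BPHE A   3       7.958   0.500   0.000  0.30  0.00           C
ATOM      7  CB  PHE A   3       8.000   1.400   0.000  1.00  0.00           C
HETATM    8  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
END
"""


def _residue(name, **atoms):
    return Residue("A", 1, "", name, {k: np.asarray(v, float) for k, v in atoms.items()})


def _random_rigid(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = 50 * rng.standard_normal(3)
    return q, t


def _transform(model, q, t, scale=1.0):
    chains = {
        c: [Residue(r.chain, r.author_number, r.icode, r.name,
                    {n: scale * (q @ xyz) + t for n, xyz in r.atoms.items()})
            for r in residues]
        for c, residues in model.chains.items()
    }
    return StructureModel(model.structure_id, chains)


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        st = read_structure(p)
        assert st.n_residues == 3
        assert set(st.chains["A"][0].atoms) == {"N", "CA", "CB"}

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        st = read_structure(p)
        phe = st.residue("A", 3)
        np.testing.assert_allclose(phe.atoms["CA"], [7.458, 0.0, 0.0])

    def test_hetatm_water_excluded(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        st = read_structure(p)
        assert all(r.name != "HOH" for r in st.chains["A"])

    def test_unparseable_file_errors(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("this is not a structure\n")
        with pytest.raises(Exception):
            read_structure(p)

    def test_synthetic_writer_round_trip(self, tmp_path, bundle_ensemble):
        models, _ = bundle_ensemble
        p = tmp_path / "bundle.pdb"
        write_pdb(models[0], p)
        back = read_structure(p)
        assert back.n_residues == models[0].n_residues
        for orig, rt in zip(models[0].chains["A"], back.chains["A"]):
            assert orig.name == rt.name
            np.testing.assert_allclose(orig.atoms["CA"], rt.atoms["CA"],
                                       atol=1e-3)


class TestRepresentativeCoordinate:
    def test_glycine_uses_ca(self):
        res = _residue("GLY", CA=[1, 2, 3], CB=[9, 9, 9])
        np.testing.assert_allclose(representative_coordinate(res), [1, 2, 3])

    def test_alanine_uses_cb(self):
        res = _residue("ALA", CA=[0, 0, 0], CB=[1, 1, 1])
        np.testing.assert_allclose(representative_coordinate(res), [1, 1, 1])

    def test_missing_cb_falls_back_to_ca(self):
        res = _residue("PHE", CA=[2, 2, 2])
        np.testing.assert_allclose(representative_coordinate(res), [2, 2, 2])

    def test_no_anchor_at_all_returns_none(self):
        assert representative_coordinate(_residue("PHE", N=[0, 0, 0])) is None


class TestFeatureSelection:
    def test_gap_free_msa_keeps_all(self):
        msa = MsaMatrix(["a", "b"], ["ACDE", "WYFG"])
        assert feature_select_positions(msa) == [1, 2, 3, 4]

    def test_boundary_presence_excluded(self):
        rows = ["A"] * 96 + ["-"] * 4
        msa = MsaMatrix([f"s{i}" for i in range(100)], rows)
        assert feature_select_positions(msa, 0.96) == []

    def test_region_restriction(self):
        msa = MsaMatrix(["a", "b"], ["ACDE", "WYFG"])
        assert feature_select_positions(msa, 0.96, region_columns=[2, 4]) == [2, 4]

    def test_engineered_pass_count(self):
        # 958-column MSA built so exactly 208 columns are nearly gap-free
        rng = np.random.default_rng(6)
        n, length = 100, 958
        keep = set(rng.choice(length, size=208, replace=False) + 1)
        cols = []
        for c in range(1, length + 1):
            n_gap = rng.integers(0, 4) if c in keep else rng.integers(5, 60)
            col = ["-"] * n_gap + ["A"] * (n - n_gap)
            cols.append(col)
        rows = ["".join(col[i] for col in cols) for i in range(n)]
        msa = MsaMatrix([f"s{i}" for i in range(n)], rows)
        assert len(feature_select_positions(msa, 0.96)) == 208


class TestDistanceMatrix:
    def _two_point_structure(self):
        residues = [
            Residue("A", 1, "", "ALA", {"CA": np.zeros(3), "CB": np.zeros(3)}),
            Residue("A", 2, "", "ALA", {"CA": np.array([3.0, 4.0, 0.0]),
                                        "CB": np.array([3.0, 4.0, 0.0])}),
        ]
        return StructureModel("t", {"A": residues})

    def test_three_four_five(self):
        st = self._two_point_structure()
        smap = SeqStructMap({1: ("A", 1), 2: ("A", 2)})
        m = distance_matrix(st, smap, [1, 2])
        assert m[0, 1] == pytest.approx(5.0)
        assert m[1, 0] == pytest.approx(5.0)
        assert m[0, 0] == 0.0

    def test_rigid_motion_invariance(self, bundle_ensemble):
        models, _ = bundle_ensemble
        st = models[0]
        nums = [r.author_number for r in st.chains["A"]][:20]
        smap = SeqStructMap({k + 1: ("A", n) for k, n in enumerate(nums)})
        positions = list(range(1, len(nums) + 1))
        base = distance_matrix(st, smap, positions)
        rng = np.random.default_rng(2)
        for _ in range(5):
            q, t = _random_rigid(rng)
            moved = distance_matrix(_transform(st, q, t), smap, positions)
            np.testing.assert_allclose(np.asarray(moved), np.asarray(base),
                                       atol=1e-9)

    def test_unmapped_position_fully_masked(self):
        st = self._two_point_structure()
        smap = SeqStructMap({1: ("A", 1)})
        m = distance_matrix(st, smap, [1, 2])
        assert m.mask[1].all() and m.mask[:, 1].all()
        assert not m.mask[0, 0]


class TestDistogramStats:
    def test_identical_replicates_zero_variance(self, bundle_ensemble):
        models, _ = bundle_ensemble
        st = models[0]
        nums = [r.author_number for r in st.chains["A"]][:15]
        smap = SeqStructMap({k + 1: ("A", n) for k, n in enumerate(nums)})
        pos = list(range(1, 16))
        m = distance_matrix(st, smap, pos)
        dg = distogram_stats([m, m, m], pos)
        assert float(np.abs(dg.variance).max()) == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_pair(self):
        a = np.ma.MaskedArray([[0.0, 4.0], [4.0, 0.0]], mask=False)
        b = np.ma.MaskedArray([[0.0, 6.0], [6.0, 0.0]], mask=False)
        dg = distogram_stats([a, b], [1, 2])
        assert dg.mean[0, 1] == pytest.approx(5.0)
        assert dg.variance[0, 1] == pytest.approx(1.0)       # population
        assert dg.norm_variance[0, 1] == pytest.approx(0.04)
        dg_s = distogram_stats([a, b], [1, 2], sample_variance=True)
        assert dg_s.variance[0, 1] == pytest.approx(2.0)

    def test_scale_invariance_of_norm_variance(self, bundle_ensemble):
        models, _ = bundle_ensemble
        nums = [r.author_number for r in models[0].chains["A"]][:15]
        smap = SeqStructMap({k + 1: ("A", n) for k, n in enumerate(nums)})
        pos = list(range(1, 16))
        mats = [distance_matrix(m, smap, pos) for m in models]
        scaled = [distance_matrix(_transform(m, np.eye(3), np.zeros(3), 2.5),
                                  smap, pos) for m in models]
        dg, dg2 = distogram_stats(mats, pos), distogram_stats(scaled, pos)
        np.testing.assert_allclose(np.asarray(dg2.norm_variance),
                                   np.asarray(dg.norm_variance), atol=1e-9)

    def test_symmetry_zero_diag_nonneg_variance(self, bundle_ensemble):
        models, _ = bundle_ensemble
        nums = [r.author_number for r in models[0].chains["A"]]
        smap = SeqStructMap({k + 1: ("A", n) for k, n in enumerate(nums)})
        pos = list(range(1, len(nums) + 1))
        dg = distogram_stats([distance_matrix(m, smap, pos) for m in models], pos)
        np.testing.assert_allclose(np.asarray(dg.mean), np.asarray(dg.mean).T)
        assert np.abs(np.asarray(dg.mean).diagonal()).max() == 0.0
        assert (np.asarray(dg.variance) >= -1e-15).all()

    def test_moved_helix_dominates_normalized_variance(self, bundle_ensemble):
        models, truth = bundle_ensemble
        nums = [r.author_number for r in models[0].chains["A"]]
        smap = SeqStructMap({k + 1: ("A", n) for k, n in enumerate(nums)})
        pos = list(range(1, len(nums) + 1))
        dg = distogram_stats([distance_matrix(m, smap, pos) for m in models], pos)
        nv = np.asarray(dg.norm_variance)
        helix_of = {k: nums[k] // 100 for k in range(len(nums))}
        moved = {int(lbl[2:]) for lbl in truth.moved_helices}
        static_cells, cross_cells = [], []
        for i in range(len(nums)):
            for j in range(i + 1, len(nums)):
                hi, hj = helix_of[i], helix_of[j]
                if hi in moved or hj in moved:
                    if (hi in moved) != (hj in moved):
                        cross_cells.append(nv[i, j])
                elif hi != hj:
                    static_cells.append(nv[i, j])
        assert np.mean(cross_cells) > 10 * np.mean(static_cells)

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(9)
        P, S = 6, 4
        mats = []
        for _ in range(S):
            pts = rng.standard_normal((P, 3)) * 10
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            mask = rng.random((P, P)) < 0.15
            mask |= mask.T
            np.fill_diagonal(mask, False)
            mats.append(np.ma.MaskedArray(d, mask=mask))
        dg = distogram_stats(mats, list(range(1, P + 1)))
        for i in range(P):
            for j in range(P):
                vals = [float(m[i, j]) for m in mats if not m.mask[i, j]]
                if not vals:
                    assert dg.mean.mask[i, j]
                    continue
                assert dg.mean[i, j] == pytest.approx(np.mean(vals), abs=1e-12)
                if len(vals) >= 2:
                    assert dg.variance[i, j] == pytest.approx(
                        np.var(vals), abs=1e-12)
                else:
                    assert dg.variance.mask[i, j]

    def test_requires_two_matrices(self):
        a = np.ma.MaskedArray(np.zeros((2, 2)), mask=False)
        with pytest.raises(ValueError):
            distogram_stats([a], [1, 2])


def test_seqstructmap_tsv_round_trip(tmp_path):
    smap = SeqStructMap({3: ("A", 101), 7: ("A", 105)})
    p = tmp_path / "map.tsv"
    smap.to_tsv(p)
    assert SeqStructMap.from_tsv(p).column_to_residue == smap.column_to_residue


def test_seqstructmap_injectivity_enforced():
    with pytest.raises(ValueError):
        SeqStructMap({1: ("A", 5), 2: ("A", 5)})


def test_align_map_fallback_recovers_identity_mapping(bundle_ensemble):
    from trpscan.structure import align_map_fallback

    models, _ = bundle_ensemble
    st = models[0]
    # a gapped alignment row spelling the structure's own sequence
    from Bio.Data.IUPACData import protein_letters_3to1
    seq = "".join(protein_letters_3to1[r.name.capitalize()]
                  for r in st.chains["A"])
    row = seq[:10] + "--" + seq[10:]
    smap = align_map_fallback(row, st, "A")
    nums = [r.author_number for r in st.chains["A"]]
    expected = {}
    k = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            expected[col] = ("A", nums[k])
            k += 1
    assert smap.column_to_residue == expected
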
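"""Pedigree/genomic relationship machinery against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from heatnorm.relationships import (
    GenotypeMatrix,
    Pedigree,
    build_A_inverse,
    build_G,
    build_H_inverse,
    extract_A22,
    inbreeding_coefficients,
    invert,
    qc_snps,
    tabular_A,
    RelationshipMatrix,
)
from conftest import recursive_A


class TestAInverse:
    def test_single_founder(self):
        ped = Pedigree.from_records([("x", "0", "0")])
        assert build_A_inverse(ped).dense() == pytest.approx(np.array([[1.0]]))

    def test_trio_closed_form(self, trio):
        expected = np.array(
            [[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]]
        )
        got = build_A_inverse(trio).dense()
        idx = [trio.code(a) for a in ("s", "d", "o")]
        assert got[np.ix_(idx, idx)] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_inverse_of_tabular_A_on_simulated_pedigrees(self, random_pedigree, seed):
        ped = random_pedigree(n_founders=20, n_generations=3, n_per_gen=50, seed=seed)
        assert len(ped) <= 200
        A = tabular_A(ped)
        Ainv = build_A_inverse(ped).dense()
        assert Ainv @ A == pytest.approx(np.eye(len(ped)), abs=1e-8)

    def test_tabular_matches_independent_recursion(self, random_pedigree):
        ped = random_pedigree(n_founders=8, n_generations=2, n_per_gen=10, seed=3)
        parents = {
            ped.ids[i]: (
                ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else None,
                ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else None,
            )
            for i in range(len(ped))
        }
        oracle = recursive_A(parents)
        A = tabular_A(ped)
        for x in ped.ids:
            for y in ped.ids:
                assert A[ped.code(x), ped.code(y)] == pytest.approx(oracle[x][y])

    def test_inbreeding_matches_tabular_diagonal(self, random_pedigree):
        ped = random_pedigree(n_founders=6, n_generations=4, n_per_gen=12, seed=7)
        F = inbreeding_coefficients(ped)
        assert F == pytest.approx(np.diag(tabular_A(ped)) - 1.0, abs=1e-10)
        assert F.max() > 0  # deep small pedigree must accumulate inbreeding

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree.from_records([("a", "b", "0"), ("b", "a", "0")])


class TestA22:
    def test_full_subset_is_A(self, trio):
        A22 = extract_A22(trio, list(trio.ids))
        assert A22.dense() == pytest.approx(tabular_A(trio))

    def test_two_founders_identity(self):
        ped = Pedigree.from_records([("a", "0", "0"), ("b", "0", "0")])
        assert extract_A22(ped, ["a", "b"]).dense() == pytest.approx(np.eye(2))

    def test_trio_sire_offspring(self, trio):
        A22 = extract_A22(trio, ["s", "o"])
        assert A22.dense() == pytest.approx(np.array([[1.0, 0.5], [0.5, 1.0]]))

    def test_subset_commutes(self, random_pedigree):
        ped = random_pedigree(seed=5)
        big = [ped.ids[i] for i in range(0, len(ped), 3)]
        small = big[::2]
        A_big = extract_A22(ped, big)
        A_small = extract_A22(ped, small)
        idx = [big.index(a) for a in small]
        assert A_small.dense() == pytest.approx(A_big.dense()[np.ix_(idx, idx)])

    def test_unknown_id_listed(self, trio):
        with pytest.raises(KeyError, match="ghost"):
            extract_A22(trio, ["s", "ghost"])


class TestQcSnps:
    def test_toy_filters(self, toy_genotypes):
        out, report = qc_snps(toy_genotypes, maf_min=0.2)
        # s2 on X; s1 monomorphic; s3 has freq 1/8 < 0.2; s0, s4 clean
        assert report == {"sex": 1, "mono": 1, "maf": 1, "retained": 2}
        assert list(out.snp_map["snp"]) == ["s0", "s4"]

    def test_clean_input_unchanged(self, toy_genotypes):
        clean = GenotypeMatrix(
            codes=toy_genotypes.codes[:, [0, 4]],
            ids=toy_genotypes.ids,
            snp_map=toy_genotypes.snp_map.iloc[[0, 4]].reset_index(drop=True),
        )
        out, report = qc_snps(clean)
        assert report == {"sex": 0, "mono": 0, "maf": 0, "retained": 2}
        assert np.array_equal(out.codes, clean.codes)

    def test_boundary_maf_retained(self):
        # 50 individuals, one heterozygote -> frequency exactly 0.01
        codes = np.zeros((50, 2), dtype=np.int8)
        codes[0, 0] = 1
        codes[:25, 1] = 1  # keep second SNP clearly polymorphic
        smap = pd.DataFrame(
            {"snp": ["a", "b"], "chrom": ["1", "1"], "pos": [1, 2],
             "counted_allele": ["A", "A"]}
        )
        geno = GenotypeMatrix(codes=codes, ids=[str(i) for i in range(50)], snp_map=smap)
        assert (geno.codes[:, 0] == 1).sum() == 1
        out, report = qc_snps(geno, maf_min=0.01)
        assert report["maf"] == 0 and report["retained"] == 2

    def test_idempotent(self, toy_genotypes):
        once, _ = qc_snps(toy_genotypes)
        twice, report = qc_snps(once)
        assert np.array_equal(once.codes, twice.codes)
        assert report["sex"] == report["mono"] == report["maf"] == 0


class TestG:
    def test_single_snp_hand_value(self):
        smap = pd.DataFrame(
            {"snp": ["s"], "chrom": ["1"], "pos": [1], "counted_allele": ["A"]}
        )
        geno = GenotypeMatrix(
            codes=np.array([[0], [2]], dtype=np.int8), ids=["a", "b"], snp_map=smap
        )
        A22 = RelationshipMatrix(values=np.eye(2), ids=["a", "b"], kind="A22")
        G = build_G(geno, A22, blend=0.0)
        assert G.dense() == pytest.approx(np.array([[2.0, -2.0], [-2.0, 2.0]]))

    def test_blend_fixed_point(self, toy_genotypes):
        keep, _ = qc_snps(toy_genotypes)
        A22_eq = build_G(
            keep,
            RelationshipMatrix(values=np.zeros((4, 4)), ids=keep.ids, kind="A22"),
            blend=0.0,
        )
        A22 = RelationshipMatrix(values=A22_eq.dense(), ids=keep.ids, kind="A22")
        for blend in (0.05, 0.5):
            G = build_G(keep, A22, blend=blend)
            assert G.dense() == pytest.approx(A22.dense())

    def test_mean_diagonal_near_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.5, size=100)
        codes = rng.binomial(2, p, size=(20, 100)).astype(np.int8)
        smap = pd.DataFrame(
            {"snp": [f"s{i}" for i in range(100)], "chrom": "1",
             "pos": np.arange(100), "counted_allele": "A"}
        )
        geno = GenotypeMatrix(codes=codes, ids=[str(i) for i in range(20)], snp_map=smap)
        A22 = RelationshipMatrix(values=np.eye(20), ids=geno.ids, kind="A22")
        G = build_G(geno, A22, blend=0.0)
        assert 0.8 <= np.diag(G.dense()).mean() <= 1.2

    def test_monomorphic_rejected(self):
        smap = pd.DataFrame(
            {"snp": ["s"], "chrom": ["1"], "pos": [1], "counted_allele": ["A"]}
        )
        geno = GenotypeMatrix(
            codes=np.array([[2], [2]], dtype=np.int8), ids=["a", "b"], snp_map=smap
        )
        A22 = RelationshipMatrix(values=np.eye(2), ids=["a", "b"], kind="A22")
        with pytest.raises(ValueError, match="monomorphic"):
            build_G(geno, A22)


class TestHInverse:
    def test_G_equals_A22_cancels(self, trio):
        Ainv = build_A_inverse(trio)
        A22 = extract_A22(trio, ["s", "o"])
        A22inv = invert(A22)
        Ginv = RelationshipMatrix(values=A22inv.dense(), ids=A22.ids, kind="G_inverse")
        idx = np.array([trio.code(a) for a in ("s", "o")])
        Hinv = build_H_inverse(Ainv, Ginv, A22inv, idx)
        assert Hinv.dense() == pytest.approx(Ainv.dense())

    def test_no_genotyped_animals(self, trio):
        Ainv = build_A_inverse(trio)
        empty = RelationshipMatrix(values=np.zeros((0, 0)), ids=[], kind="G_inverse")
        Hinv = build_H_inverse(Ainv, empty, empty, np.array([], dtype=int))
        assert Hinv.dense() == pytest.approx(Ainv.dense())

    def test_matches_dense_block_assembly(self, trio):
        rng = np.random.default_rng(4)
        Ainv = build_A_inverse(trio)
        A22 = extract_A22(trio, ["s", "o"])
        A22inv = invert(A22)
        M = rng.normal(size=(2, 2))
        Ginv = RelationshipMatrix(values=M @ M.T + np.eye(2), ids=A22.ids, kind="G_inverse")
        idx = np.array([trio.code(a) for a in ("s", "o")])
        Hinv = build_H_inverse(Ainv, Ginv, A22inv, idx)
        # independent oracle: dense scatter-add of the correction block
        expected = Ainv.dense().copy()
        delta = Ginv.dense() - A22inv.dense()
        for bi, i in enumerate(idx):
            for bj, j in enumerate(idx):
                expected[i, j] += delta[bi, bj]
        assert Hinv.dense() == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_pd(self, random_pedigree):
        ped = random_pedigree(n_founders=10, n_generations=2, n_per_gen=20, seed=9)
        assert len(ped) <= 100
        rng = np.random.default_rng(1)
        genotyped = [ped.ids[i] for i in rng.choice(len(ped), size=15, replace=False)]
        genotyped = sorted(genotyped, key=ped.code)
        p = rng.uniform(0.1, 0.5, size=60)
        codes = rng.binomial(2, p, size=(15, 60)).astype(np.int8)
        smap = pd.DataFrame(
            {"snp": [f"s{i}" for i in range(60)], "chrom": "1",
             "pos": np.arange(60), "counted_allele": "A"}
        )
        geno = GenotypeMatrix(codes=codes, ids=genotyped, snp_map=smap)
        A22 = extract_A22(ped, genotyped)
        G = build_G(geno, A22, blend=0.05)
        Hinv = build_H_inverse(
            build_A_inverse(ped), invert(G), invert(A22),
            np.array([ped.code(g) for g in genotyped]),
        )
        Hd = Hinv.dense()
        assert Hd == pytest.approx(Hd.T, abs=1e-8)
        H = np.linalg.inv(Hd)
        assert np.linalg.eigvalsh(0.5 * (H + H.T)).min() > 0


def test_relationship_matrix_npz_roundtrip(tmp_path, trio):
    Ainv = build_A_inverse(trio)
    path = tmp_path / "ainv.npz"
    Ainv.save(path)
    back = RelationshipMatrix.load(path)
    assert back.kind == "A_inverse"
    assert back.ids == Ainv.ids
    assert back.dense() == pytest.approx(Ainv.dense())


def test_pedigree_tsv_roundtrip(tmp_path, trio):
    from heatnorm.relationships import read_pedigree, write_pedigree

    path = tmp_path / "ped.tsv"
    write_pedigree(trio, path)
    back = read_pedigree(path)
    assert back.ids == trio.ids
    assert np.array_equal(back.sire, trio.sire)
    assert np.array_equal(back.dam, trio.dam)
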
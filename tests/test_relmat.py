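import numpy as np
import pytest

from xherit import (Pedigree, build_A, build_A_inverse, build_G_X,
                    build_G_auto, build_H_inverse, build_HX_inverse, build_S,
                    build_S_inverse, build_combined_grm, encode_dosage,
                    subset_and_invert, tune_and_blend)
from xherit.genotype_qc import allele_frequencies
from xherit.simdata import (SimConfig, drop_genotypes, gene_drop_covariance,
                            simulate_pedigree)
from conftest import make_genotypes


def _pos(ped, aid):
    return list(ped.ids).index(aid)


class TestA:
    def test_unrelated_founders_identity(self):
        ped = Pedigree.from_records([(f"f{k}", "0", "0", "f")
                                     for k in range(5)])
        assert np.array_equal(build_A(ped).dense(), np.eye(5))

    def test_full_sibs_half(self):
        ped = Pedigree.from_records([
            ("S", "0", "0", "m"), ("D", "0", "0", "f"),
            ("A", "S", "D", "f"), ("B", "S", "D", "m")])
        A = build_A(ped).dense()
        ia, ib = _pos(ped, "A"), _pos(ped, "B")
        assert A[ia, ib] == pytest.approx(0.5)
        assert A[ia, ia] == pytest.approx(1.0)

    def test_offspring_of_full_sibs_inbred(self):
        ped = Pedigree.from_records([
            ("S", "0", "0", "m"), ("D", "0", "0", "f"),
            ("A", "S", "D", "m"), ("B", "S", "D", "f"),
            ("I", "A", "B", "f")])
        A = build_A(ped).dense()
        assert A[_pos(ped, "I"), _pos(ped, "I")] == pytest.approx(1.25)

    def test_gene_dropping_oracle(self, eight_animal_pedigree):
        A = build_A(eight_animal_pedigree).dense()
        cov, se = gene_drop_covariance(eight_animal_pedigree, 0.3,
                                       200_000, seed=11, x_linked=False)
        assert np.all(np.abs(cov - A) <= 3.0 * np.maximum(se, 1e-12))


class TestAInverse:
    def test_single_founder(self):
        ped = Pedigree.from_records([("X", "0", "0", "m")])
        assert np.allclose(build_A_inverse(ped).dense(), [[1.0]])

    def test_trio_matches_dense_inverse(self, trio_pedigree):
        Ainv = build_A_inverse(trio_pedigree).dense()
        A = build_A(trio_pedigree).dense()
        assert np.abs(Ainv - np.linalg.inv(A)).max() < 1e-10

    def test_random_pedigree_inverse_identity(self):
        cfg = SimConfig(seed=13, n_founder_males=5, n_founder_females=30,
                        n_generations=2)
        ped = simulate_pedigree(cfg)
        A = build_A(ped).dense()
        Ainv = build_A_inverse(ped).dense()
        assert np.abs(Ainv @ A - np.eye(len(A))).max() < 1e-8


class TestS:
    def test_trio_values(self, trio_pedigree):
        S = build_S(trio_pedigree).dense()
        p = trio_pedigree
        M, F, D, O = (_pos(p, a) for a in "MFDO")
        assert S[D, M] == pytest.approx(0.5)
        assert S[D, F] == pytest.approx(0.5)
        assert S[D, D] == pytest.approx(1.0)
        assert S[O, F] == pytest.approx(0.5)
        assert S[O, M] == pytest.approx(0.0)
        assert S[O, O] == pytest.approx(0.5)
        assert S[D, O] == pytest.approx(0.25)

    def test_all_founders_diagonal_by_sex(self):
        ped = Pedigree.from_records([("m1", "0", "0", "m"),
                                     ("f1", "0", "0", "f"),
                                     ("m2", "0", "0", "m")])
        S = build_S(ped).dense()
        expect = np.diag([0.5 if s == "M" else 1.0 for s in ped.sex])
        assert np.array_equal(S, expect)

    def test_gene_dropping_oracle(self, eight_animal_pedigree):
        S = build_S(eight_animal_pedigree).dense()
        cov, se = gene_drop_covariance(eight_animal_pedigree, 0.3,
                                       200_000, seed=12, x_linked=True)
        assert np.all(np.abs(cov - S) <= 3.0 * np.maximum(se, 1e-12))

    def test_inverse_identity(self):
        cfg = SimConfig(seed=14, n_founder_males=4, n_founder_females=25,
                        n_generations=2)
        ped = simulate_pedigree(cfg)
        S = build_S(ped).dense()
        Sinv = build_S_inverse(ped).dense()
        assert np.abs(Sinv @ S - np.eye(len(S))).max() < 1e-8


class TestSubsetAndInvert:
    def test_full_subset_is_plain_inverse(self, trio_pedigree):
        A = build_A(trio_pedigree)
        sub, subinv = subset_and_invert(A, list(A.ids))
        assert np.abs(subinv.dense() - np.linalg.inv(A.dense())).max() < 1e-9

    def test_unrelated_founder_subset_identity(self):
        ped = Pedigree.from_records(
            [(f"f{k}", "0", "0", "f") for k in range(6)])
        A = build_A(ped)
        sub, subinv = subset_and_invert(A, ["f1", "f3"])
        assert np.array_equal(sub.dense(), np.eye(2))
        assert np.array_equal(subinv.dense(), np.eye(2))

    def test_random_subset_inverse(self):
        cfg = SimConfig(seed=15, n_founder_males=5, n_founder_females=40,
                        n_generations=2)
        ped = simulate_pedigree(cfg)
        A = build_A(ped)
        rng = np.random.default_rng(0)
        ids = list(rng.choice(ped.ids, size=100, replace=False))
        sub, subinv = subset_and_invert(A, ids)
        assert np.abs(sub.dense() @ subinv.dense()
                      - np.eye(100)).max() < 1e-8


class TestGenomic:
    def test_g_auto_single_snp_hand_value(self):
        # Z = (-1, 1) at p = 0.5 -> ZZ'/(2*0.25) = [[2,-2],[-2,2]]
        g = make_genotypes([[0.0], [2.0]], ["F", "F"], coding="vc")
        G = build_G_auto(g, np.array([0.5])).dense()
        assert G == pytest.approx(np.array([[2.0, -2.0], [-2.0, 2.0]]))

    def test_duplicated_animal_clone_symmetry(self):
        rng = np.random.default_rng(2)
        row = rng.integers(0, 3, size=50).astype(float)
        g = make_genotypes(np.vstack([row, row]), ["F", "F"], coding="vc")
        G = build_G_auto(g).dense()
        assert G[0, 0] == pytest.approx(G[1, 1])
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_unrelated_panel_mean_diagonal_one(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.5, size=2000)
        calls = rng.binomial(2, p, size=(200, 2000)).astype(float)
        g = make_genotypes(calls, ["F"] * 200, coding="vc")
        G = build_G_auto(g, p).dense()
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)

    def test_g_x_single_locus_arithmetic(self):
        g = make_genotypes([[2.0], [1.0]], ["F", "M"], is_x=[True],
                           coding="vc")
        G = build_G_X(g, np.array([0.5])).dense()
        assert G[0, 0] == pytest.approx(2.0)   # female Z=1, 1/(2*0.25)
        assert G[1, 1] == pytest.approx(0.5)   # male Z=0.5, 0.25/0.5

    def test_g_x_sex_specific_expected_diagonals(self):
        rng = np.random.default_rng(4)
        m = 2000
        p = rng.uniform(0.1, 0.5, size=m)
        nf, nm = 100, 100
        fem = rng.binomial(2, p, size=(nf, m)).astype(float)
        mal = rng.binomial(1, p, size=(nm, m)).astype(float)
        g = make_genotypes(np.vstack([fem, mal]), ["F"] * nf + ["M"] * nm,
                           is_x=[True] * m, coding="vc")
        G = build_G_X(g, p).dense()
        d = np.diag(G)
        assert np.mean(d[:nf]) == pytest.approx(1.0, abs=0.05)
        assert np.mean(d[nf:]) == pytest.approx(0.5, abs=0.05)

    def test_e_g_auto_close_to_a22(self):
        cfg = SimConfig(seed=16, n_founder_males=6, n_founder_females=40,
                        n_generations=2, n_auto_snps=5000, n_x_snps=10,
                        n_causal_auto=100, n_causal_x=0)
        ped = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        gvc = encode_dosage(geno, "vc")
        p = np.asarray(geno.meta["founder_freq_auto"] +
                       geno.meta["founder_freq_x"])
        G = build_G_auto(gvc, p).dense()
        A22 = build_A(ped).dense()
        assert np.mean(np.abs(G - A22)) < 0.05


class TestTuneAndBlend:
    def test_fixed_point(self, trio_pedigree):
        A = build_A(trio_pedigree)
        A22, _ = subset_and_invert(A, list(A.ids))
        G = build_G_auto(
            make_genotypes(np.random.default_rng(1).integers(
                0, 3, size=(4, 200)).astype(float),
                ["M", "F", "F", "M"], coding="vc"))
        G.ids = A22.ids.copy()
        out = tune_and_blend(A22, A22)
        assert np.abs(out.dense() - A22.dense()).max() < 1e-12
        assert out.meta["a"] == pytest.approx(0.0, abs=1e-12)
        assert out.meta["b"] == pytest.approx(1.0)

    def test_mean_diagonal_matches_target(self):
        rng = np.random.default_rng(6)
        cfg = SimConfig(seed=17, n_founder_males=5, n_founder_females=25,
                        n_generations=2, n_auto_snps=800, n_x_snps=10,
                        n_causal_auto=50, n_causal_x=0)
        ped = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        gvc = encode_dosage(geno, "vc")
        gids = list(gvc.ids)
        A22, _ = subset_and_invert(build_A(ped), gids)
        G = build_G_auto(gvc)
        out = tune_and_blend(G, A22)
        assert (np.mean(np.diag(out.dense()))
                == pytest.approx(np.mean(np.diag(A22.dense())), abs=1e-10))
        assert np.linalg.eigvalsh(out.dense())[0] > 0

    def test_alpha_one_pure_tuned(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, size=(10, 300)).astype(float)
        g = make_genotypes(calls, ["F"] * 10, coding="vc")
        G = build_G_auto(g)
        P = build_A(Pedigree.from_records(
            [(f"a{i}", "0", "0", "f") for i in range(10)]))
        out = tune_and_blend(G, P, alpha=1.0, beta=0.0)
        a, b = out.meta["a"], out.meta["b"]
        assert np.abs(out.dense() - (a + b * G.dense())).max() < 1e-12

    def test_constant_g_rejected(self):
        P = build_A(Pedigree.from_records(
            [(f"a{i}", "0", "0", "f") for i in range(3)]))
        from xherit.relmat import RelationshipMatrix
        G = RelationshipMatrix(P.ids.copy(), np.ones((3, 3)), "Gauto")
        with pytest.raises(ValueError, match="constant"):
            tune_and_blend(G, P)


class TestHInverse:
    def test_reduces_to_ainv_when_gstar_is_a22(self):
        cfg = SimConfig(seed=18, n_founder_males=4, n_founder_females=20,
                        n_generations=2)
        ped = simulate_pedigree(cfg)
        keep = ~ped.is_founder()
        gids = list(ped.ids[keep])
        A = build_A(ped)
        Ainv = build_A_inverse(ped)
        A22, A22inv = subset_and_invert(A, gids)
        H = build_H_inverse(Ainv, A22inv, A22inv)
        assert np.abs(H.dense() - Ainv.dense()).max() < 1e-12

        S = build_S(ped)
        Sinv = build_S_inverse(ped)
        S22, S22inv = subset_and_invert(S, gids)
        HX = build_HX_inverse(Sinv, S22inv, S22inv)
        assert np.abs(HX.dense() - Sinv.dense()).max() < 1e-12

    def test_no_genotyped_animals(self, trio_pedigree):
        from xherit.relmat import RelationshipMatrix
        Ainv = build_A_inverse(trio_pedigree)
        empty = RelationshipMatrix(np.array([], object),
                                   np.zeros((0, 0)), "A22inv")
        emptyg = RelationshipMatrix(np.array([], object),
                                    np.zeros((0, 0)), "Gblend")
        H = build_H_inverse(Ainv, empty, emptyg)
        assert np.abs(H.dense() - Ainv.dense()).max() == 0.0

    def test_dense_h_psd_and_matches_block_oracle(self):
        cfg = SimConfig(seed=19, n_founder_males=5, n_founder_females=15,
                        n_generations=1, n_auto_snps=500, n_x_snps=10,
                        n_causal_auto=50, n_causal_x=0)
        ped = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        keep = ~ped.is_founder()
        gvc = encode_dosage(geno.subset(animal_mask=keep), "vc")
        gids = list(gvc.ids)
        A = build_A(ped)
        Ainv = build_A_inverse(ped)
        A22, A22inv = subset_and_invert(A, gids)
        G = tune_and_blend(build_G_auto(gvc), A22)
        _, Ginv = subset_and_invert(G, gids, "Gblend", "Gblend")
        H = build_H_inverse(Ainv, A22inv, Ginv)
        # block-formula oracle on the dense H recovered from its inverse
        Hd = np.linalg.inv(H.dense())
        w = np.linalg.eigvalsh(Hd)
        assert w.min() > 0
        idx = H.index_of(gids)
        Ad = A.dense()
        A12 = np.delete(Ad, idx, axis=0)[:, idx]
        A11 = np.delete(np.delete(Ad, idx, axis=0), idx, axis=1)
        A22d = A22.dense()
        Gd = G.dense()
        T = A12 @ np.linalg.inv(A22d)
        H22 = Gd
        H12 = T @ Gd
        H11 = A11 + T @ (Gd - A22d) @ T.T
        assert np.abs(Hd[np.ix_(idx, idx)] - H22).max() < 1e-6
        other = [i for i in range(len(Ad)) if i not in set(idx)]
        assert np.abs(Hd[np.ix_(other, idx)] - H12).max() < 1e-6
        assert np.abs(Hd[np.ix_(other, other)] - H11).max() < 1e-6


class TestCombinedGrm:
    def test_autosomes_only_reduces_to_g_auto(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(12, 100)).astype(float)
        g = make_genotypes(calls, ["F"] * 12, coding="gwas")
        grm = build_combined_grm(g).dense()
        gauto = build_G_auto(g).dense()
        assert np.abs(grm - gauto).max() < 1e-12

    def test_x_only_all_female_equals_g_x(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(12, 100)).astype(float)
        g_gwas = make_genotypes(calls, ["F"] * 12, is_x=[True] * 100,
                                coding="gwas")
        g_vc = make_genotypes(calls.copy(), ["F"] * 12, is_x=[True] * 100,
                              coding="vc")
        p = allele_frequencies(g_vc)
        assert np.abs(build_combined_grm(g_gwas, p).dense()
                      - build_G_X(g_vc, p).dense()).max() < 1e-12

    def test_mixed_panel_mean_diagonal_near_one(self):
        rng = np.random.default_rng(10)
        m = 3000
        p = rng.uniform(0.1, 0.5, size=m)
        is_x = np.arange(m) >= 2400
        sex = ["M" if i % 2 else "F" for i in range(150)]
        calls = rng.binomial(2, p, size=(150, m)).astype(float)
        for i, s in enumerate(sex):   # males: X dosage 0/2
            if s == "M":
                calls[i, is_x] = 2.0 * rng.binomial(1, p[is_x])
        g = make_genotypes(calls, sex, is_x=is_x, coding="gwas")
        grm = build_combined_grm(g, p).dense()
        assert abs(np.mean(np.diag(grm)) - 1.0) < 0.1
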
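import math

import numpy as np
import pandas as pd
import pytest

from xherit import (ModelSpec, Pedigree, PhenotypeTable, TraitMeta,
                    annotate_windows, build_A_inverse, build_combined_grm,
                    deregress, mlma, pedigree_blup, read_gene_annotation,
                    reml_grm, significance_thresholds)
from xherit.gwas import EbvTable, _information_contents, dense_gls_oracle
from xherit.data_io import GeneSet
from xherit.simdata import (SimConfig, drop_genotypes, simulate_pedigree,
                            simulate_traits)
from conftest import make_genotypes


class TestPedigreeBlup:
    def test_single_own_record_reliability_equals_h2(self):
        rng = np.random.default_rng(0)
        ped = Pedigree.from_records([(f"u{i}", "0", "0", "f")
                                     for i in range(30)])
        data = PhenotypeTable(
            pd.DataFrame({"id": ped.ids, "t": rng.standard_normal(30)}),
            TraitMeta("t"))
        ebv = pedigree_blup(ModelSpec(trait="t", intercept=False), data,
                            build_A_inverse(ped), 0.5, 0.5, ped=ped)
        assert np.allclose(ebv.data["reliability"], 0.5)

    def test_animal_without_information(self):
        rng = np.random.default_rng(1)
        ped = Pedigree.from_records(
            [(f"u{i}", "0", "0", "f") for i in range(10)]
            + [("GHOST", "0", "0", "m")])
        data = PhenotypeTable(
            pd.DataFrame({"id": [f"u{i}" for i in range(10)],
                          "t": rng.standard_normal(10)}), TraitMeta("t"))
        ebv = pedigree_blup(ModelSpec(trait="t", intercept=False), data,
                            build_A_inverse(ped), 0.4, 0.6, ped=ped)
        ghost = ebv.data.set_index("id").loc["GHOST"]
        assert ghost["ebv"] == pytest.approx(0.0)
        assert ghost["reliability"] == pytest.approx(0.0)

    def test_progeny_test_closed_form(self):
        h2, nprog = 0.25, 50
        rng = np.random.default_rng(2)
        recs = ([("SIRE", "0", "0", "m")]
                + [(f"d{i}", "0", "0", "f") for i in range(nprog)]
                + [(f"o{i}", "SIRE", f"d{i}", "f") for i in range(nprog)])
        ped = Pedigree.from_records(recs)
        data = PhenotypeTable(
            pd.DataFrame({"id": [f"o{i}" for i in range(nprog)],
                          "t": rng.standard_normal(nprog)}), TraitMeta("t"))
        ebv = pedigree_blup(ModelSpec(trait="t", intercept=False), data,
                            build_A_inverse(ped), h2, 1 - h2, ped=ped)
        r2 = ebv.data.set_index("id").loc["SIRE", "reliability"]
        assert r2 == pytest.approx(nprog / (nprog + (4 - h2) / h2), abs=0.02)


class TestDeregression:
    def test_pa_free_reduction(self):
        df = pd.DataFrame({"id": ["x"], "ebv": [2.0], "pev": [0.2],
                           "reliability": [0.6], "sire": ["0"], "dam": ["0"]})
        dr = deregress(EbvTable(df, 0.5, 0.5), h2=0.5)
        assert dr.data["debv"].iloc[0] == pytest.approx(2.0 / 0.6)
        assert dr.data["reliability"].iloc[0] == pytest.approx(0.6)

    def test_zero_ebv_gives_zero_debv(self):
        df = pd.DataFrame({"id": ["x"], "ebv": [0.0], "pev": [0.2],
                           "reliability": [0.6], "sire": ["0"], "dam": ["0"]})
        dr = deregress(EbvTable(df, 0.5, 0.5), h2=0.5)
        assert dr.data["debv"].iloc[0] == 0.0

    @pytest.mark.parametrize("r2_pa,r2_i,lam", [
        (0.2, 0.55, 1.0), (0.1, 0.3, 3.0), (0.4, 0.8, 0.5)])
    def test_two_by_two_system_consistency(self, r2_pa, r2_i, lam):
        """The closed-form information contents reproduce both reliabilities
        when plugged back into the 2x2 coefficient matrix (numeric check)."""
        c_pa, c_i = _information_contents(r2_pa, r2_i, lam)
        C = np.array([[c_pa + 4 * lam, -2 * lam], [-2 * lam, c_i + 2 * lam]])
        Ci = np.linalg.inv(C)
        assert 0.5 - lam * Ci[0, 0] == pytest.approx(r2_pa, abs=1e-10)
        assert 1.0 - lam * Ci[1, 1] == pytest.approx(r2_i, abs=1e-10)

    def test_no_own_information_excluded(self):
        df = pd.DataFrame({
            "id": ["s", "d", "x"], "ebv": [1.0, -1.0, 0.1],
            "pev": [0.1, 0.1, 0.9],
            "reliability": [0.9, 0.9, 0.3], "sire": ["0", "0", "s"],
            "dam": ["0", "0", "d"]})
        dr = deregress(EbvTable(df, 1.0, 1.0), h2=0.5)
        assert "x" in set(dr.excluded["id"])
        assert dr.excluded.set_index("id").loc["x", "reason"] \
            == "no own information"

    def test_simulation_slopes(self):
        """dEBV tracks the true BV with slope ~1 and its error does not
        load on the true parent average (the PA has been removed)."""
        cfg = SimConfig(seed=21, var_x=0.0, n_causal_x=0, var_auto=0.4,
                        var_e=0.6, n_founder_males=20, n_founder_females=150,
                        n_generations=3, male_x_dosage="additive")
        ped = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        pheno, truth = simulate_traits(geno, ped, cfg)
        ebv = pedigree_blup(ModelSpec(trait="trait", fixed=["CG"]), pheno,
                            build_A_inverse(ped), 0.4, 0.6, ped=ped)
        dr = deregress(ebv, h2=0.4)
        tb = dict(zip(truth.ids, truth.tbv_total))
        sire = dict(zip(ped.ids, ped.sire))
        dam = dict(zip(ped.ids, ped.dam))
        d = dr.data.copy()
        d["tbv"] = d["id"].map(tb)
        d["pa_true"] = d["id"].map(
            lambda i: 0.5 * (tb.get(sire[i], 0.0) + tb.get(dam[i], 0.0)))
        nonf = d[~d["id"].map(
            lambda i: sire[i] == "0" and dam[i] == "0")]
        slope_tbv = np.polyfit(d["tbv"], d["debv"], 1)[0]
        slope_pa = np.polyfit(nonf["pa_true"],
                              nonf["debv"] - nonf["tbv"], 1)[0]
        assert slope_tbv == pytest.approx(1.0, abs=0.1)
        assert slope_pa == pytest.approx(0.0, abs=0.1)


class TestRemlGrm:
    def test_recovery_at_n_1000(self):
        """h2 = 0.5 recovered on pedigreed GRMs of ~1,000 animals; the mean
        over three seeds stays within one standard error (~0.08)."""
        from xherit import encode_dosage
        from xherit.simdata import drop_genotypes, simulate_pedigree

        est = []
        for seed in (3, 4, 5):
            cfg = SimConfig(seed=seed, n_founder_males=15,
                            n_founder_females=170, n_generations=3,
                            n_auto_snps=800, n_x_snps=200,
                            n_causal_auto=200, n_causal_x=50)
            ped = simulate_pedigree(cfg)
            geno = drop_genotypes(ped, cfg)
            gg = encode_dosage(geno.subset(animal_mask=~ped.is_founder()),
                               "gwas")
            n = gg.n_animals
            grm = build_combined_grm(gg)
            w, U = np.linalg.eigh(grm.dense())
            L = U * np.sqrt(np.clip(w, 0, None))
            rng = np.random.default_rng(seed + 50)
            y = (L @ rng.standard_normal(n) * math.sqrt(0.5)
                 + rng.standard_normal(n) * math.sqrt(0.5))
            _, _, info = reml_grm(y, np.ones((n, 1)), grm)
            est.append(info["h2"])
        assert np.mean(est) == pytest.approx(0.5, abs=0.08)

    def test_permuted_phenotype_near_null(self):
        rng = np.random.default_rng(4)
        n, m = 300, 800
        calls = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        g = make_genotypes(calls, ["F"] * n, coding="gwas")
        grm = build_combined_grm(g)
        y = rng.standard_normal(n)
        s2g, s2e, info = reml_grm(y, np.ones((n, 1)), grm)
        assert info["h2"] < 0.15


class TestMlma:
    def test_matches_dense_gls_oracle(self):
        rng = np.random.default_rng(5)
        n, m = 120, 80
        calls = rng.integers(0, 3, size=(n, m)).astype(float)
        g = make_genotypes(calls, ["F"] * n, coding="gwas")
        grm = build_combined_grm(g)
        V = 0.4 * grm.dense() + 0.6 * np.eye(n)
        y = rng.multivariate_normal(np.zeros(n), V)
        cov = rng.standard_normal(n)
        res = mlma(y, cov, g, grm, (0.4, 0.6)).data
        for j in range(m):
            b, se = dense_gls_oracle(y, cov, calls[:, j], V)
            assert abs(res["beta"][j] - b) < 1e-8
            assert abs(res["se"][j] - se) < 1e-8

    def test_large_effect_causal_snp_is_top_hit(self):
        for seed in (6, 7, 8):
            rng = np.random.default_rng(seed)
            n, m = 300, 200
            p = rng.uniform(0.2, 0.5, size=m)
            calls = rng.binomial(2, p, size=(n, m)).astype(float)
            g = make_genotypes(calls, ["F"] * n, coding="gwas")
            grm = build_combined_grm(g, p)
            K = grm.dense()
            L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
            poly = L @ rng.standard_normal(n) * 0.5
            y = poly + 1.0 * calls[:, 17] + rng.standard_normal(n) * 0.7
            s2g, s2e, _ = reml_grm(y, np.ones((n, 1)), grm)
            res = mlma(y, None, g, grm, (max(s2g, 1e-6), s2e)).data
            assert res["p"].idxmin() == 17

    def test_monomorphic_snp_flagged_p_one(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(60, 5)).astype(float)
        calls[:, 2] = 1.0
        g = make_genotypes(calls, ["F"] * 60, coding="gwas")
        grm = build_combined_grm(g)
        res = mlma(rng.standard_normal(60), None, g, grm, (0.2, 0.8)).data
        assert res.loc[2, "monomorphic"]
        assert res.loc[2, "p"] == 1.0


class TestThresholds:
    def test_worked_arithmetic(self):
        spec = significance_thresholds({"1": 85.0}, ne=80)
        assert spec.me["1"] == pytest.approx(1541.13, abs=0.01)
        assert spec.threshold["1"] == pytest.approx(4.489, abs=0.001)
        spec1 = significance_thresholds({"1": 1.0}, ne=80)
        assert spec1.me["1"] == pytest.approx(36.51, abs=0.01)
        assert spec1.threshold["1"] == pytest.approx(2.863, abs=0.001)

    def test_monotone_in_length(self):
        a = significance_thresholds({"1": 50.0})
        b = significance_thresholds({"1": 100.0})
        assert b.threshold["1"] > a.threshold["1"]

    def test_equal_lengths_average_equals_single(self):
        multi = significance_thresholds({str(k): 80.0 for k in range(1, 11)})
        single = significance_thresholds({"1": 80.0})
        assert multi.average == pytest.approx(single.threshold["1"])

    def test_default_assembly_average_matches_published_value(self):
        spec = significance_thresholds(ne=80, p0=0.05)
        assert spec.average == pytest.approx(4.6, abs=0.15)

    def test_degenerate_length_errors(self):
        with pytest.raises(ValueError):
            significance_thresholds({"1": 0.01}, ne=80)


class TestAnnotation:
    def _genes(self, rows):
        return GeneSet(pd.DataFrame(
            rows, columns=["id", "name", "chrom", "start", "end", "strand",
                           "biotype"]))

    def _hits(self, pos, chrom="1"):
        return pd.DataFrame({"snp": [f"s{p}" for p in pos],
                             "chrom": chrom, "pos": pos})

    def test_overlap_reported(self):
        genes = self._genes([("g1", "g1", "1", 1_400_000, 1_600_000, "+",
                              "protein_coding")])
        ann = annotate_windows(self._hits([1_000_000]), genes)
        assert len(ann) == 1
        assert ann.loc[0, "distance"] == 1_400_000 - 1_500_000 + 500_000

    def test_window_clipped_at_one(self):
        genes = self._genes([("g1", "g1", "1", 5, 10, "+", "misc")])
        ann = annotate_windows(self._hits([200_000]), genes)
        assert ann.loc[0, "win_lo"] == 1
        assert ann.loc[0, "win_hi"] == 700_000

    def test_inclusive_boundary(self):
        inside = self._genes([("g1", "g1", "1", 1_500_000, 1_600_000, "+",
                               "x")])
        outside = self._genes([("g2", "g2", "1", 1_500_001, 1_600_000, "+",
                                "x")])
        assert len(annotate_windows(self._hits([1_000_000]), inside)) == 1
        assert len(annotate_windows(self._hits([1_000_000]), outside)) == 0

    def test_dialect_invariance(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("1\t1399999\t1600000\tg1\t.\t+\tprotein_coding\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\n1\tsrc\tgene\t1400000\t1600000\t.\t"
                       "+\t.\tID=g1;biotype=protein_coding\n")
        hits = self._hits([1_000_000])
        n_bed = len(annotate_windows(hits, read_gene_annotation(bed)))
        n_gff = len(annotate_windows(hits, read_gene_annotation(gff)))
        assert n_bed == n_gff == 1
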
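"""Deregressed-EBV GWAS with Me-based thresholds and gene-window annotation.

Simulates a herd with X-linked causal variants, computes pedigree EBVs,
deregresses them, runs MLMA on the combined autosome + X GRM (males 0/2 on
X: full dosage compensation), applies chromosome-wise thresholds from
Me = 2NeL/ln(NeL), and annotates significant SNPs with genes within
+-500 kb.
"""
import numpy as np

from xherit import (ModelSpec, annotate_windows, apply_thresholds,
                    build_A_inverse, build_combined_grm, deregress,
                    encode_dosage, mlma, pedigree_blup, reml_grm,
                    significance_thresholds)
from xherit.data_io import GeneSet
from xherit.simdata import (SimConfig, drop_genotypes, simulate_pedigree,
                            simulate_traits, synthetic_genes)

cfg = SimConfig(seed=5, n_causal_auto=20, n_causal_x=8,
                var_auto=0.35, var_x=0.15, var_e=0.50)
ped = simulate_pedigree(cfg)
geno = drop_genotypes(ped, cfg)
pheno, truth = simulate_traits(geno, ped, cfg)

ebv = pedigree_blup(ModelSpec(trait="trait", fixed=["CG"]), pheno,
                    build_A_inverse(ped), cfg.var_auto + cfg.var_x,
                    cfg.var_e, ped=ped)
debv = deregress(ebv, h2=(cfg.var_auto + cfg.var_x))

gg = encode_dosage(geno.subset(animal_mask=~ped.is_founder()), "gwas")
have = debv.data[debv.data["id"].isin(set(gg.ids))]
gg = gg.select_animals(have["id"])
grm = build_combined_grm(gg)
y = have["debv"].to_numpy(float)
s2g, s2e, info = reml_grm(y, np.ones((len(y), 1)), grm)
res = mlma(y, None, gg, grm, (s2g, s2e))

lengths = {str(c): float(np.nanmax(gg.pos[gg.chrom == c]) / 1e6)
           for c in np.unique(gg.chrom)}
thr = significance_thresholds(lengths, ne=80, p0=0.05)
res = apply_thresholds(res, thr)

genes = GeneSet(synthetic_genes(geno, seed=cfg.seed + 3))
sig = res.data[res.data["significant"]]
ann = annotate_windows(sig, genes)

print(f"GRM variance split: s2_g={s2g:.3f} s2_e={s2e:.3f} (h2={info['h2']:.2f})")
print(f"average chromosome-wise threshold: {thr.average:.2f} (-log10 scale)")
print(f"significant SNPs: {len(sig)} of {len(res.data)} "
      f"({(sig['chrom'] == 'X').sum()} on X)")
print(f"genes inside +-500 kb of significant SNPs: {ann['gene_id'].nunique()}")
hits_x = set(sig["snp"]) & set(truth.causal_x)
print(f"of the {len(truth.causal_x)} X-linked causal SNPs, "
      f"{len(hits_x)} reached chromosome-wise significance")
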
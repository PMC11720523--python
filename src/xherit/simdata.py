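"""Synthetic pedigreed populations with autosomal and X-linked architecture.

Discrete generations, random mating, biallelic SNPs without linkage.
X transmission follows the biology the relationship matrices assume: a son
receives his single X allele from his dam; a daughter receives her sire's
X allele plus one of her dam's two.  Traits are polygenic with separate
autosomal and X variance targets, contemporary-group structure, an age
covariate (linear + quadratic), and optional ordinal thresholding of the
latent value.

The same machinery provides the gene-dropping Monte-Carlo oracle used to
validate the pedigree relationship recursions (A and S).
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (FEMALE, MALE, Pedigree, PhenotypeTable, TraitMeta,
                      UNKNOWN, write_genotypes, write_pedigree)
from .genotype_qc import GenotypeSet
from .relmat import build_A_inverse, build_S_inverse

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults describe a three-generation herd of ~1,800 animals with ~1,500
    genotyped non-founders, moderate marker panels, and the variance targets
    (0.30 autosomal, 0.10 X, 0.60 residual) used throughout the recovery
    studies.
    """

    seed: int
    n_founder_males: int = 25
    n_founder_females: int = 250
    n_generations: int = 3
    offspring_per_dam: int = 2
    sex_ratio: float = 0.5

    n_auto_snps: int = 1000
    n_x_snps: int = 300
    n_auto_chroms: int = 5
    founder_freq_range: tuple = (0.05, 0.5)
    snp_spacing_bp: int = 100_000

    n_causal_auto: int = 300
    n_causal_x: int = 100
    var_auto: float = 0.30
    var_x: float = 0.10
    var_e: float = 0.60
    male_x_dosage: str = "compensated"   # or "additive"

    trait_type: str = "continuous"       # or "ordinal"
    n_categories: int = 2
    thresholds: tuple | None = None      # latent-scale cut points

    n_cg: int = 20
    var_cg: float = 0.25
    n_gmand: int = 10
    var_gmand: float = 0.0
    idap_mean: float = 450.0
    idap_sd: float = 30.0
    beta_idap: float = 0.01
    beta_idap2: float = -1e-4

    genotyped: str = "nonfounders"       # or "all"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.var_auto, self.var_x, self.var_e) < 0:
            raise ValueError("variance targets must be >= 0")
        if self.n_causal_auto > self.n_auto_snps:
            raise ValueError("more autosomal causal SNPs than SNPs")
        if self.n_causal_x > self.n_x_snps:
            raise ValueError("more X causal SNPs than SNPs")
        if self.male_x_dosage not in ("compensated", "additive"):
            raise ValueError("male_x_dosage must be compensated|additive")


@dataclass
class TruthSet:
    """Everything the generator knows that an analyst would not."""

    ids: list
    tbv_auto: np.ndarray
    tbv_x: np.ndarray
    causal_auto: list
    causal_x: list
    effects_auto: np.ndarray
    effects_x: np.ndarray
    realized: dict
    thresholds: list | None = None
    cg_effects: dict | None = None

    @property
    def tbv_total(self) -> np.ndarray:
        return self.tbv_auto + self.tbv_x

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "ids": list(self.ids),
                "tbv_auto": self.tbv_auto.tolist(),
                "tbv_x": self.tbv_x.tolist(),
                "causal_auto": list(self.causal_auto),
                "causal_x": list(self.causal_x),
                "effects_auto": self.effects_auto.tolist(),
                "effects_x": self.effects_x.tolist(),
                "realized": self.realized,
                "thresholds": self.thresholds,
            }, fh)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete non-overlapping generations with random mating."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    males = [f"G0M{k:04d}" for k in range(cfg.n_founder_males)]
    females = [f"G0F{k:04d}" for k in range(cfg.n_founder_females)]
    for m in males:
        records.append((m, UNKNOWN, UNKNOWN, MALE))
    for f in females:
        records.append((f, UNKNOWN, UNKNOWN, FEMALE))

    for g in range(1, cfg.n_generations + 1):
        if not males or not females:
            raise RuntimeError(
                f"population extinct at generation {g}; "
                "increase founder counts or offspring per dam")
        new_m, new_f = [], []
        k = 0
        for dam in females:
            for _ in range(cfg.offspring_per_dam):
                sire = males[rng.integers(len(males))]
                sex = MALE if rng.uniform() < cfg.sex_ratio else FEMALE
                cid = f"G{g}{'M' if sex == MALE else 'F'}{k:04d}"
                k += 1
                records.append((cid, sire, dam, sex))
                (new_m if sex == MALE else new_f).append(cid)
        males, females = new_m, new_f
    return Pedigree.from_records(records)


def generation_of(ped: Pedigree) -> np.ndarray:
    """Generation index parsed from the generator's id scheme."""
    return np.array([int(str(i)[1:].split("M")[0].split("F")[0])
                     for i in ped.ids])


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _drop_alleles(ped: Pedigree, p: np.ndarray, rng: np.random.Generator,
                  x_linked: bool) -> np.ndarray:
    """Drop one biallelic locus per column of ``p`` through the pedigree.

    Returns gene content (allele-B count) of shape (n_animals, n_loci):
    autosomal 0/1/2 everywhere; X-linked males 0/1.  Vectorized over loci,
    so a single call with 200,000 columns is the Monte-Carlo oracle.
    """
    n = len(ped)
    m = len(p)
    s, d = ped.parent_indices()
    male = ped.sex == MALE
    pat = np.zeros((n, m), dtype=np.int8)   # allele from sire (females on X)
    mat = np.zeros((n, m), dtype=np.int8)   # allele from dam
    for i in range(n):
        si, di = s[i], d[i]
        if di < 0:
            mat[i] = rng.uniform(size=m) < p
        else:
            pick = rng.uniform(size=m) < 0.5
            if x_linked:
                # dam transmits one of her two X alleles
                mat[i] = np.where(pick, pat[di], mat[di])
            else:
                mat[i] = np.where(pick, pat[di], mat[di])
        if x_linked and male[i]:
            pat[i] = 0                       # males carry no paternal X
            continue
        if si < 0:
            pat[i] = rng.uniform(size=m) < p
        else:
            if x_linked:
                pat[i] = mat[si]             # sire passes his single X
            else:
                pick = rng.uniform(size=m) < 0.5
                pat[i] = np.where(pick, pat[si], mat[si])
    content = mat.astype(np.int16)
    if x_linked:
        content[~male] += pat[~male]
    else:
        content += pat
    return content


def gene_drop_covariance(ped: Pedigree, p: float, n_rep: int,
                         seed: int, x_linked: bool
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo relationship estimate from independent locus replicates.

    Drops ``n_rep`` independent loci at founder frequency ``p`` and returns
    (Cov(content_i, content_j) / (2 p (1-p)), entrywise MC standard error on
    the same scale).  This is the independent oracle for A (autosomal) and
    S (X-linked).
    """
    rng = np.random.default_rng(seed)
    content = _drop_alleles(ped, np.full(n_rep, p), rng, x_linked)
    X = content.astype(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    scale = 2.0 * p * (1.0 - p)
    cov = (Xc @ Xc.T) / (n_rep - 1) / scale
    # SE of each covariance entry from the spread of per-replicate products
    prod_sq = (Xc ** 2) @ (Xc ** 2).T / (n_rep - 1)
    var_prod = prod_sq - ((Xc @ Xc.T) / (n_rep - 1)) ** 2
    se = np.sqrt(np.clip(var_prod, 0.0, None) / n_rep) / scale
    return cov, se


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def drop_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeSet:
    """Drop all SNPs (unlinked) through the pedigree; raw/vc coding.

    Autosomal dosages 0/1/2; X dosages 0/1 for males, 0/1/2 for females.
    Founder frequencies are drawn per SNP from ``cfg.founder_freq_range``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.founder_freq_range
    p_auto = rng.uniform(lo, hi, size=cfg.n_auto_snps)
    p_x = rng.uniform(lo, hi, size=cfg.n_x_snps)

    auto = _drop_alleles(ped, p_auto, rng, x_linked=False)
    xcon = _drop_alleles(ped, p_x, rng, x_linked=True)
    calls = np.hstack([auto, xcon]).astype(float)

    per = max(1, math.ceil(cfg.n_auto_snps / cfg.n_auto_chroms))
    chroms = [str(1 + k // per) for k in range(cfg.n_auto_snps)]
    pos_a = [(k % per + 1) * cfg.snp_spacing_bp for k in range(cfg.n_auto_snps)]
    chroms += ["X"] * cfg.n_x_snps
    pos_x = [(k + 1) * cfg.snp_spacing_bp for k in range(cfg.n_x_snps)]

    snp = np.array([f"SNP{k:06d}" for k in range(cfg.n_auto_snps)]
                   + [f"XSNP{k:06d}" for k in range(cfg.n_x_snps)],
                   dtype=object)
    return GenotypeSet(
        ids=ped.ids.copy(), sex=ped.sex.copy(), snp=snp,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos_a + pos_x, dtype=float),
        allele_a=np.array(["A"] * len(snp), dtype=object),
        allele_b=np.array(["B"] * len(snp), dtype=object),
        is_x=np.array([False] * cfg.n_auto_snps + [True] * cfg.n_x_snps),
        calls=calls, coding="raw",
        meta={"founder_freq_auto": p_auto.tolist(),
              "founder_freq_x": p_x.tolist()},
    )


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def _rescale(u: np.ndarray, quad: float, n: int, target: float) -> tuple:
    """Scale u so the pedigree-standardized variance u'M^-1 u / n == target."""
    if target == 0.0:
        return np.zeros_like(u), 0.0
    if quad <= 0:
        raise ValueError("zero realized genetic variance; too few causal SNPs")
    f = math.sqrt(target / (quad / n))
    return u * f, target


def simulate_traits(g: GenotypeSet, ped: Pedigree, cfg: SimConfig
                    ) -> tuple[PhenotypeTable, TruthSet]:
    """Polygenic trait from causal SNPs, CG/covariate structure, residual.

    Causal effects are drawn normal and rescaled so the pedigree-
    standardized components u'A^-1 u / n and u'S^-1 u / n equal the
    variance targets exactly (the scale a relationship-matrix model
    estimates).  Male X genetic values use the configured dosage model:
    ``additive`` counts the single allele once (vc scale), ``compensated``
    doubles it.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n = len(ped)
    if list(g.ids) != list(ped.ids):
        raise ValueError("genotypes must cover the pedigree in order")

    auto_idx = np.flatnonzero(~g.is_x)
    x_idx = np.flatnonzero(g.is_x)
    causal_a = rng.choice(auto_idx, size=cfg.n_causal_auto, replace=False)
    causal_x = (rng.choice(x_idx, size=cfg.n_causal_x, replace=False)
                if cfg.n_causal_x and len(x_idx) else np.array([], dtype=int))

    # centering only: founder frequencies preferred, else observed
    p_a = (np.asarray(g.meta["founder_freq_auto"])[causal_a]
           if "founder_freq_auto" in g.meta
           else np.nanmean(g.calls[:, causal_a], axis=0) / 2.0)
    eff_a = rng.standard_normal(len(causal_a))
    u_auto = (g.calls[:, causal_a] - 2.0 * p_a) @ eff_a

    male = ped.sex == MALE
    if len(causal_x):
        x_local = causal_x - len(auto_idx)
        p_x = (np.asarray(g.meta["founder_freq_x"])[x_local]
               if "founder_freq_x" in g.meta
               else np.nanmean(g.calls[:, causal_x], axis=0) / 2.0)
        eff_x = rng.standard_normal(len(causal_x))
        dose = g.calls[:, causal_x].astype(float).copy()
        ploidy = np.where(male, 1.0, 2.0)[:, None]
        if cfg.male_x_dosage == "compensated":
            dose[male] *= 2.0
            ploidy = np.full((n, 1), 2.0)
        u_x = (dose - ploidy * p_x) @ eff_x
    else:
        eff_x = np.zeros(0)
        u_x = np.zeros(n)

    ainv = build_A_inverse(ped)
    qa = float(u_auto @ (ainv.values @ u_auto))
    u_auto, real_a = _rescale(u_auto, qa, n, cfg.var_auto)
    if cfg.var_x > 0 and len(causal_x):
        sinv = build_S_inverse(ped)
        qx = float(u_x @ (sinv.dense() @ u_x))
        u_x, real_x = _rescale(u_x, qx, n, cfg.var_x)
    else:
        u_x, real_x = np.zeros(n), 0.0

    cg = rng.integers(cfg.n_cg, size=n)
    cg_eff = rng.standard_normal(cfg.n_cg) * math.sqrt(cfg.var_cg)
    gmand = rng.integers(cfg.n_gmand, size=n)
    gmand_eff = rng.standard_normal(cfg.n_gmand) * math.sqrt(cfg.var_gmand)
    idap = rng.normal(cfg.idap_mean, cfg.idap_sd, size=n)
    idap_c = idap - cfg.idap_mean
    e = rng.standard_normal(n) * math.sqrt(cfg.var_e)

    latent = (cg_eff[cg] + cfg.beta_idap * idap_c
              + cfg.beta_idap2 * idap_c ** 2 + gmand_eff[gmand]
              + u_auto + u_x + e)

    thresholds = None
    if cfg.trait_type == "ordinal":
        K = cfg.n_categories
        if cfg.thresholds is not None:
            thresholds = list(cfg.thresholds)
        else:
            qs = np.linspace(0, 1, K + 1)[1:-1]
            thresholds = list(np.quantile(latent, qs))
        y = np.digitize(latent, thresholds) + 1
        meta = TraitMeta("trait", "binary" if K == 2 else "ordinal", K)
    else:
        y = latent
        meta = TraitMeta("trait", "continuous")

    df = pd.DataFrame({
        "id": ped.ids, "trait": y,
        "CG": [f"CG{k:02d}" for k in cg],
        "GMAND": [f"W{k:02d}" for k in gmand],
        "IDAP": idap_c, "IDAP2": idap_c ** 2,
    })
    pheno = PhenotypeTable(df, meta)
    truth = TruthSet(
        ids=list(ped.ids), tbv_auto=u_auto, tbv_x=u_x,
        causal_auto=[g.snp[k] for k in causal_a],
        causal_x=[g.snp[k] for k in causal_x],
        effects_auto=eff_a, effects_x=eff_x,
        realized={"var_auto": real_a, "var_x": real_x, "var_e": cfg.var_e,
                  "pop_var_auto": float(np.var(u_auto)),
                  "pop_var_x": float(np.var(u_x))},
        thresholds=thresholds,
        cg_effects={f"CG{k:02d}": float(v) for k, v in enumerate(cg_eff)},
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

_BIOTYPES = ["protein_coding", "lncRNA", "miRNA", "snoRNA", "snRNA",
             "pseudogene", "misc_RNA", "rRNA"]
_BIOTYPE_W = [0.55, 0.15, 0.07, 0.06, 0.06, 0.05, 0.04, 0.02]


def synthetic_genes(g: GenotypeSet, seed: int, per_bp: int = 250_000,
                    min_len: int = 5_000, max_len: int = 80_000
                    ) -> pd.DataFrame:
    """Synthetic gene intervals tiling each chromosome of the marker map."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for chrom in pd.unique(g.chrom):
        span = int(np.nanmax(g.pos[g.chrom == chrom])) + per_bp
        for start0 in range(1, span, per_bp):
            length = int(rng.integers(min_len, max_len + 1))
            start = start0 + int(rng.integers(0, max(per_bp - length, 1)))
            rows.append({
                "id": f"SYNGENE{k:05d}", "name": f"SYNG{k:05d}",
                "chrom": str(chrom), "start": start, "end": start + length - 1,
                "strand": "+" if rng.uniform() < 0.5 else "-",
                "biotype": rng.choice(_BIOTYPES, p=_BIOTYPE_W),
            })
            k += 1
    return pd.DataFrame(rows)


def _write_gff3(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in genes.iterrows():
            attrs = (f"ID={r['id']};Name={r['name']};biotype={r['biotype']}")
            fh.write(f"{r['chrom']}\tsynthetic\tgene\t{r['start']}\t{r['end']}"
                     f"\t.\t{r['strand']}\t.\t{attrs}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def generate_fixture_bundle(cfg: SimConfig, outdir) -> dict:
    """Write a fully loadable bundle; reproducible from (cfg, seed).

    Files: pedigree.csv, genotypes.raw + map.tsv (genotyped animals only),
    phenotypes.csv, genes.gff3, truth.json, config.json and manifest.json
    with per-file sha256 checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped = simulate_pedigree(cfg)
    geno = drop_genotypes(ped, cfg)
    pheno, truth = simulate_traits(geno, ped, cfg)

    # geno.ids shares the pedigree's topological order
    gsub = (geno.subset(animal_mask=~ped.is_founder())
            if cfg.genotyped == "nonfounders" else geno)

    files = {}
    write_pedigree(ped, outdir / "pedigree.csv")
    files["pedigree.csv"] = None
    write_genotypes(gsub, outdir / "genotypes.raw", outdir / "map.tsv")
    files["genotypes.raw"] = files["map.tsv"] = None
    pheno.data.to_csv(outdir / "phenotypes.csv", index=False)
    files["phenotypes.csv"] = None
    _write_gff3(synthetic_genes(geno, cfg.seed + 3), outdir / "genes.gff3")
    files["genes.gff3"] = None
    truth.to_json(outdir / "truth.json")
    files["truth.json"] = None
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, sort_keys=True)
    files["config.json"] = None

    manifest = {name: _sha256(outdir / name) for name in files}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
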
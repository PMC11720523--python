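"""End-to-end orchestration: QC -> matrices -> variance components ->
deregressed EBVs -> MLMA -> thresholds -> annotation.

Every stage output is persisted as plain text under the configured output
directory and a single ``run.log`` records seeds, thresholds and matrix
metadata, so each stage is independently re-runnable and a rerun with the
same config is numerically identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import data_io, genotype_qc, gwas, relmat, varcomp

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    pedigree: str
    genotypes: str
    map: str
    phenotypes: str
    outdir: str
    genes: str | None = None

    trait: str = "trait"
    response_type: str = "continuous"
    n_categories: int | None = None
    fixed: list = field(default_factory=lambda: ["CG"])
    covariates: list = field(default_factory=list)
    random_group: str | None = None

    qc: dict = field(default_factory=dict)          # QcThresholds overrides
    alpha: float = 0.90
    beta: float = 0.10
    chain: dict = field(default_factory=dict)       # ChainConfig overrides
    ne: int = 80
    p0: float = 0.05
    half_window: int = 500_000
    debv_c: float = 0.5
    min_cg_size: int = 5
    min_cg_sires: int = 2
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = cls(**raw)
        except TypeError as err:
            raise PipelineConfigError(str(err)) from err
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise PipelineConfigError("alpha + beta must equal 1")
        for name in ("pedigree", "genotypes", "map", "phenotypes"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineConfigError(f"{name} path does not exist: {p}")
        if self.genes and not Path(self.genes).exists():
            raise PipelineConfigError(f"genes path does not exist: {self.genes}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest of written artifacts."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("xherit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {}

    stage = "load"
    try:
        ped = data_io.read_pedigree(cfg.pedigree)
        geno = data_io.read_genotypes(cfg.genotypes, cfg.map, pedigree=ped)
        meta = data_io.TraitMeta(cfg.trait, cfg.response_type,
                                 cfg.n_categories)
        pheno = data_io.read_phenotypes(cfg.phenotypes, meta)
        logger.info("loaded %d pedigree, %d genotyped, %d records",
                    len(ped), geno.n_animals, len(pheno))

        stage = "cg-filter"
        if "CG" in pheno.data.columns:
            pheno, report = data_io.filter_contemporary_groups(
                pheno, ped, cfg.min_cg_size, cfg.min_cg_sires)
            logger.info("CG filter: %s", report)
            manifest["cg_filter"] = report

        stage = "qc"
        thr = genotype_qc.QcThresholds(**cfg.qc)
        geno, qc_report = genotype_qc.apply_qc(geno, ped, thr)
        qc_report.to_json(out / "qc_report.json")
        manifest["qc_report"] = str(out / "qc_report.json")

        stage = "relmat"
        gvc = genotype_qc.encode_dosage(geno, "vc")
        gids = list(gvc.ids)
        Ainv = relmat.build_A_inverse(ped)
        hinv, hxinv, tuning = relmat.single_step_inverses(
            ped, gvc, cfg.alpha, cfg.beta)
        logger.info("matrices built: tuning %s", tuning)
        manifest["tuning"] = tuning

        stage = "varcomp"
        chain = varcomp.ChainConfig(seed=cfg.seed, **cfg.chain)
        spec = varcomp.ModelSpec(
            trait=cfg.trait, response_type=cfg.response_type,
            n_categories=cfg.n_categories, fixed=cfg.fixed,
            covariates=cfg.covariates, random_group=cfg.random_group)
        # the sampler needs structures covering all phenotyped animals
        keep = pheno.data["id"].isin(set(ped.ids))
        pheno = data_io.PhenotypeTable(
            pheno.data[keep].reset_index(drop=True), pheno.trait)
        chains = varcomp.gibbs_sample(spec, pheno, hinv, hxinv, chain)
        summary = varcomp.summarize(chains)
        varcomp.chains_to_tsv(chains, out / "chains.tsv")
        with open(out / "varcomp_summary.json", "w") as fh:
            json.dump({"params": summary.params, "h2": summary.h2}, fh,
                      indent=2, default=float)
        manifest["varcomp_summary"] = str(out / "varcomp_summary.json")
        s2a = summary.params["s2_auto"]["mean"]
        s2x = summary.params["s2_x"]["mean"]
        s2e = summary.params["s2_e"]["mean"]
        h2_total = summary.h2["h2_total"]["mean"]
        logger.info("posterior means: s2_auto=%.4f s2_x=%.4f s2_e=%.4f",
                    s2a, s2x, s2e)

        stage = "debv"
        blup = gwas.pedigree_blup(spec, pheno, Ainv, s2a + s2x, s2e, ped=ped)
        dereg = gwas.deregress(blup, h2=max(min(h2_total, 0.99), 0.01),
                               c=cfg.debv_c)
        dereg.data.to_csv(out / "debv.tsv", sep="\t", index=False)
        manifest["debv"] = str(out / "debv.tsv")

        stage = "gwas"
        ggwas = genotype_qc.encode_dosage(geno, "gwas")
        grm = relmat.build_combined_grm(ggwas)
        have = dereg.data[dereg.data["id"].isin(set(gids))]
        ggwas = ggwas.select_animals(have["id"])
        grm_sub, _ = relmat.subset_and_invert(grm, list(have["id"]),
                                              "GRMcombined", "GRMcombined")
        y = have["debv"].to_numpy(dtype=float)
        s2g, s2e_g, info = gwas.reml_grm(y, np.ones((len(y), 1)), grm_sub)
        result = gwas.mlma(y, None, ggwas, grm_sub, (s2g, s2e_g))

        lengths = {str(c): float(np.nanmax(
            ggwas.pos[ggwas.chrom == c]) / 1e6)
            for c in np.unique(ggwas.chrom)}
        thrspec = gwas.significance_thresholds(lengths, cfg.ne, cfg.p0)
        result = gwas.apply_thresholds(result, thrspec)
        result.data.to_csv(out / "gwas_results.tsv", sep="\t", index=False)
        with open(out / "thresholds.json", "w") as fh:
            json.dump({"ne": thrspec.ne, "p0": thrspec.p0,
                       "me": thrspec.me, "threshold": thrspec.threshold,
                       "average": thrspec.average}, fh, indent=2)
        manifest["gwas_results"] = str(out / "gwas_results.tsv")
        manifest["thresholds"] = str(out / "thresholds.json")

        stage = "annotate"
        if cfg.genes:
            genes = data_io.read_gene_annotation(cfg.genes)
            sig = result.data[result.data["significant"]]
            ann = gwas.annotate_windows(sig, genes, cfg.half_window)
            ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
            manifest["annotation"] = str(out / "annotation.tsv")

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        manifest["run_log"] = str(log_path)
        return manifest
    except Exception as err:
        logger.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        root.removeHandler(handler)
        handler.close()
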
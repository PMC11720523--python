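"""Genotype quality control and the two sex-specific X dosage codings.

Autosomal genotypes are allele-B counts (AA=0, AB=1, BB=2) for both sexes.
On the X chromosome males are hemizygous, so a male call carries a single
allele; under the variance-component coding (``vc``) a male B-carrier is 1,
under the GWAS coding (``gwas``, full dosage compensation) he is 2.  Female
X coding is 0/1/2 in both schemes.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .data_io import FEMALE, MALE, Pedigree

logger = logging.getLogger(__name__)


@dataclass
class GenotypeSet:
    """Sex-annotated dosage matrix (animals x SNPs) plus marker map.

    ``calls`` holds floats with NaN for missing.  ``coding`` is one of
    ``raw`` (as read; male X 0/1), ``vc`` or ``gwas``.
    """

    ids: np.ndarray
    sex: np.ndarray
    snp: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    is_x: np.ndarray
    calls: np.ndarray
    coding: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.ids), len(self.snp)):
            raise ValueError("call matrix shape does not match ids x snps")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.calls)

    @property
    def males(self) -> np.ndarray:
        return self.sex == MALE

    @property
    def females(self) -> np.ndarray:
        return self.sex == FEMALE

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeSet":
        am = np.ones(self.n_animals, bool) if animal_mask is None else animal_mask
        sm = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypeSet(
            ids=self.ids[am], sex=self.sex[am],
            snp=self.snp[sm], chrom=self.chrom[sm], pos=self.pos[sm],
            allele_a=self.allele_a[sm], allele_b=self.allele_b[sm],
            is_x=self.is_x[sm], calls=self.calls[np.ix_(am, sm)],
            coding=self.coding)

    def select_animals(self, ids: Iterable[str]) -> "GenotypeSet":
        wanted = list(ids)
        pos = {a: k for k, a in enumerate(self.ids)}
        missing = [a for a in wanted if a not in pos]
        if missing:
            raise KeyError(f"animals not genotyped: {missing[:5]}")
        order = np.array([pos[a] for a in wanted])
        return GenotypeSet(
            ids=self.ids[order], sex=self.sex[order],
            snp=self.snp, chrom=self.chrom, pos=self.pos,
            allele_a=self.allele_a, allele_b=self.allele_b,
            is_x=self.is_x, calls=self.calls[order], coding=self.coding)


@dataclass
class QcThresholds:
    animal_call_rate: float = 0.90
    snp_call_rate: float = 0.90
    maf: float = 0.05
    het_deviation: float = 0.15
    mendelian: float = 0.01


@dataclass
class QcReport:
    """One primary reason per removed item, in the fixed rule order."""

    removed_animals: dict = field(default_factory=dict)  # id -> reason
    removed_snps: dict = field(default_factory=dict)     # snp -> reason
    thresholds: dict = field(default_factory=dict)
    before: dict = field(default_factory=dict)
    after: dict = field(default_factory=dict)
    male_het_x_set_missing: int = 0

    def counts(self) -> dict:
        out: dict = {"animals": {}, "snps": {}}
        for r in self.removed_animals.values():
            out["animals"][r] = out["animals"].get(r, 0) + 1
        for r in self.removed_snps.values():
            out["snps"][r] = out["snps"].get(r, 0) + 1
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "thresholds": self.thresholds,
                "before": self.before, "after": self.after,
                "counts": self.counts(),
                "removed_animals": self.removed_animals,
                "removed_snps": self.removed_snps,
                "male_het_x_set_missing": self.male_het_x_set_missing,
            }, fh, indent=2, sort_keys=True)


def call_rates(g: GenotypeSet) -> tuple[np.ndarray, np.ndarray]:
    """Non-missing fraction per animal and per SNP."""
    called = ~g.missing
    return called.mean(axis=1), called.mean(axis=0)


def _b_carrier(calls: np.ndarray) -> np.ndarray:
    """Male X B-carrier indicator valid for raw (0/1), vc (0/1) or gwas (0/2)."""
    return calls > 0


def allele_frequencies(g: GenotypeSet) -> np.ndarray:
    """Frequency of allele B per SNP; on X, males contribute one allele.

    SNPs with no called animals get NaN (set aside for removal).
    """
    calls = g.calls
    called = ~np.isnan(calls)
    p = np.full(g.n_snps, np.nan)

    auto = ~g.is_x
    if auto.any():
        num = np.nansum(calls[:, auto], axis=0)
        den = 2.0 * called[:, auto].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[auto] = np.where(den > 0, num / den, np.nan)

    if g.is_x.any():
        fem, mal = g.females, g.males
        xc = calls[:, g.is_x]
        xcalled = called[:, g.is_x]
        b_f = np.nansum(xc[fem], axis=0)
        b_m = _b_carrier(np.nan_to_num(xc[mal], nan=-1.0)).sum(axis=0)
        den = 2.0 * xcalled[fem].sum(axis=0) + xcalled[mal].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[g.is_x] = np.where(den > 0, (b_f + b_m) / den, np.nan)
    return p


def mendelian_conflict_rates(g: GenotypeSet, ped: Pedigree
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal parent-progeny conflict rate (max over genotyped parents).

    Autosomes: opposing homozygotes.  X: a son's X comes from his dam, so
    (dam 0, son carries B) or (dam 2, son carries A) conflict; sire-daughter
    pairs use the sire's single allele against the daughter's homozygotes.
    Sire-son X pairs are not comparable.  Returns (rates, tested flag);
    untested animals get rate 0.
    """
    pos = {a: k for k, a in enumerate(g.ids)}
    sire_of = dict(zip(ped.ids, ped.sire))
    dam_of = dict(zip(ped.ids, ped.dam))
    calls, isx = g.calls, g.is_x
    rates = np.zeros(g.n_animals)
    tested = np.zeros(g.n_animals, bool)

    for k, aid in enumerate(g.ids):
        child = calls[k]
        child_male = g.sex[k] == MALE
        best = 0.0
        for parent, is_sire in ((sire_of.get(aid), True), (dam_of.get(aid), False)):
            if parent is None or parent not in pos:
                continue
            par = calls[pos[parent]]
            ok = ~np.isnan(child) & ~np.isnan(par)
            if is_sire and child_male:
                ok = ok & ~isx  # son's X is not from his sire
            if not ok.any():
                continue
            c, pnt, x = child[ok], par[ok], isx[ok]
            conf = np.zeros(len(c), bool)
            a = ~x
            conf[a] = ((pnt[a] == 0) & (c[a] == 2)) | ((pnt[a] == 2) & (c[a] == 0))
            if x.any():
                if child_male:  # dam-son: compare son's allele to dam's
                    conf[x] = (((pnt[x] == 0) & _b_carrier(c[x]))
                               | ((pnt[x] == 2) & ~_b_carrier(c[x])))
                elif is_sire:   # sire-daughter: sire's single allele
                    conf[x] = ((~_b_carrier(pnt[x]) & (c[x] == 2))
                               | (_b_carrier(pnt[x]) & (c[x] == 0)))
                else:           # dam-daughter: opposing homozygotes
                    conf[x] = (((pnt[x] == 0) & (c[x] == 2))
                               | ((pnt[x] == 2) & (c[x] == 0)))
            tested[k] = True
            best = max(best, conf.mean())
        rates[k] = best
    return rates, tested


def _observed_expected_het(g: GenotypeSet, p: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Observed het frequency vs 2p(1-p); females only on X."""
    calls, called = g.calls, ~g.missing
    obs = np.full(g.n_snps, np.nan)
    auto = ~g.is_x
    het = calls == 1
    if auto.any():
        n = called[:, auto].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            obs[auto] = np.where(n > 0, het[:, auto].sum(axis=0) / n, np.nan)
    if g.is_x.any():
        fem = g.females
        n = called[np.ix_(fem, g.is_x)].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            obs[g.is_x] = np.where(
                n > 0, het[np.ix_(fem, g.is_x)].sum(axis=0) / n, np.nan)
    return obs, 2.0 * p * (1.0 - p)


def apply_qc(g: GenotypeSet, ped: Pedigree | None = None,
             cfg: QcThresholds | None = None) -> tuple[GenotypeSet, QcReport]:
    """Apply the fixed-order QC rules and return the filtered set + report.

    Rule order: SNP call rate -> animal call rate -> MAF -> heterozygosity
    deviation (HWE proxy; females only on X) -> Mendelian conflicts (removes
    the offspring) -> duplicated/unmapped SNPs.  Each removed item carries
    the first failing rule as its reason, so reruns are byte-identical.
    """
    cfg = cfg or QcThresholds()
    report = QcReport(thresholds=vars(cfg).copy(),
                      before={"animals": g.n_animals, "snps": g.n_snps})

    snp_reason: dict = {}
    animal_reason: dict = {}

    a_rate, s_rate = call_rates(g)
    for s in g.snp[s_rate < cfg.snp_call_rate]:
        snp_reason.setdefault(s, "call-rate")
    keep_snp = ~np.isin(g.snp, list(snp_reason))
    work = g.subset(snp_mask=keep_snp)

    a_rate, _ = call_rates(work)
    for a in work.ids[a_rate < cfg.animal_call_rate]:
        animal_reason.setdefault(a, "call-rate")
    work = work.subset(animal_mask=~np.isin(work.ids, list(animal_reason)))

    p = allele_frequencies(work)
    maf = np.minimum(p, 1.0 - p)
    bad = np.isnan(p) | (maf < cfg.maf)
    for s in work.snp[bad]:
        snp_reason.setdefault(s, "maf")
    work = work.subset(snp_mask=~bad)
    p = p[~bad]

    obs, exp = _observed_expected_het(work, p)
    with np.errstate(invalid="ignore"):
        bad = np.abs(obs - exp) > cfg.het_deviation
    bad = np.nan_to_num(bad, nan=False).astype(bool)
    for s in work.snp[bad]:
        snp_reason.setdefault(s, "hwe")
    work = work.subset(snp_mask=~bad)

    if ped is not None:
        rates, _ = mendelian_conflict_rates(work, ped)
        for a in work.ids[rates > cfg.mendelian]:
            animal_reason.setdefault(a, "mendelian")
        work = work.subset(
            animal_mask=~np.isin(work.ids, [a for a, r in animal_reason.items()
                                            if r == "mendelian"]))

    dup = np.zeros(work.n_snps, bool)
    seen: set = set()
    for k, s in enumerate(work.snp):
        if s in seen:
            dup[k] = True
        seen.add(s)
    nopos = np.isnan(work.pos)
    for s in work.snp[dup]:
        snp_reason.setdefault(s, "duplicate")
    for s in work.snp[nopos & ~dup]:
        snp_reason.setdefault(s, "no-position")
    work = work.subset(snp_mask=~(dup | nopos))

    if work.n_snps == 0:
        raise ValueError("QC removed every SNP; check input coding/thresholds")

    report.removed_snps = snp_reason
    report.removed_animals = animal_reason
    report.after = {"animals": work.n_animals, "snps": work.n_snps}
    return work, report


def encode_dosage(g: GenotypeSet, scheme: str,
                  male_x_raw: str = "haploid") -> GenotypeSet:
    """Re-code to the variance-component (``vc``) or GWAS (``gwas``) scheme.

    Autosomes are unchanged (AA=0, AB=1, BB=2 for all animals).  Female X
    cells stay 0/1/2 in both schemes.  Male X cells become B-carrier
    indicators scaled 0/1 (vc) or 0/2 (gwas).

    ``male_x_raw`` declares how the *source file* coded male X calls:
    ``"haploid"`` counts the single allele (0/1, a 2 is accepted as a
    diploid-style B hemizygote); ``"diploid"`` means 0/2 hemizygotes, so a
    male X call of 1 is a heterozygous genotyping artifact and is set
    missing (counted in ``meta['male_het_x_set_missing']``).
    """
    if scheme not in ("vc", "gwas"):
        raise ValueError(f"unknown coding scheme {scheme!r}")
    if male_x_raw not in ("haploid", "diploid"):
        raise ValueError(f"unknown male X raw convention {male_x_raw!r}")
    calls = g.calls.copy()
    n_het_male = 0
    if g.is_x.any() and g.males.any():
        mx = np.ix_(g.males, g.is_x)
        block = calls[mx].copy()
        if g.coding == "raw" and male_x_raw == "diploid":
            het = block == 1
            n_het_male = int(np.sum(het))
            block[het] = np.nan
        carrier = np.where(np.isnan(block), np.nan,
                           (block > 0).astype(float))
        calls[mx] = carrier * (2.0 if scheme == "gwas" else 1.0)
    out = replace(g, calls=calls, coding=scheme)
    out.meta = dict(getattr(g, "meta", {}) or {})
    out.meta["male_het_x_set_missing"] = n_het_male
    if n_het_male:
        logger.info("set %d male heterozygous X calls missing", n_het_male)
    return out
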
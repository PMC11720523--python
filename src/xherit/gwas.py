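"""Deregressed-EBV mixed-linear-model association with Me-based thresholds.

Pipeline: pedigree-only BLUP gives EBVs and reliabilities; Garrick-style
deregression removes the parent-average contribution and shrinkage to give
dEBV pseudo-phenotypes; a single-component REML on the combined
autosome + X GRM supplies variance components; per-SNP GLS tests run in the
GRM eigenbasis (the candidate SNP stays in the GRM — no LOCO); significance
is judged against chromosome-wise Bonferroni thresholds based on the
effective number of independent chromosome segments
Me = 2 Ne L / ln(Ne L); significant SNPs are annotated with genes inside
+-500 kb windows.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .data_io import GeneSet, PhenotypeTable, Pedigree, UNKNOWN
from .genotype_qc import GenotypeSet
from .relmat import RelationshipMatrix
from .varcomp import ModelSpec, _design

logger = logging.getLogger(__name__)

#: ARS-UCD1.2 chromosome lengths in Mb (1 cM taken as 1 Mb), BTA1-29 + X.
ARS_UCD12_MB = {
    "1": 158.534, "2": 136.231, "3": 121.005, "4": 120.000, "5": 120.089,
    "6": 117.806, "7": 110.683, "8": 113.320, "9": 105.454, "10": 103.309,
    "11": 106.982, "12": 87.216, "13": 83.472, "14": 82.403, "15": 85.008,
    "16": 81.014, "17": 73.167, "18": 65.821, "19": 63.450, "20": 71.975,
    "21": 69.863, "22": 60.773, "23": 52.499, "24": 62.317, "25": 42.350,
    "26": 51.992, "27": 45.612, "28": 45.940, "29": 51.099, "X": 139.009,
}


# ---------------------------------------------------------------------------
# Pedigree BLUP -> EBV, PEV, reliability
# ---------------------------------------------------------------------------

@dataclass
class EbvTable:
    data: pd.DataFrame          # id, ebv, pev, reliability, sire, dam
    sigma2_u: float
    sigma2_e: float


def pedigree_blup(spec: ModelSpec, data: PhenotypeTable,
                  ainv: RelationshipMatrix,
                  sigma2_u: float, sigma2_e: float,
                  ped: Pedigree | None = None) -> EbvTable:
    """Solve the single-trait animal-model MME on pedigree information only.

    PEV comes from the animal block of the inverse coefficient matrix;
    reliability r2 = 1 - PEV / sigma2_u.  ``sigma2_u`` should be the total
    additive variance (autosomal + X) on the trait scale.
    """
    spec.validate(data)
    df = data.data
    ids = df["id"].to_numpy(dtype=object)
    y = data.y.astype(float)
    n = len(y)

    X = _design(spec, data)
    p = X.shape[1]
    rec = ainv.index_of(ids)
    m = len(ainv)
    Z = np.zeros((n, m))
    Z[np.arange(n), rec] = 1.0

    lam = sigma2_e / sigma2_u
    A = ainv.dense()
    C = np.zeros((p + m, p + m))
    if p:
        C[:p, :p] = X.T @ X
        C[:p, p:] = X.T @ Z
        C[p:, :p] = Z.T @ X
    C[p:, p:] = Z.T @ Z + lam * A
    rhs = np.concatenate([X.T @ y if p else np.zeros(0), Z.T @ y])
    try:
        cf = scipy.linalg.cho_factor(C, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular MME coefficient matrix; confounded fixed effects?"
        ) from err
    sol = scipy.linalg.cho_solve(cf, rhs, check_finite=False)
    Cinv = scipy.linalg.cho_solve(cf, np.eye(p + m), check_finite=False)

    u = sol[p:]
    pev = np.clip(np.diag(Cinv)[p:] * sigma2_e, 0.0, None)
    rel = np.clip(1.0 - pev / sigma2_u, 0.0, 1.0 - 1e-12)

    sire = dam = np.full(m, UNKNOWN, dtype=object)
    if ped is not None:
        s_of = dict(zip(ped.ids, ped.sire))
        d_of = dict(zip(ped.ids, ped.dam))
        sire = np.array([s_of.get(i, UNKNOWN) for i in ainv.ids], dtype=object)
        dam = np.array([d_of.get(i, UNKNOWN) for i in ainv.ids], dtype=object)

    out = pd.DataFrame({"id": ainv.ids, "ebv": u, "pev": pev,
                        "reliability": rel, "sire": sire, "dam": dam})
    return EbvTable(out, sigma2_u=sigma2_u, sigma2_e=sigma2_e)


# ---------------------------------------------------------------------------
# Garrick deregression
# ---------------------------------------------------------------------------

@dataclass
class DeregressedTable:
    data: pd.DataFrame          # id, debv, reliability, weight
    excluded: pd.DataFrame      # id, reason
    h2: float
    c: float


def _information_contents(r2_pa: float, r2_i: float, lam: float
                          ) -> tuple[float, float]:
    """Solve for the PA and individual information contents (Z'Z terms).

    The {PA, individual} relationship matrix has inverse [[4, -2], [-2, 2]],
    so the 2x2 coefficient matrix is
    C = [[c_pa + 4 lam, -2 lam], [-2 lam, c_i + 2 lam]].  Reliabilities are
    on the individual's sigma2_u scale: the PA (prior variance 0.5 sigma2_u)
    predicts the individual with r2_PA = 0.5 - lam [C^-1]_11 (hence the
    classic 1/(0.5 - r2_PA) factor), while r2_i = 1 - lam [C^-1]_22.
    Solved in closed form.
    """
    # Writing a = c_pa + 4 lam, b = c_i + 2 lam, det = ab - 4 lam^2:
    # b/det = (0.5 - r2_pa)/lam and a/det = (1 - r2_i)/lam.
    ka = (0.5 - r2_pa) / lam     # = b / det
    kb = (1.0 - r2_i) / lam      # = a / det
    # det = a b - 4 lam^2 and a = kb det, b = ka det =>
    # det = ka kb det^2 - 4 lam^2 => ka kb det^2 - det - 4 lam^2 = 0
    disc = 1.0 + 16.0 * ka * kb * lam * lam
    det = (1.0 + math.sqrt(disc)) / (2.0 * ka * kb)
    a = kb * det
    b = ka * det
    return a - 4.0 * lam, b - 2.0 * lam


def deregress(ebvs: EbvTable, h2: float, c: float = 0.5) -> DeregressedTable:
    """Garrick-style deregression removing the parent-average contribution.

    For each animal: r2_PA = (r2_sire + r2_dam)/4; the 2x2 MME in
    {parent average, individual} is reconstructed from the reliabilities,
    right-hand sides are regenerated from (PA, EBV), and the individual
    equation is deregressed by its own information content.  Animals whose
    reliability does not exceed their parent-average reliability carry no
    own information and are excluded.  With both parents unknown the
    procedure reduces to dEBV = EBV / r2.

    Weights follow w = (1 - h2) / ((c + (1 - r2_dEBV) / r2_dEBV) h2) with
    ``c`` the fraction of genetic variance not explained by markers.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    lam = (1.0 - h2) / h2
    df = ebvs.data.set_index("id")
    rel = df["reliability"].to_dict()
    ebv = df["ebv"].to_dict()

    rows, dropped = [], []
    for aid, row in df.iterrows():
        r2_i = float(row["reliability"])
        r2_s = float(rel.get(row["sire"], 0.0))
        r2_d = float(rel.get(row["dam"], 0.0))
        # (r2_s + r2_d)/4 <= 0.5 with equality only for perfectly known
        # parents; keep strictly below 0.5 so the 2x2 system stays finite
        r2_pa = min((r2_s + r2_d) / 4.0, 0.5 - 1e-9)
        if r2_i <= 0:
            dropped.append((aid, "zero reliability"))
            continue
        if r2_pa <= 0:
            debv = float(row["ebv"]) / r2_i
            r2_debv = r2_i
        else:
            if r2_i <= r2_pa:
                dropped.append((aid, "no own information"))
                continue
            pa = 0.5 * (float(ebv.get(row["sire"], 0.0))
                        + float(ebv.get(row["dam"], 0.0)))
            c_pa, c_i = _information_contents(r2_pa, r2_i, lam)
            # regenerated RHS of the individual equation, then deregress
            y_i = -2.0 * lam * pa + (c_i + 2.0 * lam) * float(row["ebv"])
            if c_i <= 0:
                dropped.append((aid, "no own information"))
                continue
            debv = y_i / c_i
            r2_debv = c_i / (c_i + lam)
        w = (1.0 - h2) / ((c + (1.0 - r2_debv) / max(r2_debv, 1e-12)) * h2)
        rows.append((aid, debv, r2_debv, w))

    out = pd.DataFrame(rows, columns=["id", "debv", "reliability", "weight"])
    excl = pd.DataFrame(dropped, columns=["id", "reason"])
    return DeregressedTable(out, excl, h2=h2, c=c)


# ---------------------------------------------------------------------------
# REML on a GRM (eigendecomposition profile likelihood)
# ---------------------------------------------------------------------------

def reml_grm(y: np.ndarray, X: np.ndarray, grm: RelationshipMatrix
             ) -> tuple[float, float, dict]:
    """Single-component REML via the GRM eigenbasis.

    Returns (sigma2_g, sigma2_e, info) where info records convergence and a
    boundary flag when the genetic variance pins at ~0.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 50:
        raise ValueError("need at least 50 observations for REML")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]

    lam, U = scipy.linalg.eigh(grm.dense())
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def negloglik(logit_h2: float) -> float:
        h2 = 1.0 / (1.0 + math.exp(-logit_h2))
        d = h2 * lam + (1.0 - h2)
        w = 1.0 / d
        XtWX = Xt.T @ (Xt * w[:, None])
        XtWy = Xt.T @ (yt * w)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        rss = float(r @ (r * w))
        p = X.shape[1]
        s2 = rss / (n - p)
        _, ld_xwx = np.linalg.slogdet(XtWX)
        return 0.5 * ((n - p) * math.log(s2) + np.sum(np.log(d)) + ld_xwx)

    res = minimize_scalar(negloglik, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    h2 = 1.0 / (1.0 + math.exp(-res.x))
    d = h2 * lam + (1.0 - h2)
    w = 1.0 / d
    XtWX = Xt.T @ (Xt * w[:, None])
    beta = np.linalg.solve(XtWX, Xt.T @ (yt * w))
    r = yt - Xt @ beta
    s2_total = float(r @ (r * w)) / (n - X.shape[1])
    s2_g, s2_e = h2 * s2_total, (1.0 - h2) * s2_total
    boundary = h2 < 1e-4 or h2 > 1 - 1e-4
    if boundary:
        logger.info("REML variance at boundary: h2=%.2e", h2)
    return s2_g, s2_e, {"h2": h2, "boundary": boundary,
                        "converged": bool(res.success)}


# ---------------------------------------------------------------------------
# MLMA
# ---------------------------------------------------------------------------

@dataclass
class GwasResult:
    data: pd.DataFrame          # snp, chrom, pos, freq, beta, se, p, neglog10p,
    #                             threshold, significant
    thresholds: "ThresholdSpec | None" = None
    vc: tuple[float, float] | None = None


def mlma(y: np.ndarray, covars: np.ndarray | None, g: GenotypeSet,
         grm: RelationshipMatrix, vc: tuple[float, float]) -> GwasResult:
    """Per-SNP GLS under V = s2_g GRM + s2_e I via one eigendecomposition.

    Candidate SNPs remain in the GRM (no leave-one-chromosome-out).  Each
    SNP's effect and Wald chi-square(1) p-value come from the exact GLS fit
    with an intercept plus any supplied covariates; monomorphic SNPs get
    p = 1 and a flag.  Missing dosages are mean-imputed per SNP.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if list(g.ids) != list(grm.ids):
        raise ValueError("genotype and GRM animal order differ")
    s2_g, s2_e = vc
    lam, U = scipy.linalg.eigh(grm.dense())
    d = s2_g * np.clip(lam, 0.0, None) + s2_e
    w = 1.0 / np.sqrt(d)

    C = np.ones((n, 1))
    if covars is not None and np.size(covars):
        cv = np.asarray(covars, dtype=float)
        C = np.hstack([C, cv[:, None] if cv.ndim == 1 else cv])

    yt = (U.T @ y) * w
    Ct = (U.T @ C) * w[:, None]
    Q, _ = np.linalg.qr(Ct)
    y_r = yt - Q @ (Q.T @ yt)

    M = g.calls.copy()
    miss = np.isnan(M)
    col_mean = np.where(np.isnan(M).all(axis=0), 0.0, np.nanmean(M, axis=0))
    if miss.any():
        M[miss] = np.broadcast_to(col_mean, M.shape)[miss]
    mono = M.std(axis=0) == 0.0

    Mt = (U.T @ M) * w[:, None]
    M_r = Mt - Q @ (Q.T @ Mt)
    xtx = np.einsum("ij,ij->j", M_r, M_r)
    xty = M_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xtx > 0, xty / xtx, 0.0)
        se = np.where(xtx > 0, 1.0 / np.sqrt(xtx), np.inf)
    stat = (beta / se) ** 2
    pval = chi2.sf(stat, df=1)
    pval = np.where(mono, 1.0, pval)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    freq = col_mean / 2.0
    out = pd.DataFrame({
        "snp": g.snp, "chrom": g.chrom, "pos": g.pos.astype(np.int64),
        "allele_b": g.allele_b, "freq": freq,
        "beta": beta, "se": se, "p": pval,
        "neglog10p": -np.log10(pval), "monomorphic": mono,
    })
    return GwasResult(out, vc=vc)


def dense_gls_oracle(y: np.ndarray, covars: np.ndarray | None,
                     x: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """Reference single-SNP GLS with an explicit dense V (test oracle)."""
    n = len(y)
    C = np.ones((n, 1))
    if covars is not None and np.size(covars):
        cv = np.asarray(covars, dtype=float)
        C = np.hstack([C, cv[:, None] if cv.ndim == 1 else cv])
    D = np.hstack([C, np.asarray(x, dtype=float)[:, None]])
    Vi = np.linalg.inv(V)
    A = D.T @ Vi @ D
    b = np.linalg.solve(A, D.T @ Vi @ y)
    cov = np.linalg.inv(A)
    return float(b[-1]), float(math.sqrt(cov[-1, -1]))


# ---------------------------------------------------------------------------
# Me-based significance thresholds
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSpec:
    ne: int
    p0: float
    lengths: dict               # chrom -> L in cM (1 cM = 1 Mb)
    me: dict                    # chrom -> Me
    threshold: dict             # chrom -> -log10(p0 / Me)
    average: float


def significance_thresholds(lengths: dict | None = None, ne: int = 80,
                            p0: float = 0.05) -> ThresholdSpec:
    """Chromosome-wise Bonferroni thresholds from Me = 2 Ne L / ln(Ne L).

    ``lengths`` maps chromosome label to length in cM (1 cM = 1 Mb);
    defaults to the ARS-UCD1.2 assembly lengths.  The threshold on the
    -log10 scale is -log10(p0 / Me); the cross-chromosome average is also
    reported.
    """
    lengths = dict(lengths) if lengths else dict(ARS_UCD12_MB)
    me, thr = {}, {}
    for chrom, L in lengths.items():
        if L <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom}")
        nel = ne * L
        if nel <= 1:
            raise ValueError(f"Ne*L <= 1 for chromosome {chrom}")
        me[chrom] = 2.0 * nel / math.log(nel)
        thr[chrom] = -math.log10(p0 / me[chrom])
    avg = float(np.mean(list(thr.values())))
    return ThresholdSpec(ne=ne, p0=p0, lengths=lengths, me=me,
                         threshold=thr, average=avg)


def apply_thresholds(result: GwasResult, spec: ThresholdSpec) -> GwasResult:
    """Attach per-chromosome thresholds and the significance flag."""
    df = result.data.copy()
    df["threshold"] = df["chrom"].map(
        lambda c: spec.threshold.get(str(c), spec.average))
    df["significant"] = df["neglog10p"] >= df["threshold"]
    return GwasResult(df, thresholds=spec, vc=result.vc)


# ---------------------------------------------------------------------------
# Window annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationHit:
    snp: str
    chrom: str
    pos: int
    window: tuple
    gene_id: str
    gene_name: str
    biotype: str
    distance: int               # 0 when the gene contains the SNP


def annotate_windows(hits: pd.DataFrame, genes: GeneSet,
                     half_window: int = 500_000) -> pd.DataFrame:
    """Genes overlapping +-``half_window`` around each significant SNP.

    The window is [pos - half_window, pos + half_window] clipped at 1
    (1-based inclusive); a gene is reported iff
    max(start, win_lo) <= min(end, win_hi).  Distance is 0 for genes
    containing the SNP, else the gap to the nearest gene edge.
    """
    gd = genes.data
    rows = []
    for _, snp in hits.iterrows():
        chrom, pos = str(snp["chrom"]), int(snp["pos"])
        lo, hi = max(pos - half_window, 1), pos + half_window
        sub = gd[gd["chrom"].astype(str) == chrom]
        ov = sub[(np.maximum(sub["start"], lo) <= np.minimum(sub["end"], hi))]
        for _, gene in ov.iterrows():
            if gene["start"] <= pos <= gene["end"]:
                dist = 0
            else:
                dist = int(min(abs(pos - gene["start"]),
                               abs(pos - gene["end"])))
            rows.append({
                "snp": snp["snp"], "chrom": chrom, "pos": pos,
                "win_lo": lo, "win_hi": hi,
                "gene_id": gene["id"], "gene_name": gene["name"],
                "biotype": gene["biotype"], "distance": dist,
            })
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "win_lo",
                                       "win_hi", "gene_id", "gene_name",
                                       "biotype", "distance"])
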
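"""Pedigree and genomic relationship matrices and the single-step inverses.

Autosomal side: the numerator relationship matrix A (tabular method), its
sparse inverse by Henderson's rules with inbreeding, the VanRaden genomic
matrix G_auto, and the ssGBLUP H-inverse.  X side: the sex-asymmetric
pedigree matrix S (male gene content 0/1, female 0/1/2, scaled by 2p(1-p)
at a neutral locus), the sex-specifically centered G_X, and H_X-inverse.

Scaling conventions (fixed so the gene-dropping simulator is the arbiter):
founder females have S-diagonal 1, founder males 0.5; G_X shares the
autosomal denominator 2*sum(p(1-p)) so female diagonals average ~1 and male
diagonals ~0.5, commensurate with S.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .data_io import FEMALE, MALE, Pedigree
from .genotype_qc import GenotypeSet, allele_frequencies

logger = logging.getLogger(__name__)

KINDS = {"A", "Ainv", "A22", "A22inv", "S", "Sinv", "S22", "S22inv",
         "Gauto", "Gx", "Gblend", "Hinv", "HXinv", "GRMcombined"}


@dataclass
class RelationshipMatrix:
    """Symmetric labelled kinship matrix with provenance metadata."""

    ids: np.ndarray
    values: np.ndarray          # dense ndarray or scipy sparse
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        if self.kind not in KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def __len__(self) -> int:
        return len(self.ids)

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def index_of(self, ids) -> np.ndarray:
        pos = {a: k for k, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in pos]
        if missing:
            raise KeyError(f"ids not in matrix: {missing[:5]}")
        return np.array([pos[a] for a in ids], dtype=np.int64)

    def check_symmetric(self, tol: float = 1e-10) -> None:
        d = self.dense()
        if np.max(np.abs(d - d.T)) > tol:
            raise ValueError(f"{self.kind} matrix not symmetric to {tol}")


# ---------------------------------------------------------------------------
# Pedigree matrices
# ---------------------------------------------------------------------------

def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + 0.5 a_sd;  a_ij = 0.5 (a_js + a_jd), with missing-parent
    terms dropped.  Requires (and relies on) topological order.
    """
    n = len(ped)
    s, d = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[:i, si]
        if di >= 0:
            row += 0.5 * A[:i, di]
        A[:i, i] = row
        A[i, :i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return RelationshipMatrix(ped.ids.copy(), A, "A")


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = a_ii - 1 (tabular; desk scale)."""
    return np.diag(build_A(ped).dense()) - 1.0


def build_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A-inverse by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of animal i is
    d_i = 0.5 - 0.25 (F_s + F_d) with each parental term replaced by 0.25
    when that parent is unknown (classic rules).
    """
    n = len(ped)
    s, d = ped.parent_indices()
    F = inbreeding(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i); cols.append(j); vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        fs = F[si] if si >= 0 else -1.0  # unknown parent: (1+F)/4 -> 0.25 term
        fd = F[di] if di >= 0 else -1.0
        di_var = 0.5 - 0.25 * ((fs if si >= 0 else -1.0)
                               + (fd if di >= 0 else -1.0))
        # unknown parent contributes 0.25 to the variance, i.e. F := -1 term
        b = 1.0 / di_var
        add(i, i, b)
        for p in (si, di):
            if p >= 0:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
        for p in (si, di):
            for q in (si, di):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * b)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(ped.ids.copy(), Ainv, "Ainv")


def build_S(ped: Pedigree) -> RelationshipMatrix:
    """X-chromosome pedigree relationship matrix S (sex-asymmetric rules).

    In the gene-content scaling (male content 0/1, female 0/1/2; covariances
    divided by 2p(1-p)):

    * founder female: diag 1; founder male: diag 0.5; founders unrelated
    * female i (sire s, dam d): S_ij = S_js + 0.5 S_jd;  S_ii = 1 + S_sd
    * male i (dam d):           S_ij = 0.5 S_jd;         S_ii = 0.5

    Missing-parent terms are dropped.
    """
    n = len(ped)
    s, d = ped.parent_indices()
    male = ped.sex == MALE
    S = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(i)
        if male[i]:
            if di >= 0:
                row += 0.5 * S[:i, di]
            S[i, i] = 0.5
        else:
            if si >= 0:
                row += S[:i, si]
            if di >= 0:
                row += 0.5 * S[:i, di]
            S[i, i] = 1.0 + (S[si, di] if (si >= 0 and di >= 0) else 0.0)
        S[:i, i] = row
        S[i, :i] = row
    return RelationshipMatrix(ped.ids.copy(), S, "S")


def build_S_inverse(ped: Pedigree, ridge: float = 0.0) -> RelationshipMatrix:
    """Dense inverse of S (desk scale; rule-based fast inverse not needed)."""
    S = build_S(ped)
    Sinv, used = _robust_inverse(S.dense(), ridge)
    return RelationshipMatrix(ped.ids.copy(), Sinv, "Sinv",
                              meta={"ridge": used})


# ---------------------------------------------------------------------------
# Subsetting / inversion helpers
# ---------------------------------------------------------------------------

def _robust_inverse(m: np.ndarray, ridge0: float = 0.0,
                    max_ridge: float = 1e-4) -> tuple[np.ndarray, float]:
    """Cholesky inverse with an escalating recorded ridge (1e-8 ... 1e-4)."""
    ridge = ridge0
    while True:
        try:
            mm = m if ridge == 0.0 else m + ridge * np.eye(len(m))
            c, low = scipy.linalg.cho_factor(mm, check_finite=False)
            inv = scipy.linalg.cho_solve((c, low), np.eye(len(m)),
                                         check_finite=False)
            return 0.5 * (inv + inv.T), ridge
        except np.linalg.LinAlgError:
            ridge = 1e-8 if ridge == 0.0 else ridge * 10.0
            if ridge > max_ridge:
                raise np.linalg.LinAlgError(
                    f"matrix singular even with ridge {max_ridge}")


def subset_and_invert(m: RelationshipMatrix, ids,
                      kind_sub: str | None = None,
                      kind_inv: str | None = None
                      ) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Extract the block for ``ids`` (A22/S22) and its dense inverse."""
    ids = list(ids)
    idx = m.index_of(ids)
    sub = m.dense()[np.ix_(idx, idx)]
    inv, ridge = _robust_inverse(sub)
    ks = kind_sub or (m.kind + "22" if m.kind in ("A", "S") else m.kind)
    ki = kind_inv or (ks + "inv")
    meta = {"parent_kind": m.kind, "ridge": ridge}
    return (RelationshipMatrix(np.array(ids, dtype=object), sub, ks, meta),
            RelationshipMatrix(np.array(ids, dtype=object), inv, ki, meta))


# ---------------------------------------------------------------------------
# Genomic matrices
# ---------------------------------------------------------------------------

def _freqs(g: GenotypeSet, p: np.ndarray | None) -> np.ndarray:
    return allele_frequencies(g) if p is None else np.asarray(p, dtype=float)


def _impute(calls: np.ndarray, fill: np.ndarray) -> np.ndarray:
    out = calls.copy()
    miss = np.isnan(out)
    if miss.any():
        out[miss] = np.broadcast_to(fill, out.shape)[miss]
    return out


def build_G_auto(g: GenotypeSet, p: np.ndarray | None = None
                 ) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from autosomal SNPs.

    Z = M - 2p'; G = ZZ' / (2 sum p_j (1-p_j)).  Missing dosages are
    mean-imputed to 2p_j.  ``g`` must be vc- (or gwas-) coded; autosomes are
    identical under both.
    """
    auto = ~g.is_x
    if not auto.any():
        raise ValueError("no autosomal SNPs")
    ga = g.subset(snp_mask=auto)
    pa = _freqs(g, p)[auto]
    denom = 2.0 * np.sum(pa * (1.0 - pa))
    if denom <= 0:
        raise ValueError("all autosomal SNPs monomorphic")
    Z = _impute(ga.calls, 2.0 * pa) - 2.0 * pa
    G = Z @ Z.T / denom
    return RelationshipMatrix(g.ids.copy(), G, "Gauto",
                              meta={"n_snps": int(auto.sum()),
                                    "denominator": denom})


def build_G_X(g: GenotypeSet, p: np.ndarray | None = None
              ) -> RelationshipMatrix:
    """X-chromosome genomic matrix with sex-specific centering.

    vc coding required (male X dosages 0/1).  Z_X = M_X - 1p' for males and
    M_X - 2p' for females; the denominator is the autosomal-style
    2 sum p(1-p), so female diagonals average ~1 and male ~0.5.
    """
    if g.coding != "vc":
        raise ValueError("build_G_X expects vc coding (male X 0/1)")
    if not g.is_x.any():
        raise ValueError("no X SNPs")
    gx = g.subset(snp_mask=g.is_x)
    px = _freqs(g, p)[g.is_x]
    denom = 2.0 * np.sum(px * (1.0 - px))
    if denom <= 0:
        raise ValueError("all X SNPs monomorphic")
    ploidy = np.where(gx.males, 1.0, 2.0)[:, None]
    Z = _impute(gx.calls, ploidy * px) - ploidy * px
    G = Z @ Z.T / denom
    return RelationshipMatrix(g.ids.copy(), G, "Gx",
                              meta={"n_snps": int(g.is_x.sum()),
                                    "denominator": denom})


def tune_and_blend(G: RelationshipMatrix, P22: RelationshipMatrix,
                   alpha: float = 0.90, beta: float = 0.10
                   ) -> RelationshipMatrix:
    """Two-coefficient moment tuning of G to P22, then alpha/beta blending.

    First solve mean(diag(a + bG)) = mean(diag(P22)) and
    mean(offdiag(a + bG)) = mean(offdiag(P22)) for scalars (a, b); then
    G* = alpha (a + bG) + beta P22.  Guarantees mean-diagonal agreement and
    positive definiteness (via the P22 share plus a recorded ridge when
    needed).
    """
    if abs(alpha + beta - 1.0) > 1e-12:
        raise ValueError("alpha + beta must equal 1")
    if list(G.ids) != list(P22.ids):
        raise ValueError("G and P22 id sets/order differ")
    Gd, Pd = G.dense(), P22.dense()
    n = len(Gd)
    dg, dp = np.mean(np.diag(Gd)), np.mean(np.diag(Pd))
    off = ~np.eye(n, dtype=bool)
    og, op = (np.mean(Gd[off]), np.mean(Pd[off])) if n > 1 else (0.0, 0.0)
    spread = dg - og
    if not np.isfinite(spread) or abs(spread) < 1e-12:
        raise ValueError("G is constant; tuning coefficients undefined")
    b = (dp - op) / spread
    a = dp - b * dg
    Gt = a + b * Gd
    Gstar = alpha * Gt + beta * Pd
    Gstar = 0.5 * (Gstar + Gstar.T)
    w = np.linalg.eigvalsh(Gstar)
    ridge = 0.0
    if w[0] <= 1e-10:
        ridge = 1e-8
        while w[0] + ridge <= 0 and ridge < 1e-4:
            ridge *= 10.0
        Gstar = Gstar + ridge * np.eye(n)
    return RelationshipMatrix(
        G.ids.copy(), Gstar, "Gblend",
        meta={"a": a, "b": b, "alpha": alpha, "beta": beta, "ridge": ridge,
              "source_kind": G.kind, "target_kind": P22.kind})


def build_H_inverse(Ainv: RelationshipMatrix, A22inv: RelationshipMatrix,
                    Gstar_inv: RelationshipMatrix,
                    kind: str = "Hinv") -> RelationshipMatrix:
    """ssGBLUP inverse: H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1].

    Works for the autosomal (A-based) and the X (S-based) sides alike; the
    genotyped block is located by id within the pedigree matrix.  With no
    genotyped animals (empty block) the result is A^-1 itself.
    """
    H = Ainv.dense().copy()
    if len(A22inv) != len(Gstar_inv) or list(A22inv.ids) != list(Gstar_inv.ids):
        raise ValueError("A22inv and Gstar_inv ids misaligned")
    if len(A22inv):
        idx = Ainv.index_of(A22inv.ids)
        H[np.ix_(idx, idx)] += Gstar_inv.dense() - A22inv.dense()
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(Ainv.ids.copy(), H, kind,
                              meta={"n_genotyped": len(A22inv)})


def build_HX_inverse(Sinv: RelationshipMatrix, S22inv: RelationshipMatrix,
                     GXstar_inv: RelationshipMatrix) -> RelationshipMatrix:
    """X-side single-step inverse: S^-1 + [0 0; 0 G_X*^-1 - S22^-1]."""
    return build_H_inverse(Sinv, S22inv, GXstar_inv, kind="HXinv")


def single_step_inverses(ped: Pedigree, g_vc: GenotypeSet,
                         alpha: float = 0.90, beta: float = 0.10
                         ) -> tuple[RelationshipMatrix, RelationshipMatrix,
                                    dict]:
    """Build the full autosomal and X single-step pair (H^-1, H_X^-1).

    ``g_vc`` holds the vc-coded genotypes of the genotyped subset (ids must
    appear in the pedigree).  Returns the two inverses over all pedigree
    animals plus the tuning/blending metadata of both genomic matrices.
    """
    if g_vc.coding != "vc":
        raise ValueError("single_step_inverses expects vc-coded genotypes")
    p = allele_frequencies(g_vc)
    gids = list(g_vc.ids)

    A = build_A(ped)
    Ainv = build_A_inverse(ped)
    Ainv = RelationshipMatrix(Ainv.ids, Ainv.dense(), "Ainv")
    A22, A22inv = subset_and_invert(A, gids)
    Gb = tune_and_blend(build_G_auto(g_vc, p), A22, alpha, beta)
    Gbinv, _ = _robust_inverse(Gb.dense())
    hinv = build_H_inverse(Ainv, A22inv,
                           RelationshipMatrix(A22.ids, Gbinv, "Gblend"))

    S = build_S(ped)
    Sinv = build_S_inverse(ped)
    S22, S22inv = subset_and_invert(S, gids)
    Gxb = tune_and_blend(build_G_X(g_vc, p), S22, alpha, beta)
    Gxbinv, _ = _robust_inverse(Gxb.dense())
    hxinv = build_HX_inverse(Sinv, S22inv,
                             RelationshipMatrix(S22.ids, Gxbinv, "Gblend"))
    return hinv, hxinv, {"auto": Gb.meta, "x": Gxb.meta}


def build_combined_grm(g: GenotypeSet, p: np.ndarray | None = None
                       ) -> RelationshipMatrix:
    """Pooled autosome + X GRM under full dosage compensation (gwas coding).

    Every animal (including males on X, whose single allele counts as a
    diploid 0/2 dose) is centered by 2p'; autosomal and X contributions are
    summed and divided by the pooled 2 sum p(1-p).
    """
    if g.coding != "gwas":
        raise ValueError("build_combined_grm expects gwas coding (male X 0/2)")
    pall = _freqs(g, p)
    denom = 2.0 * np.sum(pall * (1.0 - pall))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic")
    Z = _impute(g.calls, 2.0 * pall) - 2.0 * pall
    G = Z @ Z.T / denom
    return RelationshipMatrix(g.ids.copy(), G, "GRMcombined",
                              meta={"n_snps": g.n_snps, "denominator": denom})
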
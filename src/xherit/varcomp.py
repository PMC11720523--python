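"""Two-genetic-component animal model fitted by Gibbs sampling.

The model is  y = Xb + W g + Z u_auto + Z u_x + e  with
u_auto ~ N(0, H sigma2_auto), u_x ~ N(0, H_X sigma2_x), an optional i.i.d.
group effect g (weaning management group), and e ~ N(0, I sigma2_e).  The
sampler works directly with the *inverse* relationship structures (the
ssGBLUP H-inverses), so the hybrid matrices never need to be formed.

Random vectors are updated as joint draws from their multivariate-normal
full conditionals (blocked Gibbs); variances come from scaled-inverse-
chi-square full conditionals.  Ordinal and binary traits are handled with
the threshold (liability) model: latent liabilities are drawn from
truncated normals, the residual variance is fixed at 1 and the first
threshold at 0 for identification.

Heritabilities are partitioned per draw as
h2_auto = s2_auto / (s2_auto + s2_x + s2_e), likewise h2_x, and
h2_total = h2_auto + h2_x exactly (extra random variances are excluded
from the denominator, matching the printed formulas).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.special import ndtr, ndtri

from .data_io import PhenotypeTable
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration containers
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Trait, response type, and model terms (all referencing data columns)."""

    trait: str
    response_type: str = "continuous"      # continuous | ordinal | binary
    n_categories: int | None = None        # ordinal K
    fixed: list = field(default_factory=list)       # class columns (CG, CRI...)
    covariates: list = field(default_factory=list)  # numeric columns (IDAP...)
    random_group: str | None = None        # e.g. GMAND
    intercept: bool = True

    def validate(self, data: PhenotypeTable) -> None:
        cols = set(data.data.columns)
        need = [self.trait, *self.fixed, *self.covariates]
        if self.random_group:
            need.append(self.random_group)
        missing = [c for c in need if c not in cols]
        if missing:
            raise ValueError(f"model columns missing from data: {missing}")


@dataclass
class ChainConfig:
    """MCMC bookkeeping; the paper-scale run is (1e6, 250e3, 100)."""

    n_iter: int = 8000
    burn_in: int = 2000
    thin: int = 4
    seed: int = 1
    prior_df: float = -2.0     # scaled-inv-chi2 df; -2 with scale 0 is flat
    prior_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if retained_count(self) < 1:
            logger.warning("chain config retains no draws")


def retained_count(cfg: ChainConfig) -> int:
    """floor((n_iter - burn_in) / thin); the paper's settings give 7,500."""
    return (cfg.n_iter - cfg.burn_in) // cfg.thin


@dataclass
class PosteriorChains:
    """Retained draws of the variance components (and thresholds)."""

    draws: dict                 # name -> ndarray of retained draws
    config: ChainConfig
    model: ModelSpec
    thresholds: np.ndarray | None = None   # retained x (K-1) for ordinal

    def __len__(self) -> int:
        return len(next(iter(self.draws.values())))


@dataclass
class PosteriorSummary:
    params: dict                # name -> dict(mean, hpd, eq_tail, geweke, mcse)
    h2: dict                    # h2_auto / h2_x / h2_total -> same structure


# ---------------------------------------------------------------------------
# Small posterior utilities
# ---------------------------------------------------------------------------

def heritability_partition(s_auto: float, s_x: float, s_e: float,
                           s_extra: tuple = ()) -> tuple[float, float, float]:
    """(h2_auto, h2_x, h2_total) with denominator s_auto + s_x + s_e.

    Extra random variances (e.g. management group) are excluded from the
    denominator.  The identity h2_auto + h2_x = h2_total holds exactly.
    """
    if min(s_auto, s_x, s_e) < 0:
        raise ValueError("variance components must be non-negative")
    den = s_auto + s_x + s_e
    if den == 0:
        raise ValueError("zero total variance")
    return s_auto / den, s_x / den, (s_auto + s_x) / den


def hpd_interval(draws, mass: float = 0.90) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass*n) sorted draws.

    Ties break to the leftmost (smallest lower bound) window.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    m = int(math.ceil(mass * n))
    if m < 1 or m > n:
        raise ValueError(f"window of {m} draws impossible with n={n}")
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first (leftmost) minimum
    return float(x[i]), float(x[i + m - 1])


def geweke_z(draws, frac_a: float = 0.10, frac_b: float = 0.50,
             n_batches: int = 20) -> float:
    """Geweke convergence Z: early-window vs late-window means.

    The variance of each window mean is estimated by batch means
    (``n_batches`` batches), a simple spectral-density-at-zero estimator.
    A chain with zero variance in both windows returns 0.0.
    """
    x = np.asarray(draws, dtype=float)
    n = len(x)
    if n < 2 * n_batches:
        raise ValueError(f"need at least {2 * n_batches} draws")
    a = x[: max(int(frac_a * n), n_batches)]
    b = x[n - max(int(frac_b * n), n_batches):]

    def batch_var_of_mean(seg: np.ndarray) -> float:
        k = len(seg) // n_batches
        means = seg[: k * n_batches].reshape(n_batches, k).mean(axis=1)
        return float(np.var(means, ddof=1) / n_batches)

    va, vb = batch_var_of_mean(a), batch_var_of_mean(b)
    if va + vb == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(va + vb))


# ---------------------------------------------------------------------------
# Design-matrix assembly
# ---------------------------------------------------------------------------

def _design(spec: ModelSpec, data: PhenotypeTable) -> np.ndarray:
    df = data.data
    blocks = []
    if spec.intercept:
        blocks.append(np.ones((len(df), 1)))
    for col in spec.fixed:
        levels = sorted(df[col].astype(str).unique())
        # drop-first under an intercept keeps X full rank
        use = levels[1:] if spec.intercept else levels
        for lv in use:
            blocks.append((df[col].astype(str) == lv).to_numpy(
                dtype=float)[:, None])
    for col in spec.covariates:
        blocks.append(df[col].to_numpy(dtype=float)[:, None])
    if not blocks:
        return np.zeros((len(df), 0))
    X = np.hstack(blocks)
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient "
                         f"(rank {r} < {X.shape[1]}); confounded terms?")
    return X


class _GeneticTerm:
    """Blocked sampler for one genetic vector given its inverse structure.

    Fast path: when every id of the relationship matrix carries exactly one
    record (Z'Z is a permuted identity), the full-conditional precision is
    diagonal in the precomputed eigenbasis of H^-1 and a joint draw costs
    two matrix-vector products.  Otherwise a dense Cholesky of the
    n x n precision is taken each iteration.
    """

    def __init__(self, hinv: RelationshipMatrix, rec_idx: np.ndarray,
                 n_records: int):
        Hd = hinv.dense()
        Hd = 0.5 * (Hd + Hd.T)
        self.n = len(Hd)
        self.rec_idx = rec_idx                      # record -> matrix row
        counts = np.bincount(rec_idx, minlength=self.n)
        self.counts = counts.astype(float)
        self.fast = bool(np.all(counts == 1))
        if self.fast:
            lam, U = scipy.linalg.eigh(Hd)
            lmax = lam[-1]
            if lam[0] < -1e-8 * max(lmax, 1.0):
                raise ValueError("inverse relationship matrix is not PSD "
                                 f"(min eigenvalue {lam[0]:.3e})")
            self.lam = np.clip(lam, 0.0, None)
            self.U = U
            # record r corresponds to matrix row rec_idx[r]
            self.perm = rec_idx
        else:
            self.H = Hd
        self.u = np.zeros(self.n)

    def gather(self) -> np.ndarray:
        """u mapped onto records (Z u)."""
        return self.u[self.rec_idx]

    def draw(self, partial_resid: np.ndarray, s2_u: float, s2_e: float,
             rng: np.random.Generator) -> None:
        rhs = np.zeros(self.n)
        np.add.at(rhs, self.rec_idx, partial_resid)
        rhs /= s2_e
        if self.fast:
            d = self.lam / s2_u + 1.0 / s2_e
            t = self.U.T @ rhs
            mean_t = t / d
            z = rng.standard_normal(self.n)
            self.u = self.U @ (mean_t + z / np.sqrt(d))
        else:
            P = self.H / s2_u + np.diag(self.counts / s2_e)
            c, low = scipy.linalg.cho_factor(P, check_finite=False)
            mean = scipy.linalg.cho_solve((c, low), rhs, check_finite=False)
            z = rng.standard_normal(self.n)
            # upper-triangular solve gives a draw with covariance P^-1
            Lt = c if not low else c.T
            self.u = mean + scipy.linalg.solve_triangular(
                Lt, z, lower=False, check_finite=False)

    def quad_form(self) -> float:
        """u' H^-1 u, used by the variance full conditional."""
        if self.fast:
            t = self.U.T @ self.u
            return float(np.sum(self.lam * t * t))
        return float(self.u @ (self.H @ self.u))


def _draw_variance(quad: float, n: int, cfg: ChainConfig,
                   rng: np.random.Generator) -> float:
    """Scaled-inverse-chi-square full conditional."""
    df = n + cfg.prior_df
    scale = quad + cfg.prior_df * cfg.prior_scale
    if df <= 0:
        raise ValueError("non-positive posterior degrees of freedom")
    return float(max(scale, 1e-12) / rng.chisquare(df))


def _truncated_normal(mean: np.ndarray, sd: float, lo: np.ndarray,
                      hi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from N(mean, sd^2) truncated to (lo, hi)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + (b - a) * rng.uniform(size=len(mean))
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return mean + sd * ndtri(u)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def gibbs_sample(spec: ModelSpec, data: PhenotypeTable,
                 hinv_auto: RelationshipMatrix,
                 hinv_x: RelationshipMatrix | None,
                 cfg: ChainConfig) -> PosteriorChains:
    """Run the blocked Gibbs sampler and return retained draws.

    ``hinv_auto`` (and optionally ``hinv_x``) are inverse relationship
    matrices covering every phenotyped animal.  Fixed effects get flat
    priors; variances scaled-inverse-chi-square priors from ``cfg``.
    Binary/ordinal traits are fitted on the liability scale with
    sigma2_e = 1.
    """
    spec.validate(data)
    rng = np.random.default_rng(cfg.seed)
    df = data.data
    ids = df["id"].to_numpy(dtype=object)
    n_obs = len(df)

    X = _design(spec, data)
    p_fix = X.shape[1]
    XtX = X.T @ X if p_fix else np.zeros((0, 0))
    if p_fix:
        XtX_chol = scipy.linalg.cho_factor(XtX + 1e-10 * np.eye(p_fix))

    terms: dict[str, _GeneticTerm] = {}
    terms["auto"] = _GeneticTerm(hinv_auto, hinv_auto.index_of(ids), n_obs)
    if hinv_x is not None:
        terms["x"] = _GeneticTerm(hinv_x, hinv_x.index_of(ids), n_obs)

    group_codes = None
    n_groups = 0
    if spec.random_group:
        labels, group_codes = np.unique(
            df[spec.random_group].astype(str), return_inverse=True)
        n_groups = len(labels)
        g_eff = np.zeros(n_groups)
        g_counts = np.bincount(group_codes, minlength=n_groups).astype(float)

    ordinal = spec.response_type in ("ordinal", "binary")
    y_obs = data.y
    if ordinal:
        K = (2 if spec.response_type == "binary"
             else (spec.n_categories or int(np.nanmax(y_obs))))
        cats = y_obs.astype(int)
        if cats.min() < 1 or cats.max() > K:
            raise ValueError(f"ordinal categories outside 1..{K}")
        thr = np.linspace(0.0, max(K - 2, 0), K - 1)  # t1 = 0 fixed
        y = _initial_liability(cats, thr, rng)
        s2_e = 1.0
    else:
        y = y_obs.astype(float)
        s2_e = float(np.var(y)) / 3.0 or 1.0

    s2 = {name: max(float(np.var(y)) / (len(terms) + 2), 1e-3)
          for name in terms}
    s2_g = max(float(np.var(y)) / 10.0, 1e-3) if spec.random_group else 0.0
    beta = np.zeros(p_fix)

    n_ret = retained_count(cfg)
    draws: dict[str, np.ndarray] = {f"s2_{k}": np.empty(n_ret) for k in terms}
    draws["s2_e"] = np.empty(n_ret)
    if spec.random_group:
        draws["s2_group"] = np.empty(n_ret)
    thr_draws = (np.empty((n_ret, K - 1)) if ordinal else None)

    def fitted(exclude: str | None = None) -> np.ndarray:
        out = X @ beta if p_fix else np.zeros(n_obs)
        for k, t in terms.items():
            if k != exclude:
                out = out + t.gather()
        if spec.random_group and exclude != "group":
            out = out + g_eff[group_codes]
        return out

    kept = 0
    for it in range(cfg.n_iter):
        if ordinal:
            # latent liabilities given current mean and thresholds
            lo = np.where(cats == 1, -np.inf,
                          thr[np.clip(cats - 2, 0, K - 2)])
            hi = np.where(cats == K, np.inf,
                          thr[np.clip(cats - 1, 0, K - 2)])
            y = _truncated_normal(fitted(), math.sqrt(s2_e), lo, hi, rng)
            if K > 2:
                for k in range(1, K - 1):  # t1 fixed at 0
                    below = y[cats == k + 1]
                    above = y[cats == k + 2]
                    lo_k = max(below.max() if len(below) else -np.inf,
                               thr[k - 1] if k >= 1 else -np.inf)
                    hi_k = min(above.min() if len(above) else np.inf,
                               thr[k + 1] if k + 1 < K - 1 else np.inf)
                    if not np.isfinite(lo_k):
                        lo_k = thr[k] - 1.0
                    if not np.isfinite(hi_k):
                        hi_k = thr[k] + 1.0
                    thr[k] = rng.uniform(lo_k, max(hi_k, lo_k + 1e-12))

        if p_fix:
            r = y - fitted() + X @ beta
            mean = scipy.linalg.cho_solve(XtX_chol, X.T @ r)
            z = rng.standard_normal(p_fix)
            half = scipy.linalg.solve_triangular(
                XtX_chol[0] if not XtX_chol[1] else XtX_chol[0].T,
                z, lower=False)
            beta = mean + math.sqrt(s2_e) * half

        for k, t in terms.items():
            t.draw(y - fitted(exclude=k), s2[k], s2_e, rng)
            s2[k] = _draw_variance(t.quad_form(), t.n, cfg, rng)

        if spec.random_group:
            r = y - fitted(exclude="group")
            rhs = np.bincount(group_codes, weights=r,
                              minlength=n_groups) / s2_e
            prec = g_counts / s2_e + 1.0 / s2_g
            g_eff = rhs / prec + rng.standard_normal(n_groups) / np.sqrt(prec)
            s2_g = _draw_variance(float(g_eff @ g_eff), n_groups, cfg, rng)

        if not ordinal:
            resid = y - fitted()
            s2_e = _draw_variance(float(resid @ resid), n_obs, cfg, rng)

        if max(max(s2.values()), s2_e) > 1e8:
            raise RuntimeError(
                f"divergent variance at iteration {it}: {s2}, s2_e={s2_e}")

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            if kept < n_ret:
                for k in terms:
                    draws[f"s2_{k}"][kept] = s2[k]
                draws["s2_e"][kept] = s2_e
                if spec.random_group:
                    draws["s2_group"][kept] = s2_g
                if ordinal:
                    thr_draws[kept] = thr
                kept += 1

    for k in draws:
        draws[k] = draws[k][:kept]
    return PosteriorChains(draws=draws, config=cfg, model=spec,
                           thresholds=(thr_draws[:kept] if ordinal else None))


def _initial_liability(cats: np.ndarray, thr: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Crude liability start values consistent with the category bounds."""
    K = len(thr) + 1
    lo = np.where(cats == 1, -1.5, thr[np.clip(cats - 2, 0, None)])
    hi = np.where(cats == K, (thr[-1] if K > 1 else 0.0) + 1.5,
                  thr[np.clip(cats - 1, 0, len(thr) - 1)])
    return lo + (hi - lo) * rng.uniform(size=len(cats))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _summary_entry(x: np.ndarray, mass: float = 0.90) -> dict:
    lo, hi = hpd_interval(x, mass)
    q = np.quantile(x, [0.05, 0.95])
    mcse = float(np.std(x, ddof=1) / math.sqrt(max(len(x), 1)))
    try:
        z = geweke_z(x)
    except ValueError:
        z = float("nan")
    return {"mean": float(np.mean(x)), "hpd": (lo, hi),
            "eq_tail": (float(q[0]), float(q[1])), "geweke": z, "mcse": mcse}


def summarize(chains: PosteriorChains, mass: float = 0.90) -> PosteriorSummary:
    """Posterior means, 90% HPD and equal-tail intervals, Geweke Z, and the
    per-draw heritability partition (posterior mean of ratios)."""
    if len(chains) == 0:
        raise ValueError("empty chains")
    params = {k: _summary_entry(v, mass) for k, v in chains.draws.items()}

    d = chains.draws
    s_auto = d.get("s2_auto")
    s_x = d.get("s2_x", np.zeros_like(s_auto))
    s_e = d["s2_e"]
    den = s_auto + s_x + s_e
    h2 = {"h2_auto": s_auto / den, "h2_x": s_x / den,
          "h2_total": (s_auto + s_x) / den}
    h2_summary = {k: _summary_entry(v, mass) for k, v in h2.items()}
    return PosteriorSummary(params=params, h2=h2_summary)


def chains_to_tsv(chains: PosteriorChains, path) -> None:
    """Write retained draws as TSV, one row per draw."""
    import pandas as pd

    cols = dict(chains.draws)
    if chains.thresholds is not None:
        for k in range(chains.thresholds.shape[1]):
            cols[f"threshold_{k + 1}"] = chains.thresholds[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
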
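"""Trait preparation, kinship, BSLMM posterior inference and polygenic scores.

The GWAS model is the Bayesian sparse linear mixed model

    y = 1 mu + X beta + u + eps,
    u ~ N(0, sigma_b^2 sigma_e^2 K),   eps ~ N(0, sigma_e^2 I),
    beta_j ~ pi N(0, sigma_a^2 sigma_e^2) + (1 - pi) delta_0,

with genotype columns standardized and hyperpriors h ~ U(0,1),
rho ~ U(0,1), log pi ~ U(log 1/p, 0).  (h, rho, pi) parameterize the slab
and random-effect scales as

    sigma_a^2 = h rho / ((1 - h) pi p),
    sigma_b^2 = h (1 - rho) / ((1 - h) kappa),   kappa = tr(K)/n,

so h is the expected fraction of variance that is genetic and rho the
sparse share of it.  Inference is a single-site spike-and-slab Gibbs
sampler with the kinship random effect handled in the eigenbasis of K
(where its components are independent), conjugate sigma_e^2 updates, and
random-walk Metropolis moves on (h, rho, log pi).  PVE is computed per
posterior sample as V(X beta + u) / (V(X beta + u) + sigma_e^2) using the
sample variance across individuals; the per-variant posterior inclusion
probability (PIP) is the inclusion fraction across samples, and the
model-averaged effect is the posterior mean of beta (zeros included).

Chains are bit-for-bit reproducible given (seed, config).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numba
import numpy as np
import pandas as pd
import scipy.stats

from migrasv.io import MISSING
from migrasv.svmerge import CohortSVMatrix

__all__ = [
    "PreparedTrait",
    "quantile_normalize",
    "regress_out_sex",
    "prepare_trait",
    "kinship",
    "BSLMMConfig",
    "GWASFit",
    "bslmm_fit",
    "PGSResult",
    "pgs_crossval",
    "genetic_correlation",
]


# ---------------------------------------------------------------------------
# trait preparation
# ---------------------------------------------------------------------------


@dataclass
class PreparedTrait:
    """Per-individual trait after sex regression and quantile transform."""

    values: np.ndarray  # NaN where missing
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)


def quantile_normalize(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Non-missing values map to Phi^-1((rank - 0.5) / m) with average ranks
    for ties; NaNs pass through.  Requires >= 5 non-missing values and a
    non-constant input.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    m = int(ok.sum())
    if m < 5:
        raise ValueError("quantile transform needs >= 5 non-missing values")
    if np.all(values[ok] == values[ok][0]):
        raise ValueError("quantile transform undefined for a constant trait")
    ranks = scipy.stats.rankdata(values[ok], method="average")
    out = np.full_like(values, np.nan)
    out[ok] = scipy.stats.norm.ppf((ranks - 0.5) / m)
    return out


def regress_out_sex(values: Sequence[float], sex: Sequence[str]) -> np.ndarray:
    """OLS residuals of the trait on a sex indicator (applied before the
    quantile transform).  With a single sex present the values are
    returned unchanged with a warning."""
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    ok = np.isfinite(values)
    is_f = (sex == "F").astype(float)
    if len(set(sex[ok])) < 2:
        warnings.warn("only one sex present; sex regression skipped", stacklevel=2)
        return values.copy()
    X = np.column_stack([np.ones(ok.sum()), is_f[ok]])
    coef, *_ = np.linalg.lstsq(X, values[ok], rcond=None)
    out = values.copy()
    out[ok] = values[ok] - X @ coef
    return out


def prepare_trait(values: Sequence[float], sex: Sequence[str] | None = None) -> PreparedTrait:
    """Sex regression followed by the rank-based normal quantile transform."""
    values = np.asarray(values, dtype=float)
    if sex is not None:
        values = regress_out_sex(values, sex)
    transformed = quantile_normalize(values)
    return PreparedTrait(values=transformed, missing_mask=~np.isfinite(transformed))


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship(matrix: CohortSVMatrix) -> np.ndarray:
    """Realized-relationship matrix K = W W^T / p from centered dosages.

    Missing dosages are mean-imputed per locus before centering.
    """
    if matrix.n_loci == 0:
        raise ValueError("kinship needs >= 1 locus")
    W = matrix.dosages.astype(float).T  # individuals x loci
    miss = matrix.dosages.T == MISSING
    W[miss] = np.nan
    means = np.nanmean(W, axis=0)
    W = np.where(np.isnan(W), means, W) - means
    return W @ W.T / matrix.n_loci


# ---------------------------------------------------------------------------
# BSLMM sampler
# ---------------------------------------------------------------------------


@dataclass
class BSLMMConfig:
    """MCMC settings; the defaults are a desk-scale configuration.

    ``h_fixed``, ``rho_fixed``, ``pi_fixed`` and ``sigma_e2_fixed`` pin a
    hyperparameter instead of sampling it (used to reach the Bayesian
    ridge / pure-LMM special cases).
    """

    burn_in: int = 10_000
    steps: int = 100_000
    thin: int = 10
    n_chains: int = 4
    seed: int = 0
    mh_step: float = 0.5
    h_fixed: float | None = None
    rho_fixed: float | None = None
    pi_fixed: float | None = None
    sigma_e2_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.steps <= 0 or self.burn_in < 0 or self.n_chains < 1:
            raise ValueError("steps must be > 0, burn_in >= 0, n_chains >= 1")
        if not (0 < self.thin <= self.steps):
            raise ValueError("thin must be in (0, steps]")


@numba.njit(cache=True)
def _logtarget_hrho(h, rho, pi, p, kappa, ng, npos, ssb_raw, ssu_raw, se2,
                    h_free, rho_free):  # pragma: no cover - numba
    if h <= 0.0 or h >= 1.0 or rho < 0.0 or rho > 1.0:
        return -np.inf
    sa2 = h * rho / ((1.0 - h) * pi * p)
    sb2 = h * (1.0 - rho) / ((1.0 - h) * kappa)
    lt = 0.0
    if ng > 0:
        if sa2 <= 0.0:
            return -np.inf
        lt += -0.5 * (ng * np.log(sa2 * se2) + ssb_raw / (sa2 * se2))
    if sb2 > 0.0:
        lt += -0.5 * (npos * np.log(sb2 * se2) + ssu_raw / (sb2 * se2))
    elif ssu_raw > 0.0:
        return -np.inf
    if h_free:
        lt += np.log(h * (1.0 - h))  # logit-transform Jacobian, uniform prior
    if rho_free:
        lt += np.log(max(rho * (1.0 - rho), 1e-300))
    return lt


@numba.njit(cache=True)
def _bslmm_kernel(Xt, yt, c, d, colsq, kappa, burn, steps, thin, seed,
                  fix_h, fix_rho, fix_pi, fix_se2, mh_step):  # pragma: no cover - numba
    np.random.seed(seed)
    n, p = Xt.shape
    n_rec = (steps + thin - 1) // thin
    samples = np.zeros((n_rec, 7))
    pip_counts = np.zeros(p)
    beta_sum = np.zeros(p)
    mu_sum = 0.0

    h = fix_h if not np.isnan(fix_h) else 0.5
    rho = fix_rho if not np.isnan(fix_rho) else 0.5
    pi = fix_pi if not np.isnan(fix_pi) else min(0.5, 10.0 / p)
    pi = max(pi, 1.0 / p)
    logpi_lo = np.log(1.0 / p)

    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=np.int8)
    u = np.zeros(n)
    csq = 0.0
    for i in range(n):
        csq += c[i] * c[i]
    ymean = 0.0
    for i in range(n):
        ymean += c[i] * yt[i]
    mu = ymean / csq
    r = np.empty(n)
    yvar = 0.0
    for i in range(n):
        r[i] = yt[i] - mu * c[i]
        yvar += r[i] * r[i]
    se2 = fix_se2 if not np.isnan(fix_se2) else max(yvar / (n - 1), 1e-8)
    npos = 0
    for i in range(n):
        if d[i] > 0.0:
            npos += 1

    rec = 0
    total = burn + steps
    for it in range(total):
        sa2 = h * rho / ((1.0 - h) * pi * p)
        sb2 = h * (1.0 - rho) / ((1.0 - h) * kappa)

        # --- single-site spike-slab sweep over loci ---
        ng = 0
        for j in range(p):
            bj = beta[j]
            if bj != 0.0:
                for i in range(n):
                    r[i] += Xt[i, j] * bj
            a = colsq[j]
            if a <= 0.0 or sa2 <= 0.0:
                beta[j] = 0.0
                gamma[j] = 0
                continue
            b = 0.0
            for i in range(n):
                b += Xt[i, j] * r[i]
            v = sa2 * se2
            prec = a / se2 + 1.0 / v
            m = b / (se2 * prec)
            include = False
            if pi >= 1.0:
                include = True
            else:
                logbf = 0.5 * (-np.log(v) - np.log(prec)) + 0.5 * m * m * prec
                lo = np.log(pi) - np.log(1.0 - pi) + logbf
                if lo > 35.0:
                    include = True
                elif lo < -35.0:
                    include = False
                else:
                    include = np.random.random() < 1.0 / (1.0 + np.exp(-lo))
            if include:
                bnew = m + np.random.normal() / np.sqrt(prec)
                beta[j] = bnew
                gamma[j] = 1
                ng += 1
                for i in range(n):
                    r[i] -= Xt[i, j] * bnew
            else:
                beta[j] = 0.0
                gamma[j] = 0

        # --- random effect in the eigenbasis ---
        if sb2 > 0.0:
            for i in range(n):
                ti = r[i] + u[i]
                vi = sb2 * se2 * d[i]
                if vi <= 0.0:
                    u[i] = 0.0
                    r[i] = ti
                else:
                    w = vi / (vi + se2)
                    ui = w * ti + np.random.normal() * np.sqrt(w * se2)
                    u[i] = ui
                    r[i] = ti - ui
        else:
            for i in range(n):
                r[i] += u[i]
                u[i] = 0.0

        # --- intercept ---
        num = 0.0
        for i in range(n):
            r[i] += mu * c[i]
            num += c[i] * r[i]
        mu = num / csq + np.random.normal() * np.sqrt(se2 / csq)
        for i in range(n):
            r[i] -= mu * c[i]

        # --- residual variance (conjugate, prior ~ 1/sigma_e^2) ---
        ssb_raw = 0.0
        for j in range(p):
            if gamma[j] == 1:
                ssb_raw += beta[j] * beta[j]
        ssu_raw = 0.0
        for i in range(n):
            if d[i] > 0.0:
                ssu_raw += u[i] * u[i] / d[i]
        if np.isnan(fix_se2):
            ssr = 0.0
            for i in range(n):
                ssr += r[i] * r[i]
            k = float(n)
            scale = ssr
            if ng > 0 and sa2 > 0.0:
                scale += ssb_raw / sa2
                k += ng
            if sb2 > 0.0:
                scale += ssu_raw / sb2
                k += npos
            g = np.random.gamma(0.5 * k, 1.0)
            se2 = max(0.5 * scale / max(g, 1e-300), 1e-12)

        # --- MH on h and rho ---
        h_free = np.isnan(fix_h)
        rho_free = np.isnan(fix_rho)
        if h_free or rho_free:
            for _ in range(2):
                cur = _logtarget_hrho(h, rho, pi, p, kappa, ng, npos,
                                      ssb_raw, ssu_raw, se2, h_free, rho_free)
                if h_free:
                    lh = np.log(h / (1.0 - h)) + np.random.normal() * mh_step
                    hp = 1.0 / (1.0 + np.exp(-lh))
                    hp = min(max(hp, 1e-8), 1.0 - 1e-8)
                    prop = _logtarget_hrho(hp, rho, pi, p, kappa, ng, npos,
                                           ssb_raw, ssu_raw, se2, h_free, rho_free)
                    if np.log(np.random.random() + 1e-300) < prop - cur:
                        h = hp
                        cur = prop
                if rho_free:
                    rr = min(max(rho, 1e-8), 1.0 - 1e-8)
                    lr = np.log(rr / (1.0 - rr)) + np.random.normal() * mh_step
                    rp = 1.0 / (1.0 + np.exp(-lr))
                    rp = min(max(rp, 1e-8), 1.0 - 1e-8)
                    prop = _logtarget_hrho(h, rp, pi, p, kappa, ng, npos,
                                           ssb_raw, ssu_raw, se2, h_free, rho_free)
                    if np.log(np.random.random() + 1e-300) < prop - cur:
                        rho = rp

        # --- MH on log pi ---
        if np.isnan(fix_pi):
            logpi = np.log(pi)
            for _ in range(2):
                lp_prop = logpi + np.random.normal() * mh_step
                if lp_prop < logpi_lo or lp_prop > -1e-9:
                    continue
                pi_prop = np.exp(lp_prop)
                sa2_cur = h * rho / ((1.0 - h) * pi * p)
                sa2_prop = h * rho / ((1.0 - h) * pi_prop * p)
                cur = ng * logpi + (p - ng) * np.log(1.0 - pi)
                prop = ng * lp_prop + (p - ng) * np.log(1.0 - pi_prop)
                if ng > 0:
                    cur += -0.5 * (ng * np.log(sa2_cur * se2) + ssb_raw / (sa2_cur * se2))
                    prop += -0.5 * (ng * np.log(sa2_prop * se2) + ssb_raw / (sa2_prop * se2))
                if np.log(np.random.random() + 1e-300) < prop - cur:
                    logpi = lp_prop
                    pi = pi_prop

        # --- record ---
        if it >= burn and (it - burn) % thin == 0:
            varg = 0.0
            gm = 0.0
            gsq = 0.0
            for i in range(n):
                gi = yt[i] - mu * c[i] - r[i]
                gm += c[i] * gi
                gsq += gi * gi
            gm /= n
            varg = (gsq - n * gm * gm) / (n - 1)
            if varg < 0.0:
                varg = 0.0
            samples[rec, 0] = h
            samples[rec, 1] = rho
            samples[rec, 2] = pi
            samples[rec, 3] = varg / (varg + se2)
            samples[rec, 4] = se2
            samples[rec, 5] = sb2 * se2
            samples[rec, 6] = ng
            for j in range(p):
                if gamma[j] == 1:
                    pip_counts[j] += 1.0
                    beta_sum[j] += beta[j]
            mu_sum += mu
            rec += 1
    return samples, pip_counts, beta_sum, mu_sum


@dataclass
class GWASFit:
    """Posterior summaries of a BSLMM fit.

    ``pip`` and ``beta_bar`` (model-averaged effects on the standardized
    genotype scale) cover all loci of the input matrix; loci with zero
    variance get PIP 0.  ``samples`` holds the thinned post-burn-in draws
    of the hyperparameters, PVE and residual variance, pooled across
    chains with a ``chain`` column.
    """

    pip: np.ndarray
    beta_bar: np.ndarray
    samples: pd.DataFrame
    pve_mean: float
    pve_sd: float
    pve_per_chain: np.ndarray
    mu_mean: float
    se2_mean: float
    vu_mean: float  # posterior mean of sigma_b^2 sigma_e^2 (scale of K)
    locus_means: np.ndarray = field(repr=False, default=None)
    locus_sds: np.ndarray = field(repr=False, default=None)
    active: np.ndarray = field(repr=False, default=None)
    individuals: list[str] = field(repr=False, default=None)


def _standardized_genotypes(
    dosages: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    X = dosages.astype(float).T  # individuals x loci
    X[dosages.T == MISSING] = np.nan
    means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), means, X)
    sds = X.std(axis=0, ddof=1)
    active = sds > 0
    Xs = (X[:, active] - means[active]) / sds[active]
    return Xs, means, sds, active


def bslmm_fit(
    trait: PreparedTrait | np.ndarray,
    matrix: CohortSVMatrix,
    K: np.ndarray | None = None,
    config: BSLMMConfig | None = None,
) -> GWASFit:
    """Sample the BSLMM posterior for one trait.

    ``trait`` must be complete (no NaN) over the matrix's individuals;
    subset the matrix to phenotyped individuals first.
    """
    config = config or BSLMMConfig()
    y = trait.values if isinstance(trait, PreparedTrait) else np.asarray(trait, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trait contains non-finite values; subset individuals first")
    n = matrix.n_individuals
    if len(y) != n:
        raise ValueError("trait length does not match matrix individuals")
    if matrix.n_loci == 0:
        raise ValueError("empty matrix")
    Xs, means, sds, active = _standardized_genotypes(matrix.dosages)
    if K is None:
        K = kinship(matrix)
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    Xt = np.ascontiguousarray(U.T @ Xs)
    yt = U.T @ y
    c = U.T @ np.ones(n)
    colsq = (Xt**2).sum(axis=0)
    kappa = float(d.mean()) if d.mean() > 0 else 1.0

    def nanf(v):
        return np.nan if v is None else float(v)

    all_samples = []
    p_active = Xs.shape[1]
    pip = np.zeros(p_active)
    beta_bar = np.zeros(p_active)
    mu_total = 0.0
    n_rec_total = 0
    pve_chain = []
    for chain in range(config.n_chains):
        chain_seed = int((config.seed + 1_000_003 * (chain + 1)) % (2**31 - 1))
        samples, pip_counts, beta_sum, mu_sum = _bslmm_kernel(
            Xt, yt, c, d, colsq, kappa,
            config.burn_in, config.steps, config.thin, chain_seed,
            nanf(config.h_fixed), nanf(config.rho_fixed),
            nanf(config.pi_fixed), nanf(config.sigma_e2_fixed),
            float(config.mh_step),
        )
        n_rec = samples.shape[0]
        df = pd.DataFrame(
            samples, columns=["h", "rho", "pi", "pve", "sigma_e2", "v_u", "n_gamma"]
        )
        df["chain"] = chain
        all_samples.append(df)
        pip += pip_counts
        beta_bar += beta_sum
        mu_total += mu_sum
        n_rec_total += n_rec
        pve_chain.append(float(samples[:, 3].mean()))
    pooled = pd.concat(all_samples, ignore_index=True)
    pip /= n_rec_total
    beta_bar /= n_rec_total
    pip_full = np.zeros(matrix.n_loci)
    beta_full = np.zeros(matrix.n_loci)
    pip_full[active] = pip
    beta_full[active] = beta_bar
    return GWASFit(
        pip=pip_full,
        beta_bar=beta_full,
        samples=pooled,
        pve_mean=float(pooled["pve"].mean()),
        pve_sd=float(pooled["pve"].std(ddof=1)),
        pve_per_chain=np.array(pve_chain),
        mu_mean=mu_total / n_rec_total,
        se2_mean=float(pooled["sigma_e2"].mean()),
        vu_mean=float(pooled["v_u"].mean()),
        locus_means=means,
        locus_sds=sds,
        active=active,
        individuals=list(matrix.individuals),
    )


# ---------------------------------------------------------------------------
# polygenic-score cross-validation
# ---------------------------------------------------------------------------


@dataclass
class PGSResult:
    fold_assignment: np.ndarray  # per individual, 0..n_folds-1
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    p_value: float


def _blup_prediction(
    fit: GWASFit,
    dosages: np.ndarray,
    K: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    y_train: np.ndarray,
) -> np.ndarray:
    """mu + x beta_bar + conditional mean of the random effect.

    The random-effect term is the BLUP E[u_test | training residuals]
    under u ~ N(0, Vu K) with Vu and sigma_e^2 at their posterior means.
    """
    X = dosages.astype(float).T
    X[dosages.T == MISSING] = np.nan
    X = np.where(np.isnan(X), fit.locus_means, X)
    Xs = (X[:, fit.active] - fit.locus_means[fit.active]) / fit.locus_sds[fit.active]
    fixed = fit.mu_mean + Xs @ fit.beta_bar[fit.active]
    resid_train = y_train - fixed[train_idx]
    vu, se2 = fit.vu_mean, fit.se2_mean
    A = vu * K[np.ix_(train_idx, train_idx)] + se2 * np.eye(len(train_idx))
    u_test = vu * K[np.ix_(test_idx, train_idx)] @ np.linalg.solve(A, resid_train)
    return fixed[test_idx] + u_test


def pgs_crossval(
    trait: PreparedTrait | np.ndarray,
    matrix: CohortSVMatrix,
    K: np.ndarray | None = None,
    config: BSLMMConfig | None = None,
    n_folds: int = 4,
    mask_fraction: float = 0.25,
    seed: int = 0,
) -> PGSResult:
    """Masked-phenotype cross-validation yielding per-individual polygenic scores.

    Individuals are randomly partitioned into ``n_folds`` disjoint folds
    (about ``mask_fraction`` each); each fold's phenotypes are masked and
    predicted from a BSLMM trained on the rest, so every individual is
    predicted exactly once.  The returned r and p come from an ordinary
    least-squares fit of observed on predicted values.
    """
    config = config or BSLMMConfig()
    y = trait.values if isinstance(trait, PreparedTrait) else np.asarray(trait, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trait contains non-finite values")
    n = matrix.n_individuals
    if abs(n_folds * mask_fraction - 1.0) > 0.25:
        warnings.warn("mask_fraction and n_folds are inconsistent", stacklevel=2)
    if K is None:
        K = kinship(matrix)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    if min(len(f) for f in folds) < 2:
        raise ValueError("each fold needs >= 2 individuals")
    assignment = np.empty(n, dtype=int)
    predicted = np.empty(n)
    for k, test_idx in enumerate(folds):
        assignment[test_idx] = k
        train_idx = np.sort(np.setdiff1d(order, test_idx))
        sub = matrix.subset_individuals(train_idx.tolist())
        fold_config = replace(config, seed=int((config.seed + 7919 * (k + 1)) % (2**31 - 1)))
        fit = bslmm_fit(y[train_idx], sub, K=K[np.ix_(train_idx, train_idx)], config=fold_config)
        predicted[test_idx] = _blup_prediction(
            fit, matrix.dosages, K, train_idx, test_idx, y[train_idx]
        )
    res = scipy.stats.linregress(predicted, y)
    return PGSResult(
        fold_assignment=assignment,
        predicted=predicted,
        observed=y.copy(),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
    )


def genetic_correlation(
    fits: Mapping[str, GWASFit], pip_threshold: float = 0.01
) -> pd.DataFrame:
    """Pairwise Pearson correlation of model-averaged effects.

    For each trait pair the union of variants with PIP above the
    threshold in either trait is used; pairs with < 3 such variants are
    NaN.  The diagonal is 1.
    """
    names = list(fits)
    if len(names) < 2:
        raise ValueError("need >= 2 traits")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            sel = (fits[a].pip > pip_threshold) | (fits[b].pip > pip_threshold)
            if sel.sum() < 3:
                value = np.nan
            else:
                value = float(np.corrcoef(fits[a].beta_bar[sel], fits[b].beta_bar[sel])[0, 1])
            out.loc[a, b] = out.loc[b, a] = value
    return out
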
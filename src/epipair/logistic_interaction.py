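"""Stage-2 test: logistic regression with a multiplicative interaction term.

The model is logit P(D=1) = b0 + b1*snp1 + b2*snp2 + b3*snp1*snp2 + sum(bi*cov_i)
with additive dosage coding (0-2, possibly fractional for imputed data).  The
interaction null b3 = 0 is tested with a Wald z statistic; exp(b3) is the
interaction odds ratio reported per cohort and pooled downstream.

Fitting is maximum likelihood by iteratively reweighted least squares with
step halving; the covariance is the inverse observed information at the
optimum.  Quasi-complete separation is detected by a coefficient-magnitude
heuristic on the genetic terms and flagged (p set to NaN) rather than
silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .core_io import GenotypeStudy

__all__ = [
    "LogisticFit",
    "InteractionResult",
    "PCResult",
    "fit_logistic",
    "interaction_test",
    "compute_pcs",
    "CollinearityError",
]

MAX_ITER = 50
SCORE_TOL = 1e-8
LOGLIK_RTOL = 1e-10
SEPARATION_BETA = 30.0  # |beta| beyond this on a genetic term flags separation


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    separated: bool
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class InteractionResult:
    """Logistic interaction fit for one SNP pair in one cohort."""

    snp1: str
    snp2: str
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    covariate_betas: dict[str, float]
    se3: float
    or_interaction: float
    p: float
    n_used: int
    converged: bool


@dataclass
class PCResult:
    components: np.ndarray       # samples x k scores
    explained_variance: np.ndarray  # k values, nonincreasing


def _check_rank(X: np.ndarray, names: list[str] | None) -> None:
    """Reject rank-deficient designs, naming the dependent columns."""
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = sorted(piv[rank:])
        labels = [names[j] if names else f"column {j}" for j in bad]
        raise CollinearityError(f"design matrix is rank deficient; collinear columns: {labels}")


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    column_names: list[str] | None = None,
    genetic_cols: list[int] | None = None,
    max_iter: int = MAX_ITER,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS with step halving.

    Converges when max |score| < 1e-8 or the relative log-likelihood change
    drops below 1e-10 (at most 50 iterations).  ``genetic_cols`` are the
    columns watched for separation: if any of their coefficients exceeds 30 in
    absolute value the fit is flagged ``separated`` and not converged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be n x p and y length n")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary 0/1")
    _check_rank(X, column_names)

    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        info = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the likelihood monotone
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            eta = X @ cand
            mu_c = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
            mu_c = np.clip(mu_c, 1e-300, 1 - 1e-16)
            new_ll = float(np.sum(y * np.log(mu_c) + (1 - y) * np.log1p(-mu_c)))
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        beta, mu = cand, mu_c
        if abs(new_ll - ll) < LOGLIK_RTOL * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    watch = genetic_cols if genetic_cols is not None else list(range(p))
    separated = bool(np.any(np.abs(beta[watch]) > SEPARATION_BETA))
    w = np.clip(mu * (1.0 - mu), 1e-300, None)
    info = X.T @ (w[:, None] * X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        separated = True
    return LogisticFit(
        coef=beta, cov=cov, loglik=ll,
        converged=converged and not separated,
        separated=separated, n_iter=it,
    )


def interaction_test(
    study: GenotypeStudy,
    snp1: str,
    snp2: str,
    covariate_names: tuple[str, ...] | list[str] = (),
) -> InteractionResult:
    """Fit the interaction model for one SNP pair in one cohort.

    Design is [1, g1, g2, g1*g2, covariates] on additive dosages; samples with
    a missing value in either SNP or any covariate are dropped (complete-case).
    Returns the Wald test of the interaction coefficient; a separated fit is
    flagged not-converged with p = NaN.
    """
    g1 = study.genotype(snp1)
    g2 = study.genotype(snp2)
    C = study.covariate_matrix(tuple(covariate_names))
    if study.status is None:
        raise ValueError(f"study {study.name!r} has no case/control status")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if C.size:
        ok &= ~np.isnan(C).any(axis=1)
    g1, g2, y = g1[ok], g2[ok], np.asarray(study.status, float)[ok]
    C = C[ok]
    X = np.column_stack([np.ones(g1.size), g1, g2, g1 * g2, C])
    names = ["intercept", snp1, snp2, f"{snp1}x{snp2}", *covariate_names]
    fit = fit_logistic(X, y, column_names=names, genetic_cols=[1, 2, 3])
    beta = fit.coef
    se3 = float(fit.se[3])
    if fit.separated or not np.isfinite(se3) or se3 == 0.0:
        p = float("nan")
    else:
        p = float(2.0 * stats.norm.sf(abs(beta[3] / se3)))
        p = max(p, np.nextafter(0, 1))
    return InteractionResult(
        snp1=snp1, snp2=snp2,
        beta0=float(beta[0]), beta1=float(beta[1]),
        beta2=float(beta[2]), beta3=float(beta[3]),
        covariate_betas={c: float(b) for c, b in zip(covariate_names, beta[4:])},
        se3=se3,
        or_interaction=float(np.exp(beta[3])),
        p=p,
        n_used=int(g1.size),
        converged=fit.converged,
    )


def compute_pcs(study: GenotypeStudy, k: int) -> PCResult:
    """Principal components of the column-standardized dosage matrix.

    Zero-variance SNPs are dropped; missing dosages are mean-imputed (i.e.
    set to 0 after centering) before the SVD.  Sign convention: the
    largest-magnitude SNP loading of each component is positive.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k == 0:
        return PCResult(
            components=np.empty((study.n_samples, 0)), explained_variance=np.empty(0)
        )
    D = study.dosage.copy()
    mean = np.nanmean(D, axis=0)
    D = np.where(np.isnan(D), mean, D)
    sd = D.std(axis=0, ddof=0)
    keep = sd > 0
    Z = (D[:, keep] - mean[keep]) / sd[keep]
    rank = min(Z.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank bound {rank} of the standardized matrix")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = (U * S) * flip
    var = S**2 / max(Z.shape[0] - 1, 1)
    return PCResult(components=scores[:, :k], explained_variance=var[:k])
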
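"""Characterization of significant SNP pairs.

Three views of an interaction:

* stratified association -- the tested SNP's marginal (additive) effect fitted
  separately in carriers vs non-carriers of the partner SNP's minor allele;
* joint-genotype odds ratios -- carrier patterns 1/0, 0/1 and 1/1 each get an
  indicator in one logistic model, with the double non-carrier group 0/0 as
  the reference (OR = 1 by construction);
* expression interaction -- an ordinary linear model of an expression trait on
  dominant-coded genotypes d1 + d2 + d1*d2 (+ covariates), the eQTL-style
  test of whether the two loci jointly shift expression.

Dominant coding collapses a dosage to carrier status: 1 when dosage >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core_io import GenotypeStudy
from .logistic_interaction import CollinearityError, fit_logistic

__all__ = [
    "StratumFit",
    "StratifiedResult",
    "JointGenotypeResult",
    "ExpressionInteractionResult",
    "dominant_code",
    "stratified_association",
    "joint_genotype_or",
    "eqtl_interaction",
]

MIN_PER_ARM = 10   # cases and controls needed to estimate a stratum
MIN_GROUP_N = 5    # joint-genotype group size below which the eQTL fit is flagged
CARRIER_DOSAGE = 0.5  # dosage at or above this counts as carrying the minor allele


def dominant_code(g: np.ndarray) -> np.ndarray:
    """Carrier status: 1 iff dosage >= 0.5 (hard calls: g >= 1); NaN propagates."""
    g = np.asarray(g, dtype=float)
    out = (g >= CARRIER_DOSAGE).astype(float)
    out[np.isnan(g)] = np.nan
    return out


@dataclass
class StratumFit:
    or_value: float
    p: float
    n: int
    estimable: bool
    note: str = ""


@dataclass
class StratifiedResult:
    snp_tested: str
    snp_conditioning: str
    strata: dict[int, StratumFit]


@dataclass
class GroupFit:
    label: str
    or_value: float
    p: float
    n: int
    estimable: bool


@dataclass
class JointGenotypeResult:
    snp1: str
    snp2: str
    groups: dict[str, GroupFit]  # keys "0/0", "1/0", "0/1", "1/1"


@dataclass
class ExpressionInteractionResult:
    probe: str
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    group_means: dict[str, float]
    group_counts: dict[str, int]
    fragile: bool  # some joint-genotype group has fewer than MIN_GROUP_N samples
    covariate_betas: dict[str, float] = field(default_factory=dict)


def _complete_case(study: GenotypeStudy, snps: list[str], covariate_names) -> tuple:
    gs = [study.genotype(s) for s in snps]
    C = study.covariate_matrix(tuple(covariate_names))
    ok = np.ones(study.n_samples, dtype=bool)
    for g in gs:
        ok &= ~np.isnan(g)
    if C.size:
        ok &= ~np.isnan(C).any(axis=1)
    y = np.asarray(study.status, dtype=float)[ok]
    return [g[ok] for g in gs], C[ok], y


def stratified_association(
    study: GenotypeStudy,
    snp_tested: str,
    snp_conditioning: str,
    covariate_names: tuple[str, ...] | list[str] = (),
) -> StratifiedResult:
    """Single-SNP association of ``snp_tested`` within carrier strata of the partner.

    Samples are split by dominant-coded genotype at ``snp_conditioning``
    (0 = no minor allele, 1 = at least one copy); within each stratum, a
    logistic model of status on the additive dosage of ``snp_tested`` plus
    covariates gives the stratum OR and Wald p.  A stratum with fewer than 10
    cases or 10 controls is reported as not estimable.
    """
    if study.status is None:
        raise ValueError(f"study {study.name!r} has no case/control status")
    (gt, gc), C, y = _complete_case(study, [snp_tested, snp_conditioning], covariate_names)
    carrier = dominant_code(gc)
    strata: dict[int, StratumFit] = {}
    for level in (0, 1):
        sel = carrier == level
        n = int(sel.sum())
        n_case = int(y[sel].sum())
        n_ctrl = n - n_case
        if n_case < MIN_PER_ARM or n_ctrl < MIN_PER_ARM:
            strata[level] = StratumFit(
                or_value=float("nan"), p=float("nan"), n=n, estimable=False,
                note=f"stratum has {n_case} cases / {n_ctrl} controls (need >= {MIN_PER_ARM} each)",
            )
            continue
        X = np.column_stack([np.ones(n), gt[sel], C[sel]])
        names = ["intercept", snp_tested, *covariate_names]
        try:
            fit = fit_logistic(X, y[sel], column_names=names, genetic_cols=[1])
        except CollinearityError as exc:
            strata[level] = StratumFit(float("nan"), float("nan"), n, False, str(exc))
            continue
        beta, se = fit.coef[1], fit.se[1]
        if fit.separated or not np.isfinite(se) or se == 0:
            strata[level] = StratumFit(float("nan"), float("nan"), n, False, "separation")
            continue
        p = float(2.0 * stats.norm.sf(abs(beta / se)))
        strata[level] = StratumFit(
            or_value=float(np.exp(beta)), p=max(p, np.nextafter(0, 1)), n=n, estimable=True,
        )
    return StratifiedResult(snp_tested=snp_tested, snp_conditioning=snp_conditioning, strata=strata)


def joint_genotype_or(
    study: GenotypeStudy,
    snp1: str,
    snp2: str,
    covariate_names: tuple[str, ...] | list[str] = (),
) -> JointGenotypeResult:
    """Odds ratios of the carrier patterns 1/0, 0/1 and 1/1 versus reference 0/0.

    One logistic model with three pattern indicators (+ covariates); the
    exponentiated coefficients are the group ORs.  The reference group's OR is
    1 by construction; an empty pattern group is reported as not estimable.
    """
    if study.status is None:
        raise ValueError(f"study {study.name!r} has no case/control status")
    (g1, g2), C, y = _complete_case(study, [snp1, snp2], covariate_names)
    d1, d2 = dominant_code(g1), dominant_code(g2)
    patterns = {"1/0": (1, 0), "0/1": (0, 1), "1/1": (1, 1)}
    indicators = {k: ((d1 == a) & (d2 == b)).astype(float) for k, (a, b) in patterns.items()}
    counts = {k: int(v.sum()) for k, v in indicators.items()}
    counts["0/0"] = int(((d1 == 0) & (d2 == 0)).sum())
    present = [k for k in patterns if counts[k] > 0]
    X = np.column_stack([np.ones(y.size)] + [indicators[k] for k in present] + [C])
    names = ["intercept", *present, *covariate_names]
    fit = fit_logistic(X, y, column_names=names, genetic_cols=list(range(1, 1 + len(present))))
    groups: dict[str, GroupFit] = {
        "0/0": GroupFit("0/0", 1.0, float("nan"), counts["0/0"], True)
    }
    for k in patterns:
        if k not in present:
            groups[k] = GroupFit(k, float("nan"), float("nan"), 0, False)
            continue
        j = 1 + present.index(k)
        beta, se = fit.coef[j], fit.se[j]
        if fit.separated or not np.isfinite(se) or se == 0:
            groups[k] = GroupFit(k, float("nan"), float("nan"), counts[k], False)
            continue
        p = float(2.0 * stats.norm.sf(abs(beta / se)))
        groups[k] = GroupFit(k, float(np.exp(beta)), max(p, np.nextafter(0, 1)),
                             counts[k], True)
    return JointGenotypeResult(snp1=snp1, snp2=snp2, groups=groups)


def eqtl_interaction(
    expression: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] | list[str] = (),
    probe: str = "trait",
) -> ExpressionInteractionResult:
    """Linear-model test of a genotype-by-genotype effect on an expression trait.

    OLS of expression on d1 + d2 + d1*d2 (+ covariates) with dominant-coded
    genotypes; the interaction p comes from the t statistic of the product
    term.  Group means over the four joint-carrier groups are reported on the
    samples entering the model; if any group has fewer than 5 samples the
    result is flagged fragile (estimable, but resting on few individuals).
    """
    expression = np.asarray(expression, dtype=float)
    d1, d2 = dominant_code(g1), dominant_code(g2)
    C = np.empty((expression.size, 0)) if covariates is None else np.asarray(covariates, float)
    ok = ~(np.isnan(expression) | np.isnan(d1) | np.isnan(d2))
    if C.size:
        ok &= ~np.isnan(C).any(axis=1)
    e, d1, d2, C = expression[ok], d1[ok], d2[ok], C[ok]
    X = np.column_stack([np.ones(e.size), d1, d2, d1 * d2, C])
    fit = sm.OLS(e, X).fit()
    group_means: dict[str, float] = {}
    group_counts: dict[str, int] = {}
    for label, (a, b) in (("0/0", (0, 0)), ("1/0", (1, 0)), ("0/1", (0, 1)), ("1/1", (1, 1))):
        sel = (d1 == a) & (d2 == b)
        group_counts[label] = int(sel.sum())
        group_means[label] = float(e[sel].mean()) if sel.any() else float("nan")
    return ExpressionInteractionResult(
        probe=probe,
        beta_interaction=float(fit.params[3]),
        se_interaction=float(fit.bse[3]),
        p_interaction=float(fit.pvalues[3]),
        group_means=group_means,
        group_counts=group_counts,
        fragile=any(n < MIN_GROUP_N for n in group_counts.values()),
        covariate_betas={c: float(b) for c, b in zip(covariate_names, fit.params[4:])},
    )
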
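"""Fixed-effect meta-analysis across cohorts, heterogeneity, and replication rules.

Per-cohort interaction estimates are pooled on the log odds ratio scale by
inverse-variance weighting (one common effect assumed).  Cochran's Q and I^2
quantify heterogeneity.  When only a published (OR, p) pair is available for
a cohort, the standard error is recovered from the normal quantile,
se = |ln OR| / PhiInv(1 - p/2), which is exact for a Wald summary.

A pair counts as replicated when the replication-cohorts meta p-value is
below 0.05 and the interaction direction (OR above or below 1) agrees across
the discovery and every replication cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .logistic_interaction import InteractionResult

__all__ = [
    "StudySummary",
    "MetaResult",
    "se_from_or_p",
    "fixed_effect_meta",
    "replication_filter",
]


def se_from_or_p(or_value: float, p: float) -> float:
    """Standard error of ln(OR) implied by a two-sided Wald p-value."""
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    if or_value == 1.0:
        raise ValueError("cannot recover se when OR = 1 (z is undefined)")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    z = stats.norm.isf(p / 2.0)
    return float(abs(np.log(or_value)) / z)


@dataclass
class StudySummary:
    """One cohort's interaction estimate on the log-OR scale."""

    cohort: str
    ln_or: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"cohort {self.cohort}: se must be positive, got {self.se}")

    @property
    def or_value(self) -> float:
        return float(np.exp(self.ln_or))

    @classmethod
    def from_or_p(cls, cohort: str, or_value: float, p: float) -> "StudySummary":
        """Build from a published (OR, p) cell, recovering the SE from the quantile."""
        return cls(cohort=cohort, ln_or=float(np.log(or_value)), se=se_from_or_p(or_value, p))

    @classmethod
    def from_fit(cls, result: InteractionResult, cohort: str | None = None) -> "StudySummary":
        """Build from a logistic interaction fit (uses the fitted SE directly)."""
        return cls(
            cohort=cohort or f"{result.snp1}:{result.snp2}",
            ln_or=result.beta3,
            se=result.se3,
        )


@dataclass
class MetaResult:
    pooled_ln_or: float
    pooled_or: float
    pooled_se: float
    z: float
    p: float
    q_statistic: float
    q_df: int
    q_p: float
    i_squared: float


def fixed_effect_meta(summaries: list[StudySummary]) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Cochran's Q heterogeneity."""
    if not summaries:
        raise ValueError("fixed_effect_meta needs at least one study summary")
    theta = np.array([s.ln_or for s in summaries])
    w = np.array([1.0 / s.se**2 for s in summaries])
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p = float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(summaries) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return MetaResult(
        pooled_ln_or=pooled,
        pooled_or=float(np.exp(pooled)),
        pooled_se=pooled_se,
        z=float(z),
        p=p,
        q_statistic=q,
        q_df=df,
        q_p=q_p,
        i_squared=i2,
    )


def replication_filter(
    discovery: InteractionResult | StudySummary,
    replication_meta: MetaResult,
    per_study: list[StudySummary],
    p_replication: float = 0.05,
) -> tuple[bool, str]:
    """Replication rule: meta p < p_replication and direction-consistent effects.

    Direction consistency means sign(ln OR) is identical across the discovery
    estimate and every replication cohort (ORs all above 1 or all below 1).
    Returns (passed, reason); the reason names the failed condition.
    """
    if not per_study:
        raise ValueError("replication_filter needs at least one replication summary")
    disc_ln = discovery.beta3 if isinstance(discovery, InteractionResult) else discovery.ln_or
    signs = {np.sign(disc_ln)} | {np.sign(s.ln_or) for s in per_study}
    if len(signs) > 1 or 0.0 in signs:
        return False, "inconsistent interaction direction across cohorts"
    if not replication_meta.p < p_replication:
        return False, (
            f"replication meta p {replication_meta.p:.3g} not below {p_replication:g}"
        )
    return True, "replicated: meta p below threshold with consistent direction"
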
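"""Effective number of independent tests and Bonferroni threshold arithmetic.

With SNPs correlated by linkage disequilibrium, counting every pairwise test
in a Bonferroni correction is too strict.  The panel's effective number of
independent SNPs (Meff) is estimated from the eigen-spectrum of the inter-SNP
correlation matrix, block by block: each eigenvalue lambda contributes
1 if lambda >= 1 plus its fractional part (a Li-Ji style rule), so a block of
perfectly correlated SNPs contributes 1 and an uncorrelated block contributes
its size.  The pairwise test count is Meff*(Meff-1)/2 and the per-test
threshold alpha divided by that count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core_io import GenotypeStudy

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplicityEstimate",
    "effective_snp_count",
    "pairwise_test_count",
    "bonferroni_threshold",
    "multiplicity_report",
]

DEFAULT_BLOCK_SIZE = 200


@dataclass
class MultiplicityEstimate:
    m_total: int
    m_eff: int
    eigenvalues: list[np.ndarray]
    n_pair_tests: int
    alpha: float
    threshold: float

    @property
    def threshold_3sig(self) -> float:
        return float(f"{self.threshold:.2e}")


def _block_correlation(block: np.ndarray) -> np.ndarray:
    """Pearson correlation of dosage columns; constant SNPs treated as independent."""
    # mean-impute missing entries so one missing call does not drop a sample
    mean = np.nanmean(block, axis=0)
    B = np.where(np.isnan(block), mean, block)
    sd = B.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        logger.warning("%d constant SNP column(s) in block treated as independent",
                       int(const.sum()))
        sd = np.where(const, 1.0, sd)
    Z = (B - B.mean(axis=0)) / sd
    R = (Z.T @ Z) / B.shape[0]
    R[const, :] = 0.0
    R[:, const] = 0.0
    np.fill_diagonal(R, 1.0)
    return R


def _spectrum_contribution(eigvals: np.ndarray) -> float:
    lam = np.clip(eigvals, 0.0, None)  # numerical negatives from eigh
    # the integer/fractional split is discontinuous at integers: snap
    # eigenvalues within numerical error of an integer before flooring
    near = np.abs(lam - np.round(lam)) < 1e-8
    lam = np.where(near, np.round(lam), lam)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def effective_snp_count(
    genotypes: GenotypeStudy | np.ndarray,
    block_size: int = DEFAULT_BLOCK_SIZE,
    chrom: np.ndarray | list[str] | None = None,
) -> tuple[int, list[np.ndarray]]:
    """Effective number of independent SNPs from per-block LD eigen-spectra.

    SNPs are split into consecutive non-overlapping blocks of ``block_size``
    within each chromosome (panel order preserved).  Returns the rounded Meff
    and the per-block eigenvalue arrays.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if isinstance(genotypes, GenotypeStudy):
        D = genotypes.dosage
        if chrom is None:
            chrom = [v.chrom for v in genotypes.variants]
    else:
        D = np.asarray(genotypes, dtype=float)
    m = D.shape[1]
    chrom = ["1"] * m if chrom is None else list(chrom)

    spectra: list[np.ndarray] = []
    total = 0.0
    start = 0
    while start < m:
        c = chrom[start]
        end = start
        while end < m and chrom[end] == c and end - start < block_size:
            end += 1
        R = _block_correlation(D[:, start:end])
        lam = np.linalg.eigvalsh(R)[::-1]
        spectra.append(lam)
        total += _spectrum_contribution(lam)
        start = end
    m_eff = int(math.floor(total + 0.5))  # round half-up to match integer reporting
    return max(1, min(m_eff, m)), spectra


def pairwise_test_count(m_eff: int) -> int:
    """Number of unordered SNP pairs among m_eff independent SNPs."""
    if m_eff < 2:
        raise ValueError(f"m_eff must be >= 2, got {m_eff}")
    return m_eff * (m_eff - 1) // 2


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise per-test cutoff alpha / n_tests (full precision)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def multiplicity_report(
    genotypes: GenotypeStudy | np.ndarray,
    block_size: int = DEFAULT_BLOCK_SIZE,
    alpha: float = 0.05,
    chrom: np.ndarray | list[str] | None = None,
) -> MultiplicityEstimate:
    """Full Meff -> pair count -> threshold report for one genotype panel."""
    if isinstance(genotypes, GenotypeStudy):
        m_total = genotypes.n_variants
    else:
        m_total = np.asarray(genotypes).shape[1]
    m_eff, spectra = effective_snp_count(genotypes, block_size=block_size, chrom=chrom)
    n_tests = pairwise_test_count(max(m_eff, 2))
    return MultiplicityEstimate(
        m_total=m_total,
        m_eff=m_eff,
        eigenvalues=spectra,
        n_pair_tests=n_tests,
        alpha=alpha,
        threshold=bonferroni_threshold(alpha, n_tests),
    )
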
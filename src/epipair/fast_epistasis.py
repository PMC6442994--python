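"""Stage-1 screen: fast allelic Z-score test over all eligible SNP pairs.

For a pair of unphased biallelic SNPs, each individual's two-locus genotype
(a, b) is expanded into allele pairings: a*b weight on (minor, minor),
a*(2-b) on (minor, major), (2-a)*b on (major, minor) and (2-a)*(2-b) on
(major, major), then scaled by 1/2 so each individual carries total weight 2
(one pairing per chromosome; double heterozygotes split evenly across the two
possible phases).  The allelic log odds ratio of the resulting 2x2 table is
computed separately in cases and controls, and their difference is tested
with a normal Z statistic -- an imprecise but fast screen whose survivors
proceed to the logistic regression stage.

``screen_pairs`` evaluates every eligible pair exhaustively via matrix
products over the genotype matrix, so panels of a few thousand SNPs screen in
seconds; results are independent of sample and execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .snp_filtering import FilteredPanel

__all__ = [
    "AllelePairingTable",
    "PairScreenResult",
    "allele_pairing_table",
    "allelic_log_or",
    "fast_epistasis_z",
    "screen_pairs",
]


@dataclass
class AllelePairingTable:
    """2x2 allele-pairing counts: rows = SNP1 allele (minor, major), cols = SNP2."""

    counts: np.ndarray
    n_individuals: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2):
            raise ValueError("allele pairing table must be 2x2")
        if np.any(self.counts < 0):
            raise ValueError("allele pairing counts must be nonnegative")


@dataclass
class PairScreenResult:
    """Allelic Z-score contrast for one SNP pair."""

    snp1: str
    snp2: str
    lnor_case: float
    lnor_control: float
    se_case: float
    se_control: float
    z: float
    p: float


def _complete_pairs(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    return g1[ok], g2[ok]


def allele_pairing_table(g1: np.ndarray, g2: np.ndarray) -> AllelePairingTable:
    """Build the 2x2 allele-pairing table for one SNP pair from hard calls.

    Missing entries are dropped pairwise; at least 2 complete individuals are
    required.  Total counts equal 2 x n_individuals.
    """
    a, b = _complete_pairs(g1, g2)
    if a.size < 1:
        raise ValueError("no individuals with complete genotypes for this pair")
    if not (np.isin(a, (0, 1, 2)).all() and np.isin(b, (0, 1, 2)).all()):
        raise ValueError("allele pairing requires hard calls in {0, 1, 2}")
    counts = 0.5 * np.array(
        [
            [np.sum(a * b), np.sum(a * (2 - b))],
            [np.sum((2 - a) * b), np.sum((2 - a) * (2 - b))],
        ]
    )
    return AllelePairingTable(counts=counts, n_individuals=int(a.size))


def allelic_log_or(table: AllelePairingTable) -> tuple[float, float]:
    """Allelic log odds ratio and its standard error from a pairing table.

    If any cell is zero, 0.5 is added to every cell (Haldane-Anscombe), which
    keeps both the estimate and the SE finite.
    """
    cells = table.counts.astype(float).copy()
    if np.any(cells == 0):
        cells += 0.5
    lnor = float(np.log(cells[0, 0] * cells[1, 1] / (cells[0, 1] * cells[1, 0])))
    se = float(np.sqrt(np.sum(1.0 / cells)))
    return lnor, se


def fast_epistasis_z(
    g1: np.ndarray, g2: np.ndarray, status: np.ndarray, snp1: str = "snp1", snp2: str = "snp2"
) -> PairScreenResult:
    """Z test of the case-vs-control difference in SNP1-SNP2 allelic association."""
    status = np.asarray(status)
    if not np.isin(status, (0, 1)).all():
        raise ValueError("status must contain only 0 (control) and 1 (case)")
    results = {}
    for label, grp in (("case", 1), ("control", 0)):
        sel = status == grp
        if not sel.any():
            raise ValueError(f"no {label} individuals present")
        try:
            table = allele_pairing_table(np.asarray(g1, float)[sel], np.asarray(g2, float)[sel])
        except ValueError as exc:
            raise ValueError(f"{label} group: {exc}") from exc
        if table.n_individuals < 2:
            raise ValueError(
                f"{label} group has fewer than 2 individuals with complete genotypes"
            )
        results[label] = allelic_log_or(table)
    (lnor_ca, se_ca), (lnor_co, se_co) = results["case"], results["control"]
    z = (lnor_ca - lnor_co) / np.hypot(se_ca, se_co)
    p = 2.0 * stats.norm.sf(abs(z))
    return PairScreenResult(
        snp1=snp1, snp2=snp2,
        lnor_case=lnor_ca, lnor_control=lnor_co,
        se_case=se_ca, se_control=se_co,
        z=float(z), p=float(max(p, np.nextafter(0, 1))),
    )


def _group_lnor_matrices(G: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Allelic lnOR and squared SE for all SNP pairs within one phenotype group.

    The four pairing-table cells for every pair are linear in the cross-product
    matrices G'G, G'M and M'M (M = observed indicator), so the whole
    pairs x pairs grid comes out of three matmuls.
    """
    Gm = np.where(observed, G, 0.0)
    M = observed.astype(float)
    S = Gm.T @ Gm
    SA = Gm.T @ M  # SA[i, j] = sum of g_i over samples observed at both i and j
    N = M.T @ M
    c11 = S / 2.0
    c10 = (2.0 * SA - S) / 2.0
    c01 = (2.0 * SA.T - S) / 2.0
    c00 = (4.0 * N - 2.0 * SA - 2.0 * SA.T + S) / 2.0
    zero = (c11 == 0) | (c10 == 0) | (c01 == 0) | (c00 == 0)
    corr = np.where(zero, 0.5, 0.0)
    c11, c10, c01, c00 = c11 + corr, c10 + corr, c01 + corr, c00 + corr
    with np.errstate(divide="ignore", invalid="ignore"):
        lnor = np.log(c11 * c00 / (c10 * c01))
        se2 = 1.0 / c11 + 1.0 / c10 + 1.0 / c01 + 1.0 / c00
    # pairs with <2 jointly observed individuals are not testable
    lnor[N < 2] = np.nan
    return lnor, se2


def screen_pairs(
    panel: FilteredPanel,
    status: np.ndarray | None = None,
    threshold: float = 1e-6,
    within_gene: bool = False,
) -> list[PairScreenResult]:
    """Exhaustive allelic Z screen over eligible SNP pairs; keep pairs with p < threshold.

    Dosages are rounded to hard calls for this stage.  By default only
    cross-gene pairs are eligible: a pair is tested when the two SNPs' gene
    assignments differ in at least one gene (``within_gene=True`` lifts the
    restriction).  Results are sorted ascending by p, ties broken by
    (snp1, snp2) id, so output is independent of execution order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    study = panel.study
    if status is None:
        status = study.status
    if status is None:
        raise ValueError("no case/control status available for screening")
    status = np.asarray(status)

    G = np.round(study.dosage)
    observed = ~np.isnan(G)
    m = study.n_variants

    lnors, se2s = {}, {}
    for label, grp in (("case", 1), ("control", 0)):
        sel = status == grp
        if not sel.any():
            raise ValueError(f"no {label} individuals present")
        lnors[label], se2s[label] = _group_lnor_matrices(G[sel], observed[sel])

    with np.errstate(invalid="ignore"):
        z = (lnors["case"] - lnors["control"]) / np.sqrt(se2s["case"] + se2s["control"])
    p = 2.0 * stats.norm.sf(np.abs(z))

    ids = [v.id for v in study.variants]
    gene_code: dict[tuple[str, ...], int] = {}
    codes = np.array(
        [gene_code.setdefault(panel.snp_to_gene[i], len(gene_code)) for i in ids]
    )
    iu, ju = np.triu_indices(m, k=1)
    eligible = np.ones(iu.size, dtype=bool) if within_gene else codes[iu] != codes[ju]
    keep = eligible & np.isfinite(z[iu, ju]) & (p[iu, ju] < threshold)

    results = [
        PairScreenResult(
            snp1=ids[i], snp2=ids[j],
            lnor_case=float(lnors["case"][i, j]),
            lnor_control=float(lnors["control"][i, j]),
            se_case=float(np.sqrt(se2s["case"][i, j])),
            se_control=float(np.sqrt(se2s["control"][i, j])),
            z=float(z[i, j]),
            p=float(max(p[i, j], np.nextafter(0, 1))),
        )
        for i, j in zip(iu[keep], ju[keep])
    ]
    results.sort(key=lambda r: (r.p, r.snp1, r.snp2))
    return results


def n_eligible_pairs(panel: FilteredPanel, within_gene: bool = False) -> int:
    """Count the pairs the screen would evaluate (used for run reports)."""
    gene_code: dict[tuple[str, ...], int] = {}
    codes = np.array(
        [gene_code.setdefault(panel.snp_to_gene[v.id], len(gene_code))
         for v in panel.study.variants]
    )
    m = codes.size
    if within_gene:
        return m * (m - 1) // 2
    iu, ju = np.triu_indices(m, k=1)
    return int(np.sum(codes[iu] != codes[ju]))
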
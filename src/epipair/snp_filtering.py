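"""Restrict the variant panel to SNPs inside cancer-related genes with MAF above threshold.

The search space of the interaction scan is filtered in two steps: keep only
SNPs whose position falls inside a retained gene's transcript interval
(untranslated regions included), then drop SNPs with minor allele frequency
below ``maf_min`` (default 0.005) -- low-frequency variants carry essentially
no power in a pairwise interaction test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import GeneMap, GenotypeStudy

logger = logging.getLogger(__name__)

__all__ = ["FilteredPanel", "map_snps_to_genes", "filter_panel"]

DEFAULT_MAF_MIN = 0.005


@dataclass
class FilteredPanel:
    """A study restricted to the retained SNPs, plus the SNP-to-gene assignment."""

    study: GenotypeStudy
    snp_to_gene: dict[str, tuple[str, ...]]
    report: dict[str, int] = field(default_factory=dict)

    def genes_of(self, variant_id: str) -> tuple[str, ...]:
        return self.snp_to_gene[variant_id]


def map_snps_to_genes(study: GenotypeStudy, gene_map: GeneMap) -> dict[str, tuple[str, ...]]:
    """Map each SNP to every gene interval containing its position.

    Intervals are 1-based inclusive on both ends.  SNPs inside no interval are
    absent from the returned dict; a SNP inside overlapping genes maps to all
    of them (sorted tuple).
    """
    mapping: dict[str, list[str]] = {}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene, ivs in gene_map.intervals.items():
        for chrom, start, end in ivs:
            by_chrom.setdefault(chrom, []).append((start, end, gene))
    for v in study.variants:
        hits = [g for s, e, g in by_chrom.get(v.chrom, []) if s <= v.pos <= e]
        if hits:
            mapping[v.id] = sorted(set(hits))
    return {k: tuple(v) for k, v in mapping.items()}


def filter_panel(
    study: GenotypeStudy, gene_map: GeneMap, maf_min: float = DEFAULT_MAF_MIN
) -> FilteredPanel:
    """Retain SNPs mapped to a gene and with maf >= maf_min, preserving order."""
    if not (0.0 <= maf_min < 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    mapping = map_snps_to_genes(study, gene_map)
    keep: list[int] = []
    n_unmapped = 0
    n_low_maf = 0
    for j, v in enumerate(study.variants):
        if v.id not in mapping:
            n_unmapped += 1
        elif v.maf < maf_min:
            n_low_maf += 1
        else:
            keep.append(j)
    if not keep:
        raise ValueError(
            "no SNP survives filtering: check that the gene map covers the panel "
            f"and that maf_min={maf_min} is not too strict "
            f"({n_unmapped} unmapped, {n_low_maf} below MAF threshold)"
        )
    report = {
        "n_input": study.n_variants,
        "n_unmapped": n_unmapped,
        "n_low_maf": n_low_maf,
        "n_retained": len(keep),
    }
    logger.info(
        "panel filter: %(n_input)d input SNPs, %(n_unmapped)d outside gene intervals, "
        "%(n_low_maf)d below MAF threshold, %(n_retained)d retained", report
    )
    sub = study.subset_variants(np.asarray(keep))
    return FilteredPanel(
        study=sub,
        snp_to_gene={v.id: mapping[v.id] for v in sub.variants},
        report=report,
    )
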
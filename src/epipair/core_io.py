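"""Readers/writers for the formats the pipeline touches and the internal data model.

The internal unit of analysis is a :class:`GenotypeStudy`: one cohort's
minor-allele dosage matrix (samples x variants, values in [0, 2], ``NaN`` for
missing) together with variant metadata, case/control status and optional
covariates.  All readers normalize to this representation; in particular the
minor allele is re-oriented per study so that every variant satisfies
``maf <= 0.5``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantInfo",
    "GenotypeStudy",
    "GeneMap",
    "PairRecord",
    "read_vcf",
    "read_matrix_tables",
    "read_gene_map",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class VariantInfo:
    """Metadata for one biallelic variant.

    ``pos`` is 1-based inclusive (VCF convention).  ``allele_minor`` is the
    allele counted by the dosage column; ``maf`` is its frequency in the study
    and is always <= 0.5.
    """

    id: str
    chrom: str
    pos: int
    allele_minor: str
    allele_major: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"variant {self.id}: maf must be in [0, 0.5], got {self.maf}")


@dataclass
class GenotypeStudy:
    """One cohort: dosage matrix plus per-sample phenotype and covariates.

    dosage[i, j] is the minor-allele dosage of sample i at variant j
    (hard calls 0/1/2 or imputed dosages in [0, 2]); missing entries are NaN.
    ``status`` is 1 for cases and 0 for controls, or None for genotype-only
    studies (e.g. straight from a VCF).
    """

    name: str
    variants: list[VariantInfo]
    samples: list[str]
    dosage: np.ndarray
    status: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique within a study")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"dosage out of [0, 2] at sample {self.samples[i]!r}, "
                f"variant {self.variants[j].id!r}: {self.dosage[i, j]}"
            )
        if self.status is not None:
            self.status = np.asarray(self.status)
            if self.status.shape != (len(self.samples),):
                raise ValueError("status length does not match sample count")
            if not np.isin(self.status, [0, 1]).all():
                raise ValueError("status values must be 0 (control) or 1 (case)")
        if self.covariates is not None and len(self.covariates) != len(self.samples):
            raise ValueError("covariate table length does not match sample count")
        self._index = {v.id: j for j, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in study {self.name!r}") from None

    def genotype(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant (copy)."""
        return self.dosage[:, self.variant_index(variant_id)].copy()

    def covariate_matrix(self, names: tuple[str, ...] | list[str]) -> np.ndarray:
        """Selected covariate columns as a float matrix (samples x k)."""
        if not names:
            return np.empty((self.n_samples, 0))
        if self.covariates is None:
            raise ValueError(f"study {self.name!r} has no covariate table")
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise KeyError(f"covariates not in study {self.name!r}: {missing}")
        return self.covariates[list(names)].to_numpy(dtype=float)

    def subset_variants(self, indices: np.ndarray | list[int]) -> "GenotypeStudy":
        indices = np.asarray(indices, dtype=int)
        return GenotypeStudy(
            name=self.name,
            variants=[self.variants[j] for j in indices],
            samples=list(self.samples),
            dosage=self.dosage[:, indices].copy(),
            status=None if self.status is None else self.status.copy(),
            covariates=None if self.covariates is None else self.covariates.copy(),
        )

    def subset_samples(self, mask: np.ndarray, name: str | None = None) -> "GenotypeStudy":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return GenotypeStudy(
            name=self.name if name is None else name,
            variants=list(self.variants),
            samples=[self.samples[i] for i in idx],
            dosage=self.dosage[idx, :].copy(),
            status=None if self.status is None else self.status[idx].copy(),
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[idx].reset_index(drop=True),
        )


@dataclass
class GeneMap:
    """Gene transcript intervals (1-based inclusive) for the retained gene list.

    ``intervals`` maps gene symbol -> list of (chrom, start, end), with
    overlapping intervals of the same gene merged.
    """

    intervals: dict[str, list[tuple[str, int, int]]]
    gene_list: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for gene, ivs in self.intervals.items():
            for chrom, start, end in ivs:
                if not start < end:
                    raise ValueError(f"gene {gene}: interval start must be < end ({start}, {end})")
        if not self.gene_list:
            self.gene_list = set(self.intervals)

    def genes(self) -> list[str]:
        return sorted(self.intervals)


def _merge_intervals(ivs: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union overlapping intervals per chromosome (transcripts of one gene)."""
    out: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in ivs}):
        spans = sorted((s, e) for c, s, e in ivs if c == chrom)
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # overlapping or touching transcripts
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def _orient_minor(dosage: np.ndarray, a1: str, a2: str) -> tuple[np.ndarray, str, str, float]:
    """Flip a dosage column so it counts the minor allele; return (dosage, minor, major, maf).

    Frequency is computed over non-missing calls, cases and controls pooled.
    A tie at 0.5 is broken lexicographically: the later-sorting allele string
    is called minor, so orientation is deterministic.
    """
    obs = dosage[~np.isnan(dosage)]
    freq = float(obs.mean() / 2.0) if obs.size else 0.0
    flip = freq > 0.5 or (freq == 0.5 and a2 > a1)
    if flip:
        return 2.0 - dosage, a2, a1, 1.0 - freq
    return dosage, a1, a2, freq


def read_vcf(path: str, name: str | None = None) -> GenotypeStudy:
    """Read a VCF into a GenotypeStudy (no status/covariates).

    Dosages are taken from the DS FORMAT field when present, else from GT
    allele counts.  Multi-allelic records are skipped with a warning.  The
    dosage column is oriented to the per-study minor allele.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises plain Exceptions
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantInfo] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping multi-allelic site %s:%s (%s) in %s", rec.CHROM, rec.POS, rec.ID, path
            )
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            col = np.full(len(samples), np.nan)
            for i, gt in enumerate(rec.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                if len(alleles) == 2:
                    col[i] = float(sum(alleles))
        ref, alt = rec.REF, rec.ALT[0]
        col, minor, major, maf = _orient_minor(col, alt, ref)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantInfo(
                id=vid,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                allele_minor=minor,
                allele_major=major,
                maf=maf,
            )
        )
        columns.append(col)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeStudy(
        name=name or str(path),
        variants=variants,
        samples=samples,
        dosage=dosage,
    )


#: sample-column labels of the metadata rows of a genotype matrix TSV
_META_ROWS = ("#chrom", "#pos", "#a1", "#a2")


def read_matrix_tables(
    genotype_path: str,
    phenotype_path: str,
    covariate_path: str | None = None,
    name: str | None = None,
) -> GenotypeStudy:
    """Read a genotype matrix TSV plus phenotype (and optional covariate) TSVs.

    The genotype table is samples x variants with a leading ``sample`` column;
    the first four rows carry variant metadata (sample column values
    ``#chrom``, ``#pos``, ``#a1``, ``#a2``), with dosages counting the a1
    allele.  The phenotype table needs ``sample`` and ``status`` columns
    (1 = case, 0 = control).  Tables are inner-joined on sample id; samples
    absent from any table are dropped with a logged count.
    """
    geno = pd.read_csv(genotype_path, sep="\t", dtype=str)
    if geno.columns[0] != "sample":
        raise ValueError(f"{genotype_path}: first column must be 'sample'")
    meta = geno.iloc[: len(_META_ROWS)]
    if list(meta["sample"]) != list(_META_ROWS):
        raise ValueError(
            f"{genotype_path}: expected metadata rows {_META_ROWS} at the top of the table"
        )
    body = geno.iloc[len(_META_ROWS) :]
    variant_ids = list(geno.columns[1:])
    chroms = list(meta.iloc[0, 1:])
    positions = [int(p) for p in meta.iloc[1, 1:]]
    a1 = list(meta.iloc[2, 1:])
    a2 = list(meta.iloc[3, 1:])
    sample_ids = list(body["sample"])
    dosage = body[variant_ids].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw = body[variant_ids].to_numpy()
    with np.errstate(invalid="ignore"):
        bad = (dosage < 0) | (dosage > 2)
    missing_txt = (raw == "NA") | (raw == ".") | pd.isna(raw)
    if np.any(np.isnan(dosage) & ~missing_txt):
        i, j = map(int, np.argwhere(np.isnan(dosage) & ~missing_txt)[0])
        raise ValueError(
            f"{genotype_path}: non-numeric dosage {raw[i, j]!r} at sample "
            f"{sample_ids[i]!r}, variant {variant_ids[j]!r}"
        )
    if np.any(bad):
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{genotype_path}: dosage {dosage[i, j]} outside [0, 2] at sample "
            f"{sample_ids[i]!r}, variant {variant_ids[j]!r}"
        )

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample": str})
    if "sample" not in pheno.columns or "status" not in pheno.columns:
        raise ValueError(f"{phenotype_path}: needs 'sample' and 'status' columns")
    tables = {"genotype": set(sample_ids), "phenotype": set(pheno["sample"])}
    covar = None
    if covariate_path is not None:
        covar = pd.read_csv(covariate_path, sep="\t", dtype={"sample": str})
        if "sample" not in covar.columns:
            raise ValueError(f"{covariate_path}: needs a 'sample' column")
        tables["covariate"] = set(covar["sample"])
    shared = set.intersection(*tables.values())
    if not shared:
        raise ValueError("no overlapping samples across genotype/phenotype/covariate tables")
    n_dropped = len(set.union(*tables.values())) - len(shared)
    if n_dropped:
        logger.warning("dropping %d samples absent from at least one table", n_dropped)

    keep = [i for i, s in enumerate(sample_ids) if s in shared]
    sample_ids = [sample_ids[i] for i in keep]
    dosage = dosage[keep, :]
    pheno = pheno.set_index("sample").loc[sample_ids]
    status = pheno["status"].to_numpy(dtype=int)
    if covar is not None:
        covar = covar.set_index("sample").loc[sample_ids].reset_index(drop=True)

    variants = []
    for j, vid in enumerate(variant_ids):
        col, minor, major, maf = _orient_minor(dosage[:, j], a1[j], a2[j])
        dosage[:, j] = col
        variants.append(
            VariantInfo(
                id=vid, chrom=str(chroms[j]), pos=positions[j],
                allele_minor=minor, allele_major=major, maf=maf,
            )
        )
    return GenotypeStudy(
        name=name or str(genotype_path),
        variants=variants,
        samples=sample_ids,
        dosage=dosage,
        status=status,
        covariates=covar,
    )


def read_gene_map(bed_path: str, gene_list_path: str) -> GeneMap:
    """Read BED intervals and a gene list (one symbol per line) into a GeneMap.

    BED starts are 0-based half-open and are converted to the 1-based
    inclusive convention used for variant positions.  Only intervals whose
    symbol appears in the list are retained; transcripts of one gene are
    unioned.
    """
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
    )
    with open(gene_list_path) as fh:
        wanted = {line.strip() for line in fh if line.strip()}
    if not wanted:
        raise ValueError(f"{gene_list_path}: empty gene list")
    present = set(bed["gene"])
    missing = wanted - present
    for sym in sorted(missing):
        logger.warning("gene list symbol %r absent from BED; ignored", sym)
    keep = wanted & present
    if not keep:
        raise ValueError("no gene-list symbol found in the BED file")
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    for row in bed.itertuples(index=False):
        if row.gene in keep:
            intervals.setdefault(row.gene, []).append(
                (str(row.chrom), int(row.start) + 1, int(row.end))
            )
    intervals = {g: _merge_intervals(ivs) for g, ivs in intervals.items()}
    return GeneMap(intervals=intervals, gene_list=keep)


@dataclass
class PairRecord:
    """One SNP pair's per-stage statistics, the row unit of the results table."""

    snp1: str
    a1_1: str
    maf1: float
    gene1: str
    snp2: str
    a1_2: str
    maf2: float
    gene2: str
    cohort_or: dict[str, float] = field(default_factory=dict)
    cohort_p: dict[str, float] = field(default_factory=dict)
    or_joint: float = float("nan")
    p_joint: float = float("nan")
    q_p: float = float("nan")


def _fmt_p(p: float) -> str:
    return "NA" if not np.isfinite(p) else f"{p:.1E}"


def _fmt_or(x: float) -> str:
    return "NA" if not np.isfinite(x) else f"{x:.4g}"


def write_results(records: list[PairRecord], path: str, cohorts: list[str] | None = None) -> None:
    """Write SNP-pair results as TSV, one row per pair.

    Layout mirrors the standard joint-analysis table: identifying columns for
    both SNPs, per-cohort OR and P, joint OR/P and the heterogeneity Q p-value.
    P-values are serialized in scientific notation with 2 significant digits.
    """
    if cohorts is None:
        seen: list[str] = []
        for r in records:
            for c in r.cohort_or:
                if c not in seen:
                    seen.append(c)
        cohorts = seen
    cols = ["SNP1", "A1_1", "MAF1", "GENE1", "SNP2", "A1_2", "MAF2", "GENE2"]
    for c in cohorts:
        cols += [f"OR_{c}", f"P_{c}"]
    cols += ["OR_joint", "P_joint", "Q"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.snp1, r.a1_1, f"{r.maf1:.4g}", r.gene1,
                r.snp2, r.a1_2, f"{r.maf2:.4g}", r.gene2,
            ]
            for c in cohorts:
                row += [_fmt_or(r.cohort_or.get(c, float("nan"))),
                        _fmt_p(r.cohort_p.get(c, float("nan")))]
            row += [_fmt_or(r.or_joint), _fmt_p(r.p_joint), _fmt_p(r.q_p)]
            fh.write("\t".join(row) + "\n")


def read_results(path: str) -> list[PairRecord]:
    """Read back a file written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cohorts = [c[3:] for c in df.columns if c.startswith("OR_") and c != "OR_joint"]

    def num(x: str) -> float:
        return float("nan") if x in ("NA", None) or pd.isna(x) else float(x)

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            PairRecord(
                snp1=d["SNP1"], a1_1=d["A1_1"], maf1=num(d["MAF1"]), gene1=d["GENE1"],
                snp2=d["SNP2"], a1_2=d["A1_2"], maf2=num(d["MAF2"]), gene2=d["GENE2"],
                cohort_or={c: num(d[f"OR_{c}"]) for c in cohorts},
                cohort_p={c: num(d[f"P_{c}"]) for c in cohorts},
                or_joint=num(d["OR_joint"]),
                p_joint=num(d["P_joint"]),
                q_p=num(d["Q"]),
            )
        )
    return records
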
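"""Multi-cohort case-control simulator with LD blocks and planted interactions.

The generator emulates the statistical structure the analysis assumes:

* genotypes -- per individual, two independent haplotypes per LD block; each
  haplotype is drawn by thresholding a correlated standard-normal vector at
  PhiInv(maf) per SNP, so every SNP is in Hardy-Weinberg equilibrium exactly
  and the target minor allele frequency is the marginal allele probability.
  Block correlation models: independent, AR(rho) or equicorrelated(rho).
* disease -- a large source population receives a logistic risk
  logit P(D) = b0 + sum(b_j g_j) + sum(b3 g_i g_j over planted pairs)
  + sum(b_c cov_c); cases and controls are then sampled without replacement
  to the requested counts (retrospective case-control design).
* expression -- one trait per configured model: baseline + effects on
  dominant-coded genotypes + delta * d1 * d2 + covariate effects + N(0, sigma)
  noise, mirroring the eQTL interaction analysis.

Everything is driven by a single integer seed through numpy's seed-sequence
spawning, so a config reproduces bit-identical cohorts on any platform.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneMap, GenotypeStudy, VariantInfo

__all__ = [
    "BlockSpec",
    "PlantedPair",
    "DiseaseModel",
    "CohortSpec",
    "ExpressionModel",
    "SimulationConfig",
    "SimulatedStudySet",
    "simulate_genotypes",
    "simulate_case_control",
    "simulate_expression",
    "simulate_study_set",
    "write_fixture_set",
    "demo_config",
]

SNP_SPACING_BP = 10_000
GENE_MARGIN_BP = 1_000


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: SNP count, MAF spectrum and correlation model."""

    n_snps: int
    maf_range: tuple[float, float] = (0.01, 0.5)
    model: str = "independent"  # independent | ar | equicorrelated
    rho: float = 0.0
    chrom: str = "1"

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.model not in ("independent", "ar", "equicorrelated"):
            raise ValueError(f"unknown correlation model {self.model!r}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")


@dataclass(frozen=True)
class PlantedPair:
    """A true interaction planted on the log-odds scale."""

    snp1: str
    snp2: str
    beta: float               # interaction log odds ratio
    coding: str = "additive"  # additive | dominant

    def __post_init__(self) -> None:
        if self.coding not in ("additive", "dominant"):
            raise ValueError(f"unknown interaction coding {self.coding!r}")


@dataclass(frozen=True)
class DiseaseModel:
    intercept: float = float(np.log(0.15 / 0.85))
    main_effects: dict = field(default_factory=dict)       # snp id -> log OR
    planted_pairs: tuple = ()
    covariate_effects: dict = field(default_factory=dict)  # cov name -> effect


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_cases: int
    n_controls: int
    effect_multiplier: float = 1.0  # scales genetic effects to exercise heterogeneity


@dataclass(frozen=True)
class ExpressionModel:
    snp1: str
    snp2: str
    baseline: float = 0.0
    effect1: float = 0.0
    effect2: float = 0.0
    delta: float = 0.0   # interaction effect on the 1/1 carrier group
    sigma: float = 1.0
    covariate_effects: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationConfig:
    blocks: tuple = ()
    cohorts: tuple = ()
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    snps_per_gene: int = 10
    n_covariates: int = 2
    maf_overrides: dict = field(default_factory=dict)  # snp id -> maf
    expression: ExpressionModel | None = None
    seed: int = 0
    source_margin: float = 1.4  # oversampling headroom for the source population

    def variant_ids(self) -> list[str]:
        m = sum(b.n_snps for b in self.blocks)
        return [f"snp{j:04d}" for j in range(m)]

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulatedStudySet:
    studies: list[GenotypeStudy]
    truth: list[dict]
    gene_map: GeneMap
    expression: np.ndarray | None = None
    expression_study: str | None = None
    config: SimulationConfig | None = None


def _block_chol(spec: BlockSpec) -> np.ndarray | None:
    m = spec.n_snps
    if spec.model == "independent" or spec.rho == 0.0 or m == 1:
        return None
    if spec.model == "ar":
        idx = np.arange(m)
        sigma = spec.rho ** np.abs(idx[:, None] - idx[None, :])
    else:
        sigma = np.full((m, m), spec.rho)
        np.fill_diagonal(sigma, 1.0)
    return np.linalg.cholesky(sigma)


def _draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    mafs = np.concatenate(
        [rng.uniform(b.maf_range[0], b.maf_range[1], b.n_snps) for b in config.blocks]
    )
    ids = config.variant_ids()
    for snp, maf in config.maf_overrides.items():
        mafs[ids.index(snp)] = maf
    return mafs


def simulate_genotypes(
    blocks: tuple | list,
    mafs: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw an n x m genotype matrix: two latent-Gaussian haplotypes per block."""
    cols: list[np.ndarray] = []
    start = 0
    for spec in blocks:
        m = spec.n_snps
        thresh = stats.norm.ppf(mafs[start : start + m])
        L = _block_chol(spec)
        geno = np.zeros((n, m), dtype=np.int8)
        for _hap in range(2):
            z = rng.standard_normal((n, m))
            if L is not None:
                z = z @ L.T
            geno += (z < thresh).astype(np.int8)
        cols.append(geno)
        start += m
    return np.concatenate(cols, axis=1).astype(float)


def _risk_eta(
    dosage: np.ndarray,
    covariates: np.ndarray,
    ids: list[str],
    model: DiseaseModel,
    cov_names: list[str],
    multiplier: float,
) -> np.ndarray:
    index = {s: j for j, s in enumerate(ids)}
    eta = np.full(dosage.shape[0], model.intercept)
    for snp, beta in model.main_effects.items():
        eta += multiplier * beta * dosage[:, index[snp]]
    for pair in model.planted_pairs:
        g1 = dosage[:, index[pair.snp1]]
        g2 = dosage[:, index[pair.snp2]]
        if pair.coding == "dominant":
            g1, g2 = (g1 >= 1).astype(float), (g2 >= 1).astype(float)
        eta += multiplier * pair.beta * g1 * g2
    for cov, beta in model.covariate_effects.items():
        eta += beta * covariates[:, cov_names.index(cov)]
    return eta


def simulate_case_control(
    eta: np.ndarray,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Retrospective sampling: draw disease status, then sample the two arms.

    Returns (indices into the source population, status vector for those
    indices).  Raises if the source population cannot supply the requested
    counts.
    """
    prob = 1.0 / (1.0 + np.exp(-eta))
    disease = rng.random(eta.size) < prob
    case_pool = np.flatnonzero(disease)
    control_pool = np.flatnonzero(~disease)
    if case_pool.size < n_cases or control_pool.size < n_controls:
        raise ValueError(
            f"source population of {eta.size} yielded {case_pool.size} cases / "
            f"{control_pool.size} controls, fewer than the requested "
            f"{n_cases}/{n_controls}; increase source_margin"
        )
    cases = rng.choice(case_pool, size=n_cases, replace=False)
    controls = rng.choice(control_pool, size=n_controls, replace=False)
    idx = np.concatenate([cases, controls])
    status = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    return idx, status


def _gene_assignment(
    config: SimulationConfig,
) -> tuple[list[str], list[str], np.ndarray, GeneMap]:
    """Variant metadata, positions and a gene map with snps_per_gene SNPs per gene."""
    ids = config.variant_ids()
    chroms: list[str] = []
    for b in config.blocks:
        chroms += [b.chrom] * b.n_snps
    pos = np.zeros(len(ids), dtype=int)
    counter: dict[str, int] = {}
    for j, c in enumerate(chroms):
        counter[c] = counter.get(c, 0) + 1
        pos[j] = counter[c] * SNP_SPACING_BP
    genes: dict[str, list[tuple[str, int, int]]] = {}
    for g in range(math.ceil(len(ids) / config.snps_per_gene)):
        lo = g * config.snps_per_gene
        hi = min(lo + config.snps_per_gene, len(ids))
        span = range(lo, hi)
        chrom_set = {chroms[j] for j in span}
        sym = f"GENE{g:03d}"
        for c in sorted(chrom_set):
            ps = [pos[j] for j in span if chroms[j] == c]
            genes[sym] = genes.get(sym, []) + [
                (c, max(1, min(ps) - GENE_MARGIN_BP), max(ps) + GENE_MARGIN_BP)
            ]
    gene_map = GeneMap(intervals=genes)
    return ids, chroms, pos, gene_map


def simulate_study_set(config: SimulationConfig) -> SimulatedStudySet:
    """Generate all cohorts (and optionally expression) from one config + seed."""
    if not config.blocks or not config.cohorts:
        raise ValueError("config needs at least one block and one cohort")
    root = np.random.SeedSequence(config.seed)
    maf_ss, expr_ss, *cohort_ss = root.spawn(2 + len(config.cohorts))
    mafs = _draw_mafs(config, np.random.default_rng(maf_ss))
    ids, chroms, pos, gene_map = _gene_assignment(config)
    cov_names = [f"cov{i + 1}" for i in range(config.n_covariates)]

    prev = 1.0 / (1.0 + np.exp(-config.disease_model.intercept))
    studies: list[GenotypeStudy] = []
    for spec, ss in zip(config.cohorts, cohort_ss):
        rng = np.random.default_rng(ss)
        batch_n = int(
            math.ceil(
                config.source_margin
                * max(spec.n_cases / prev, spec.n_controls / (1.0 - prev))
            )
        )
        # grow the source population in batches: planted effects can shift the
        # realized prevalence away from the intercept-implied value
        dosage = np.empty((0, len(ids)))
        covs = np.empty((0, config.n_covariates))
        eta = np.empty(0)
        for _attempt in range(6):
            d = simulate_genotypes(config.blocks, mafs, batch_n, rng)
            c = rng.standard_normal((batch_n, config.n_covariates))
            e = _risk_eta(d, c, ids, config.disease_model, cov_names, spec.effect_multiplier)
            dosage = np.vstack([dosage, d])
            covs = np.vstack([covs, c])
            eta = np.concatenate([eta, e])
            prob = 1.0 / (1.0 + np.exp(-eta))
            if (prob.sum() > 1.2 * spec.n_cases
                    and (1 - prob).sum() > 1.2 * spec.n_controls):
                break
        idx, status = simulate_case_control(eta, spec.n_cases, spec.n_controls, rng)
        dosage = dosage[idx]
        covs = covs[idx]
        realized_maf = dosage.mean(axis=0) / 2.0
        variants = [
            VariantInfo(
                id=ids[j], chrom=chroms[j], pos=int(pos[j]),
                allele_minor="A", allele_major="G",
                maf=float(min(realized_maf[j], 1.0 - realized_maf[j])),
            )
            for j in range(len(ids))
        ]
        # orient to the within-cohort minor allele, as the readers do
        flip = realized_maf > 0.5
        dosage[:, flip] = 2.0 - dosage[:, flip]
        for j in np.flatnonzero(flip):
            variants[j] = VariantInfo(
                id=ids[j], chrom=chroms[j], pos=int(pos[j]),
                allele_minor="G", allele_major="A", maf=variants[j].maf,
            )
        studies.append(
            GenotypeStudy(
                name=spec.name,
                variants=variants,
                samples=[f"{spec.name}_s{i:05d}" for i in range(len(idx))],
                dosage=dosage,
                status=status,
                covariates=pd.DataFrame(covs, columns=cov_names),
            )
        )

    truth = [
        {
            "snp1": p.snp1, "snp2": p.snp2, "beta": p.beta,
            "or": float(np.exp(p.beta)), "coding": p.coding,
        }
        for p in config.disease_model.planted_pairs
    ]

    expression = None
    expression_study = None
    if config.expression is not None:
        expression = simulate_expression(
            studies[0], config.expression, np.random.default_rng(expr_ss)
        )
        expression_study = studies[0].name
    return SimulatedStudySet(
        studies=studies, truth=truth, gene_map=gene_map,
        expression=expression, expression_study=expression_study, config=config,
    )


def simulate_expression(
    study: GenotypeStudy, model: ExpressionModel, rng: np.random.Generator
) -> np.ndarray:
    """One expression trait carrying a dominant-coded genotype x genotype effect."""
    d1 = (study.genotype(model.snp1) >= 1).astype(float)
    d2 = (study.genotype(model.snp2) >= 1).astype(float)
    trait = (
        model.baseline
        + model.effect1 * d1
        + model.effect2 * d2
        + model.delta * d1 * d2
    )
    for cov, beta in model.covariate_effects.items():
        trait = trait + beta * study.covariates[cov].to_numpy(dtype=float)
    if model.sigma > 0:
        trait = trait + model.sigma * rng.standard_normal(study.n_samples)
    return trait


def write_fixture_set(
    simulated: SimulatedStudySet, out_dir: str | Path, force: bool = False
) -> Path:
    """Write cohorts as TSV tables plus gene map, truth JSON and a manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    for study in simulated.studies:
        _write_genotype_tsv(study, out / f"{study.name}_genotypes.tsv")
        with open(out / f"{study.name}_phenotype.tsv", "w") as fh:
            fh.write("sample\tstatus\n")
            for s, st in zip(study.samples, study.status):
                fh.write(f"{s}\t{int(st)}\n")
        if study.covariates is not None:
            cov = study.covariates.copy()
            cov.insert(0, "sample", study.samples)
            cov.to_csv(out / f"{study.name}_covariates.tsv", sep="\t", index=False)
    with open(out / "genes.bed", "w") as fh:
        for gene in simulated.gene_map.genes():
            for chrom, start, end in simulated.gene_map.intervals[gene]:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene}\n")  # back to BED half-open
    with open(out / "genes.txt", "w") as fh:
        fh.write("\n".join(simulated.gene_map.genes()) + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(simulated.truth, fh, indent=1)
    if simulated.expression is not None:
        study = simulated.studies[0]
        with open(out / f"{study.name}_expression.tsv", "w") as fh:
            fh.write("sample\ttrait\n")
            for s, v in zip(study.samples, simulated.expression):
                fh.write(f"{s}\t{v:.6g}\n")
    manifest = {
        "seed": None if simulated.config is None else simulated.config.seed,
        "config_hash": None if simulated.config is None else simulated.config.config_hash(),
        "cohorts": [s.name for s in simulated.studies],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def _write_genotype_tsv(study: GenotypeStudy, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(v.id for v in study.variants) + "\n")
        fh.write("#chrom\t" + "\t".join(v.chrom for v in study.variants) + "\n")
        fh.write("#pos\t" + "\t".join(str(v.pos) for v in study.variants) + "\n")
        fh.write("#a1\t" + "\t".join(v.allele_minor for v in study.variants) + "\n")
        fh.write("#a2\t" + "\t".join(v.allele_major for v in study.variants) + "\n")
        for i, s in enumerate(study.samples):
            row = [
                "NA" if np.isnan(x) else (str(int(x)) if float(x).is_integer() else f"{x:.4g}")
                for x in study.dosage[i]
            ]
            fh.write(s + "\t" + "\t".join(row) + "\n")


def demo_config(
    seed: int = 0,
    n_cases: int = 4_000,
    n_controls: int = 3_000,
    planted_or: float = 0.4,
    planted_mafs: tuple[float, float] = (0.05, 0.2),
) -> SimulationConfig:
    """The desk-scale study conditions: 500 SNPs / 50 genes, three cohorts.

    One interaction (OR ``planted_or`` on the additive x additive log-odds
    scale) is planted between two SNPs in different genes and different
    (uncorrelated) LD blocks, at MAFs 0.05 and 0.20.  Discovery is
    ``n_cases``/``n_controls``; the two replication cohorts are roughly 5/7
    and 1/4 of the discovery size, chosen so that a true interaction of this
    magnitude is expected to clear the replication meta-analysis at this
    desk scale (the full-size design can afford proportionally smaller
    replication cohorts because its discovery arm is ~5x larger).
    """
    blocks = []
    for b in range(10):
        model = ("independent", "ar", "equicorrelated")[b % 3]
        rho = {"independent": 0.0, "ar": 0.8, "equicorrelated": 0.3}[model]
        blocks.append(BlockSpec(n_snps=50, model=model, rho=rho, chrom=str(b % 2 + 1)))
    scale = n_cases / 4_000
    cohorts = (
        CohortSpec("discovery", n_cases, n_controls),
        CohortSpec("replication1", int(2_400 * scale), int(2_600 * scale)),
        CohortSpec("replication2", max(int(800 * scale), 60), max(int(880 * scale), 60)),
    )
    # snp0010 sits in GENE001 (block 0); snp0310 in GENE031 (block 6); both independent blocks
    disease = DiseaseModel(
        planted_pairs=(PlantedPair("snp0010", "snp0310", beta=float(np.log(planted_or))),),
        covariate_effects={"cov1": 0.2},
    )
    return SimulationConfig(
        blocks=tuple(blocks),
        cohorts=cohorts,
        disease_model=disease,
        snps_per_gene=10,
        n_covariates=2,
        maf_overrides={"snp0010": 0.05, "snp0310": 0.2},
        seed=seed,
    )
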
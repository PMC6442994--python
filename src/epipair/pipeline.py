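"""End-to-end orchestration of the two-stage interaction scan.

Stage order on a set of cohorts (first = discovery, rest = replication):

1. filter the discovery panel to gene-mapped SNPs with MAF >= maf_min;
2. allelic Z screen on discovery, keep pairs with p < p_screen;
3. logistic interaction on discovery survivors, keep p < p_regress;
4. logistic interaction per replication cohort at the surviving pairs;
5. replication meta-analysis + direction-consistency filter;
6. joint meta over all cohorts (discovery included, so joint estimates carry
   the same winner's-curse bias as any two-stage design);
7. Bonferroni threshold from the discovery panel's effective SNP count;
   pairs with joint p below it are the significant set and are characterized
   downstream (stratified and joint-genotype views).

Pairs that survive discovery but fail replication are kept in an appendix
table rather than dropped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .core_io import GeneMap, GenotypeStudy, PairRecord
from .downstream import joint_genotype_or, stratified_association
from .fast_epistasis import n_eligible_pairs, screen_pairs
from .logistic_interaction import CollinearityError, InteractionResult, interaction_test
from .meta_analysis import MetaResult, StudySummary, fixed_effect_meta, replication_filter
from .multiplicity import multiplicity_report
from .snp_filtering import filter_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PairOutcome", "RunReport", "run_pipeline", "stratify_by_subtype"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and switches for one pipeline run."""

    p_screen: float = 1e-6
    p_regress: float = 1e-5
    p_replication: float = 0.05
    alpha: float = 0.05
    maf_min: float = 0.005
    covariate_names: tuple[str, ...] = ()
    block_size: int = 200
    within_gene: bool = False

    def __post_init__(self) -> None:
        for name in ("p_screen", "p_regress", "p_replication", "alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PairOutcome:
    """Everything the pipeline learned about one surviving SNP pair."""

    snp1: str
    snp2: str
    screen_p: float
    discovery: InteractionResult
    replication: dict[str, InteractionResult] = field(default_factory=dict)
    replication_meta: MetaResult | None = None
    replicated: bool = False
    replication_reason: str = ""
    joint: MetaResult | None = None
    significant: bool = False
    characterization: dict | None = None


@dataclass
class RunReport:
    stage_counts: dict[str, int]
    m_eff: int
    n_pair_tests: int
    threshold: float
    significant_pairs: list[tuple[str, str]]
    replicated_pairs: list[tuple[str, str]]
    appendix_pairs: list[tuple[str, str]]
    version: str
    config: dict
    wall_time_s: float

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["significant_pairs"] = [list(p) for p in self.significant_pairs]
        d["replicated_pairs"] = [list(p) for p in self.replicated_pairs]
        d["appendix_pairs"] = [list(p) for p in self.appendix_pairs]
        return json.dumps(d, indent=1)


def _pair_record(panel, outcome: PairOutcome) -> PairRecord:
    study = panel.study
    v1 = study.variants[study.variant_index(outcome.snp1)]
    v2 = study.variants[study.variant_index(outcome.snp2)]
    cohort_or = {"discovery": outcome.discovery.or_interaction}
    cohort_p = {"discovery": outcome.discovery.p}
    for name, res in outcome.replication.items():
        cohort_or[name] = res.or_interaction
        cohort_p[name] = res.p
    rec = PairRecord(
        snp1=v1.id, a1_1=v1.allele_minor, maf1=v1.maf, gene1=";".join(panel.genes_of(v1.id)),
        snp2=v2.id, a1_2=v2.allele_minor, maf2=v2.maf, gene2=";".join(panel.genes_of(v2.id)),
        cohort_or=cohort_or, cohort_p=cohort_p,
    )
    if outcome.joint is not None:
        rec.or_joint = outcome.joint.pooled_or
        rec.p_joint = outcome.joint.p
        rec.q_p = outcome.joint.q_p
    return rec


def run_pipeline(
    studies: list[GenotypeStudy],
    gene_map: GeneMap,
    config: PipelineConfig = PipelineConfig(),
    characterize: bool = True,
) -> tuple[RunReport, list[PairOutcome], list[PairRecord]]:
    """Run the full two-stage scan; returns (report, outcomes, result records).

    The first study is the discovery cohort; any further studies are
    replication cohorts (with none, the replication and joint stages are
    skipped with a notice and every stage-2 survivor lands in the appendix).
    A stage with zero survivors ends the run cleanly with a complete report.
    """
    if not studies:
        raise ValueError("run_pipeline needs at least one study (discovery)")
    t0 = time.monotonic()
    discovery, replication_studies = studies[0], studies[1:]

    panel = filter_panel(discovery, gene_map, maf_min=config.maf_min)
    mult = multiplicity_report(panel.study, block_size=config.block_size, alpha=config.alpha)
    counts = {
        "snps_retained": panel.study.n_variants,
        "pairs_eligible": n_eligible_pairs(panel, within_gene=config.within_gene),
    }

    outcomes: list[PairOutcome] = []
    if config.p_screen > 0.0:
        screened = screen_pairs(
            panel, threshold=config.p_screen, within_gene=config.within_gene
        )
    else:
        screened = []
    counts["pairs_screened"] = len(screened)
    logger.info("stage 1 screen: %d pairs below p_screen", len(screened))

    for hit in screened:
        try:
            res = interaction_test(panel.study, hit.snp1, hit.snp2, config.covariate_names)
        except CollinearityError:
            logger.warning("pair %s:%s degenerate in discovery; skipped", hit.snp1, hit.snp2)
            continue
        if np.isfinite(res.p) and res.p < config.p_regress:
            outcomes.append(
                PairOutcome(snp1=hit.snp1, snp2=hit.snp2, screen_p=hit.p, discovery=res)
            )
    counts["pairs_stage2"] = len(outcomes)
    logger.info("stage 2 regression: %d pairs below p_regress", len(outcomes))

    if not replication_studies:
        logger.warning("no replication cohorts supplied; replication/joint stages skipped")
    for outcome in outcomes:
        if not replication_studies:
            continue
        per_study: list[StudySummary] = []
        estimable = True
        for rep in replication_studies:
            try:
                res = interaction_test(rep, outcome.snp1, outcome.snp2, config.covariate_names)
            except CollinearityError:
                estimable = False
                continue
            outcome.replication[rep.name] = res
            if np.isfinite(res.p) and res.se3 > 0 and np.isfinite(res.se3):
                per_study.append(StudySummary.from_fit(res, cohort=rep.name))
            else:
                estimable = False
        if not estimable or not per_study:
            outcome.replicated = False
            outcome.replication_reason = "replication fit not estimable in some cohort"
            continue
        outcome.replication_meta = fixed_effect_meta(per_study)
        outcome.replicated, outcome.replication_reason = replication_filter(
            outcome.discovery, outcome.replication_meta, per_study,
            p_replication=config.p_replication,
        )
        if outcome.replicated:
            joint = [StudySummary.from_fit(outcome.discovery, cohort="discovery")] + per_study
            outcome.joint = fixed_effect_meta(joint)
            outcome.significant = outcome.joint.p < mult.threshold
    counts["pairs_replicated"] = sum(o.replicated for o in outcomes)
    counts["pairs_significant"] = sum(o.significant for o in outcomes)

    if characterize:
        for outcome in outcomes:
            if not outcome.significant:
                continue
            outcome.characterization = {
                "stratified": stratified_association(
                    panel.study, outcome.snp2, outcome.snp1, config.covariate_names
                ),
                "joint_genotype": joint_genotype_or(
                    panel.study, outcome.snp1, outcome.snp2, config.covariate_names
                ),
            }

    records = [_pair_record(panel, o) for o in outcomes]
    report = RunReport(
        stage_counts=counts,
        m_eff=mult.m_eff,
        n_pair_tests=mult.n_pair_tests,
        threshold=mult.threshold,
        significant_pairs=[(o.snp1, o.snp2) for o in outcomes if o.significant],
        replicated_pairs=[(o.snp1, o.snp2) for o in outcomes if o.replicated],
        appendix_pairs=[(o.snp1, o.snp2) for o in outcomes if not o.replicated],
        version=__version__,
        config=dict(
            p_screen=config.p_screen, p_regress=config.p_regress,
            p_replication=config.p_replication, alpha=config.alpha,
            maf_min=config.maf_min, covariates=list(config.covariate_names),
            block_size=config.block_size, within_gene=config.within_gene,
        ),
        wall_time_s=time.monotonic() - t0,
    )
    return report, outcomes, records


def stratify_by_subtype(
    studies: list[GenotypeStudy],
    subtype_labels: dict[str, np.ndarray],
    subtype: str,
) -> list[GenotypeStudy]:
    """Restrict cases to one histology subtype; all controls are retained.

    ``subtype_labels`` maps study name -> per-sample label array (labels are
    meaningful for cases; controls are kept regardless of label).
    """
    out = []
    for study in studies:
        labels = np.asarray(subtype_labels[study.name])
        if labels.shape != (study.n_samples,):
            raise ValueError(f"label vector length mismatch for study {study.name!r}")
        case_labels = set(labels[study.status == 1])
        if subtype not in case_labels:
            raise ValueError(
                f"subtype {subtype!r} has no cases in study {study.name!r}; "
                f"available: {sorted(map(str, case_labels))}"
            )
        keep = (study.status == 0) | (labels == subtype)
        out.append(study.subset_samples(keep, name=f"{study.name}[{subtype}]"))
    return out
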
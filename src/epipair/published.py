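"""Published per-cohort interaction summaries for the lead lung-cancer SNP pairs.

These are the printed per-cohort (odds ratio, p-value) cells for the
flagship pairs of the lung-cancer oncogene interaction scan this package
implements: an OncoArray discovery cohort and Affymetrix/GELCC replication
cohorts, one row set per histology stratum.  They serve as inputs for
recomputing the joint fixed-effect odds ratios from summary statistics
(the per-study standard errors are recovered from the printed Wald
p-values); the joint values themselves are never stored here.
"""

from __future__ import annotations

from .meta_analysis import MetaResult, StudySummary, fixed_effect_meta

__all__ = ["LEAD_PAIR_SUMMARIES", "pooled_lead_pair"]

#: stratum -> (snp1, snp2, [(cohort, OR, p), ...])
LEAD_PAIR_SUMMARIES: dict[str, tuple[str, str, list[tuple[str, float, float]]]] = {
    "ALL": (
        "rs74826777", "rs17835244",
        [
            ("OncoArray", 0.48, 2.89e-08),
            ("Affymetrix", 0.17, 4.84e-04),
            ("GELCC", 0.29, 5.66e-02),
        ],
    ),
    "NSCLC": (
        "rs74826777", "rs1474960",
        [
            ("OncoArray", 0.44, 7.23e-08),
            ("Affymetrix", 0.13, 6.84e-04),
            ("GELCC", 0.22, 3.92e-02),
        ],
    ),
    "ADE": (
        "rs1554783", "rs10515157",
        [
            ("OncoArray", 0.79, 3.04e-07),
            ("Affymetrix", 0.79, 8.69e-03),
            ("GELCC", 0.52, 5.47e-03),
        ],
    ),
    "SQC": (
        "rs1882898", "rs1705235",
        [
            ("OncoArray", 1.51, 1.45e-07),
            ("Affymetrix", 2.26, 2.91e-02),
            ("GELCC", 9.95, 9.31e-04),
        ],
    ),
}


def pooled_lead_pair(stratum: str) -> MetaResult:
    """Recompute the joint fixed-effect meta for one stratum's lead pair.

    Standard errors are recovered from each cohort's printed (OR, p) cell;
    pooling is inverse-variance fixed-effect.
    """
    _, _, cells = LEAD_PAIR_SUMMARIES[stratum]
    summaries = [StudySummary.from_or_p(c, o, p) for c, o, p in cells]
    return fixed_effect_meta(summaries)
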
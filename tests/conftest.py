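import numpy as np
import pandas as pd
import pytest

from epipair.core_io import GeneMap, GenotypeStudy, VariantInfo


def make_study(
    dosage,
    status=None,
    name="toy",
    chrom="1",
    positions=None,
    covariates=None,
    ids=None,
):
    """Build a GenotypeStudy from a raw dosage matrix with sensible metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions or [1000 * (j + 1) for j in range(m)]
    ids = ids or [f"snp{j}" for j in range(m)]
    variants = []
    for j in range(m):
        obs = dosage[:, j][~np.isnan(dosage[:, j])]
        freq = float(obs.mean() / 2) if obs.size else 0.0
        variants.append(
            VariantInfo(
                id=ids[j], chrom=chrom, pos=positions[j],
                allele_minor="A", allele_major="G", maf=min(freq, 1 - freq),
            )
        )
    return GenotypeStudy(
        name=name,
        variants=variants,
        samples=[f"s{i}" for i in range(n)],
        dosage=dosage,
        status=None if status is None else np.asarray(status),
        covariates=None if covariates is None else pd.DataFrame(covariates),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_gene_map():
    return GeneMap(intervals={"GA": [("1", 500, 1500)], "GB": [("1", 1501, 5000)]})
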
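import json

import numpy as np
import pytest
from scipy import stats

from epipair.core_io import read_matrix_tables
from epipair.logistic_interaction import interaction_test
from epipair.synthetic_data import (
    BlockSpec,
    CohortSpec,
    DiseaseModel,
    ExpressionModel,
    PlantedPair,
    SimulationConfig,
    demo_config,
    simulate_case_control,
    simulate_genotypes,
    simulate_study_set,
    write_fixture_set,
)


def small_config(seed=0, **kwargs):
    defaults = dict(
        blocks=(BlockSpec(n_snps=6, maf_range=(0.1, 0.4)),),
        cohorts=(CohortSpec("c1", 150, 150),),
        disease_model=DiseaseModel(),
        snps_per_gene=3,
        n_covariates=1,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestSimulateGenotypes:
    def test_independent_blocks_uncorrelated(self, rng):
        n = 4000
        blocks = (BlockSpec(n_snps=10, maf_range=(0.2, 0.4)),)
        G = simulate_genotypes(blocks, np.full(10, 0.3), n, rng)
        R = np.corrcoef(G, rowvar=False)
        off = R[~np.eye(10, dtype=bool)]
        assert np.max(np.abs(off)) < 4 / np.sqrt(n)

    def test_ar_block_correlation_decays(self, rng):
        n = 5000
        blocks = (BlockSpec(n_snps=10, model="ar", rho=0.9),)
        G = simulate_genotypes(blocks, np.full(10, 0.3), n, rng)
        R = np.corrcoef(G, rowvar=False)
        adjacent = np.mean([R[i, i + 1] for i in range(9)])
        distant = np.mean([R[i, i + 5] for i in range(5)])
        assert adjacent > 0.5
        assert distant < adjacent

    def test_hwe_by_construction(self, rng):
        n, m = 20_000, 40
        blocks = (BlockSpec(n_snps=m, model="equicorrelated", rho=0.4,
                            maf_range=(0.1, 0.45)),)
        mafs = rng.uniform(0.1, 0.45, m)
        G = simulate_genotypes(blocks, mafs, n, rng)
        ps = []
        for j in range(m):
            counts = np.bincount(G[:, j].astype(int), minlength=3)
            p_hat = (2 * counts[2] + counts[1]) / (2 * n)
            expected = n * np.array(
                [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]
            )
            chi2 = np.sum((counts - expected) ** 2 / expected)
            ps.append(stats.chi2.sf(chi2, 1))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_realized_maf_near_target(self, rng):
        n = 5000
        mafs = np.array([0.05, 0.2, 0.4])
        G = simulate_genotypes((BlockSpec(n_snps=3),), mafs, n, rng)
        realized = G.mean(axis=0) / 2
        se = np.sqrt(mafs * (1 - mafs) / (2 * n))
        assert np.all(np.abs(realized - mafs) < 3.5 * se)


class TestSimulateCaseControl:
    def test_null_prevalence_matches_intercept(self, rng):
        eta = np.full(50_000, np.log(0.1 / 0.9))
        prob = 1 / (1 + np.exp(-eta))
        disease = rng.random(eta.size) < prob
        assert disease.mean() == pytest.approx(0.1, abs=0.01)

    def test_exact_arm_counts(self, rng):
        eta = np.full(5000, 0.0)
        idx, status = simulate_case_control(eta, 800, 900, rng)
        assert status.sum() == 800 and (status == 0).sum() == 900
        assert len(np.unique(idx)) == 1700

    def test_insufficient_source_is_error(self, rng):
        eta = np.full(100, -5.0)  # prevalence ~0.7%
        with pytest.raises(ValueError, match="source population"):
            simulate_case_control(eta, 50, 10, rng)

    def test_interaction_ci_coverage(self):
        """Planted beta3 = ln 2: the stage-2 Wald CI covers the truth ~95%."""
        beta3 = np.log(2.0)
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = SimulationConfig(
                blocks=(BlockSpec(n_snps=2, maf_range=(0.3, 0.3)),),
                cohorts=(CohortSpec("c", 700, 700),),
                disease_model=DiseaseModel(
                    planted_pairs=(PlantedPair("snp0000", "snp0001", beta3),)
                ),
                snps_per_gene=1,
                n_covariates=0,
                seed=100_000 + rep,
            )
            study = simulate_study_set(cfg).studies[0]
            res = interaction_test(study, "snp0000", "snp0001")
            lo, hi = res.beta3 - 1.96 * res.se3, res.beta3 + 1.96 * res.se3
            covered += lo <= beta3 <= hi
        assert covered / n_rep == pytest.approx(0.95, abs=0.045)

    def test_same_seed_bit_identical(self):
        a = simulate_study_set(small_config(seed=5)).studies[0]
        b = simulate_study_set(small_config(seed=5)).studies[0]
        np.testing.assert_array_equal(a.dosage, b.dosage)
        np.testing.assert_array_equal(a.status, b.status)
        assert a.samples == b.samples

    def test_different_seed_differs(self):
        a = simulate_study_set(small_config(seed=5)).studies[0]
        b = simulate_study_set(small_config(seed=6)).studies[0]
        assert not np.array_equal(a.dosage, b.dosage)


class TestSimulateExpression:
    def test_noiseless_identity(self):
        cfg = small_config(
            expression=ExpressionModel("snp0000", "snp0001", delta=1.0, sigma=0.0)
        )
        simset = simulate_study_set(cfg)
        study = simset.studies[0]
        from epipair.downstream import eqtl_interaction

        res = eqtl_interaction(simset.expression, study.genotype("snp0000"),
                               study.genotype("snp0001"))
        assert res.beta_interaction == pytest.approx(1.0, abs=1e-9)

    def test_null_interaction_p_uniform(self):
        from epipair.downstream import eqtl_interaction

        ps = []
        for rep in range(200):
            cfg = small_config(
                seed=200_000 + rep,
                cohorts=(CohortSpec("c1", 200, 209),),
                expression=ExpressionModel("snp0000", "snp0001", delta=0.0, sigma=1.0),
            )
            simset = simulate_study_set(cfg)
            study = simset.studies[0]
            ps.append(
                eqtl_interaction(
                    simset.expression, study.genotype("snp0000"), study.genotype("snp0001")
                ).p_interaction
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_monotone_in_delta(self):
        from epipair.downstream import eqtl_interaction

        power = []
        for delta in (0.0, 0.4, 0.8):
            hits = 0
            for rep in range(60):
                cfg = small_config(
                    seed=300_000 + rep,
                    cohorts=(CohortSpec("c1", 200, 209),),
                    expression=ExpressionModel("snp0000", "snp0001", delta=delta, sigma=1.0),
                )
                simset = simulate_study_set(cfg)
                study = simset.studies[0]
                res = eqtl_interaction(
                    simset.expression, study.genotype("snp0000"), study.genotype("snp0001")
                )
                hits += res.p_interaction < 0.05
            power.append(hits / 60)
        assert power[0] < power[-1]
        assert power == sorted(power)


class TestWriteFixtureSet:
    def test_round_trip_through_core_io(self, tmp_path):
        simset = simulate_study_set(small_config(seed=3))
        out = write_fixture_set(simset, tmp_path / "fx")
        study = read_matrix_tables(
            str(out / "c1_genotypes.tsv"),
            str(out / "c1_phenotype.tsv"),
            str(out / "c1_covariates.tsv"),
        )
        orig = simset.studies[0]
        np.testing.assert_array_equal(study.dosage, orig.dosage)
        np.testing.assert_array_equal(study.status, orig.status)
        assert [v.id for v in study.variants] == [v.id for v in orig.variants]

    def test_manifest_hash_tracks_config(self, tmp_path):
        c1, c2 = small_config(seed=1), small_config(seed=2)
        assert c1.config_hash() != c2.config_hash()
        assert c1.config_hash() == small_config(seed=1).config_hash()
        out = write_fixture_set(simulate_study_set(c1), tmp_path / "fx")
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["config_hash"] == c1.config_hash()

    def test_truth_ids_resolve(self, tmp_path):
        cfg = small_config(
            disease_model=DiseaseModel(
                planted_pairs=(PlantedPair("snp0000", "snp0003", 0.5),)
            )
        )
        simset = simulate_study_set(cfg)
        out = write_fixture_set(simset, tmp_path / "fx")
        truth = json.loads((out / "truth.json").read_text())
        header = (out / "c1_genotypes.tsv").read_text().splitlines()[0].split("\t")
        for rec in truth:
            assert rec["snp1"] in header and rec["snp2"] in header

    def test_nonempty_dir_without_force_is_error(self, tmp_path):
        d = tmp_path / "fx"
        d.mkdir()
        (d / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_fixture_set(simulate_study_set(small_config()), d)
        write_fixture_set(simulate_study_set(small_config()), d, force=True)


class TestDemoConfig:
    def test_demo_config_structure(self):
        cfg = demo_config(seed=1)
        assert sum(b.n_snps for b in cfg.blocks) == 500
        assert len(cfg.cohorts) == 3
        assert cfg.cohorts[0].n_cases == 4000
        (pair,) = cfg.disease_model.planted_pairs
        assert np.exp(pair.beta) == pytest.approx(0.4)

    def test_planted_mafs_realized(self):
        simset = simulate_study_set(demo_config(seed=11, n_cases=400, n_controls=300))
        study = simset.studies[0]
        maf1 = study.variants[study.variant_index("snp0010")].maf
        maf2 = study.variants[study.variant_index("snp0310")].maf
        assert maf1 == pytest.approx(0.05, abs=0.03)
        assert maf2 == pytest.approx(0.2, abs=0.05)
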
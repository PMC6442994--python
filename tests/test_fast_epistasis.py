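"""Allelic screen: table construction, Z contrast, and the vectorized scan.

The reference oracle for the pairing table enumerates haplotype phases
directly: a non-double-heterozygote's two allele pairings are determined by
its genotypes; a double heterozygote splits weight 1/2 over each of its two
possible phase configurations.  The production code computes the same table
through dosage products, so agreement across all genotype configurations is
a genuine dual-route check.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epipair.fast_epistasis import (
    allele_pairing_table,
    allelic_log_or,
    fast_epistasis_z,
    screen_pairs,
)
from epipair.snp_filtering import filter_panel

from conftest import make_study


def phase_enumeration_table(g1, g2):
    """Independent oracle: per-individual haplotype-phase enumeration."""
    counts = np.zeros((2, 2))
    for a, b in zip(g1, g2):
        if np.isnan(a) or np.isnan(b):
            continue
        hap1 = [1] * int(a) + [0] * (2 - int(a))  # 1 = minor allele
        if a == 1 and b == 1:
            # two phases, each with probability 1/2
            for h2 in ([1, 0], [0, 1]):
                for x, y in zip(hap1, h2):
                    counts[1 - x, 1 - y] += 0.5
        else:
            hap2 = [1] * int(b) + [0] * (2 - int(b))
            for x, y in zip(hap1, hap2):
                counts[1 - x, 1 - y] += 1.0
    return counts


class TestAllelePairingTable:
    def test_double_het_splits_evenly(self):
        t = allele_pairing_table([1, 1], [1, 1])
        # duplicated individual keeps the per-individual pattern of all-0.5 cells
        np.testing.assert_allclose(t.counts, [[1, 1], [1, 1]])
        t1 = allele_pairing_table(np.array([1.0, np.nan]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(t1.counts, [[0.5, 0.5], [0.5, 0.5]])

    def test_double_minor_homozygote(self):
        t = allele_pairing_table(np.array([2.0, np.nan]), np.array([2.0, 0.0]))
        np.testing.assert_allclose(t.counts, [[2, 0], [0, 0]])

    def test_hand_summed_cohort(self):
        t = allele_pairing_table([0, 2, 1], [0, 2, 1])
        np.testing.assert_allclose(t.counts, [[2.5, 0.5], [0.5, 2.5]])
        assert t.n_individuals == 3

    def test_matches_phase_enumeration_on_all_pair_configs(self):
        # every two-individual configuration of genotype pairs: 3^4 cases
        for a1, b1, a2, b2 in itertools.product((0, 1, 2), repeat=4):
            g1, g2 = [a1, a2], [b1, b2]
            t = allele_pairing_table(g1, g2)
            np.testing.assert_allclose(
                t.counts, phase_enumeration_table(g1, g2), atol=1e-6,
                err_msg=f"config {(a1, b1, a2, b2)}",
            )

    @given(
        st.lists(
            st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=2, max_size=30
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_total_weight_is_two_per_individual(self, pairs):
        g1 = [a for a, _ in pairs]
        g2 = [b for _, b in pairs]
        t = allele_pairing_table(g1, g2)
        assert t.counts.sum() == pytest.approx(2 * len(pairs))

    def test_single_individual_double_het(self):
        t = allele_pairing_table([1], [1])
        np.testing.assert_allclose(t.counts, [[0.5, 0.5], [0.5, 0.5]])

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError, match="no individuals"):
            allele_pairing_table(np.array([np.nan, np.nan]), np.array([1.0, 1]))

    def test_single_individual_group_is_error_in_z_test(self):
        g = np.array([0.0, 1, 2])
        with pytest.raises(ValueError, match="fewer than 2"):
            fast_epistasis_z(g, g, np.array([1, 0, 0]))


class TestAllelicLogOr:
    def test_symmetric_table_closed_form(self):
        from epipair.fast_epistasis import AllelePairingTable

        lnor, se = allelic_log_or(AllelePairingTable(np.array([[4., 2], [2, 4]]), 6))
        assert lnor == pytest.approx(np.log(4.0))
        assert se == pytest.approx(np.sqrt(1 / 4 + 1 / 2 + 1 / 2 + 1 / 4))

    def test_independence_gives_zero(self):
        from epipair.fast_epistasis import AllelePairingTable

        lnor, _ = allelic_log_or(AllelePairingTable(np.ones((2, 2)), 2))
        assert lnor == 0.0

    def test_zero_cell_continuity_correction(self):
        from epipair.fast_epistasis import AllelePairingTable

        lnor, se = allelic_log_or(AllelePairingTable(np.array([[3., 0], [1, 2]]), 3))
        assert lnor == pytest.approx(np.log(3.5 * 2.5 / (0.5 * 1.5)))
        assert np.isfinite(se)


class TestFastEpistasisZ:
    def null_data(self):
        g1 = np.array([0, 1, 2, 1, 0, 1, 2, 0] * 2, dtype=float)
        g2 = np.array([1, 1, 0, 2, 0, 1, 1, 0] * 2, dtype=float)
        status = np.array([1] * 8 + [0] * 8)
        return g1, g2, status

    def test_identical_groups_give_z_zero_p_one(self):
        g1, g2, status = self.null_data()
        r = fast_epistasis_z(g1, g2, status)
        assert r.z == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_snp_order_symmetry(self):
        rng = np.random.default_rng(5)
        g1 = rng.binomial(2, 0.3, 200).astype(float)
        g2 = rng.binomial(2, 0.4, 200).astype(float)
        status = rng.integers(0, 2, 200)
        r12 = fast_epistasis_z(g1, g2, status)
        r21 = fast_epistasis_z(g2, g1, status)
        assert r12.z == pytest.approx(r21.z)

    def test_case_control_relabel_flips_sign(self):
        rng = np.random.default_rng(6)
        g1 = rng.binomial(2, 0.3, 200).astype(float)
        g2 = rng.binomial(2, 0.4, 200).astype(float)
        status = rng.integers(0, 2, 200)
        r = fast_epistasis_z(g1, g2, status)
        r_flip = fast_epistasis_z(g1, g2, 1 - status)
        assert r_flip.z == pytest.approx(-r.z)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(8)
        g1 = rng.binomial(2, 0.3, 100).astype(float)
        g2 = rng.binomial(2, 0.4, 100).astype(float)
        status = rng.integers(0, 2, 100)
        perm = rng.permutation(100)
        r = fast_epistasis_z(g1, g2, status)
        rp = fast_epistasis_z(g1[perm], g2[perm], status[perm])
        assert rp.z == pytest.approx(r.z)

    def test_empty_group_is_error(self):
        g = np.array([0.0, 1, 2])
        with pytest.raises(ValueError, match="case"):
            fast_epistasis_z(g, g, np.zeros(3, dtype=int))

    def test_null_calibration_matches_frozen_reference(self):
        """The screen is conservative: its null rejection rate at alpha=0.05,
        measured once at 0.006 (n=1000, 2000 pairs), is a stable property."""
        from scipy.stats import binom

        rng = np.random.default_rng(777)
        n, n_pairs = 1000, 2000
        hits = 0
        for _ in range(n_pairs):
            maf1, maf2 = rng.uniform(0.05, 0.5, 2)
            r = fast_epistasis_z(
                rng.binomial(2, maf1, n).astype(float),
                rng.binomial(2, maf2, n).astype(float),
                rng.integers(0, 2, n),
            )
            hits += r.p < 0.05
        lo = binom.ppf(0.005, n_pairs, 0.006)
        hi = binom.ppf(0.995, n_pairs, 0.006)
        assert lo <= hits <= hi


class TestScreenPairs:
    def five_gene_panel(self, rng, n=300, m=5):
        dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        study = make_study(dosage, status=rng.integers(0, 2, n),
                           positions=[1000 * (j + 1) for j in range(m)])
        from epipair.core_io import GeneMap

        gm = GeneMap(intervals={
            f"G{j}": [("1", 1000 * (j + 1) - 10, 1000 * (j + 1) + 10)] for j in range(m)
        })
        return filter_panel(study, gm, maf_min=0.0)

    def test_threshold_one_returns_all_pairs(self, rng):
        panel = self.five_gene_panel(rng)
        assert len(screen_pairs(panel, threshold=1.0)) == 10  # C(5,2)

    def test_results_sorted_by_p(self, rng):
        panel = self.five_gene_panel(rng)
        ps = [r.p for r in screen_pairs(panel, threshold=1.0)]
        assert ps == sorted(ps)

    def test_vectorized_scan_matches_scalar_test(self, rng):
        panel = self.five_gene_panel(rng, n=200)
        # add missingness to exercise pairwise complete-case handling
        d = panel.study.dosage
        d[rng.random(d.shape) < 0.05] = np.nan
        status = panel.study.status
        for r in screen_pairs(panel, threshold=1.0):
            scalar = fast_epistasis_z(
                panel.study.genotype(r.snp1), panel.study.genotype(r.snp2), status
            )
            assert r.z == pytest.approx(scalar.z, rel=1e-10)
            assert r.p == pytest.approx(scalar.p, rel=1e-10)

    def test_within_gene_pairs_excluded_by_default(self, rng):
        from epipair.core_io import GeneMap

        dosage = rng.binomial(2, 0.3, size=(100, 4)).astype(float)
        study = make_study(dosage, status=rng.integers(0, 2, 100),
                           positions=[1000, 1100, 5000, 5100])
        gm = GeneMap(intervals={"GA": [("1", 900, 2000)], "GB": [("1", 4900, 6000)]})
        panel = filter_panel(study, gm, maf_min=0.0)
        cross = screen_pairs(panel, threshold=1.0)
        assert len(cross) == 4  # 2 x 2 cross-gene pairs only
        everything = screen_pairs(panel, threshold=1.0, within_gene=True)
        assert len(everything) == 6

    def test_planted_interaction_ranks_first(self):
        """A strong planted interaction (OR 2, n=4000) should top the screen."""
        n, m = 4000, 12
        first = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
            eta = -0.6 + np.log(2.0) * dosage[:, 0] * dosage[:, 1]
            status = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            study = make_study(dosage, status=status,
                               positions=[1000 * (j + 1) for j in range(m)])
            from epipair.core_io import GeneMap

            gm = GeneMap(intervals={
                f"G{j}": [("1", 1000 * (j + 1) - 10, 1000 * (j + 1) + 10)]
                for j in range(m)
            })
            panel = filter_panel(study, gm, maf_min=0.0)
            hits = screen_pairs(panel, threshold=1.0)
            if {hits[0].snp1, hits[0].snp2} == {"snp0", "snp1"}:
                first += 1
        assert first >= 0.95 * n_rep
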
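"""The tiered Balding–Nichols cohort generator."""

import numpy as np
import pytest
from scipy import stats as st

import multindel as md
from multindel.fst import _pool_stats, wc_theta_multilocus
from multindel.sim import SimConfig, draw_balding_nichols_frequencies


class TestBaldingNichols:
    def test_zero_F_returns_ancestral_exactly(self):
        rng = np.random.default_rng(0)
        out = draw_balding_nichols_frequencies(0.5, 0.0, 3, rng)
        assert np.array_equal(out, [0.5, 0.5, 0.5])

    def test_variance_matches_beta_moment(self):
        """Sample variance of draws approx F p (1-p) (within 10%)."""
        rng = np.random.default_rng(1)
        draws = np.concatenate(
            [draw_balding_nichols_frequencies(0.5, 0.2, 5, rng) for _ in range(2000)]
        )
        expected = 0.2 * 0.25
        assert np.var(draws) == pytest.approx(expected, rel=0.10)
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    def test_high_F_is_bimodal(self):
        rng = np.random.default_rng(2)
        draws = np.concatenate(
            [draw_balding_nichols_frequencies(0.3, 0.99, 2, rng) for _ in range(2000)]
        )
        assert np.mean((draws > 0.2) & (draws < 0.8)) < 0.2

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_degenerate_ancestral_frequency_rejected(self, p):
        with pytest.raises(ValueError):
            draw_balding_nichols_frequencies(p, 0.2, 2, np.random.default_rng(0))


class TestSimConfigValidation:
    def test_invalid_fixation_index(self):
        with pytest.raises(ValueError):
            SimConfig(F_continental=1.0)

    def test_ancestral_range_must_be_interior(self):
        with pytest.raises(ValueError):
            SimConfig(ancestral_freq_range=(0.0, 0.9))


class TestTieredCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=11, n_loci=60, samples_per_pop=10, cluster_fraction=0.4)
        for name in ("a", "b"):
            md.emit_vcf(md.simulate_tiered_cohort(cfg), tmp_path / f"{name}.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_theta_recovers_generating_F_sub(self):
        """Two sub-populations at F_sub = 0.15: estimated theta within 0.02."""
        cfg = SimConfig(
            seed=13, n_loci=2000, samples_per_pop=100, cluster_fraction=0.0,
            F_continental=0.0, F_sub=0.15,
            tier_structure=[("EAS", ["CHB", "KHV"])],
        )
        cohort = md.simulate_tiered_cohort(cfg)
        n, p, h = _pool_stats(cohort, [["CHB"], ["KHV"]])
        assert wc_theta_multilocus(n, p, h) == pytest.approx(0.15, abs=0.02)

    def test_cluster_gaps_respect_configured_range(self):
        cfg = SimConfig(
            seed=3, n_loci=120, samples_per_pop=5, cluster_fraction=0.5,
            cluster_size_range=(3, 3), cluster_gap_range=(40, 80),
        )
        cohort = md.simulate_tiered_cohort(cfg)
        groups = md.cluster_candidates(cohort.loci, max_gap=81)
        clustered = [g for g in groups if len(g) >= 3]
        assert clustered, "expected clustered triples"
        for g in clustered:
            gaps = [b.position - a.position for a, b in zip(g, g[1:])]
            assert all(40 <= gap <= 80 for gap in gaps)

    def test_hardy_weinberg_at_each_locus(self):
        """Chi-square GoF against p^2, 2pq, q^2 non-rejected at >= 93% of loci."""
        cfg = SimConfig(
            seed=29, n_loci=1000, samples_per_pop=500, cluster_fraction=0.0,
            F_continental=0.0, tier_structure=[("X", ["X"])],
        )
        cohort = md.simulate_tiered_cohort(cfg)
        dose = cohort.haplotypes.sum(axis=1)  # (n, L)
        n = cohort.n_samples
        non_rejected = 0
        tested = 0
        for j in range(cohort.n_loci):
            obs = np.bincount(dose[:, j], minlength=3)
            p = obs @ np.array([0, 1, 2]) / (2 * n)
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            keep = exp > 5
            if keep.sum() < 2:
                continue
            chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            tested += 1
            if chi2 < st.chi2.ppf(0.95, df=keep.sum() - 1):
                non_rejected += 1
        assert tested > 500
        assert non_rejected / tested >= 0.93

    def test_clustered_loci_are_in_ld(self):
        """Shared cluster backgrounds yield allele correlation ~ ld_coefficient,
        i.e. r^2 ~ 0.5 at the default 0.7."""
        cfg = SimConfig(
            seed=31, n_loci=400, samples_per_pop=300, cluster_fraction=1.0,
            cluster_size_range=(2, 2), F_continental=0.0,
            tier_structure=[("X", ["X"])], ld_coefficient=0.7,
        )
        cohort = md.simulate_tiered_cohort(cfg)
        h = cohort.haplotypes.reshape(-1, cohort.n_loci).astype(float)
        index = cohort.locus_index()
        rs = []
        for g in md.cluster_candidates(cohort.loci, max_gap=200):
            a = h[:, index[(g[0].chrom, g[0].position)]]
            b = h[:, index[(g[1].chrom, g[1].position)]]
            if a.std() > 0 and b.std() > 0:
                rs.append(np.corrcoef(a, b)[0, 1] ** 2)
        assert np.mean(rs) == pytest.approx(0.49, abs=0.1)


class TestMarkerCohort:
    def test_shapes_labels_and_determinism(self):
        g1, labels, truth = md.simulate_marker_cohort(seed=5)
        g2, _, _ = md.simulate_marker_cohort(seed=5)
        assert g1.equals(g2)
        assert len(truth) == 12
        assert set(labels.values()) == {"POP1", "POP2"}
        n1 = sum(1 for v in labels.values() if v == "POP1")
        assert (n1, len(labels) - n1) == (110, 100)
        assert len(g1) == 210 * 12

    def test_null_cohort_has_identical_population_frequencies(self):
        _, _, truth = md.simulate_marker_cohort(seed=6, theta_range=(0.0, 0.0))
        for freqs in truth.values():
            assert np.allclose(freqs[0], freqs[1])

    def test_counted_frequencies_approach_truth(self):
        geno, labels, truth = md.simulate_marker_cohort(
            seed=7, pop_sizes={"A": 500, "B": 500}
        )
        tables = md.count_haplotype_frequencies(geno, labels)
        for mid, true_f in truth.items():
            df = tables[mid]
            for pi, pop in enumerate(["A", "B"]):
                for k, key in enumerate(f"h{j}" for j in range(true_f.shape[1])):
                    got = df.at[pop, key] if key in df.columns else 0.0
                    assert got == pytest.approx(true_f[pi, k], abs=0.05)
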
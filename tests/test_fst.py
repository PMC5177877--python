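"""Weir–Cockerham theta estimation and the two-tier ancestry screen."""

import numpy as np
import pytest

import multindel as md
from multindel.fst import (
    LocusPopStats,
    pairwise_theta_matrices,
    screen_loci,
    theta_components,
    wc_theta,
    wc_theta_multilocus,
    wc_theta_vector,
)

from .wc_oracle import wc_theta_oracle


class TestWcTheta:
    def test_fixed_difference_gives_theta_one(self):
        stats = LocusPopStats.from_genotype_counts([(10, 0, 0), (0, 0, 10)])
        a, b, c = theta_components(stats.n, stats.p, stats.h)
        assert a == pytest.approx(0.5)
        assert b == pytest.approx(0.0)
        assert c == pytest.approx(0.0)
        assert wc_theta(stats) == pytest.approx(1.0)

    def test_shared_fixation_is_undefined(self):
        stats = LocusPopStats.from_genotype_counts([(0, 0, 10), (0, 0, 10)])
        assert np.isnan(wc_theta(stats))

    def test_hand_counts_match_exact_oracle(self):
        counts = [(6, 3, 1), (1, 3, 6)]
        expected = float(wc_theta_oracle(counts))
        got = wc_theta(LocusPopStats.from_genotype_counts(counts))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_hundred_random_instances_match_oracle_to_1e12(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            r = int(rng.integers(2, 5))
            counts = [tuple(int(x) for x in rng.integers(0, 12, size=3)) for _ in range(r)]
            if any(sum(c) == 0 for c in counts):
                continue
            expected = wc_theta_oracle(counts)
            got = wc_theta(LocusPopStats.from_genotype_counts(counts))
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(float(expected), abs=1e-12)
            checked += 1

    def test_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(5, 50, size=2).astype(float)
            p = rng.random(2)
            # h consistent with some genotype configuration: h <= 2 min(p, 1-p) not
            # required by the estimator, any h in [0,1] is algebraically valid
            h = rng.random(2)
            s1 = LocusPopStats(n=n, p=p, h=h)
            s2 = LocusPopStats(n=n, p=1 - p, h=h)
            t1, t2 = wc_theta(s1), wc_theta(s2)
            assert t1 == pytest.approx(t2, abs=1e-10)

    def test_balding_nichols_parameter_recovery(self):
        """Multi-locus weighted theta recovers the generating F within 0.02."""
        rng = np.random.default_rng(123)
        F, L, n = 0.2, 2000, 100
        anc = rng.uniform(0.05, 0.95, L)
        scale = (1 - F) / F
        pf = np.stack([rng.beta(anc * scale, (1 - anc) * scale) for _ in range(2)])
        dose = np.stack(
            [(rng.random((2 * n, L)) < pf[k]).reshape(n, 2, L).sum(axis=1) for k in range(2)]
        )
        nn = np.full((2, L), float(n))
        p = dose.sum(axis=1) / (2 * n)
        h = (dose == 1).sum(axis=1) / n
        assert wc_theta_multilocus(nn, p, h) == pytest.approx(F, abs=0.02)
        # and the vectorized per-locus path agrees with the scalar path
        th_vec = wc_theta_vector(nn, p, h)
        for j in rng.integers(0, L, size=10):
            scalar = wc_theta(LocusPopStats(n=nn[:, j], p=p[:, j], h=h[:, j]))
            assert th_vec[j] == pytest.approx(scalar, nan_ok=True, abs=1e-12)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = md.SimConfig(seed=5, n_loci=50, samples_per_pop=40, cluster_fraction=0.0)
    return md.simulate_tiered_cohort(cfg), cfg


class TestPairwiseMatrices:
    def test_five_tiers_give_ten_pairs_and_symmetry(self, small_cohort):
        cohort, cfg = small_cohort
        results = pairwise_theta_matrices(cohort, cfg.tier_structure)
        assert len(results) == cohort.n_loci
        r = results[0]
        off = ~np.eye(5, dtype=bool)
        assert np.isfinite(r.continental_theta[off]).sum() + np.isnan(
            r.continental_theta[off]
        ).sum() == 20  # 10 unordered pairs stored symmetrically
        assert np.allclose(r.continental_theta, r.continental_theta.T, equal_nan=True)
        assert np.allclose(r.sub_theta, r.sub_theta.T, equal_nan=True)
        assert np.isnan(np.diag(r.continental_theta)).all()

    def test_duplicated_population_has_near_zero_theta(self):
        cfg = md.SimConfig(
            seed=9, n_loci=200, samples_per_pop=100, cluster_fraction=0.0,
            tier_structure=[("A", ["A"]), ("B", ["B"])], F_continental=0.3,
        )
        cohort = md.simulate_tiered_cohort(cfg)
        # same samples twice under two names
        import numpy as np_

        dup = md.PhasedCohort(
            sample_ids=[f"x{i}" for i in range(2 * cohort.n_samples)],
            populations=["P"] * cohort.n_samples + ["Q"] * cohort.n_samples,
            loci=cohort.loci,
            haplotypes=np_.concatenate([cohort.haplotypes, cohort.haplotypes]),
        )
        results = pairwise_theta_matrices(dup, [("P", ["P"]), ("Q", ["Q"])])
        thetas = np.array([r.continental_theta[0, 1] for r in results])
        assert np.nanmax(np.abs(thetas)) < 0.01


class TestScreen:
    def _result(self, cont, sub, locus=None):
        locus = locus or md.InDelVariant("rs1", "1", 100, "-", "A")
        T, S = len(cont), len(sub)
        cm = np.full((T, T), np.nan)
        sm = np.full((S, S), np.nan)
        for i in range(T):
            for j in range(T):
                if i != j:
                    cm[i, j] = cont[min(i, j)][max(i, j)] if isinstance(cont[0], dict) else cont[i][j]
        for i in range(S):
            for j in range(S):
                if i != j:
                    sm[i, j] = sub[i][j]
        return md.ScreenResult(
            locus=locus,
            continental_names=[f"T{i}" for i in range(T)],
            sub_names=[f"S{i}" for i in range(S)],
            continental_theta=cm,
            sub_theta=sm,
        )

    def test_locus_passing_both_minima_passes(self):
        cont = np.full((3, 3), 0.45)
        sub = np.full((3, 3), 0.16)
        res = self._result(cont, sub)
        passing = screen_loci([res])
        assert passing == [res] and res.passed and not res.reasons

    def test_one_low_sub_pair_fails_and_names_the_pair(self):
        cont = np.full((3, 3), 0.45)
        sub = np.full((3, 3), 0.16)
        sub[0, 1] = sub[1, 0] = 0.10
        res = self._result(cont, sub)
        assert screen_loci([res]) == []
        assert not res.passed
        assert any("S0-S1" in reason for reason in res.reasons)

    def test_undefined_pair_fails_with_monomorphic_reason(self):
        cont = np.full((3, 3), 0.45)
        cont[1, 2] = cont[2, 1] = np.nan
        res = self._result(cont, np.full((2, 2), 0.2))
        assert screen_loci([res]) == []
        assert any("monomorphic" in reason for reason in res.reasons)

    def test_thresholds_are_strict(self):
        cont = np.full((2, 2), 0.4)  # exactly at threshold -> fail
        sub = np.full((2, 2), 0.2)
        res = self._result(cont, sub)
        assert screen_loci([res]) == []

    def test_simulated_screen_agrees_with_brute_force_oracle(self):
        # strict min-over-pairs screening is only satisfiable for small
        # population counts (pairwise theta > 0.4 needs large frequency gaps),
        # so the feasibility check uses one out-group plus a 2-member tier
        cfg = md.SimConfig(
            seed=17, n_loci=2000, samples_per_pop=50,
            F_continental=0.5, F_sub=0.15, cluster_fraction=0.0,
            tier_structure=[("AFR", ["AFR"]), ("EAS", ["CHB", "KHV"])],
        )
        cohort = md.simulate_tiered_cohort(cfg)
        results = pairwise_theta_matrices(cohort, cfg.tier_structure)
        passing = screen_loci(results)
        assert 0 < len(passing) < len(results)
        # oracle: re-check every verdict from the raw matrices
        for res in results:
            t, s = len(res.continental_names), len(res.sub_names)
            cont_off = res.continental_theta[~np.eye(t, dtype=bool)]
            sub_off = res.sub_theta[~np.eye(s, dtype=bool)]
            should_pass = (
                not np.isnan(cont_off).any()
                and not np.isnan(sub_off).any()
                and cont_off.min() > 0.4
                and sub_off.min() > 0.15
            )
            assert res.passed == should_pass
        # deterministic ordering: descending min continental theta
        minima = [r.min_continental for r in passing]
        assert minima == sorted(minima, reverse=True)
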
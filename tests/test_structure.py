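"""No-admixture Gibbs clustering, ln P(X|K), Evanno delta-K, alignment, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import multindel as md
from multindel.structure import (
    align_replicates,
    estimate_lnP,
    evanno_delta_k,
    gibbs_no_admixture,
    pca_genotypes,
)


def _disjoint_two_pop_frame(n_per_pop=30, n_markers=12, seed=0):
    """Two populations with disjoint haplotype alphabets at every marker."""
    rng = np.random.default_rng(seed)
    rows = []
    for pop, haps in (("A", ["a1", "a2"]), ("B", ["b1", "b2"])):
        for i in range(n_per_pop):
            for m in range(n_markers):
                pair = sorted(rng.choice(haps, size=2))
                rows.append((f"{pop}{i}", f"m{m:02d}", pair[0], pair[1]))
    labels = {f"{p}{i}": p for p in "AB" for i in range(n_per_pop)}
    return pd.DataFrame(rows, columns=["sample_id", "marker_id", "hap1", "hap2"]), labels


def _dirichlet_multinomial_lnP(genotypes: pd.DataFrame, lam=1.0) -> float:
    """Closed-form log marginal likelihood of all data in ONE cluster.

    Independent of the sampler: product over markers of the ordered
    Dirichlet-multinomial marginal of pooled haplotype counts, times 2 per
    heterozygous genotype.
    """
    total = 0.0
    for _, sub in genotypes.groupby("marker_id"):
        counts = pd.concat([sub["hap1"], sub["hap2"]]).value_counts()
        H, T = len(counts), int(counts.sum())
        total += float(
            gammaln(H * lam) - gammaln(H * lam + T)
            + sum(gammaln(lam + c) - gammaln(lam) for c in counts)
        )
    total += float(genotypes["hap1"].ne(genotypes["hap2"]).sum()) * math.log(2.0)
    return total


class TestEstimateLnP:
    def test_constant_trace_returns_the_constant(self):
        assert estimate_lnP(np.full(100, -55.5)) == pytest.approx(-55.5)

    def test_two_point_trace(self):
        # mean -101, sample variance 2 -> -101 - 1 = -102
        assert estimate_lnP(np.array([-100.0, -102.0])) == pytest.approx(-102.0)

    def test_decreases_with_variance_at_fixed_mean(self):
        narrow = estimate_lnP(np.array([-100.0, -102.0]))
        wide = estimate_lnP(np.array([-98.0, -104.0]))
        assert wide < narrow

    def test_empty_trace_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_lnP(np.array([]))


class TestGibbs:
    def test_k1_posterior_trivial_and_lnP_matches_closed_form(self):
        geno, _ = _disjoint_two_pop_frame(n_per_pop=10, n_markers=4, seed=3)
        run = gibbs_no_admixture(geno, K=1, burn_in=10, kept=50, seed=1)
        assert np.allclose(run.posterior, 1.0)
        expected = _dirichlet_multinomial_lnP(geno)
        assert run.lnP == pytest.approx(expected, abs=1e-9)
        assert np.allclose(run.trace, expected)  # collapsed trace is constant at K=1

    def test_separable_populations_recovered_at_k2(self):
        geno, labels = _disjoint_two_pop_frame(seed=5)
        run = gibbs_no_admixture(geno, K=2, burn_in=300, kept=500, seed=9)
        pops = np.array([labels[s] for s in run.sample_ids])
        post = run.posterior
        confident = post.max(axis=1) > 0.99
        assert confident.mean() >= 0.99
        z = post.argmax(axis=1)
        agreement = max((z == (pops == p)).mean() for p in "AB")
        assert agreement >= 0.99

    def test_same_seed_identical_trace(self):
        geno, _ = _disjoint_two_pop_frame(seed=7)
        r1 = gibbs_no_admixture(geno, K=3, burn_in=50, kept=100, seed=4)
        r2 = gibbs_no_admixture(geno, K=3, burn_in=50, kept=100, seed=4)
        assert np.array_equal(r1.trace, r2.trace)
        assert np.array_equal(r1.posterior, r2.posterior)

    def test_posterior_rows_sum_to_one(self):
        geno, _ = _disjoint_two_pop_frame(n_per_pop=10, seed=2)
        run = gibbs_no_admixture(geno, K=3, burn_in=50, kept=200, seed=8)
        assert np.allclose(run.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_k_exceeding_samples_is_an_error(self):
        geno, _ = _disjoint_two_pop_frame(n_per_pop=2, n_markers=2, seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            gibbs_no_admixture(geno, K=10, burn_in=5, kept=5, seed=0)


class TestEvanno:
    def test_second_difference_arithmetic_and_optimum(self):
        # means (-500, -300, -290, -288), sd = 1 exactly (two reps +/- sqrt2/2)
        d = math.sqrt(2) / 2
        lnP = {k: [m - d, m + d] for k, m in zip(range(1, 5), (-500, -300, -290, -288))}
        sel = evanno_delta_k(lnP)
        assert sel.sds[2] == pytest.approx(1.0)
        assert sel.delta_k[2] == pytest.approx(abs(-290 - 2 * (-300) + (-500)))  # 190
        assert sel.delta_k[3] == pytest.approx(abs(-288 - 2 * (-290) + (-300)))  # 8
        assert sel.optimum == 2 and sel.method == "delta_k"

    def test_flat_means_fall_back_to_max_mean(self):
        lnP = {k: [-100.0, -102.0] for k in range(1, 5)}
        sel = evanno_delta_k(lnP)
        assert sel.method == "max_mean"

    def test_declining_lnP_from_k1_selects_k1(self):
        lnP = {1: [-100.0, -100.1], 2: [-105.0, -106.0], 3: [-111.0, -113.0]}
        sel = evanno_delta_k(lnP)
        assert sel.optimum == 1 and sel.method == "max_mean"

    def test_fewer_than_three_k_values_falls_back(self):
        sel = evanno_delta_k({1: [-10.0, -10.5], 2: [-8.0, -8.2]})
        assert sel.optimum == 2 and sel.method == "max_mean"


class TestAlignment:
    def test_label_swap_collapses_after_alignment(self):
        geno, _ = _disjoint_two_pop_frame(n_per_pop=10, seed=4)
        r1 = gibbs_no_admixture(geno, K=2, burn_in=100, kept=200, seed=3)
        r2 = md.ClusterRun(
            K=2, sample_ids=r1.sample_ids, posterior=r1.posterior[:, ::-1],
            trace=r1.trace, lnP=r1.lnP, seed=0, burn_in=r1.burn_in, kept=r1.kept,
        )
        mean_q = align_replicates([r1, r2])
        assert np.allclose(mean_q, r1.posterior)

    def test_cyclic_permutations_collapse_at_k3(self):
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(3), size=20)
        ids = [f"s{i}" for i in range(20)]

        def run(perm):
            return md.ClusterRun(
                K=3, sample_ids=ids, posterior=q[:, list(perm)],
                trace=np.array([-1.0, -1.0]), lnP=-1.0, seed=0, burn_in=1, kept=2,
            )

        mean_q = align_replicates([run((0, 1, 2)), run((1, 2, 0)), run((2, 0, 1))])
        assert np.allclose(mean_q, q)

    def test_aligned_mean_rows_sum_to_one(self):
        geno, _ = _disjoint_two_pop_frame(n_per_pop=8, seed=6)
        runs = [gibbs_no_admixture(geno, K=3, burn_in=50, kept=100, seed=s) for s in range(3)]
        mean_q = align_replicates(runs)
        assert np.allclose(mean_q.sum(axis=1), 1.0, atol=1e-9)

    def test_mismatched_sample_sets_rejected(self):
        geno, _ = _disjoint_two_pop_frame(n_per_pop=5, seed=1)
        r1 = gibbs_no_admixture(geno, K=2, burn_in=10, kept=10, seed=0)
        r2 = md.ClusterRun(
            K=2, sample_ids=list(reversed(r1.sample_ids)), posterior=r1.posterior,
            trace=r1.trace, lnP=r1.lnP, seed=0, burn_in=1, kept=1,
        )
        with pytest.raises(ValueError, match="sample set"):
            align_replicates([r1, r2])


class TestPca:
    def test_two_samples_symmetric_about_zero(self):
        geno = pd.DataFrame(
            [("s1", "m1", "x", "x"), ("s2", "m1", "y", "y")],
            columns=["sample_id", "marker_id", "hap1", "hap2"],
        )
        ids, coords, ev = pca_genotypes(geno)
        assert coords[0, 0] == pytest.approx(-coords[1, 0])
        assert ev[0] == pytest.approx(1.0)

    def test_separated_populations_split_along_pc1(self):
        geno, labels = _disjoint_two_pop_frame(n_per_pop=40, seed=9)
        ids, coords, ev = pca_genotypes(geno)
        y = np.array([1.0 if labels[s] == "A" else 0.0 for s in ids])
        r = abs(np.corrcoef(coords[:, 0], y)[0, 1])
        assert r >= 0.9

    def test_explained_variance_sums_to_one(self):
        geno, _, _ = md.simulate_marker_cohort(seed=8, pop_sizes={"A": 20, "B": 20})
        _, _, ev = pca_genotypes(geno)
        assert ev.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_handled(self):
        geno = pd.DataFrame(
            [("s1", "m1", "x", "x"), ("s2", "m1", "x", "x"), ("s3", "m1", "x", "x")],
            columns=["sample_id", "marker_id", "hap1", "hap2"],
        )
        _, coords, ev = pca_genotypes(geno)
        assert np.allclose(coords, 0.0) and np.allclose(ev, 0.0)
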
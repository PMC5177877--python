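import numpy as np
import pytest

import multindel as md


@pytest.fixture(scope="session")
def panel():
    """The bundled 12-marker panel definition."""
    return md.bundled_panel()

@pytest.fixture(scope="session")
def amplicon_sizes():
    return md.bundled_amplicon_sizes()


@pytest.fixture(scope="session")
def two_pop_marker_cohort():
    """Two populations (110 + 100), 12 markers, per-marker theta in [0.15, 0.4]."""
    return md.simulate_marker_cohort(seed=20_260_919)


def all_pass_screen(loci):
    """ScreenResults marking every locus as passing (formation rules under test)."""
    return [
        md.ScreenResult(
            locus=v, continental_names=[], sub_names=[],
            continental_theta=np.empty((0, 0)), sub_theta=np.empty((0, 0)), passed=True,
        )
        for v in loci
    ]


def planted_panel_cohort(n_good=12, seed=99):
    """A cohort with ``n_good`` rule-compliant clusters plus one decoy per
    formation rule: adjacent gap >= 250 bp, a single observed haplotype, an
    observed amplicon >= 300 bp (at flank padding 30), and a degenerate
    (colliding) size encoding.
    """
    rng = np.random.default_rng(seed)
    loci = []
    roles = []
    pos = 10_000
    for i in range(n_good):
        k = 2 + i % 2
        deltas = [1, 4, 9][:k]
        for j in range(k):
            loci.append(md.InDelVariant(f"good{i}_{j}", "1", pos, "-", "G" * deltas[j]))
            pos += 60
        roles.append(("good", k))
        pos += 5_000
    loci.append(md.InDelVariant("far_a", "1", pos, "-", "T"))
    loci.append(md.InDelVariant("far_b", "1", pos + 400, "-", "TT"))
    roles.append(("gap", 2))
    pos += 5_000
    loci.append(md.InDelVariant("mono_a", "1", pos, "-", "C"))
    loci.append(md.InDelVariant("mono_b", "1", pos + 50, "-", "CC"))
    roles.append(("mono", 2))
    pos += 5_000
    loci.append(md.InDelVariant("long_a", "1", pos, "-", "A"))
    loci.append(md.InDelVariant("long_b", "1", pos + 240, "-", "AA"))
    roles.append(("long", 2))
    pos += 5_000
    loci.append(md.InDelVariant("coll_a", "1", pos, "-", "GG"))
    loci.append(md.InDelVariant("coll_b", "1", pos + 50, "-", "TT"))
    roles.append(("collision", 2))

    n_samples = 20
    h = np.zeros((n_samples, 2, len(loci)), dtype=np.int8)
    col = 0
    for role, k in roles:
        block = h[:, :, col : col + k]
        if role == "mono":
            pass  # stays all-short: one haplotype
        elif role == "collision":
            half = n_samples // 2
            block[:half, :, 0] = 1  # haplotype (1,0)
            block[half:, :, 1] = 1  # haplotype (0,1)
        else:
            block[:] = rng.integers(0, 2, size=(n_samples, 2, k)).astype(np.int8)
        col += k
    return make_cohort(loci, h)


def make_cohort(loci, haplotypes, populations=None, sample_ids=None):
    """Hand-built PhasedCohort from a nested allele-state list.

    haplotypes: list over samples of (hap_vec_1, hap_vec_2).
    """
    h = np.array(haplotypes, dtype=np.int8)
    n = h.shape[0]
    return md.PhasedCohort(
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        populations=populations or ["POP"] * n,
        loci=loci,
        haplotypes=h,
    )
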
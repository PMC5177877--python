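"""Per-locus Weir–Cockerham FST (theta) estimation and the two-tier screen.

The estimator is the classic variance-component theta-hat for one di-allelic
locus over r populations: with per-population sample sizes n_i (diploid
individuals), long-allele frequencies p_i and observed heterozygote
proportions h_i,

    n_bar = mean n_i
    n_c   = (r n_bar - sum n_i^2 / (r n_bar)) / (r - 1)
    p_bar = sum n_i p_i / (r n_bar)
    s^2   = sum n_i (p_i - p_bar)^2 / ((r - 1) n_bar)
    h_bar = sum n_i h_i / (r n_bar)

    a = n_bar/n_c * [ s^2 - ( p_bar(1-p_bar) - (r-1)/r s^2 - h_bar/4 ) / (n_bar - 1) ]
    b = n_bar/(n_bar-1) * [ p_bar(1-p_bar) - (r-1)/r s^2 - (2 n_bar - 1)/(4 n_bar) h_bar ]
    c = h_bar / 2

    theta = a / (a + b + c)

a, b and c are the among-population, among-individual-within-population and
within-individual variance components. theta may be slightly negative by
sampling and is reported unclamped; it is undefined (NaN, reason
"monomorphic") when all populations are fixed for the same allele.

The screen nominates ancestry-informative InDels by two strict thresholds:
theta > 0.4 for every pair of continental populations AND theta > 0.15 for
every pair of sub-populations within the target continental group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import PhasedCohort
from .panel import InDelVariant

TierStructure = list[tuple[str, list[str]]]

DEFAULT_T_CONTINENTAL = 0.4
DEFAULT_T_SUB = 0.15


@dataclass
class LocusPopStats:
    """Per-population summary of one di-allelic locus.

    n: diploid sample sizes; p: long-allele frequencies; h: observed
    heterozygote proportions. Arrays of equal length r >= 2.
    """

    n: np.ndarray
    p: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if not (self.n.shape == self.p.shape == self.h.shape):
            raise ValueError("n, p, h must have equal shape")
        if self.n.shape[0] < 2:
            raise ValueError("need at least 2 populations")
        if (self.n < 1).any():
            raise ValueError("sample sizes must be >= 1")
        if ((self.p < 0) | (self.p > 1)).any() or ((self.h < 0) | (self.h > 1)).any():
            raise ValueError("p and h must lie in [0, 1]")

    @classmethod
    def from_genotype_counts(cls, counts: list[tuple[int, int, int]]) -> "LocusPopStats":
        """Build from (n_short_hom, n_het, n_long_hom) triples, one per population."""
        n = np.array([sum(c) for c in counts], dtype=float)
        het = np.array([c[1] for c in counts], dtype=float)
        long_hom = np.array([c[2] for c in counts], dtype=float)
        return cls(n=n, p=(het + 2 * long_hom) / (2 * n), h=het / n)


def theta_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Variance components (a, b, c), vectorized over trailing locus axes.

    n, p, h have shape (r,) + locus_shape; n may also be (r,) broadcast over loci.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = p.shape[0]
    if n.ndim < p.ndim:
        n = np.broadcast_to(n.reshape((r,) + (1,) * (p.ndim - 1)), p.shape)
    n_tot = n.sum(axis=0)
    n_bar = n_tot / r
    n_c = (n_tot - (n**2).sum(axis=0) / n_tot) / (r - 1)
    p_bar = (n * p).sum(axis=0) / n_tot
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=0) / n_tot

    inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4
    a = n_bar / n_c * (s2 - inner / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, b, c


def wc_theta(stats: LocusPopStats) -> float:
    """Weir–Cockerham theta for one locus; NaN if monomorphic across populations."""
    a, b, c = theta_components(stats.n, stats.p, stats.h)
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return float(a / denom)


def wc_theta_vector(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> np.ndarray:
    """theta over many loci at once; NaN where a+b+c = 0."""
    a, b, c = theta_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    return theta


def wc_theta_multilocus(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> float:
    """Multi-locus theta: ratio of summed variance components over loci.

    This "ratio of averages" is the standard genome-wide Weir–Cockerham
    estimate (the weighted FST genome scanners report); unlike the mean of
    per-locus ratios it is unbiased for the generating fixation index when
    loci drift to near-fixation.
    """
    a, b, c = theta_components(n, p, h)
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def cohort_pairwise_multilocus_theta(cohort: PhasedCohort, pop_a: str, pop_b: str) -> float:
    """Genome-wide weighted theta between two cohort populations."""
    n, p, h = _pool_stats(cohort, [[pop_a], [pop_b]])
    return wc_theta_multilocus(n, p, h)


def _pool_stats(cohort: PhasedCohort, pops: list[list[str]]):
    """Per-pool per-locus (n, p, h) arrays, each of shape (n_pools, n_loci)."""
    H = cohort.haplotypes
    L = cohort.n_loci
    n = np.empty((len(pops), L))
    p = np.empty((len(pops), L))
    h = np.empty((len(pops), L))
    pop_arr = np.asarray(cohort.populations)
    for k, members in enumerate(pops):
        idx = np.flatnonzero(np.isin(pop_arr, members))
        if idx.size == 0:
            raise ValueError(f"no samples for population group {members}")
        sub = H[idx]  # (n_k, 2, L)
        ok = (sub >= 0).all(axis=1)  # both alleles called
        n_k = ok.sum(axis=0).astype(float)
        if (n_k == 0).any():
            raise ValueError(f"population group {members} has loci with 0 called samples")
        calls = np.where(ok[:, None, :], sub, 0)
        dose = calls.sum(axis=1)  # long-allele dosage, 0 where not ok
        p[k] = dose.sum(axis=0) / (2 * n_k)
        h[k] = ((dose == 1) & ok).sum(axis=0) / n_k
        n[k] = n_k
    return n, p, h


@dataclass
class ScreenResult:
    """Pairwise theta matrices and screen verdict for one locus."""

    locus: InDelVariant
    continental_names: list[str]
    sub_names: list[str]
    continental_theta: np.ndarray  # (T, T), NaN diagonal
    sub_theta: np.ndarray  # (S, S), NaN diagonal
    passed: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def min_continental(self) -> float:
        off = self.continental_theta[~np.eye(len(self.continental_names), dtype=bool)]
        return float(np.min(off)) if off.size else float("nan")

    @property
    def min_sub(self) -> float:
        off = self.sub_theta[~np.eye(len(self.sub_names), dtype=bool)]
        return float(np.min(off)) if off.size else float("nan")


def pairwise_theta_matrices(
    cohort: PhasedCohort, tier_structure: TierStructure
) -> list[ScreenResult]:
    """Two-population theta for every pair of continental tiers and every pair
    of sub-populations within multi-member tiers, at every locus.

    A tier's allele pool is the union of its member populations; matrices are
    symmetric with empty (NaN) diagonals.
    """
    tier_names = [name for name, _ in tier_structure]
    tier_members = [list(members) for _, members in tier_structure]
    sub_names = [p for _, members in tier_structure if len(members) > 1 for p in members]

    n_t, p_t, h_t = _pool_stats(cohort, tier_members)
    n_s, p_s, h_s = _pool_stats(cohort, [[p] for p in sub_names]) if sub_names else (None,) * 3

    L = cohort.n_loci
    T, S = len(tier_names), len(sub_names)
    cont = np.full((L, T, T), np.nan)
    sub = np.full((L, S, S), np.nan)

    def fill(mat, n, p, h, count):
        for i in range(count):
            for j in range(i + 1, count):
                th = wc_theta_vector(
                    np.stack([n[i], n[j]]), np.stack([p[i], p[j]]), np.stack([h[i], h[j]])
                )
                mat[:, i, j] = th
                mat[:, j, i] = th

    fill(cont, n_t, p_t, h_t, T)
    if S:
        fill(sub, n_s, p_s, h_s, S)

    return [
        ScreenResult(
            locus=cohort.loci[l],
            continental_names=tier_names,
            sub_names=sub_names,
            continental_theta=cont[l],
            sub_theta=sub[l],
        )
        for l in range(L)
    ]


def screen_loci(
    results: list[ScreenResult],
    t_continental: float = DEFAULT_T_CONTINENTAL,
    t_sub: float = DEFAULT_T_SUB,
) -> list[ScreenResult]:
    """Apply the two-tier screen; returns passing loci sorted by descending
    minimum continental theta (ties broken by chromosome, position).

    Both criteria are strict inequalities over EVERY pair; a locus with any
    undefined pairwise theta fails with a reason naming the pair.
    """
    passing = []
    for res in results:
        res.reasons = []
        _judge_matrix(res, res.continental_theta, res.continental_names, t_continental, "continental")
        _judge_matrix(res, res.sub_theta, res.sub_names, t_sub, "sub-population")
        res.passed = not res.reasons
        if res.passed:
            passing.append(res)
    passing.sort(key=lambda r: (-r.min_continental, r.locus.chrom, r.locus.position))
    return passing


def _judge_matrix(res, mat, names, threshold, label) -> None:
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            th = mat[i, j]
            pair = f"{names[i]}-{names[j]}"
            if np.isnan(th):
                res.reasons.append(f"{label} pair {pair}: theta undefined (monomorphic)")
            elif th <= threshold:
                res.reasons.append(f"{label} pair {pair}: theta {th:.4f} <= {threshold}")


def screen_table(results: list[ScreenResult]):
    """Per-locus summary as a DataFrame (chrom, pos, rsid, minima, pass, reason)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [r.locus.chrom for r in results],
            "pos": [r.locus.position for r in results],
            "rsid": [r.locus.rsid for r in results],
            "min_continental_theta": [r.min_continental for r in results],
            "min_sub_theta": [r.min_sub for r in results],
            "pass": [r.passed for r in results],
            "reason": ["; ".join(r.reasons) for r in results],
        }
    )
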
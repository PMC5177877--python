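"""No-admixture Bayesian clustering, ln P(X|K) estimation, Evanno delta-K
model choice, replicate alignment, and genotype PCA.

The sampler is the classic no-admixture Gibbs scheme: each individual
originates wholly from one of K clusters; each cluster has its own
haplotype-frequency vector per marker under a symmetric Dirichlet(lambda)
prior; genotype probabilities within a cluster are Hardy–Weinberg. The two
alternating updates are

  1. cluster frequencies | assignments  ~  Dirichlet(lambda + counts)
  2. sample cluster | frequencies       ~  categorical, weight proportional
     to the product over markers of the HWE genotype probability

The recorded per-iteration statistic is the collapsed data log-likelihood
log P(X | z) with cluster frequencies integrated out analytically
(a product of Dirichlet-multinomial terms per cluster per marker). It is
invariant to label switching and has lower variance than the conditional
log P(X | z, p); at K = 1 it is constant and equals the model's exact log
marginal likelihood. ln P(X|K) is then estimated as mean minus half the
sample variance of the trace, and the Evanno delta-K second-difference
statistic picks the optimum K across replicate runs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

DEFAULT_BURN_IN = 5_000
DEFAULT_KEPT = 5_000


@dataclass
class _Encoded:
    """Genotype frame re-encoded as flat haplotype-class indices."""

    sample_ids: list[str]
    marker_ids: list[str]
    alphabets: dict[str, list[str]]
    offsets: np.ndarray  # start of each marker's class block, len M+1
    idx1: np.ndarray  # (N, M) flat class index of first haplotype
    idx2: np.ndarray
    n_het: int  # heterozygous genotypes (contributes a constant log 2 each)

    @property
    def n_classes(self) -> int:
        return int(self.offsets[-1])


def _encode(genotypes: pd.DataFrame) -> _Encoded:
    markers = sorted(set(genotypes["marker_id"]))
    alphabets = {
        m: sorted(set(sub["hap1"]) | set(sub["hap2"]))
        for m, sub in genotypes.groupby("marker_id")
    }
    offsets = np.zeros(len(markers) + 1, dtype=int)
    for i, m in enumerate(markers):
        offsets[i + 1] = offsets[i] + len(alphabets[m])
    lookup = {
        (m, k): offsets[i] + j
        for i, m in enumerate(markers)
        for j, k in enumerate(alphabets[m])
    }

    wide = genotypes.pivot(index="sample_id", columns="marker_id", values=["hap1", "hap2"])
    if wide.isna().any().any():
        incomplete = wide.index[wide.isna().any(axis=1)]
        logger.warning("dropping %d samples with incomplete marker genotypes", len(incomplete))
        wide = wide.dropna()
    samples = list(wide.index)
    N, M = len(samples), len(markers)
    idx1 = np.empty((N, M), dtype=np.int64)
    idx2 = np.empty((N, M), dtype=np.int64)
    for j, m in enumerate(markers):
        idx1[:, j] = [lookup[(m, k)] for k in wide[("hap1", m)]]
        idx2[:, j] = [lookup[(m, k)] for k in wide[("hap2", m)]]
    return _Encoded(
        sample_ids=samples,
        marker_ids=markers,
        alphabets=alphabets,
        offsets=offsets,
        idx1=idx1,
        idx2=idx2,
        n_het=int((idx1 != idx2).sum()),
    )


@dataclass
class ClusterRun:
    """Output of one MCMC run at one K."""

    K: int
    sample_ids: list[str]
    posterior: np.ndarray  # (N, K), rows sum to 1
    trace: np.ndarray  # collapsed log-likelihood per kept iteration
    lnP: float  # mean(trace) - var(trace)/2
    seed: int
    burn_in: int
    kept: int

    @property
    def assignments(self) -> np.ndarray:
        return self.posterior.argmax(axis=1)


def estimate_lnP(trace: np.ndarray) -> float:
    """STRUCTURE's estimator of ln P(X|K): mean(trace) - var(trace)/2."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty log-likelihood trace")
    var = float(trace.var(ddof=1)) if trace.size > 1 else 0.0
    return float(trace.mean()) - var / 2.0


def _collapsed_loglik(counts: np.ndarray, offsets: np.ndarray, lam: float, het_const: float) -> float:
    """log P(X | z): Dirichlet-multinomial per cluster per marker, plus the
    constant heterozygote pairing term."""
    K = counts.shape[0]
    total = het_const
    seg = np.add.reduceat(counts, offsets[:-1], axis=1)  # (K, M) chromosomes per cluster/marker
    sizes = np.diff(offsets)
    total += float(gammaln(lam + counts).sum() - gammaln(lam) * counts.size)
    total += float((gammaln(sizes * lam)[None, :] - gammaln(sizes * lam + seg)).sum())
    return total


def _greedy_permutation(contingency: np.ndarray) -> np.ndarray:
    """perm[current_label] = reference_label, by greedy max-overlap."""
    K = contingency.shape[0]
    perm = np.full(K, -1, dtype=int)
    c = contingency.astype(float).copy()
    for _ in range(K):
        ref, cur = np.unravel_index(np.argmax(c), c.shape)
        perm[cur] = ref
        c[ref, :] = -1
        c[:, cur] = -1
    return perm


def gibbs_no_admixture(
    genotypes: pd.DataFrame,
    K: int,
    dirichlet_lambda: float = 1.0,
    burn_in: int = DEFAULT_BURN_IN,
    kept: int = DEFAULT_KEPT,
    seed: int = 0,
) -> ClusterRun:
    """Run the no-admixture Gibbs sampler at one K.

    The assignment posterior is the empirical label frequency over kept
    iterations, with each iteration's labels aligned to the first kept
    iteration by greedy maximum-overlap permutation (label switching).
    Deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    enc = _encode(genotypes)
    N = len(enc.sample_ids)
    if K > N:
        raise ValueError(f"K={K} exceeds the number of samples ({N})")
    if kept < 1:
        raise ValueError("kept must be >= 1")
    rng = np.random.default_rng(seed)
    Htot = enc.n_classes
    lam = float(dirichlet_lambda)
    het_const = enc.n_het * math.log(2.0)
    sizes = np.diff(enc.offsets)
    marker_of_class = np.repeat(np.arange(len(sizes)), sizes)

    z = rng.integers(0, K, size=N)
    posterior_counts = np.zeros((N, K), dtype=np.int64)
    trace = np.empty(kept, dtype=float)
    reference: np.ndarray | None = None

    flat_base = np.arange(N)  # reused
    for t in range(burn_in + kept):
        counts = (
            np.bincount((z[:, None] * Htot + enc.idx1).ravel(), minlength=K * Htot)
            + np.bincount((z[:, None] * Htot + enc.idx2).ravel(), minlength=K * Htot)
        ).reshape(K, Htot)

        if t >= burn_in:
            trace[t - burn_in] = _collapsed_loglik(counts, enc.offsets, lam, het_const)
            if reference is None:
                reference = z.copy()
                perm = np.arange(K)
            else:
                contingency = np.zeros((K, K), dtype=np.int64)
                np.add.at(contingency, (reference, z), 1)
                perm = _greedy_permutation(contingency)
            posterior_counts[flat_base, perm[z]] += 1

        # frequencies | assignments
        g = rng.gamma(lam + counts)
        seg_tot = np.add.reduceat(g, enc.offsets[:-1], axis=1)
        p = g / seg_tot[:, marker_of_class]
        logp = np.log(np.clip(p, 1e-300, None))

        # assignments | frequencies (Gumbel-max categorical, uniform prior)
        loglik = logp[:, enc.idx1].sum(axis=2) + logp[:, enc.idx2].sum(axis=2)  # (K, N)
        if K == 1:
            z = np.zeros(N, dtype=int)
        else:
            gumbel = -np.log(-np.log(rng.random((K, N))))
            z = np.argmax(loglik + gumbel, axis=0)

    posterior = posterior_counts / kept
    return ClusterRun(
        K=K,
        sample_ids=enc.sample_ids,
        posterior=posterior,
        trace=trace,
        lnP=estimate_lnP(trace),
        seed=seed,
        burn_in=burn_in,
        kept=kept,
    )


@dataclass
class KSelection:
    """Replicate ln P(X|K) summaries, delta-K statistics and the chosen K."""

    means: dict[int, float]
    sds: dict[int, float]
    delta_k: dict[int, float]
    optimum: int
    method: str  # "delta_k" | "max_mean"
    notes: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        ks = sorted(self.means)
        return pd.DataFrame(
            {
                "K": ks,
                "mean_lnP": [self.means[k] for k in ks],
                "sd_lnP": [self.sds[k] for k in ks],
                "delta_K": [self.delta_k.get(k, float("nan")) for k in ks],
            }
        )


def evanno_delta_k(lnP_by_K: dict[int, list[float]]) -> KSelection:
    """Choose the optimum K from replicate ln P(X|K) values.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K), defined
    for interior K with nonzero replicate standard deviation. delta-K cannot
    evaluate K = 1, so when mean ln P is globally maximal at the smallest K
    (no gain from any structure) the selection falls back to the max-mean
    rule; the same fallback covers fewer than 3 K values or all-zero sds.
    """
    ks = sorted(lnP_by_K)
    means = {k: float(np.mean(lnP_by_K[k])) for k in ks}
    sds = {
        k: float(np.std(lnP_by_K[k], ddof=1)) if len(lnP_by_K[k]) > 1 else 0.0 for k in ks
    }
    notes: list[str] = []

    def max_mean(reason: str) -> KSelection:
        notes.append(reason)
        logger.info("K selection fallback: %s", reason)
        best = max(ks, key=lambda k: means[k])
        return KSelection(means=means, sds=sds, delta_k=delta, optimum=best, method="max_mean", notes=notes)

    delta: dict[int, float] = {}
    if len(ks) < 3:
        return max_mean(f"only {len(ks)} K values; delta-K needs >= 3")
    for i, k in enumerate(ks[1:-1], start=1):
        if ks[i - 1] != k - 1 or ks[i + 1] != k + 1:
            continue  # non-consecutive K grid
        if sds[k] == 0:
            notes.append(f"delta-K undefined at K={k}: zero replicate sd")
            continue
        delta[k] = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
    if not delta:
        return max_mean("no K with a defined delta-K")
    if means[ks[0]] >= max(means.values()):
        return max_mean(
            f"mean ln P is maximal at K={ks[0]}; no support for additional clusters"
        )
    best = max(sorted(delta), key=lambda k: delta[k])
    return KSelection(means=means, sds=sds, delta_k=delta, optimum=best, method="delta_k", notes=notes)


def align_replicates(runs: list[ClusterRun]) -> np.ndarray:
    """Resolve label switching across replicate runs of one K.

    Each run's cluster labels are permuted (exhaustively over K!
    permutations, K <= 7 in practice) to maximize the summed posterior
    agreement with the first run; returns the mean aligned posterior matrix.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    ref = runs[0]
    for r in runs[1:]:
        if r.K != K:
            raise ValueError("runs disagree on K")
        if r.sample_ids != ref.sample_ids:
            raise ValueError("runs disagree on the sample set")
    acc = ref.posterior.copy()
    for r in runs[1:]:
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(K)):
            score = float((ref.posterior * r.posterior[:, list(perm)]).sum())
            if score > best_score:
                best_score, best_perm = score, perm
        acc += r.posterior[:, list(best_perm)]
    return acc / len(runs)


def structure_scan(
    genotypes: pd.DataFrame,
    k_min: int = 1,
    k_max: int = 7,
    replicates: int = 5,
    dirichlet_lambda: float = 1.0,
    burn_in: int = DEFAULT_BURN_IN,
    kept: int = DEFAULT_KEPT,
    seed: int = 0,
) -> tuple[dict[int, list[ClusterRun]], KSelection]:
    """Replicate runs over a K grid plus Evanno model choice.

    Replicate seeds are derived deterministically from ``seed`` via a
    seed sequence, so the whole scan is reproducible from one integer.
    """
    ss = np.random.SeedSequence(seed)
    runs: dict[int, list[ClusterRun]] = {}
    child = ss.spawn((k_max - k_min + 1) * replicates)
    i = 0
    for K in range(k_min, k_max + 1):
        runs[K] = []
        for _ in range(replicates):
            rep_seed = int(child[i].generate_state(1)[0] % (2**31))
            i += 1
            runs[K].append(
                gibbs_no_admixture(
                    genotypes, K, dirichlet_lambda=dirichlet_lambda,
                    burn_in=burn_in, kept=kept, seed=rep_seed,
                )
            )
    selection = evanno_delta_k({K: [r.lnP for r in rr] for K, rr in runs.items()})
    return runs, selection


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(genotypes: pd.DataFrame) -> tuple[list[str], np.ndarray, np.ndarray]:
    """PCA of haplotype-dosage-encoded marker genotypes.

    Each marker contributes one dosage column (0/1/2 copies) per haplotype
    class except a reference class dropped to avoid exact collinearity;
    columns are centered and the centered matrix eigendecomposed. Returns
    (sample_ids, coordinates (N x C), explained-variance fractions summing
    to 1; all zeros for a constant matrix).
    """
    enc = _encode(genotypes)
    N, Htot = len(enc.sample_ids), enc.n_classes
    if N < 2:
        raise ValueError("PCA needs at least 2 samples")
    dosage = np.zeros((N, Htot))
    rows = np.arange(N)[:, None]
    np.add.at(dosage, (rows, enc.idx1), 1.0)
    np.add.at(dosage, (rows, enc.idx2), 1.0)
    keep = np.ones(Htot, dtype=bool)
    keep[enc.offsets[:-1]] = False  # drop one reference class per marker
    X = dosage[:, keep]
    X = X - X.mean(axis=0)
    if not np.any(np.abs(X) > 1e-12):
        C = min(N - 1, X.shape[1]) or 1
        return enc.sample_ids, np.zeros((N, C)), np.zeros(C)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = U * s
    var = s**2
    return enc.sample_ids, coords, var / var.sum()
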
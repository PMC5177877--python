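"""Naive-Bayes ancestry assignment from haplotype-frequency training tables.

The model mirrors the frequency-based classifier forensic practitioners use
for AIM panels: within each candidate population, marker genotype
probabilities are Hardy–Weinberg (p_i^2 for homozygotes, 2 p_i p_j for
heterozygotes) in smoothed training frequencies, and markers multiply as
independent loci. Assignment is the maximum-likelihood population and its
strength is the ratio of the two highest likelihoods.

Smoothing is Laplace with pseudocount alpha per haplotype class:
p~ = (c + alpha) / (T + alpha*H), with c the training chromosome count, T
the population's total counted chromosomes at the marker and H the number
of haplotype classes. alpha = 0 reproduces raw counting (and lets unseen
haplotypes zero out a likelihood); the default alpha = 1 keeps every
genotype's likelihood finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotyping import count_haplotypes
from .io import HaplotypeFrequencyTable

TIE_TOL = 1e-12


@dataclass
class TrainingSet:
    """Per-marker haplotype chromosome counts by population, plus smoothing policy."""

    counts: dict[str, pd.DataFrame]
    alpha: float = 1.0

    def __post_init__(self) -> None:
        pops = None
        for mid, df in self.counts.items():
            cur = set(df.index)
            if pops is None:
                pops = cur
            elif cur != pops:
                raise ValueError(
                    f"marker {mid}: population set {sorted(cur)} differs from {sorted(pops)}"
                )
        if self.alpha < 0:
            raise ValueError("pseudocount alpha must be >= 0")

    @classmethod
    def from_genotypes(
        cls, genotypes: pd.DataFrame, populations: dict[str, str], alpha: float = 1.0
    ) -> "TrainingSet":
        return cls(counts=count_haplotypes(genotypes, populations), alpha=alpha)

    @classmethod
    def from_frequencies(
        cls,
        tables: HaplotypeFrequencyTable,
        chromosomes_per_population: dict[str, int],
        alpha: float = 1.0,
    ) -> "TrainingSet":
        """Rebuild counts from a frequency workbook and known sample depths."""
        counts = {}
        for mid, df in tables:
            n = pd.Series({p: chromosomes_per_population[p] for p in df.index})
            counts[mid] = df.mul(n, axis=0)
        return cls(counts=counts, alpha=alpha)

    @property
    def populations(self) -> list[str]:
        first = next(iter(self.counts.values()))
        return list(first.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.counts)

    def log_frequency(self, marker_id: str, population: str, key: str) -> float:
        """log of the smoothed haplotype frequency; -inf only when alpha = 0."""
        df = self.counts[marker_id]
        H = df.shape[1] + (0 if key in df.columns else 1)
        c = float(df.at[population, key]) if key in df.columns else 0.0
        total = float(df.loc[population].sum())
        p = (c + self.alpha) / (total + self.alpha * H)
        return math.log(p) if p > 0 else float("-inf")


@dataclass
class AssignmentResult:
    """Per-population log-likelihoods and the resulting assignment."""

    sample_id: str
    log_likelihoods: dict[str, float]
    best: str
    second: str | None
    likelihood_ratio: float
    status: str  # "assigned" | "tie"
    posterior: dict[str, float] = field(default_factory=dict)

    @property
    def log10_lr(self) -> float:
        return math.log10(self.likelihood_ratio) if self.likelihood_ratio > 0 else float("inf")


def genotype_log_likelihood(
    sample_genotypes: pd.DataFrame, training: TrainingSet, population: str
) -> float:
    """Sum over markers of the HWE log genotype probability for one sample.

    Markers absent from the training set are skipped; a sample sharing no
    markers with training is an error.
    """
    total = 0.0
    used = 0
    for _, row in sample_genotypes.iterrows():
        mid = str(row["marker_id"])
        if mid not in training.counts:
            continue
        used += 1
        l1 = training.log_frequency(mid, population, str(row["hap1"]))
        l2 = training.log_frequency(mid, population, str(row["hap2"]))
        total += l1 + l2
        if str(row["hap1"]) != str(row["hap2"]):
            total += math.log(2.0)
    if used == 0:
        raise ValueError(
            f"sample {sample_genotypes['sample_id'].iloc[0] if len(sample_genotypes) else '?'}: "
            "no markers shared with the training set"
        )
    return total


def classify(sample_genotypes: pd.DataFrame, training: TrainingSet) -> AssignmentResult:
    """Assign a sample to the maximum-likelihood population.

    Reports the ratio of the two highest likelihoods and a flat-prior
    posterior; a ratio of 1 (within 1e-12) is a tie, not an assignment.
    """
    sample_id = str(sample_genotypes["sample_id"].iloc[0]) if len(sample_genotypes) else "?"
    lls = {p: genotype_log_likelihood(sample_genotypes, training, p) for p in training.populations}
    ordered = sorted(lls, key=lambda p: (-lls[p], p))
    best = ordered[0]
    second = ordered[1] if len(ordered) > 1 else None
    if second is None:
        ratio, status = float("inf"), "assigned"
    else:
        d = lls[best] - lls[second]
        ratio = math.exp(d) if d < 700 else float("inf")
        status = "tie" if abs(ratio - 1.0) <= TIE_TOL else "assigned"

    finite = {p: v for p, v in lls.items() if v > float("-inf")}
    if finite:
        m = max(finite.values())
        w = {p: math.exp(v - m) for p, v in finite.items()}
        z = sum(w.values())
        posterior = {p: w.get(p, 0.0) / z for p in lls}
    else:
        posterior = {p: 1.0 / len(lls) for p in lls}
    return AssignmentResult(
        sample_id=sample_id,
        log_likelihoods=lls,
        best=best,
        second=second,
        likelihood_ratio=ratio,
        status=status,
        posterior=posterior,
    )


def blind_trial(
    genotypes: pd.DataFrame,
    populations: dict[str, str],
    n_holdout: int = 10,
    seed: int | np.random.Generator = 0,
    alpha: float = 1.0,
) -> tuple[float, list[tuple[str, str, AssignmentResult]]]:
    """Hold out samples, retrain on the rest, classify the holdouts.

    The holdout is drawn uniformly over the pooled cohort without
    replacement (no stratification); training frequencies are recounted
    WITHOUT the held-out samples. Returns (accuracy, per-sample results as
    (sample_id, true population, assignment)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = sorted(set(genotypes["sample_id"]))
    if n_holdout >= len(samples):
        raise ValueError(f"n_holdout={n_holdout} must be < total samples ({len(samples)})")
    holdout = set(rng.choice(samples, size=n_holdout, replace=False))
    train_df = genotypes[~genotypes["sample_id"].isin(holdout)]
    remaining_pops = {populations[s] for s in samples if s not in holdout}
    if remaining_pops != set(populations[s] for s in samples):
        raise ValueError("a population lost all its training samples in the holdout draw")
    training = TrainingSet.from_genotypes(
        train_df, {s: populations[s] for s in samples if s not in holdout}, alpha=alpha
    )
    results = []
    correct = 0
    for s in sorted(holdout):
        res = classify(genotypes[genotypes["sample_id"] == s], training)
        truth = populations[s]
        if res.status == "assigned" and res.best == truth:
            correct += 1
        results.append((s, truth, res))
    return correct / n_holdout, results


def assignments_table(results: list[tuple[str, str, AssignmentResult]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s for s, _, _ in results],
            "true_population": [t for _, t, _ in results],
            "best_population": [r.best for _, _, r in results],
            "log10_LR": [r.log10_lr for _, _, r in results],
            "status": [r.status for _, _, r in results],
        }
    )
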
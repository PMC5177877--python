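"""Synthetic phased InDel cohorts with controlled hierarchical divergence.

The generator emulates 1000 Genomes-like tiered structure: five continental
populations with high divergence and, within one continental tier (the East
Asian analog), five sub-populations with low divergence. Per-population
allele frequencies follow the Balding–Nichols model: around an ancestral
frequency p, population frequencies are Beta-distributed with mean p and
variance F·p·(1−p), so loci simulated at fixation index F have expected
Weir–Cockerham theta ≈ F — the quantity the downstream screen estimates.

A fraction of loci is placed in tight genomic clusters (the raw material for
multi-InDel markers); within a cluster, long alleles are placed on
correlated haplotype backgrounds so clusters carry more than two but usually
not all 2^k haplotypes, as real multi-InDel markers do.

No coalescent machinery, recombination maps or mutation processes: sampling
is Hardy–Weinberg within each population, which is all the downstream
statistics assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING, PhasedCohort
from .fst import TierStructure
from .io import write_sample_map
from .panel import InDelVariant

DEFAULT_TIERS: TierStructure = [
    ("AFR", ["AFR"]),
    ("EAS", ["CHS", "CHB", "JPT", "KHV", "CDX"]),
    ("EUR", ["EUR"]),
    ("SAS", ["SAS"]),
    ("AMR", ["AMR"]),
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the tiered cohort generator."""

    seed: int = 0
    n_loci: int = 1000
    tier_structure: TierStructure = field(default_factory=lambda: [(t, list(m)) for t, m in DEFAULT_TIERS])
    F_continental: float = 0.5
    F_sub: float = 0.15
    samples_per_pop: int = 100
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    cluster_fraction: float = 0.3
    cluster_size_range: tuple[int, int] = (2, 7)
    cluster_gap_range: tuple[int, int] = (10, 150)
    indel_length_range: tuple[int, int] = (1, 14)
    # probability a chromosome copies the whole shared cluster background;
    # equals the within-cluster allele correlation r, so r^2 ~ 0.5 by default
    ld_coefficient: float = 0.7
    isolated_gap: int = 10_000

    def __post_init__(self) -> None:
        if not (0 <= self.F_continental < 1 and 0 <= self.F_sub < 1):
            raise ValueError("fixation indices must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_freq_range must lie strictly inside (0, 1)")
        if not (0 <= self.cluster_fraction <= 1):
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.cluster_gap_range[0] < 1 or self.cluster_gap_range[0] > self.cluster_gap_range[1]:
            raise ValueError("invalid cluster_gap_range")
        if self.cluster_size_range[0] < 2:
            raise ValueError("clusters need at least 2 loci")
        if not (0 <= self.ld_coefficient <= 1):
            raise ValueError("ld_coefficient must lie in [0, 1]")
        if self.indel_length_range[0] < 1:
            raise ValueError("InDel length deltas must be >= 1")

    @property
    def populations(self) -> list[str]:
        return [p for _, members in self.tier_structure for p in members]


def draw_balding_nichols_frequencies(
    ancestral_freq: float, F: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-population allele frequencies under the Balding–Nichols model.

    Beta draws with mean ``ancestral_freq`` and variance F·p·(1−p); F = 0
    returns the ancestral frequency exactly for every population.
    """
    p = float(ancestral_freq)
    if not 0 < p < 1:
        raise ValueError(f"ancestral frequency must lie strictly in (0, 1), got {p}")
    if not 0 <= F < 1:
        raise ValueError(f"F must lie in [0, 1), got {F}")
    if F == 0:
        return np.full(n_pops, p)
    scale = (1 - F) / F
    return rng.beta(p * scale, (1 - p) * scale, size=n_pops)


def _bn_matrix(p: np.ndarray, F: float, n_pops: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized Balding–Nichols: (n_pops, len(p)) frequency matrix."""
    if F == 0:
        return np.tile(p, (n_pops, 1))
    scale = (1 - F) / F
    return rng.beta(np.tile(p * scale, (n_pops, 1)), np.tile((1 - p) * scale, (n_pops, 1)))


def _layout_loci(config: SimConfig, rng: np.random.Generator):
    """Assign loci to clusters and genomic positions on one chromosome.

    Returns (positions, cluster_id) where cluster_id is -1 for isolated loci.
    """
    L = config.n_loci
    n_clustered = int(round(config.cluster_fraction * L))
    sizes: list[int] = []
    remaining = n_clustered
    lo, hi = config.cluster_size_range
    while remaining >= 2:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, remaining)
        if remaining - s == 1:  # avoid stranding a singleton
            s = remaining
        sizes.append(max(2, s))
        remaining -= sizes[-1]

    cluster_id = np.full(L, -1, dtype=int)
    positions = np.zeros(L, dtype=int)
    pos = 1_000_000
    i = 0
    for cid, s in enumerate(sizes):
        for j in range(s):
            if j > 0:
                pos += int(rng.integers(config.cluster_gap_range[0], config.cluster_gap_range[1] + 1))
            positions[i] = pos
            cluster_id[i] = cid
            i += 1
        pos += config.isolated_gap
    while i < L:
        positions[i] = pos
        pos += config.isolated_gap
        i += 1
    return positions, cluster_id


def simulate_tiered_cohort(config: SimConfig) -> PhasedCohort:
    """Draw a phased cohort under the two-level Balding–Nichols hierarchy.

    Continental-tier frequencies diverge from the ancestral frequency at
    F_continental; sub-population frequencies within each multi-member tier
    diverge from their tier frequency at F_sub. 2·samples_per_pop
    chromosomes per population are sampled under Hardy–Weinberg; clustered
    loci share a latent haplotype background with probability
    ``ld_coefficient`` so clusters are in linkage disequilibrium.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    positions, cluster_id = _layout_loci(config, rng)

    # member loci of one cluster share a frequency "unit": one ancestral
    # frequency and one Balding-Nichols draw per population, so clusters sit
    # on a common haplotype background as real multi-InDels do
    clustered = cluster_id >= 0
    n_clusters = int(cluster_id.max() + 1) if clustered.any() else 0
    unit_of_locus = np.where(clustered, cluster_id, n_clusters + np.cumsum(~clustered) - 1)
    n_units = n_clusters + int((~clustered).sum())

    anc_unit = rng.uniform(*config.ancestral_freq_range, size=n_units)
    tiers = config.tier_structure
    tier_freq = _bn_matrix(anc_unit, config.F_continental, len(tiers), rng)
    tier_freq = np.clip(tier_freq, 1e-9, 1 - 1e-9)

    unit_freq: dict[str, np.ndarray] = {}
    for t, (_, members) in enumerate(tiers):
        if len(members) == 1:
            unit_freq[members[0]] = tier_freq[t]
        else:
            sub = np.clip(_bn_matrix(tier_freq[t], config.F_sub, len(members), rng), 0.0, 1.0)
            for k, pop in enumerate(members):
                unit_freq[pop] = sub[k]
    pop_freq = {pop: f[unit_of_locus] for pop, f in unit_freq.items()}

    deltas = rng.integers(config.indel_length_range[0], config.indel_length_range[1] + 1, size=L)
    loci = [
        InDelVariant(
            rsid=f"sim{i + 1}",
            chrom="1",
            position=int(positions[i]),
            short_allele="-",
            long_allele="".join(_BASES[rng.integers(0, 4, size=int(deltas[i]))]),
        )
        for i in range(L)
    ]

    sample_ids: list[str] = []
    pops: list[str] = []
    blocks: list[np.ndarray] = []
    for pop in config.populations:
        p = pop_freq[pop]
        n_chrom = 2 * config.samples_per_pop
        alleles = (rng.random((n_chrom, L)) < p).astype(np.int8)
        if n_clusters:
            # with probability ld_coefficient a chromosome carries the shared
            # background at ALL member loci of a cluster (one latent per
            # cluster), otherwise its member alleles are independent draws
            u = rng.random((n_chrom, n_clusters))
            shared = (u[:, np.clip(cluster_id, 0, None)] < p).astype(np.int8)
            copy_background = rng.random((n_chrom, n_clusters)) < config.ld_coefficient
            use_shared = copy_background[:, np.clip(cluster_id, 0, None)] & clustered
            alleles = np.where(use_shared, shared, alleles)
        blocks.append(alleles.reshape(config.samples_per_pop, 2, L))
        sample_ids.extend(f"{pop}_{i + 1:04d}" for i in range(config.samples_per_pop))
        pops.extend([pop] * config.samples_per_pop)

    return PhasedCohort(
        sample_ids=sample_ids,
        populations=pops,
        loci=loci,
        haplotypes=np.concatenate(blocks, axis=0),
    )


def emit_vcf(cohort: PhasedCohort, vcf_path: str | Path, sample_map_path: str | Path | None = None) -> None:
    """Write the cohort as phased VCF 4.2 plus a side-car sample-map TSV.

    REF/ALT use a one-base anchor ("A") prepended to the short/long alleles
    so each record's length delta equals the locus's delta; GT allele 0 is
    always the short allele.
    """
    vcf_path = Path(vcf_path)
    chroms = list(dict.fromkeys(v.chrom for v in cohort.loci))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=multindel-sim\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.sample_ids) + "\n")
        H = cohort.haplotypes
        for j, v in enumerate(cohort.loci):
            ref = "A" + ("" if v.short_allele == "-" else v.short_allele)
            alt = "A" + v.long_allele
            gts = []
            for i in range(cohort.n_samples):
                a0, a1 = int(H[i, 0, j]), int(H[i, 1, j])
                if a0 == MISSING or a1 == MISSING:
                    gts.append(".|.")
                else:
                    gts.append(f"{a0}|{a1}")
            fh.write(f"{v.chrom}\t{v.position}\t{v.rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")
    if sample_map_path is None:
        sample_map_path = vcf_path.with_suffix(".samples.tsv")
    write_sample_map(cohort, sample_map_path)


# ---------------------------------------------------------------------------
# Marker-level simulation (multi-allelic Balding–Nichols)
# ---------------------------------------------------------------------------

def simulate_marker_cohort(
    n_markers: int = 12,
    pop_sizes: dict[str, int] | None = None,
    theta_range: tuple[float, float] = (0.15, 0.4),
    haplotypes_per_marker: tuple[int, int] = (3, 5),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, np.ndarray]]:
    """Simulate per-marker multi-allelic genotypes for validation studies.

    Each marker is one multi-allelic locus whose alleles are haplotype
    classes. The ancestral haplotype-frequency vector q is Dirichlet(1);
    each population's vector is Dirichlet(q·(1−F)/F) — the multi-allelic
    Balding–Nichols model — with the marker's F drawn uniformly from
    ``theta_range`` (F = 0 collapses all populations onto q, the null of
    identical populations). Diploid genotypes are Hardy–Weinberg draws.

    Default cohort sizes mirror the validation study this pipeline emulates:
    110 + 100 samples from two target populations.

    Returns (genotype frame with columns sample_id/marker_id/hap1/hap2,
    sample -> population mapping, marker -> true per-population frequency
    matrix of shape (n_pops, n_haplotypes)).
    """
    if pop_sizes is None:
        pop_sizes = {"POP1": 110, "POP2": 100}
    rng = np.random.default_rng(seed)
    pops = list(pop_sizes)
    sample_ids = [f"{p}_{i + 1:04d}" for p in pops for i in range(pop_sizes[p])]
    labels = {s: s.rsplit("_", 1)[0] for s in sample_ids}

    rows: list[tuple[str, str, str, str]] = []
    true_freqs: dict[str, np.ndarray] = {}
    per_sample: list[list] = [[] for _ in sample_ids]
    for m in range(n_markers):
        marker_id = f"M{m + 1:02d}"
        H = int(rng.integers(haplotypes_per_marker[0], haplotypes_per_marker[1] + 1))
        q = rng.dirichlet(np.ones(H))
        lo, hi = theta_range
        F = float(rng.uniform(lo, hi)) if hi > 0 else 0.0
        if F == 0:
            freqs = np.tile(q, (len(pops), 1))
        else:
            freqs = np.vstack([rng.dirichlet(q * (1 - F) / F) for _ in pops])
        true_freqs[marker_id] = freqs
        keys = [f"h{k}" for k in range(H)]
        s = 0
        for pi, p in enumerate(pops):
            n = pop_sizes[p]
            draws = rng.choice(H, size=(n, 2), p=freqs[pi])
            for i in range(n):
                pair = sorted((keys[draws[i, 0]], keys[draws[i, 1]]))
                per_sample[s + i].append((marker_id, pair))
            s += n
    for si, sid in enumerate(sample_ids):
        for marker_id, pair in per_sample[si]:
            rows.append((sid, marker_id, pair[0], pair[1]))

    genotypes = pd.DataFrame(rows, columns=["sample_id", "marker_id", "hap1", "hap2"])
    return genotypes, labels, true_freqs
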
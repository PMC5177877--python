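"""Phased diploid cohorts: samples, population labels and haplotype states."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import InDelVariant

MISSING = -1  # sentinel allele state for missing genotypes


@dataclass
class PhasedCohort:
    """Samples with population labels and phased allele states per InDel locus.

    ``haplotypes`` has shape (n_samples, 2, n_loci) with entries 0 (short
    allele), 1 (long allele) or -1 (missing). Loci are sorted by
    (chromosome, position) with no duplicate positions; the two rows per
    sample are the two phased chromosomes.
    """

    sample_ids: list[str]
    populations: list[str]
    loci: list[InDelVariant]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n, two, m = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes must have shape (n_samples, 2, n_loci)")
        if n != len(self.sample_ids) or n != len(self.populations):
            raise ValueError("sample_ids, populations and haplotypes disagree on n_samples")
        if m != len(self.loci):
            raise ValueError("loci and haplotypes disagree on n_loci")
        if not set(np.unique(self.haplotypes)) <= {-1, 0, 1}:
            raise ValueError("allele states must be 0, 1 or -1 (missing)")
        seen: set[tuple[str, int]] = set()
        prev: tuple[str, int] | None = None
        done_chroms: set[str] = set()
        for v in self.loci:
            key = (v.chrom, v.position)
            if key in seen:
                raise ValueError(f"duplicate locus position {key}")
            seen.add(key)
            if prev is not None and v.chrom == prev[0] and v.position <= prev[1]:
                raise ValueError(f"loci not sorted by position at {key}")
            if prev is not None and v.chrom != prev[0]:
                if v.chrom in done_chroms:
                    raise ValueError(f"chromosome {v.chrom} blocks are not contiguous")
                done_chroms.add(prev[0])
            prev = key

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_names(self) -> list[str]:
        out: list[str] = []
        for p in self.populations:
            if p not in out:
                out.append(p)
        return out

    def samples_of(self, population: str) -> np.ndarray:
        """Indices of samples belonging to one population."""
        return np.array([i for i, p in enumerate(self.populations) if p == population])

    def locus_index(self) -> dict[tuple[str, int], int]:
        return {(v.chrom, v.position): i for i, v in enumerate(self.loci)}

    def allele_frequencies(self, population: str | None = None) -> np.ndarray:
        """Long-allele frequency per locus, over non-missing chromosomes."""
        h = self.haplotypes
        if population is not None:
            h = h[self.samples_of(population)]
        flat = h.reshape(-1, h.shape[-1]).astype(float)
        mask = flat >= 0
        with np.errstate(invalid="ignore"):
            return np.where(flat >= 0, flat, 0.0).sum(0) / mask.sum(0)
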
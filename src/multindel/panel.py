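"""Domain types for multi-InDel marker panels.

A *multi-InDel* marker is a cluster of physically tight insertion/deletion
polymorphisms (here: adjacent members < 250 bp apart) treated as one
multi-allelic locus. Its alleles are haplotypes — the combination of
short/long states across the member InDels on one chromosome — and each
haplotype is observed on capillary electrophoresis (CE) as a distinct PCR
amplicon size, provided the size encoding is injective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

Haplotype = tuple[int, ...]  # one 0/1 state per member locus; 0 = short allele


def allele_length(allele: str) -> int:
    """Length of an allele string, with the absence marker ``-`` counting as 0."""
    return 0 if allele == "-" else len(allele)


@dataclass(frozen=True)
class InDelVariant:
    """One di-allelic insertion/deletion locus.

    ``short_allele`` and ``long_allele`` are the two allele sequences
    (``-`` denotes the absent/empty allele); ``delta`` is the length
    difference in bp and is strictly positive by construction.
    """

    rsid: str
    chrom: str
    position: int  # 1-based
    short_allele: str
    long_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.position}")
        if self.delta <= 0:
            raise ValueError(
                f"{self.rsid}: long allele {self.long_allele!r} is not longer than "
                f"short allele {self.short_allele!r}"
            )

    @property
    def delta(self) -> int:
        """Long-minus-short allele length in bp (> 0)."""
        return allele_length(self.long_allele) - allele_length(self.short_allele)


def haplotype_string(hap: Haplotype) -> str:
    return "".join(str(int(a)) for a in hap)


@dataclass
class MultiInDelMarker:
    """An ordered cluster of InDels with a haplotype -> CE amplicon-size map.

    ``size_map`` sends each allele-state haplotype to the bp length of the
    PCR product: the all-short haplotype amplifies at ``base_amplicon_size``
    and every long allele carried adds that locus's length delta.
    """

    marker_id: str
    loci: tuple[InDelVariant, ...]
    base_amplicon_size: int | None = None
    size_map: dict[Haplotype, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        if not self.loci:
            raise ValueError(f"marker {self.marker_id}: no member loci")
        chroms = {v.chrom for v in self.loci}
        if len(chroms) > 1:
            raise ValueError(f"marker {self.marker_id}: members span chromosomes {chroms}")
        pos = [v.position for v in self.loci]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(
                f"marker {self.marker_id}: member positions not strictly increasing: {pos}"
            )
        if self.base_amplicon_size is not None and not self.size_map:
            self.size_map = self.compute_size_map(self.base_amplicon_size)

    @property
    def chrom(self) -> str:
        return self.loci[0].chrom

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def span(self) -> int:
        """Genomic extent from first to last member position, inclusive, in bp."""
        return self.loci[-1].position - self.loci[0].position + 1

    def adjacent_gaps(self) -> list[int]:
        """Position differences between consecutive member loci."""
        pos = [v.position for v in self.loci]
        return [b - a for a, b in zip(pos, pos[1:])]

    def compute_size_map(self, base_amplicon_size: int) -> dict[Haplotype, int]:
        """Amplicon size of every possible haplotype.

        size(h) = base + sum of deltas at loci where h carries the long allele.
        """
        if base_amplicon_size <= 0:
            raise ValueError("base_amplicon_size must be positive")
        deltas = [v.delta for v in self.loci]
        out: dict[Haplotype, int] = {}
        for code in range(2 ** len(deltas)):
            hap = tuple((code >> i) & 1 for i in range(len(deltas)))
            out[hap] = base_amplicon_size + sum(d for d, a in zip(deltas, hap) if a)
        return out

    def haplotype_size(self, hap: Haplotype) -> int:
        if not self.size_map:
            raise ValueError(f"marker {self.marker_id}: size_map not computed")
        return self.size_map[tuple(int(a) for a in hap)]


def check_size_degeneracy(
    marker: MultiInDelMarker, observed: set[Haplotype] | None = None
) -> list[tuple[Haplotype, Haplotype]]:
    """Pairs of haplotypes that collide onto the same amplicon size.

    Restricted to ``observed`` haplotypes when given (CE genotyping only
    needs the realized haplotypes to be distinguishable); otherwise checked
    over the marker's full size_map domain.
    """
    if not marker.size_map:
        raise ValueError(f"marker {marker.marker_id}: size_map not computed")
    haps = sorted(marker.size_map) if observed is None else sorted(observed)
    collisions = []
    for i, h1 in enumerate(haps):
        for h2 in haps[i + 1 :]:
            if marker.size_map[h1] == marker.size_map[h2]:
                collisions.append((h1, h2))
    return collisions


@dataclass
class PanelDefinition:
    """An ordered collection of multi-InDel markers forming one assay panel."""

    markers: list[MultiInDelMarker]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for m in self.markers:
            for v in m.loci:
                key = (v.chrom, v.position)
                if key in seen:
                    raise ValueError(
                        f"locus {v.rsid} at {key} belongs to markers "
                        f"{seen[key]} and {m.marker_id}"
                    )
                seen[key] = m.marker_id

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def marker(self, marker_id: str) -> MultiInDelMarker:
        for m in self.markers:
            if m.marker_id == str(marker_id):
                return m
        raise KeyError(f"no marker {marker_id!r} in panel")

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def all_loci(self) -> list[InDelVariant]:
        return [v for m in self.markers for v in m.loci]
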
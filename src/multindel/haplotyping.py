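"""From phase to CE peaks to haplotype frequencies.

A diploid sample shows one or two amplicon-size peaks per marker on
capillary electrophoresis: homozygotes one peak, heterozygotes two. Because
each haplotype maps to a distinct size (for non-degenerate markers), the
peak set determines the unordered haplotype pair exactly — no statistical
phasing is ever needed for panel genotypes. Haplotype frequencies are
maximum-likelihood counts of chromosomes, with no pseudocount; smoothing is
the classifier's concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PhasedCohort
from .io import HaplotypeFrequencyTable
from .panel import Haplotype, MultiInDelMarker, PanelDefinition, check_size_degeneracy, haplotype_string

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerGenotype:
    """One sample's unordered haplotype pair at one marker."""

    sample_id: str
    marker_id: str
    haplotypes: tuple[Haplotype, Haplotype]

    def __post_init__(self) -> None:
        a, b = self.haplotypes
        object.__setattr__(self, "haplotypes", tuple(sorted([tuple(a), tuple(b)])))

    @property
    def is_heterozygote(self) -> bool:
        return self.haplotypes[0] != self.haplotypes[1]


@dataclass(frozen=True)
class PeakSet:
    """The 1 or 2 distinct amplicon sizes a sample shows at one marker."""

    marker_id: str
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(sorted(set(int(s) for s in self.sizes)))
        if not 1 <= len(sizes) <= 2:
            raise ValueError(
                f"marker {self.marker_id}: {len(sizes)} distinct peaks (artifact/mixture?)"
            )
        object.__setattr__(self, "sizes", sizes)


def _require_nondegenerate(marker: MultiInDelMarker, observed: set[Haplotype]) -> None:
    collisions = check_size_degeneracy(marker, observed=observed)
    if collisions:
        raise ValueError(
            f"marker {marker.marker_id}: size map degenerate over haplotypes {collisions}; "
            "CE genotyping is ill-defined"
        )


def ce_peaks(genotype: MarkerGenotype, marker: MultiInDelMarker) -> PeakSet:
    """Amplicon sizes produced by a genotype: two peaks if heterozygous, one if not."""
    _require_nondegenerate(marker, set(genotype.haplotypes))
    return PeakSet(
        marker_id=marker.marker_id,
        sizes=tuple(marker.haplotype_size(h) for h in genotype.haplotypes),
    )


def call_genotype_from_peaks(
    peaks: PeakSet, marker: MultiInDelMarker, sample_id: str = ""
) -> MarkerGenotype:
    """Invert the CE size encoding: one peak -> homozygote, two -> heterozygote.

    Any size present in the size_map is callable even if never seen in
    training data. Sizes outside the map raise an off-ladder error.
    """
    inverse: dict[int, list[Haplotype]] = {}
    for h, s in marker.size_map.items():
        inverse.setdefault(s, []).append(h)
    haps: list[Haplotype] = []
    for s in peaks.sizes:
        if s not in inverse:
            raise ValueError(f"marker {marker.marker_id}: off-ladder peak at {s} bp")
        if len(inverse[s]) > 1:
            raise ValueError(
                f"marker {marker.marker_id}: size {s} is degenerate ({inverse[s]})"
            )
        haps.append(inverse[s][0])
    if len(haps) == 1:
        haps = [haps[0], haps[0]]
    return MarkerGenotype(sample_id=sample_id, marker_id=marker.marker_id, haplotypes=(haps[0], haps[1]))


def _key_of(hap: Haplotype, marker: MultiInDelMarker, key: str) -> str:
    if key == "state":
        return haplotype_string(hap)
    if key == "size":
        return str(marker.haplotype_size(hap))
    raise ValueError("key must be 'state' or 'size'")


def marker_genotypes_from_phase(
    cohort: PhasedCohort, panel: PanelDefinition, key: str = "size"
) -> pd.DataFrame:
    """Restrict each sample's two phased haplotype vectors to each marker.

    Returns a tidy frame (sample_id, marker_id, hap1, hap2) with the
    unordered pair in sorted order, keyed by amplicon size (default) or by
    allele-state string. Samples missing any member genotype are dropped at
    that marker with a logged count, never imputed.
    """
    index = cohort.locus_index()
    frames = []
    for marker in panel:
        if key == "size" and not marker.size_map:
            raise ValueError(f"marker {marker.marker_id}: size_map needed for size keys")
        try:
            cols = [index[(v.chrom, v.position)] for v in marker.loci]
        except KeyError as e:
            raise ValueError(f"marker {marker.marker_id}: member locus {e} absent from cohort") from e
        sub = cohort.haplotypes[:, :, cols]  # (n, 2, k)
        ok = (sub >= 0).all(axis=(1, 2))
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.warning("marker %s: dropped %d samples with missing members", marker.marker_id, n_dropped)
        rows = []
        for i in np.flatnonzero(ok):
            h1 = tuple(int(a) for a in sub[i, 0])
            h2 = tuple(int(a) for a in sub[i, 1])
            k1, k2 = sorted([_key_of(h1, marker, key), _key_of(h2, marker, key)])
            rows.append((cohort.sample_ids[i], marker.marker_id, k1, k2))
        frames.append(pd.DataFrame(rows, columns=["sample_id", "marker_id", "hap1", "hap2"]))
    if not frames:
        return pd.DataFrame(columns=["sample_id", "marker_id", "hap1", "hap2"])
    return pd.concat(frames, ignore_index=True)


def _sorted_keys(keys: set[str]) -> list[str]:
    try:
        return sorted(keys, key=lambda k: (0, int(k)))
    except ValueError:
        return sorted(keys)


def count_haplotypes(
    genotypes: pd.DataFrame, populations: dict[str, str]
) -> dict[str, pd.DataFrame]:
    """Raw chromosome counts per marker: populations as rows, haplotype keys
    as columns. Samples absent from ``populations`` raise; populations with
    zero genotyped samples at a marker are omitted with a warning.
    """
    missing = set(genotypes["sample_id"]) - set(populations)
    if missing:
        raise ValueError(f"samples without population label: {sorted(missing)[:5]}")
    out: dict[str, pd.DataFrame] = {}
    all_pops = list(dict.fromkeys(populations[s] for s in genotypes["sample_id"]))
    for marker_id, sub in genotypes.groupby("marker_id", sort=True):
        keys = _sorted_keys(set(sub["hap1"]) | set(sub["hap2"]))
        table = pd.DataFrame(0, index=all_pops, columns=keys, dtype=int)
        pops = sub["sample_id"].map(populations)
        for hap_col in ("hap1", "hap2"):
            cnt = pd.crosstab(pops, sub[hap_col])
            table = table.add(cnt.reindex(index=all_pops, columns=keys, fill_value=0), fill_value=0)
        empty = table.sum(axis=1) == 0
        if empty.any():
            logger.warning(
                "marker %s: populations %s have no genotyped samples; rows omitted",
                marker_id, list(table.index[empty]),
            )
            table = table[~empty]
        out[str(marker_id)] = table.astype(int)
    return out


def count_haplotype_frequencies(
    genotypes: pd.DataFrame, populations: dict[str, str]
) -> HaplotypeFrequencyTable:
    """Haplotype frequencies determined by counting chromosomes.

    frequency = carriers / (2 x non-missing samples), per marker per
    population; every row sums to 1. No pseudocount is applied.
    """
    counts = count_haplotypes(genotypes, populations)
    tables = {
        mid: table.div(table.sum(axis=1), axis=0) for mid, table in counts.items()
    }
    return HaplotypeFrequencyTable(tables)


def write_genotype_table(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index=False)


def read_genotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if missing := {"sample_id", "marker_id", "hap1", "hap2"} - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
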
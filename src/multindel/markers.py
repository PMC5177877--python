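"""Assemble screened InDels into multi-InDel markers.

Formation rules: (i) consecutive member loci on one chromosome with every
ADJACENT gap < 250 bp — adjacency, not total span, is what the rule bounds
(the bundled 7-InDel marker spans 291 bp while its largest adjacent gap is
104 bp, so only the adjacency reading admits such markers); (ii) at least
two distinct haplotypes observed in the cohort; (iii) maximum observed
amplicon size < 300 bp; plus injectivity of the size encoding over observed
haplotypes, without which CE genotyping is ill-defined.
"""

from __future__ import annotations

import logging

import numpy as np

from .cohort import PhasedCohort
from .fst import ScreenResult
from .panel import (
    Haplotype,
    InDelVariant,
    MultiInDelMarker,
    PanelDefinition,
    check_size_degeneracy,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 250
DEFAULT_MAX_AMPLICON = 300
DEFAULT_FLANK_PADDING = 30


def cluster_candidates(
    loci: list[InDelVariant], max_gap: int = DEFAULT_MAX_GAP
) -> list[list[InDelVariant]]:
    """Greedy left-to-right chaining of sorted loci into candidate clusters.

    A locus joins the current group iff it is on the same chromosome and its
    gap to the previous member is strictly below ``max_gap``; single-locus
    groups are discarded (a multi-InDel needs >= 2 members).
    """
    loci = sorted(loci, key=lambda v: (v.chrom, v.position))
    groups: list[list[InDelVariant]] = []
    current: list[InDelVariant] = []
    for v in loci:
        if current and v.chrom == current[-1].chrom and v.position - current[-1].position < max_gap:
            current.append(v)
        else:
            if len(current) >= 2:
                groups.append(current)
            current = [v]
    if len(current) >= 2:
        groups.append(current)
    return groups


def enumerate_haplotypes(cohort: PhasedCohort, marker: MultiInDelMarker) -> dict[Haplotype, int]:
    """Distinct phased haplotypes over the marker's member loci, with
    chromosome counts. Chromosomes missing any member genotype are skipped;
    counts therefore sum to at most 2 x n_samples.
    """
    index = cohort.locus_index()
    try:
        cols = [index[(v.chrom, v.position)] for v in marker.loci]
    except KeyError as e:
        raise ValueError(f"marker {marker.marker_id}: member locus {e} absent from cohort") from e
    sub = cohort.haplotypes[:, :, cols].reshape(-1, len(cols))
    ok = (sub >= 0).all(axis=1)
    counts: dict[Haplotype, int] = {}
    haps, n = np.unique(sub[ok], axis=0, return_counts=True)
    for hap, c in zip(haps, n):
        counts[tuple(int(a) for a in hap)] = int(c)
    return counts


def model_base_amplicon(marker: MultiInDelMarker, flank_padding: int) -> int:
    """Modeled amplicon length of the all-short haplotype: the genomic span
    of the member loci plus symmetric primer flanks. Real primer placement
    is an assay concern; a supplied assay size overrides this model.
    """
    return marker.span + 2 * flank_padding


def build_panel(
    cohort: PhasedCohort,
    screen_results: list[ScreenResult],
    max_gap: int = DEFAULT_MAX_GAP,
    max_amplicon: int = DEFAULT_MAX_AMPLICON,
    flank_padding: int = DEFAULT_FLANK_PADDING,
) -> PanelDefinition:
    """Cluster screened loci, keep clusters satisfying all formation rules.

    Pipeline per candidate cluster: enumerate observed haplotypes (reject
    < 2), compute the haplotype -> amplicon-size map from the modeled base
    size, reject clusters whose maximum OBSERVED amplicon is >= max_amplicon
    (strict rule) or whose observed sizes collide. Marker ids are assigned
    M01, M02, ... in genomic order; output is invariant to input order.
    """
    passing = [r.locus for r in screen_results if r.passed]
    groups = cluster_candidates(passing, max_gap=max_gap)

    markers: list[MultiInDelMarker] = []
    for group in groups:
        marker = MultiInDelMarker(marker_id="candidate", loci=tuple(group))
        observed = enumerate_haplotypes(cohort, marker)
        if len(observed) < 2:
            logger.info(
                "rejecting cluster at %s:%d: %d haplotype(s) observed",
                marker.chrom, group[0].position, len(observed),
            )
            continue
        base = model_base_amplicon(marker, flank_padding)
        marker.base_amplicon_size = base
        marker.size_map = marker.compute_size_map(base)
        max_size = max(marker.size_map[h] for h in observed)
        if max_size >= max_amplicon:
            logger.info(
                "rejecting cluster at %s:%d: observed amplicon %d >= %d",
                marker.chrom, group[0].position, max_size, max_amplicon,
            )
            continue
        collisions = check_size_degeneracy(marker, observed=set(observed))
        if collisions:
            logger.info(
                "rejecting cluster at %s:%d: degenerate size map %s",
                marker.chrom, group[0].position, collisions,
            )
            continue
        markers.append(marker)

    for i, m in enumerate(markers, start=1):
        m.marker_id = f"M{i:02d}"
    return PanelDefinition(markers=markers, provenance="built by multindel.markers.build_panel")
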
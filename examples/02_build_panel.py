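"""Cluster screened InDels into multi-InDel markers.

Simulates a cohort where 60% of loci sit in tight clusters (< 250 bp
spacing, shared haplotype backgrounds), screens them, then assembles
markers under the formation rules: adjacent gaps < 250 bp, at least two
observed haplotypes, maximum observed amplicon < 300 bp, and an injective
haplotype -> amplicon-size encoding.
"""

import multindel as md

cfg = md.SimConfig(
    seed=11,
    n_loci=2000,
    samples_per_pop=100,
    F_continental=0.8,
    F_sub=0.4,
    cluster_fraction=0.6,
    cluster_size_range=(2, 4),
    tier_structure=[("AFR", ["AFR"]), ("EAS", ["CHB", "KHV"])],
)
cohort = md.simulate_tiered_cohort(cfg)
results = md.pairwise_theta_matrices(cohort, cfg.tier_structure)
passing = md.screen_loci(results)
print(f"{len(passing)} of {cohort.n_loci} loci pass the theta screen")

panel = md.build_panel(cohort, results, max_gap=250, max_amplicon=300, flank_padding=30)
print(f"assembled {len(panel)} multi-InDel markers:")
for m in panel:
    sizes = sorted(set(m.size_map.values()))
    print(f"  {m.marker_id}: {m.n_loci} InDels, span {m.span} bp, "
          f"amplicons {sizes[0]}-{sizes[-1]} bp")
print("Each marker is a multi-allelic locus whose alleles are haplotypes,")
print("each resolvable as one distinct capillary-electrophoresis peak size.")
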
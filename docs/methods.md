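# Methods

This note documents the models and estimators implemented in `multindel`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the package's known limitations.

## The marker model

A multi-InDel marker is an ordered cluster of di-allelic
insertion/deletion loci on one chromosome. Each locus has a *short* and a
*long* allele differing by `delta` bp (> 0 by construction; `-` denotes the
empty allele). A haplotype is the vector of short/long states across the
member loci on one chromosome; with a base amplicon of `b` bp (the PCR
product of the all-short haplotype), haplotype `h` amplifies at

    size(h) = b + sum of delta_i over loci where h carries the long allele.

When this map is injective over the haplotypes that actually occur, one CE
peak identifies one haplotype and a diploid genotype is the pre-image of
its one- or two-peak set — phase is observed, not inferred. Markers whose
observed sizes collide are excluded from CE genotyping (`check_size_degeneracy`).

Because primer placement is an assay concern outside this package's scope,
the base amplicon is modeled as the genomic span of the member loci plus a
symmetric flank (`flank_padding`, default 30 bp — a typical minimal primer
offset). When a real assay size is known (as for the bundled panel) it
overrides the model.

### The formation rules

`build_panel` keeps a candidate cluster iff

1. every **adjacent** gap between consecutive members is < 250 bp (default
   `max_gap`). Adjacency, not total span, is the right reading: the bundled
   7-InDel marker spans 291 bp while its largest adjacent gap is 104 bp,
   so a span-based rule would contradict the panel it has to admit;
2. at least two distinct haplotypes are observed in the supplied cohort
   (a haplotype "exists" from one observed chromosome; no frequency floor);
3. the maximum observed amplicon is < 300 bp (strict), keeping amplicons
   short enough for degraded samples and keeping intra-marker
   recombination negligible (< 300 bp at ~1 cM/Mb is of the order of SNP
   mutation rates);
4. the observed size encoding is injective.

Clustering is greedy left-to-right over position-sorted loci: deterministic,
order-invariant, and exactly what a genome-scan over sorted coordinates
does. Single loci are never emitted — a "multi"-InDel has ≥ 2 members.

## Weir–Cockerham theta

`wc_theta` implements the per-locus variance-component estimator for r
populations from (n_i, p_i, h_i) — diploid sample sizes, long-allele
frequencies, observed heterozygote proportions:

    n̄  = Σn_i / r                       n_c = (Σn_i − Σn_i²/Σn_i) / (r−1)
    p̄  = Σn_i p_i / Σn_i                s²  = Σn_i (p_i − p̄)² / ((r−1) n̄)
    h̄  = Σn_i h_i / Σn_i

    a = n̄/n_c · [ s² − (p̄(1−p̄) − (r−1)/r·s² − h̄/4) / (n̄−1) ]
    b = n̄/(n̄−1) · [ p̄(1−p̄) − (r−1)/r·s² − (2n̄−1)/(4n̄)·h̄ ]
    c = h̄/2
    θ = a / (a + b + c)

θ is reported unclamped (slightly negative values are legitimate sampling
outcomes and can never pass the screen) and is NaN with reason
"monomorphic" when all populations are fixed for the same allele. The
implementation is validated to 1e-12 against an independent
exact-rational-arithmetic oracle on random genotype-count instances.

Genome-wide divergence is summarized by the **multi-locus ratio of summed
components**, Σa / Σ(a+b+c) (`wc_theta_multilocus`) — the standard
"weighted" genome estimate. The mean of per-locus ratios is biased low on
Balding–Nichols data because loci drifting near fixation contribute ratios
near zero; the ratio-of-sums recovers the generating F within ±0.02 at
2,000 loci and n = 100 per population, which is the parameter-recovery
contract the tests enforce.

### The two-tier screen, and a feasibility caveat

`screen_loci` passes a locus iff the **minimum** pairwise θ over all
continental-tier pairs exceeds 0.4 and the minimum over all sub-population
pairs within the target tier exceeds 0.15 — both strict. The minimum-over-
all-pairs rule is intentionally demanding, and it has a hard geometric
consequence: pairwise θ > 0.4 between two di-allelic frequencies requires
a gap of roughly 0.45–0.55 (position-dependent), and at most three
frequencies in [0, 1] can be pairwise separated that far. With five
continental populations the all-pairs criterion is therefore unsatisfiable,
and with five sub-populations at θ > 0.15 it is borderline-impossible.
Screens meant to produce candidates should either use few population pools
(e.g. one out-group plus the two target sub-populations, as the examples
and tests do) or relax which pairs must clear the bar. The thresholds and
tier structure are parameters, so both styles are available; the default
semantics stay min-over-pairs because that is the stated contract.

## Synthetic cohorts

`simulate_tiered_cohort` draws phased diploid cohorts under a two-level
Balding–Nichols hierarchy emulating 1000-Genomes-like structure — five
continental tiers (AFR/EAS/EUR/SAS/AMR analogs, F_continental default 0.5,
the high-divergence regime) with five sub-populations inside the
East-Asian analog (CHS/CHB/JPT/KHV/CDX analogs, F_sub default 0.15, the
low-divergence regime that motivates the whole design). Per locus:
ancestral frequency ~ Uniform(0.05, 0.95); tier frequency ~ Beta with mean
p and variance F_c·p(1−p); sub-population frequency ~ Beta around the tier
frequency with F_sub. Chromosomes are independent Bernoulli draws, so
Hardy–Weinberg holds exactly by construction (the chi-square goodness-of-fit
non-rejection rate over loci is ≥ 93% at α = 0.05, i.e. nominal).

A `cluster_fraction` of loci (default 0.3) is laid out in runs of 2–7 loci
with gaps from `cluster_gap_range` (default 10–150 bp; configurable above
and below 250 bp so the spacing filter can be exercised in both
directions). Member loci of a cluster share one ancestral and one
per-population frequency draw, and each chromosome copies the whole shared
cluster background with probability `ld_coefficient` (else draws members
independently). That makes the within-cluster allele correlation ≈
`ld_coefficient`; the default 0.7 targets r² ≈ 0.5. Real multi-InDel LD
structure is not quantitatively characterized, so this coefficient is an
honest free parameter chosen to produce what the markers need: more than
two but rarely all 2^k haplotypes per cluster. The generator does **not**
model coalescent genealogies, recombination maps, mutation, selection, or
allele-frequency correlations between tiers (every tier drifts
independently from the ancestor); conclusions from passing tests transfer
to real data only insofar as HWE-with-drift is an adequate description.

`simulate_marker_cohort` generates validation cohorts directly at the
marker level: each marker is one multi-allelic locus with 3–5 haplotype
classes, ancestral frequency vector q ~ Dirichlet(1), per-population
vectors ~ Dirichlet(q·(1−F)/F) — the multi-allelic Balding–Nichols model —
with F drawn per marker from `theta_range`. Defaults mirror the validation
study this pipeline emulates: two target populations of 110 and 100
diploid samples, 12 markers, per-marker θ ∈ [0.15, 0.4]; `theta_range=(0,0)`
gives the identical-populations null.

## Haplotype frequencies and the classifier

Frequencies are maximum-likelihood chromosome counts —
carriers / (2 × non-missing samples) — with **no pseudocount**, keeping the
counting stage literal; rows sum to 1 to 1e-9 and zero columns are
preserved so the haplotype alphabet is stable. Missing genotypes exclude
the sample marker-wise, never imputed; unphased heterozygotes are rejected
by default (an opt-in drops them as missing), since exact haplotype
counting needs phase — which the CE assay observes directly.

The classifier is naive Bayes over markers: within a candidate population,
genotype probability is Hardy–Weinberg in smoothed training frequencies
(p̃ = (c + α)/(T + α·H), Laplace pseudocount α = 1 by default so unseen
haplotypes keep likelihoods finite; α = 0 reproduces raw counting), and
markers multiply as independent loci (the bundled panel sits on five
chromosomes; intra-panel linkage is ignored by design). Assignment is the
maximum-likelihood population, reported with the ratio of the two highest
likelihoods and a flat-prior posterior; a ratio within 1e-12 of 1 is a tie,
not an assignment. Blind trials hold out samples uniformly over the pooled
cohort (no stratification), recount training frequencies without them, and
report holdout accuracy. On the default validation conditions the mean
accuracy over 100 seeds exceeds 0.95, and on the identical-populations
null it is chance (0.5 ± 0.1 over 200 seeds) — both recomputed by the test
suite.

## No-admixture clustering and model choice

`gibbs_no_admixture` is the classic two-block Gibbs sampler: cluster
haplotype frequencies | assignments ~ Dirichlet(λ + counts) per marker per
cluster (uncorrelated-frequencies prior, λ = 1; the prior is a parameter),
then each sample's cluster | frequencies ~ categorical with HWE genotype
weights. Defaults are desk-scale: 5,000 burn-in + 5,000 kept iterations
(larger runs are a flag away). Label switching within a run is resolved by
greedy maximum-overlap permutation of each kept iteration against the
first kept iteration; across replicate runs, `align_replicates` searches
all K! permutations (K ≤ 7 ⇒ ≤ 5,040) for maximal posterior agreement with
the first run.

The recorded per-iteration statistic is the **collapsed** data
log-likelihood log P(X | z), with cluster frequencies integrated out
analytically (a product of Dirichlet-multinomial terms per cluster and
marker, plus log 2 per heterozygote). It is label-invariant and has lower
variance than the conditional log P(X | z, p); at K = 1 it is constant and
*equals the exact log marginal likelihood*, which the tests verify against
a closed form to 1e-9. ln P(X|K) is then estimated as mean − var/2 of the
trace (sample variance), and `evanno_delta_k` computes
ΔK(K) = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(K) over replicates, choosing the
argmax. ΔK cannot evaluate K = 1, so when the mean ln P(X|K) is globally
maximal at the smallest K — no gain from any structure — the selection
falls back to the max-mean rule and reports that K; the same fallback
covers < 3 K values or zero replicate sds. On two-population cohorts the
procedure selects K = 2; on one-population cohorts it reports K = 1.

Per-sample "ancestry proportions" under a strict no-admixture model are
assignment posteriors (empirical label frequencies over kept iterations),
not admixture fractions; the package reports them as such.

## PCA

Genotypes are encoded as haplotype-dosage columns (0/1/2 copies of each
haplotype class), dropping one reference class per marker to remove exact
collinearity; columns are centered and the matrix decomposed by SVD.
Explained-variance fractions sum to 1; an all-constant matrix yields zero
coordinates and zero variance rather than an error. On divergent
two-population cohorts PC1 correlates with the population label at
|r| ≥ 0.9.

## Numerical and interface choices

* Coordinates are 1-based at every interface (panel tables, VCF); VCF
  records use a one-base anchor so the record's length delta equals the
  locus delta, and allele states are normalized to 0 = short / 1 = long
  regardless of which of REF/ALT is shorter. Only the single anchor base
  is stripped on read; left-aligned VCFs with longer shared affixes keep
  their delta but not necessarily the panel-table allele spelling
  (normalization against a reference genome is out of scope).
* Frequency workbooks are a directory of per-marker CSVs (populations as
  rows, haplotype keys as columns) — diff-able and dependency-free; keys
  are amplicon sizes by default, allele-state strings as an alternative,
  never mixed in one table.
* All randomness flows from explicit integer seeds (`numpy` Generators;
  replicate seeds derived via `SeedSequence.spawn`); fixed seed ⇒
  bit-identical outputs, which the pipeline manifest verifies by content
  hash.
* Ties in screening order are broken by (chromosome, position); marker ids
  are assigned in genomic order.
* Test problem sizes are desk-scale by design: 2,000-locus scans, 100–200
  replicate seeds for classifier studies, and K = 1..7 × 5 replicates ×
  10,000 iterations for the clustering checks.

## Known limitations

* The screen's min-over-all-pairs semantics is unsatisfiable for five
  continental pools (see above); practical scans should restrict the pools
  or the pair set.
* No admixture model: individuals wholly belong to one cluster; admixed
  individuals will be forced to their majority component.
* No EM-based frequency estimation from unphased data; phase (or CE
  observation) is required.
* The correlated-allele-frequencies prior (the F-model) is not
  implemented; for strongly related populations the uncorrelated prior
  needs more data for the same resolution.
* Haplotype-level (multi-allelic) FST of assembled markers is not a
  filter; screening is per-InDel only.
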
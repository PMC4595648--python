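# Methods

## Scope and model

`clonarch` analyzes targeted-panel sequencing of early lung glandular
neoplasms sampled as multiple histologic zones per lesion, with a matched
normal per patient, plus droplet-digital-PCR (ddPCR) measurements of mutant
circulating DNA. The package treats five questions: which mutations are
somatic, which genes are copy-number altered, how zones relate clonally,
what the cohort-level mutation statistics are, and how much mutant template
a fluid sample contains.

## Somatic calling

The counting unit is the *distinct read pair*: deduplicated paired fragments,
collapsed on a fragment signature (endpoints). Upstream filters drop
unpaired, quality-failed and poorly mapped observations (mapping quality
< 20; "poorly mapped" is not standardized, so the conventional MAPQ 20 floor
is used and exposed as a threshold) and bases at or below phred 30 in the
tumor / 20 in the normal — both bounds strict, as is conventional for
"quality > Q" filters.

A candidate is accepted iff all of:

1. alternate distinct pairs ≥ `min_alt_pairs` (default 2 — "pairs", plural);
2. alternate/total ≥ `tumor_fraction_min` (default 0.02, inclusive);
3. normal alternate/total ≤ `normal_fraction_max` (default 0.01, inclusive:
   "not present in *more than* 1%") and the site is absent from the
   common-germline database;
4. both tumor and normal totals are positive.

Acceptance is the conjunction; the recorded rejection code reports the
headline fraction rule (ii) ahead of the pair-count rule (i) when both fail,
then iii, the germline database, and iv. Raising any threshold can only
shrink the accepted set (a property test asserts this). The manual
visual-inspection step used by clinical pipelines is non-computational; an
optional site blacklist (rejection code "quality") stands in for it.

Consequence classes come from codon substitution against a strand-aware CDS
model: SNVs are missense/nonsense/silent (stop-loss is folded into missense;
it does not arise in the synthetic panel), indels are frameshift or in-frame
by length mod 3, intronic positions within 2 bp of an interior exon edge are
splice, and silent/intronic calls are rejected post hoc. Coordinates are
1-based closed throughout.

Fractional abundance is 100 × alternate/total distinct pairs, kept at full
precision internally and rounded half-up to one decimal for reporting.

## Copy number

Per-gene average per-base coverage is normalized by the sample-wide mean
gene coverage (median available by flag for robustness); the call is on the
tumor:normal ratio of normalized values. No fold-change cutoffs are standard
for this design, so the defaults are the conventional log₂ ±1 (amplify at
≥ 2.0, delete at ≤ 0.5), both configurable. Calls are scale-invariant in
each sample's raw coverages, and swapping tumor and normal inverts every
ratio exactly. Note that with mean normalization a true gain also inflates
the normalization constant, so single-gene events on small panels are
attenuated (the 4-copy-at-purity-0.6 worked case, expected raw ratio 1.6,
is neutral at the defaults by design).

## Clonal ordering

Input is a zones × mutations boolean matrix over accepted, non-synonymous
calls, keyed by (gene, locus, ref, alt). Ancestry follows set containment:

* a zone whose set is a strict subset of another's is its ancestor; among
  multiple candidate ancestors the largest (closest) wins, which the
  agglomerative construction below yields automatically;
* zones with identical non-empty sets merge into one clade node rather than
  an arbitrary chain (the data cannot order them);
* where no zone is an ancestor, an inferred precursor node is created
  holding the intersection of the sets it joins.

The construction is agglomerative: repeatedly merge the pair of clusters
with the largest intersection; if the intersection equals one cluster's set
that cluster becomes the parent, if it equals both they merge, otherwise an
inferred node is created. Ties are broken on canonical mutation-set keys —
never on zone labels — so relabeling zones permutes but cannot change the
topology. The root's set is the intersection of all non-empty zone sets.
Mutation-free zones attach as parallel leaf branches at the root (when any
exist the root carries the empty set, keeping every root-to-leaf path
monotonically non-decreasing); the `empty_as_ancestor` switch instead places
them as the common ancestor of the mutated zones. An exhaustive test checks
the implementation against an independent brute-force application of the
rule over all 4-zone × 3-mutation matrices (4,096 cases).

Dendrograms serialize to Newick with edge lengths equal to the count of
gained mutations and inferred ancestors as labeled internal nodes
(A1, A2, ... in preorder; clades join zone names with `+`).

Heterogeneity is 100 × (mutations absent from ≥ 1 zone)/(all mutations),
reported to the nearest integer (half-up); `cohort_heterogeneity` pools
numerator and denominator across lesions.

## Cohort statistics

* Mutation rate: accepted calls per lesion — mean (one decimal, half-up)
  and range; lesions with zero calls count.
* Substitution spectrum: 12 directional reference>alternate classes.
  Spectra are deliberately *not* collapsed to the 6 pyrimidine-context
  classes because the reported convention distinguishes G–A from C–T.
  Silent calls are excluded; indels are counted and set aside.
* Stage overlap: genes partitioned by their exact stage-membership
  signature; the all-stages cell is always reported explicitly.
* Abundance progression: a mutation tracked across precursor samples into
  the primary is "increasing" iff the primary strictly exceeds every
  earlier value and the earlier values are non-decreasing in listed order —
  the definition that admits flat precursor plateaus (2,2→9; 6,8,8→13)
  while excluding interior decreases.

## ddPCR quantification

With k of n droplets positive for a channel, occupancy is
λ = −ln(1 − k/n) copies per droplet and concentration λ/v × 1000 copies/µl
for droplet volume v in nanoliters (default 1 nl, the nominal droplet size;
instrument-specific calibrations such as 0.85 nl can be passed in). The 95%
CI uses the delta method on the binomial proportion, SE(λ) = √(k/(n(n−k))),
floored at zero — an approximation to vendor software's unpublished exact
method; at k = n the estimate is undefined and raised as a saturation error.
Mutant fractional abundance is λ_m/(λ_m + λ_w) with both channel variances
propagated; it is invariant to droplet volume and to common scaling.

Detection of mutant DNA requires ≥ 3 mutant-positive droplets (no published
criterion exists; 3 is a conventional false-positive guard and is
configurable). The limit of detection of a dilution series is the smallest
tested fraction detected in ≥ 95% of simulated replicates.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: 4 zones
per lesion by default (3 for AIS-like runs), 3 truncal + 4 shared-branch +
5 private mutations on a two-sided clone tree, tumor purity 0.6 per zone
(microdissection guarantees > 60% neoplastic cells but per-lesion truth is
unknown, so the bound is used as the default), 400× mean depth (Poisson per
locus), per-base error 0.1%, and ddPCR wells of 20,000 droplets × 1 nl with
10,000 template copies (≈ 35 ng input at 3.3 pg per haploid genome is
~10,600 genome equivalents; 10,000 is the round default). True fluid
fractional abundances are drawn log-uniform in [0.03%, 1%], the observed
range for early-lesion circulating DNA.

Modeling choices: mutations are heterozygous single-copy (expected allele
fraction = purity × cellular fraction × 0.5), consistent with observed
abundances ≤ 35%; distinct pairs are simulated directly (deduplication is
treated as already done); normal contamination enters only through purity;
germline heterozygous sites are off by default and switchable for targeted
tests of the normal-contamination rule. Per-zone clone mixing weights are
drawn in [0.25, 0.5] and normalized, so every mutation's cellular fraction
is ≥ 0.2 — the regime in which the containment rule is informative. All
draws come from named sub-streams of one master seed (SHA-256 of the
(purpose, zone, locus) key), so outputs are byte-identical across runs and
adding zones or loci never perturbs existing draws.

What the generator does **not** model: read-level alignment and mapping
error, duplicate structure, indel realignment, GC and capture bias,
subclonal copy number, contamination between zones, and droplet "rain" or
amplitude thresholding. Passing tests therefore demonstrate correctness of
the statistical chain under its stated assumptions, not robustness to those
real-data artifacts.

## Problem sizes and numerics

Default test problem sizes: 10 simulated cohorts per recovery property,
1,000 SNVs for caller sensitivity, 200 replicates per dilution fraction,
4,096-case exhaustive ancestry oracle, 10,000 loci for the binomial-mean
check. Reported percentages use half-up rounding (one decimal for
abundances and rates, integers for heterogeneity). Degenerate inputs raise
`ValueError` with the offending field named: zero-total fractional
abundance, all-zero coverage profiles, zero-mutation heterogeneity,
saturated ddPCR channels, and mismatched tumor/normal loci are all errors,
not silent NaNs.

## Known limitations

* The consequence classifier is a minimal single-transcript model (no UTRs,
  no canonical-transcript choice, no stop-loss/start-loss classes).
* Ancestry inference is combinatorial, not likelihood-based: it ignores
  allele fractions and cannot express mutation loss or recurrent mutation.
* The CNA caller is gene-level only; small panels attenuate single-gene
  events under mean normalization (see above).
* The ddPCR CI is a large-n approximation and degenerates at k = 0
  (zero-width interval) and near saturation.
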
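# Methods

This note records the models, parameter choices and numerical conventions
behind each analysis stage, what the synthetic-data generator does and does
not emulate, and the design decisions taken where more than one reasonable
convention exists.

## Coordinates and formats

All on-disk formats (VCF, segment/annotation TSVs, the cohort tables) use
1-based inclusive coordinates, matching VCF convention.  Interval algebra
inside the package is 0-based half-open; conversions happen at the module
boundaries.  One visible consequence: with 1 Mb windows, a variant at
position 1,000,000 falls in the first window and 1,000,001 opens the second.

## Record-level filters

Variants require ≥ 10 reads at the site (inclusive), are removed when their
known population frequency is strictly above 0.05, and are removed on an
exact (chrom, pos, ref, alt) match against an artefact blacklist built from
unrelated constitutional genomes.  Missing annotations never cause removal:
a record without a population frequency is kept, because absence of evidence
is not evidence of commonness.  All filters are pure, order-preserving and
idempotent, so their composition order is immaterial for independent
predicates — asserted by property tests.  Breakpoint predictions are kept at
score ≥ 99 (confidence scores cap at 99, so "score of 99" is read as a
minimum) with ≥ 10 supporting read pairs and, optionally, at least one
anchor inside a catalogued gene.

## Mutation spectrum

Substitutions are strand-collapsed to the six pyrimidine-reference classes.
Spectrum comparison against a reference proportion vector uses a χ²
goodness-of-fit on the observed counts (expected = total × reference),
merging any expected cell below 5 into its nearest neighbouring class
(df = remaining cells − 1), plus cosine similarity of the proportion vectors
as a scale-free descriptive measure.  The 6-class representation is
deliberate; trinucleotide-context (96-class) signatures are out of scope.
Region-subset spectra use pooled counts over the cohort, not per-sample
means.

## Driver prioritization

The cascade keeps every protein-truncating (stop-gain, stop-loss,
frameshift) and splice-site mutation, and excludes a missense mutation only
when both predictors agree it is benign: SIFT > 0.2 **and** PolyPhen2 < 0.8
(SIFT is benign-high, PolyPhen2 benign-low).  A missense record missing
either score cannot satisfy the conjunction and is retained — exclusion
requires both conditions demonstrably true.  Synonymous/UTR/intergenic
consequences never enter the cascade.  Manual read review is represented by
a per-variant quality flag honoured before the cascade; human inspection
itself is not implementable.  The recurrence filter then removes genes with
filtered mutations in fewer than 2 distinct samples; an explicit
known-driver whitelist (empty by default) can bypass it, since established
drivers are meaningful even as singletons.

## Hotspot scan

Non-overlapping 1 Mb tiling windows (the trailing window of each chromosome
may be shorter).  Combined SNV+indel counts are tested one-sided against
Poisson(genome-wide per-bp rate × window length) — the minimal defensible
null for count data in fixed windows — with Benjamini–Hochberg control
across windows at q ≤ 0.05.  Kataegis is not modelled separately (no
inter-mutation-distance changepoint); dense clusters surface as hotspot
windows.  Flagged windows are annotated with two artefact explanations:
length-weighted mean total copy number > 2.5 over the window, and overlap
(≥ 1 bp) with a 2 Mb band around centromeres or telomeres.  Null calibration
is checked by simulation: on uniform-null genomes the per-genome family-wise
flag rate stays at or below α (the discrete Poisson p-values make BH
conservative).

## Copy-number analysis

"Altered" means total CN ≠ 2 **or** LOH, so copy-neutral LOH counts toward
the percent-genome-altered burden; the CNV count is the number of discrete
altered segments.  Chromothripsis is operationalized as ≥ 10 transitions of
the joint (total CN, LOH) state between adjacent segments on a single arm —
equivalently, distinct joint-state runs − 1 — with centromere-straddling
segments split at the centromere rather than discarded, so each arm is
scored on exactly its own territory.  Cohort-recurrent regions come from a
breakpoint boundary sweep: within each elementary interval the per-sample
event state is constant, so per-interval sample counts equal per-base counts
(asserted against a per-base oracle), and adjacent qualifying intervals
merge into maximal regions.  Amplicon profiling grows the maximal contiguous
run of segments with total CN ≥ 3 around the anchor gene (3 being the
smallest amplified state), collects tumour BAF/VAF of germline hets and
somatic variants in the region, and summarizes allelic asymmetry as
mean |BAF − ½| over hets: 0 for a balanced region, major/CN − ½ under pure
one-allele amplification (e.g. 0.375 at 7:1 in CN 8).  Mutation excess in
the region is reported both against the raw background density and against
a copy-number-adjusted expectation (background × mean CN / 2), so an excess
beyond the extra template copies is visible.

## Clonal structure

Cellular prevalence of a variant with VAF *f* at a locus of total copy
number *C*, in a sample of purity *ρ*, with the mutation on *m* copies:

    φ = f · (ρC + 2(1 − ρ)) / (ρ m)

Multiplicity defaults to 1 (the conservative choice when allele-specific
placement is unknown) and is configurable per variant.  Estimates outside
[0, 1] are clamped and logged; CN-0 loci are excluded with a log entry.
Variant selection for clustering follows the candidate-drivers + 50 random
genome-wide SNVs design, drawn without replacement and deterministic given
the seed.

Clustering is a Dirichlet-process binomial mixture: cluster parameter φ has
a uniform base measure on [0, 1]; observation *i* contributes
Binomial(depth, φ·c_i) with c_i = ρm/(ρC_i + 2(1−ρ)).  Inference is Gibbs
sampling with three auxiliary components per assignment step (Neal's
algorithm 8), cluster-φ resampling on a 101-point grid (the binomial
coefficient cancels, so only the likelihood shape matters), and a
Gamma(1, 1) prior on the concentration resampled by the Escobar–West
auxiliary-variable move.  Defaults: 5,000 sweeps, 1,000 burn-in, every 10th
post-burn-in partition kept; a seed is mandatory.  The reported clustering
is the kept sample minimizing Binder loss against the pairwise
co-clustering matrix; cluster prevalences are posterior means on the grid
given that partition; the cluster-count trace is exposed as a convergence
diagnostic, never silently swallowed.  A deterministic fallback bins
point-estimate prevalences at width 0.1 and merges adjacent occupied bins —
useful where a non-stochastic path is needed.  The DNA-index sensitivity
analysis rescales every locus CN by candidate/reference, re-clusters, and
reports whether cluster counts agree within ±1; candidates implying
near-zero effective purity are flagged unreliable.

At well-separated prevalences (e.g. 1.0 vs 0.2 at depth 100) the sampler
recovers the partition essentially exactly (ARI ≥ 0.9 across seeds), though
an occasional seed reports a singleton outlier as a third cluster — the
Binder-loss point estimate inherits the DP's small-cluster posterior mass.

## Burden associations

Spearman uses midranks with the t-approximation p-value and pairwise-complete
cases; a constant vector is an explicit error, not NaN.  The two-group test
is the Wilcoxon rank-sum under the normal approximation with tie-corrected
variance and **no continuity correction** — fixed as the default because it
is the unique standard variant consistent with both the no-ties and the
tied cohort-table stage comparisons; an exact-test flag exists.
Kruskal–Wallis is tie-corrected with a χ² (k − 1 df) p-value; for two groups
H equals the square of the tie-corrected rank-sum z (asserted as an
identity test).  pT1 and pT2+ are pooled against pTa for stage tests, since
no burden measure separates pT1 from pT2 at this cohort size.  No
multiple-testing correction is applied by default (raw p-values are
reported); a BH option exists on the hotspot scan where the test count is
large.  The sub-clone counts in the cohort table are treated as fixture
inputs for the association tests — the settings behind the published counts
are not recoverable, so they are not recomputation targets.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
reads or calling.  Defaults describe the study design the package targets:

| parameter | default | rationale |
|---|---|---|
| genome | 22 autosomes at 1/20 GRCh37 scale | analyses are rate-based, scale-free; desk-sized runtimes; full scale via `scale=1.0` |
| group sizes | 4 pTa + 5 pT1 + 5 pT2 | the discovery-cohort design |
| mean SNVs/group | 1,750 / 5,700 / 5,900 | cohort-table burden scale × 1/20, monotone in stage |
| indel ratio | 0.22 | indel:SNV count ratio at the cohort's median scale; indel count is deterministic in the SNV draw (the correlation's coefficient is unreported) |
| spectrum | C:G>T:A 0.33, T:A>C:G 0.20, C:G>G:C 0.17, C:G>A:T 0.12, T:A>A:T 0.10, T:A>G:C 0.08 | observed genome-wide class ordering with C:G>T:A at 33% |
| depth | Poisson(80), normals Poisson(30) | ~80× tumour design coverage |
| purity | 0.8 | mid-range of the 70–90% histology estimates |
| subclones | pTa (1.0); pT1 (1.0, 0.45); pT2 (1.0, 0.5, 0.2) | clonal diversity increasing with stage |
| CNA event rates | gain 4, loss 4, LOH 2, homdel 0.7 per genome; ×3 when invasive | reproduces the qualitative CNV%-by-stage gradient |
| amplicon | anchor MDM2, CN ladder (3, 8, 3), minor CN 1 | internally heterogeneous amplicon, 3–8 range, one destabilized allele |
| chromothripsis | 12 transitions on 3p and 5q of one invasive sample | above the ≥ 10 calling threshold |
| germline hets | 3 × 10⁻⁵ per bp | enough sites for BAF profiling without bulk |

Read counts are Binomial(depth, expected VAF) with the expected VAF from
the prevalence formula above; variants landing in homozygously-deleted
segments are unobservable and dropped.  Every emitted variant carries its
true subclone, multiplicity and expected VAF in a truth table.  A fixed
seed yields byte-identical output (asserted).

Not emulated: sequencing error, mapping artefacts, germline variation
beyond het seeding, trinucleotide context, kataegis as a distinct process,
and subclonal copy number.  Passing recovery tests on this generator
therefore demonstrates correctness of the estimators under their stated
model, not robustness to real-data artefacts such as mapping noise near
centromeres — which is precisely why the hotspot scan carries explanation
flags rather than claims of biological hotspots.

## Problem sizes used in tests

Fixture statistics run on the 15-tumour cohort tables.  Simulation-based
checks use: 10,000 SNVs for spectrum recovery; 20 seeds for burden
monotonicity; 200 uniform-null genomes × 100 windows (λ = 5) for hotspot
calibration; 1,000 random segmentations for transition counting; 100
observations at depth 100 (and 400 at depth 1,000) for clonal recovery, with
the full 5,000-sweep sampler.  These sizes were chosen so the entire suite
runs in about a minute while keeping Monte-Carlo standard errors well inside
the asserted tolerances.

## Known limitations

* The DP mixture is a simplification of full genotype-aware subclonal
  reconstruction: multiplicity is fixed per variant rather than marginalized
  over genotype states, and there is no Beta-Binomial overdispersion.
* Recurrent-region counts are per-interval sample counts; no significance
  model (e.g. against a background rearrangement rate) is attached.
* The hotspot scan's Poisson null ignores covariates (replication timing,
  GC content); its flags are descriptive screens, not causal claims.
* Platypus-style posterior/genotype-likelihood call filters operate on raw
  calls upstream of this package and are documented but not implemented.
* VCF support covers single-sample files with DP/AD and multi-allelic
  splitting; phasing and symbolic structural-variant alleles are out of
  scope.
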
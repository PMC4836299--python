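# Methods

This note documents the model behind `orthocombine`, the conventions and
numerical choices it commits to, what the synthetic generator does and does
not emulate, and the known limitations.

## The confirmation model

Two whole-exome assays of the same sample are treated as statistically
independent observations because they share neither selection chemistry
(bait hybridization vs multiplex PCR) nor sequencing chemistry (reversible
terminators vs semiconductor pH sensing).  Under independence, the
probability that both platforms report the *same wrong* genotype at the
same locus is roughly the product of two small error rates, so cross-platform
concordance is strong evidence of correctness — the positive predictive
value of concordant calls approaches 1 even when each platform alone sits
near 99.5%.

Role A is the capture/reversible-terminator platform, role B the
amplicon/semiconductor platform.  The roles are deliberately asymmetric:

* Role-A calls carry DP and GQ and are pass-filtered here (PASS iff
  DP > `min_dp` and GQ > `min_gq`, both **strict** bounds, defaults 8
  and 20 — DP = 8 fails).  Calls failing the filter are retained as NoPass
  rather than dropped, because a NoPass call confirmed by platform B is
  still informative (the Reliable category).
* Role-B calls arrive pre-filtered by their upstream caller; any non-PASS,
  non-missing FILTER string is treated alike as `CALLER_FILTERED`, and a
  caller-filtered call is never upgraded by the DP/GQ filter.

Classification of each site follows the decision table in the README.  The
asymmetric treatment of singletons reflects the platforms' error structure:
a passing capture-only singleton is usually real, whereas an amplicon-only
call at a locus the capture platform covered but did not call is usually an
artifact.  "Covered" defaults to depth ≥ 8, mirroring the DP > 8
callability bound; it has no canonical value and is configurable.  A
conflicting call (same locus, different allele or zygosity) counts as
coverage: the other platform *looked* and saw something else, so both sides
of a conflict are classified under singleton rules with the other platform
covered — allele-discordant pairs therefore produce one Likely TP/FP from
each side rather than a bogus concordance.

## Variant representation

All comparisons run on canonical variants: alleles uppercased and trimmed,
indels left-aligned with one retained anchor base (the usual VCF
convention), multi-allelic records split per alt before normalization
(zygosity of a split allele is HET unless the genotype is homozygous for
that allele).  Left-alignment uses the standard iterate-truncate-extend
algorithm and is idempotent; the shift is capped at a 200 bp window and
shifting past the window or the contig start raises rather than silently
stopping.  Without a reference the result is trim-only and flagged as such.
The test suite checks the implementation against an exhaustive
minimal-leftmost enumeration and against `bcftools norm`.

MNVs are decomposed into component SNVs on **both** sides before matching
(default `mnv_mode="atomic"`): callers disagree on whether to emit a
multi-base substitution whole or per-base, and representation mismatches at
MNVs are a documented source of spurious discordance.  A `whole` mode
preserves MNVs for callers known to agree.  Indels are never decomposed.
Structural variants, breakends, symbolic alleles and spanning deletions are
out of scope and skipped on read.

Coordinates are 1-based internally (VCF convention); BED inputs/outputs are
0-based half-open and converted only at the I/O boundary.  Contig-name
mismatches between inputs ("chr1" vs "1") are a hard error unless an alias
map is supplied — never a silent zero overlap.

## Benchmarking conventions

The analysis region is always `regions ∩ confident_regions`; truth sets are
read through the same VCF path as call sets so both sides are normalized
identically.  Matching is representation-based (no vcfeval-style haplotype
replay).  In the default strict genotype mode a zygosity mismatch at a
truth site counts as FP + FN — the convention under which a het site
miscalled hom-alt is a false positive; `gt_mode="allele"` relaxes this.
TP + FN is then invariant to the call set (checked by property test).

TN is defined as analysis-region bases minus distinct event positions, and
is shared across the SNV/indel strata (an event-free base is
reference-concordant for both variant types); TP/FP/FN are additive across
strata, TN deliberately is not.  FP/Mb uses the analysis-region size in
megabases as its denominator.  Undefined ratios (0/0) are reported as
absent, never as 0 or 100.  Reported percentages carry two decimals, except
per-class PPV which carries three when ≥ 99.99% so that values like
99.998% survive rounding.

One caveat surfaced while validating the arithmetic against published
per-platform tables of this design: printed *indel* sensitivities in such
tables are not always reproducible as TP/(TP+FN) from their own printed
counts (the SNV rows are).  The tool always reports the formulaic value
and makes no attempt to replicate unknown upstream accounting.

## Coverage analysis

Per-exon mean depth is the per-base average over the exon interval as
given; if splice-flank padding is wanted, `pad_exons` (default 10 bp) must
be applied explicitly — the analysis never pads implicitly.  Normalization
is one global scalar per platform, `target_mean / exome-wide mean`, where
the exome-wide mean is the exon-base-weighted average; after normalization
the weighted mean equals the 100× target to ~1e-15 relative error (1e-9
asserted).  The quadrant test (default 20×) uses normalized depths,
consistent with comparing platforms of different raw yield on one scale.
Zeros stay zero for all threshold logic; the floor of 1× exists only in the
`plot_a`/`plot_b` export columns for log-scale scatter plots.  GC fraction
is (G+C)/(A+C+G+T) with ambiguous bases excluded; GC bins are 0.05 wide,
right-open except the last, so GC = 1.0 lands in the final bin.

## Replicate concordance

Cross-run matching keys on the canonical variant and **ignores zygosity**:
a zygosity flip between runs is a category change of one variant, not a
disappearance plus a new variant.  This keeps row sums equal to run-1
category counts.  The (not-called, not-called) cell is structurally zero.
No statistical test is attached to the table.

## Synthetic generator

The generator emulates, at the call/coverage level (no reads, no
alignment):

* toy contigs whose exons have exactly realized GC fractions (G+C count
  fixed per exon, positions shuffled);
* truth variants placed uniformly in exons with ≥ 10 bp spacing, 1–3 bp
  indels, configurable het fraction (default 0.6);
* per-platform emission with class-specific sensitivity, zygosity flips at
  a configurable rate, Poisson false positives at `fp_per_mb` over exon
  bases (alleles uniform over the three non-reference bases; FP indels are
  1 bp), and DP/GQ filled from the local simulated depth with sub-threshold
  NoPass injections for role A;
* per-exon depth as a negative-binomial draw (dispersion configurable,
  default size 8) around `mean_depth` times a GC factor linear in
  |gc − 0.5| on the penalized side — the minimal shape that reproduces
  "best coverage at mid-GC, role A degrading toward AT-rich exons and role
  B toward GC-rich ones".

Default profiles mirror the measured behaviour of the two platform roles:
role A — SNV sensitivity 0.996, indel 0.95, 1.85 FP/Mb, zygosity-error
2×10⁻³, 125× mean depth, AT-side dropout 0.5, NoPass rate 3×10⁻³; role B —
0.969 / 0.51, 2.66 FP/Mb, 2×10⁻³, 133×, GC-side dropout 0.5.  The
"exome-like" bundle scales the exome down to 3 Mb of exon bases (5 contigs
× 3000 exons × 200 bp) with 1,530 SNVs + 170 indels, sized so binomial
standard errors on recovered sensitivities are a few tenths of a percent
while the full pipeline runs in seconds.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: errors here are independent across sites and
platforms (no shared systematic artifacts, which are exactly what
orthogonal confirmation cannot catch), emission is independent of the
drawn depth, there are no mapping artifacts, no true MNVs in truth sets,
no multi-allelic truth sites, and no population structure in allele
choice.  Closed-form expectations such as
p(OC) = s_A·s_B·(1−z_A)(1−z_B) for shared sites hold exactly by
construction and are used as calibration checks, not as claims about real
platforms.

Determinism: every stochastic step draws from a `numpy` Generator seeded
via `SeedSequence` spawning; iteration orders are explicit and sorted, so a
bundle is byte-identical across runs for a fixed config + seed.

## Design choices where the design was open

* Whether concordance should compare MNVs whole or atomically is not
  canonically settled; atomic is the default (robust to caller spelling
  differences), whole is an option.
* Site-level coverage (depth at the variant's leftmost position) decides
  "covered", not allele-level support.
* The covered-depth default (8) reuses the callability bound; nothing in
  the confirmation logic forces this identification.
* Pass/NoPass filtering applies to role A only; role B is taken as
  pre-filtered.  Swapping roles is just swapping inputs.
* Category names are role-based ("A"/"B"), not vendor-based, so any two
  orthogonal platforms can be substituted.
* The replicate cross-tab takes the region restriction as an explicit
  argument rather than defaulting to anything.

## Limitations

* Representation-based truth matching undercounts TPs where only a
  haplotype-level comparison would reconcile representations (complex
  indel clusters); a vcfeval-style matcher is deliberately out of scope.
* Two platforms only; no three-way integration, no somatic/low-VAF logic,
  no phasing.
* Depth is consumed pre-computed (BED runs or per-base text); BAM/CRAM
  parsing is out of scope.
* The per-exon analysis assumes the supplied BED defines the exons of
  interest; overlapping exon records are averaged independently, not
  deduplicated.
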
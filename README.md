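# orthocombine

Orthogonal dual-platform NGS variant confirmation.

Clinical exome sequencing requires every reported variant to be confirmed,
traditionally by Sanger sequencing — slow and unscalable.  An alternative is
to sequence the same sample twice with *independent* selection and
sequencing chemistries (hybrid-capture + reversible-terminator sequencing,
and amplicon + semiconductor sequencing): a variant called identically by
both platforms is confirmed at genomic scale, and each platform covers
exons the other misses.  `orthocombine` implements the informatics side of
that strategy for laboratory and pipeline developers:

* **Canonical variant model** — trimming, reference left-alignment,
  multi-allelic splitting and multi-nucleotide-variant (MNV) decomposition,
  so differently-spelled but equivalent calls compare equal.
* **Combinator** — matches the two call sets (allele + zygosity) and
  classifies every call into a confidence category:

  | Category | Rule (A = capture role, B = amplicon role) | Typical use |
  |---|---|---|
  | Orthogonally Confirmed | A Pass call matches B call | report without follow-up |
  | Reliable | A NoPass/filtered call matches B call | inspect, then report |
  | Likely TP | singleton A Pass call, or singleton B call with no A coverage | confirm before reporting |
  | Likely FP | singleton A NoPass call, or singleton B call where A was covered | usually artifact |

  A role-A call *passes* iff DP > 8 and GQ > 20 (both strict); a site
  counts as *covered* at depth ≥ 8.  All four thresholds are configurable.
* **Truth-set benchmarking** — genotype-aware TP/FP/FN/TN against a
  GIAB-style truth set over intersected confident regions, reporting
  sensitivity = 100·TP/(TP+FN), PPV = 100·TP/(TP+FP) and FP/Mb, per
  SNV/indel stratum and per confidence category, with optional restriction
  to a variant subset (e.g. population-rare variants).
* **Coverage complementarity** — per-exon mean depths normalized to a
  common 100× exome mean, 20× quadrant analysis, and GC-binned counts of
  poorly covered exons.
* **Replicate concordance** — 5×5 cross-tabulation of categories between
  two runs of the same individual, with per-category repeat rates.
* **Synthetic fixtures** — toy genomes, truth sets, paired platform call
  sets and GC-biased coverage tracks with configurable sensitivity /
  FP-rate / zygosity-error profiles, so the whole pipeline is testable
  without any downloads.

## Worked example

Generate the hand-checkable 12-site bundle, combine, and benchmark:

```bash
orthocombine simulate --bundle tiny --seed 0 --out bundle
orthocombine combine \
    --vcf-a bundle/platform_a.vcf --vcf-b bundle/platform_b.vcf \
    --cov-a bundle/coverage_a.bed --cov-b bundle/coverage_b.bed \
    --regions bundle/exons.bed --fasta bundle/reference.fa \
    --out combined.vcf --summary summary.tsv
```

prints the per-category counts

```
orthogonally_confirmed  5
reliable                2
likely_tp               3
likely_fp               2
```

— five concordant Pass calls, two concordant calls where the capture-role
call failed DP/GQ or carried an upstream filter, three credible singletons
(two passing capture-only calls and one amplicon-only call at a locus the
capture platform did not cover), and two suspect singletons.  Benchmarking
the combined VCF against the bundled truth set,

```bash
orthocombine benchmark --calls combined.vcf \
    --truth-vcf bundle/truth.vcf --truth-bed bundle/truth_regions.bed \
    --regions bundle/exons.bed --per-category --out metrics.tsv
```

```
stratum  tp  fp  fn   tn sensitivity_pct fp_per_mb ppv_pct
    SNV   8   2   0 2988         100.000    666.67   80.00
  INDEL   2   0   0 2988         100.000      0.00 100.000
    ALL  10   2   0 2988         100.000    666.67   83.33
              category  n share_pct  fp  tp ppv_pct
orthogonally_confirmed  5     41.67   0   5 100.000
              reliable  2     16.67   0   2 100.000
             likely_tp  3     25.00   0   3 100.000
             likely_fp  2     16.67   2   0    0.00
```

all ten real variants are recovered and the only false calls are exactly
the two Likely FP sites the bundle plants (the large FP/Mb is an artifact
of the 3 kb toy region).  The same machinery scales to whole-exome inputs;
`orthocombine coverage` and `orthocombine crosstab` cover the per-exon
quadrant/GC analysis and replicate reproducibility tables.

The library mirrors the CLI one-to-one
(`orthocombine.combine_calls`, `compare_to_truth`, `ppv_by_category`,
`quadrant_counts`, `crosstab_categories`, ...); see `docs/methods.md` for
the underlying model, conventions and numerical choices.

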
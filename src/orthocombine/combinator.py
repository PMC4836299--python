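"""Cross-platform call matching and confidence classification.

The central idea of orthogonal NGS confirmation: the same exome is selected
and sequenced twice with independent chemistries (hybrid capture +
reversible terminators = role A; amplicon + semiconductor = role B).  A
variant called identically by both is confirmed without Sanger follow-up;
everything else is triaged by which platform called it, whether role A's
call passed its depth/quality filter, and whether the silent platform even
had the coverage to call it.

Categories (A-pass refers to DP/GQ filtering of role-A calls only; role B
arrives pre-filtered by its caller):

==========================  ==================================================
ORTHOGONALLY_CONFIRMED      A PASS call matches a B call (allele + zygosity)
RELIABLE                    A NoPass/caller-filtered call matches a B call
LIKELY_TP                   singleton A PASS call, or singleton B call where
                            A had no coverage
LIKELY_FP                   singleton A NoPass call, or singleton B call
                            where A was covered (or made a conflicting call)
==========================  ==================================================
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pysam

from .platform_io import (
    CoverageTrack,
    IntervalSet,
    check_contig_compatibility,
    read_callset,
    read_coverage,
)
from .variant_model import (
    CanonicalVariant,
    PassStatus,
    PlatformCall,
    Zygosity,
    decompose_call,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PassThresholds",
    "CoveredPredicate",
    "Category",
    "MatchedSite",
    "ClassifiedCall",
    "CombinedCallSet",
    "apply_pass_filter",
    "match_callsets",
    "classify_site",
    "combine_calls",
    "combine",
    "write_combined_vcf",
]


@dataclass(frozen=True)
class PassThresholds:
    """Strict lower bounds on depth and genotype quality: a role-A call
    passes iff DP > min_dp AND GQ > min_gq (so DP=8 or GQ=20 fail the
    defaults)."""

    min_dp: int = 8
    min_gq: int = 20


@dataclass(frozen=True)
class CoveredPredicate:
    """A site counts as covered on a platform iff depth >= min_covered_depth.
    The default mirrors the DP>8 callability bound."""

    min_covered_depth: int = 8

    def covered(self, track: Optional[CoverageTrack], chrom: str, pos1: int) -> bool:
        if track is None:
            return False
        return track.depth_at(chrom, pos1) >= self.min_covered_depth


class Category(str, enum.Enum):
    ORTHOGONALLY_CONFIRMED = "orthogonally_confirmed"
    RELIABLE = "reliable"
    LIKELY_TP = "likely_tp"
    LIKELY_FP = "likely_fp"


class Provenance(str, enum.Enum):
    A_ONLY = "A_only"
    B_ONLY = "B_only"
    BOTH = "both"


@dataclass(frozen=True)
class MatchedSite:
    """Paired per-platform evidence at one canonical variant key.

    ``conflict_a`` / ``conflict_b`` mark a singleton whose locus carries a
    different (allele- or zygosity-discordant) call on the other platform.
    """

    variant: CanonicalVariant
    call_a: Optional[PlatformCall] = None
    call_b: Optional[PlatformCall] = None
    conflict_a: bool = False
    conflict_b: bool = False

    def __post_init__(self) -> None:
        if self.call_a is None and self.call_b is None:
            raise ValueError("a MatchedSite needs at least one call")


@dataclass(frozen=True)
class ClassifiedCall:
    variant: CanonicalVariant
    call_a: Optional[PlatformCall]
    call_b: Optional[PlatformCall]
    covered_a: bool
    covered_b: bool
    category: Category
    provenance: Provenance

    @property
    def zygosity(self) -> Zygosity:
        """Representative zygosity (role A's where both called)."""
        call = self.call_a if self.call_a is not None else self.call_b
        return call.zygosity


@dataclass
class CombinedCallSet:
    calls: list[ClassifiedCall]
    config: dict = field(default_factory=dict)

    def category_counts(self) -> dict[Category, int]:
        counts = Counter(c.category for c in self.calls)
        return {cat: counts.get(cat, 0) for cat in Category}

    def summary_frame(self):
        import pandas as pd

        counts = self.category_counts()
        total = sum(counts.values())
        rows = [
            {
                "category": cat.value,
                "count": n,
                "share_pct": round(100.0 * n / total, 2) if total else None,
            }
            for cat, n in counts.items()
        ]
        return pd.DataFrame(rows)

    def restricted_to(self, regions: IntervalSet) -> "CombinedCallSet":
        keep = [c for c in self.calls if regions.contains(c.variant.chrom, c.variant.pos)]
        return CombinedCallSet(keep, dict(self.config))


def apply_pass_filter(call: PlatformCall, thresholds: PassThresholds = PassThresholds()) -> PlatformCall:
    """Resolve a role-A call's pass status against the DP/GQ thresholds.

    CALLER_FILTERED is sticky — an upstream-filtered call is never upgraded.
    Missing DP or GQ yields NOPASS (with a logged reason), not an exception.
    """
    if call.pass_status is PassStatus.CALLER_FILTERED:
        return call
    if call.dp is None or call.gq is None:
        logger.debug("call %s missing DP/GQ -> NoPass", call.variant)
        return replace(call, pass_status=PassStatus.NOPASS)
    status = (
        PassStatus.PASS
        if call.dp > thresholds.min_dp and call.gq > thresholds.min_gq
        else PassStatus.NOPASS
    )
    return replace(call, pass_status=status)


def _dedup(calls: Sequence[PlatformCall]) -> list[PlatformCall]:
    seen: set[tuple] = set()
    out = []
    dups = 0
    for c in calls:
        if c.key in seen:
            dups += 1
            continue
        seen.add(c.key)
        out.append(c)
    if dups:
        logger.warning("deduplicated %d identical calls within platform %s", dups, calls[0].platform_id)
    return out


def match_callsets(
    calls_a: Sequence[PlatformCall], calls_b: Sequence[PlatformCall]
) -> list[MatchedSite]:
    """Pair calls across platforms on (canonical variant, zygosity).

    Every input call lands in exactly one site.  Unpaired calls whose locus
    carries a discordant call on the other platform are flagged as
    conflicting singletons.  Inputs are expected canonical (and atomically
    decomposed under the default MNV strategy).
    """
    calls_a = _dedup(list(calls_a))
    calls_b = _dedup(list(calls_b))
    by_key_a = {c.key: c for c in calls_a}
    by_key_b = {c.key: c for c in calls_b}
    loci_a = {c.variant.locus for c in calls_a}
    loci_b = {c.variant.locus for c in calls_b}

    sites: list[MatchedSite] = []
    for c in calls_a:
        mate = by_key_b.get(c.key)
        if mate is not None:
            sites.append(MatchedSite(c.variant, call_a=c, call_b=mate))
        else:
            sites.append(
                MatchedSite(c.variant, call_a=c, conflict_b=c.variant.locus in loci_b)
            )
    matched_keys = set(by_key_a) & set(by_key_b)
    for c in calls_b:
        if c.key in matched_keys:
            continue
        sites.append(
            MatchedSite(c.variant, call_b=c, conflict_a=c.variant.locus in loci_a)
        )
    return sites


def classify_site(
    site: MatchedSite,
    cov_a: Optional[CoverageTrack],
    cov_b: Optional[CoverageTrack],
    predicate: CoveredPredicate = CoveredPredicate(),
    thresholds: PassThresholds = PassThresholds(),
) -> ClassifiedCall:
    """Assign the confidence category for one matched site.

    Role-A calls must already carry a resolved pass status (see
    :func:`apply_pass_filter`); a conflicting call on the other platform
    counts as that platform being covered.
    """
    chrom, pos = site.variant.chrom, site.variant.pos
    covered_a = site.conflict_a or predicate.covered(cov_a, chrom, pos)
    covered_b = site.conflict_b or predicate.covered(cov_b, chrom, pos)

    a, b = site.call_a, site.call_b
    if a is not None and a.pass_status is None:
        a = apply_pass_filter(a, thresholds)
    if b is not None and b.pass_status is None:
        b = replace(b, pass_status=PassStatus.PASS)

    if a is not None and b is not None:
        category = (
            Category.ORTHOGONALLY_CONFIRMED
            if a.pass_status is PassStatus.PASS
            else Category.RELIABLE
        )
        provenance = Provenance.BOTH
    elif a is not None:
        category = Category.LIKELY_TP if a.pass_status is PassStatus.PASS else Category.LIKELY_FP
        provenance = Provenance.A_ONLY
    else:
        category = Category.LIKELY_FP if covered_a else Category.LIKELY_TP
        provenance = Provenance.B_ONLY

    return ClassifiedCall(
        variant=site.variant,
        call_a=a,
        call_b=b,
        covered_a=covered_a,
        covered_b=covered_b,
        category=category,
        provenance=provenance,
    )


def combine_calls(
    calls_a: Sequence[PlatformCall],
    calls_b: Sequence[PlatformCall],
    cov_a: Optional[CoverageTrack],
    cov_b: Optional[CoverageTrack],
    regions: Optional[IntervalSet] = None,
    thresholds: PassThresholds = PassThresholds(),
    predicate: CoveredPredicate = CoveredPredicate(),
    mnv_mode: str = "atomic",
) -> CombinedCallSet:
    """Match, filter and classify two in-memory call sets.

    ``mnv_mode='atomic'`` (default) decomposes MNVs on both sides into
    component SNVs before matching, which makes an MNV on one platform
    match its per-base spelling on the other; ``'whole'`` preserves MNVs.
    """
    if mnv_mode not in ("atomic", "whole"):
        raise ValueError(f"mnv_mode must be 'atomic' or 'whole', got {mnv_mode!r}")
    if mnv_mode == "atomic":
        calls_a = [p for c in calls_a for p in decompose_call(c)]
        calls_b = [p for c in calls_b for p in decompose_call(c)]
    n_read = (len(calls_a), len(calls_b))
    if regions is not None:
        calls_a = [c for c in calls_a if regions.contains(c.variant.chrom, c.variant.pos)]
        calls_b = [c for c in calls_b if regions.contains(c.variant.chrom, c.variant.pos)]
        if not calls_a and not calls_b and any(n_read):
            logger.warning("no calls fall inside the supplied regions")
    calls_a = [apply_pass_filter(c, thresholds) for c in calls_a]
    calls_b = [
        c if c.pass_status is not None else replace(c, pass_status=PassStatus.PASS)
        for c in calls_b
    ]
    sites = match_callsets(calls_a, calls_b)
    classified = [classify_site(s, cov_a, cov_b, predicate, thresholds) for s in sites]
    classified.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt))
    logger.info(
        "combine: read %d/%d calls, %d region-filtered, %d sites classified",
        *n_read,
        len(calls_a) + len(calls_b),
        len(classified),
    )
    config = {
        "min_dp": thresholds.min_dp,
        "min_gq": thresholds.min_gq,
        "min_covered_depth": predicate.min_covered_depth,
        "mnv_mode": mnv_mode,
    }
    return CombinedCallSet(classified, config)


def combine(
    vcf_a: Union[str, Path],
    vcf_b: Union[str, Path],
    coverage_a: Union[str, Path, CoverageTrack, None],
    coverage_b: Union[str, Path, CoverageTrack, None],
    regions: Union[str, Path, IntervalSet, None] = None,
    reference=None,
    thresholds: PassThresholds = PassThresholds(),
    predicate: CoveredPredicate = CoveredPredicate(),
    mnv_mode: str = "atomic",
    alias_map: Optional[Mapping[str, str]] = None,
) -> CombinedCallSet:
    """End-to-end driver from files: read -> normalize/decompose -> region
    restrict -> match -> classify.  Deterministic for fixed inputs."""
    calls_a = read_callset(vcf_a, "A", reference=reference, alias_map=alias_map)
    calls_b = read_callset(vcf_b, "B", reference=reference, alias_map=alias_map)
    if calls_a and calls_b:
        check_contig_compatibility(
            (c.variant.chrom for c in calls_a), (c.variant.chrom for c in calls_b)
        )
    cov_a = read_coverage(coverage_a, "A", alias_map=alias_map) if isinstance(coverage_a, (str, Path)) else coverage_a
    cov_b = read_coverage(coverage_b, "B", alias_map=alias_map) if isinstance(coverage_b, (str, Path)) else coverage_b
    if isinstance(regions, (str, Path)):
        regions = IntervalSet.read_bed(regions, alias_map=alias_map)
    return combine_calls(
        calls_a, calls_b, cov_a, cov_b, regions,
        thresholds=thresholds, predicate=predicate, mnv_mode=mnv_mode,
    )


_CATEGORY_VCF = {
    Category.ORTHOGONALLY_CONFIRMED: "OC",
    Category.RELIABLE: "Reliable",
    Category.LIKELY_TP: "LikelyTP",
    Category.LIKELY_FP: "LikelyFP",
}


def write_combined_vcf(
    combined: CombinedCallSet,
    path: Union[str, Path],
    contigs: Optional[Mapping[str, int]] = None,
    sample: str = "SAMPLE",
    tool_version: str = "",
) -> None:
    """Emit the classified calls as a VCF with CATEGORY/PLATFORMS/DP_A/DP_B/
    GQ_A INFO annotations; the effective configuration is embedded in the
    header for reproducibility."""
    if contigs is None:
        contigs = {}
        for c in combined.calls:
            contigs[c.variant.chrom] = max(contigs.get(c.variant.chrom, 0), c.variant.end + 1000)
    h = pysam.VariantHeader()
    for name, length in sorted(contigs.items()):
        h.add_line(f"##contig=<ID={name},length={length}>")
    if tool_version:
        h.add_line(f"##orthocombine_version={tool_version}")
    for k, v in combined.config.items():
        h.add_line(f"##orthocombine_{k}={v}")
    h.info.add("CATEGORY", 1, "String", "Orthogonal confirmation category")
    h.info.add("PLATFORMS", 1, "String", "Which platform roles called the variant (A_only/B_only/both)")
    h.info.add("DP_A", 1, "Integer", "Role-A read depth")
    h.info.add("DP_B", 1, "Integer", "Role-B read depth")
    h.info.add("GQ_A", 1, "Integer", "Role-A genotype quality")
    h.formats.add("GT", 1, "String", "Genotype")
    h.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=h) as vf:
        for call in combined.calls:
            v = call.variant
            rec = vf.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            rec.info["CATEGORY"] = _CATEGORY_VCF[call.category]
            rec.info["PLATFORMS"] = call.provenance.value
            if call.call_a is not None and call.call_a.dp is not None:
                rec.info["DP_A"] = call.call_a.dp
            if call.call_b is not None and call.call_b.dp is not None:
                rec.info["DP_B"] = call.call_b.dp
            if call.call_a is not None and call.call_a.gq is not None:
                rec.info["GQ_A"] = call.call_a.gq
            gt = (1, 1) if call.zygosity is Zygosity.HOM_ALT else (0, 1)
            rec.samples[sample]["GT"] = gt
            vf.write(rec)


def read_combined_vcf(path: Union[str, Path]) -> CombinedCallSet:
    """Read back a combined VCF written by :func:`write_combined_vcf`."""
    rev = {v: k for k, v in _CATEGORY_VCF.items()}
    calls: list[ClassifiedCall] = []
    config: dict = {}
    with pysam.VariantFile(str(path)) as vf:
        for line in str(vf.header).splitlines():
            if line.startswith("##orthocombine_") and "=" in line:
                k, v = line[len("##orthocombine_"):].split("=", 1)
                config[k] = v
        for rec in vf:
            variant = CanonicalVariant(rec.contig, rec.pos, rec.ref, rec.alts[0])
            gt = rec.samples[0].get("GT")
            zyg = Zygosity.HOM_ALT if gt == (1, 1) else Zygosity.HET
            provenance = Provenance(rec.info["PLATFORMS"])
            dp_a = rec.info.get("DP_A")
            dp_b = rec.info.get("DP_B")
            gq_a = rec.info.get("GQ_A")
            call_a = call_b = None
            if provenance in (Provenance.A_ONLY, Provenance.BOTH):
                call_a = PlatformCall(variant, zyg, dp=dp_a, gq=gq_a, platform_id="A")
            if provenance in (Provenance.B_ONLY, Provenance.BOTH):
                call_b = PlatformCall(variant, zyg, dp=dp_b, platform_id="B")
            calls.append(
                ClassifiedCall(
                    variant=variant,
                    call_a=call_a,
                    call_b=call_b,
                    covered_a=call_a is not None,
                    covered_b=call_b is not None,
                    category=rev[rec.info["CATEGORY"]],
                    provenance=provenance,
                )
            )
    return CombinedCallSet(calls, config)
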
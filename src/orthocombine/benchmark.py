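"""Truth-set benchmarking: confusion counts, sensitivity, FP/Mb and PPV.

Comparison is representation-based: both the evaluated call set and the
truth set are normalized (and, by default, atomically decomposed) through
the same code path, then matched on exact (variant, zygosity) identity
inside the intersection of the analysis regions with the truth set's
confident regions.  A genotype mismatch at a truth site counts as one FP
and one FN under the default strict mode — the convention under which a
het site miscalled hom-alt is a false positive; an allele-only lenient
mode is available.  Haplotype-replay matching (vcfeval-style) is out of
scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .combinator import Category, ClassifiedCall, CombinedCallSet
from .platform_io import IntervalSet, TruthSet
from .variant_model import (
    CanonicalVariant,
    PlatformCall,
    VariantClass,
    Zygosity,
    decompose_mnv,
)

__all__ = [
    "Stratum",
    "ConfusionCounts",
    "MetricsRow",
    "BenchmarkResult",
    "compare_to_truth",
    "compute_metrics",
    "ppv_by_category",
    "restrict_truth",
    "union_calls",
]


class Stratum(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    ALL = "ALL"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    stratum: Stratum = Stratum.ALL

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricsRow:
    """Sensitivity and PPV in percent, FP per megabase; undefined ratios
    (0/0) are None, never 0 or 100."""

    sensitivity: Optional[float]
    fp_per_mb: float
    ppv: Optional[float]


GenotypedVariant = tuple[CanonicalVariant, Zygosity]


def _as_pairs(calls: Iterable, decompose: bool) -> set[GenotypedVariant]:
    pairs: set[GenotypedVariant] = set()
    for c in calls:
        if isinstance(c, PlatformCall):
            v, z = c.variant, c.zygosity
        elif isinstance(c, ClassifiedCall):
            v, z = c.variant, c.zygosity
        else:
            v, z = c
        if decompose and v.vclass is VariantClass.MNV:
            for part in decompose_mnv(v):
                pairs.add((part, z))
        else:
            pairs.add((v, z))
    return pairs


def _stratum_of(v: CanonicalVariant) -> Stratum:
    # MNVs (possible only in whole-MNV mode) are multi-base substitutions and
    # are counted with SNVs, not indels.
    return Stratum.INDEL if v.vclass is VariantClass.INDEL else Stratum.SNV


class BenchmarkResult(dict):
    """Mapping stratum -> ConfusionCounts, plus the region size used."""

    def __init__(self, counts: dict[Stratum, ConfusionCounts], region_bases: int):
        super().__init__(counts)
        self.region_bases = region_bases

    def metrics(self, stratum: Stratum = Stratum.ALL) -> MetricsRow:
        return compute_metrics(self[stratum], self.region_bases)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stratum in (Stratum.SNV, Stratum.INDEL, Stratum.ALL):
            c = self[stratum]
            m = compute_metrics(c, self.region_bases)
            rows.append(
                {
                    "stratum": stratum.value,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                    "sensitivity_pct": m.sensitivity,
                    "fp_per_mb": m.fp_per_mb,
                    "ppv_pct": m.ppv,
                }
            )
        return pd.DataFrame(rows)


def compare_to_truth(
    calls: Iterable,
    truth: TruthSet,
    regions: IntervalSet,
    gt_mode: str = "strict",
    decompose: bool = True,
) -> BenchmarkResult:
    """Confusion counts of a call set against a truth set.

    The analysis region is ``regions ∩ truth.confident_regions``; calls and
    truth entries outside it are ignored.  ``gt_mode='strict'`` requires
    allele + zygosity identity for a TP (mismatched zygosity → FP + FN);
    ``'allele'`` matches on the variant alone.  TN is the number of
    analysis-region bases carrying no counted event, shared across strata
    (an event-free base is reference-concordant for SNVs and indels alike).
    """
    if gt_mode not in ("strict", "allele"):
        raise ValueError(f"gt_mode must be 'strict' or 'allele', got {gt_mode!r}")
    region = regions.intersect(truth.confident_regions)
    if not region:
        raise ValueError("empty analysis region: regions do not intersect the confident regions")

    call_pairs = {
        (v, z) for v, z in _as_pairs(calls, decompose)
        if region.contains(v.chrom, v.pos)
    }
    truth_pairs = {
        (v, z) for v, z in _as_pairs(truth.calls, decompose)
        if region.contains(v.chrom, v.pos)
    }

    if gt_mode == "strict":
        tp_pairs = call_pairs & truth_pairs
        fp_pairs = call_pairs - truth_pairs
        fn_pairs = truth_pairs - call_pairs
    else:
        call_vars = {v for v, _ in call_pairs}
        truth_vars = {v for v, _ in truth_pairs}
        tp_pairs = {(v, z) for v, z in call_pairs if v in truth_vars}
        fp_pairs = {(v, z) for v, z in call_pairs if v not in truth_vars}
        fn_pairs = {(v, z) for v, z in truth_pairs if v not in call_vars}

    event_positions = {v.locus for v, _ in tp_pairs | fp_pairs | fn_pairs}
    tn = region.total_bases - len(event_positions)

    counts: dict[Stratum, ConfusionCounts] = {}
    for stratum in (Stratum.SNV, Stratum.INDEL):
        tp = sum(1 for v, _ in tp_pairs if _stratum_of(v) is stratum)
        fp = sum(1 for v, _ in fp_pairs if _stratum_of(v) is stratum)
        fn = sum(1 for v, _ in fn_pairs if _stratum_of(v) is stratum)
        counts[stratum] = ConfusionCounts(tp, fp, fn, tn, stratum)
    counts[Stratum.ALL] = ConfusionCounts(
        len(tp_pairs), len(fp_pairs), len(fn_pairs), tn, Stratum.ALL
    )
    return BenchmarkResult(counts, region.total_bases)


def compute_metrics(c: ConfusionCounts, region_bases: int) -> MetricsRow:
    """Sensitivity = 100·TP/(TP+FN); PPV = 100·TP/(TP+FP); FP/Mb uses the
    analysis-region size in megabases as denominator."""
    if region_bases <= 0:
        raise ValueError("region_bases must be positive")
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    ppv = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    fp_per_mb = c.fp / (region_bases / 1e6)
    return MetricsRow(sensitivity=sens, fp_per_mb=fp_per_mb, ppv=ppv)


def category_share_ppv(counts: dict[Category, tuple[int, int]]) -> pd.DataFrame:
    """Per-category share-of-total and PPV from (fp, tp) counts.

    This is the arithmetic backbone of the per-class confidence table: each
    category's share is its call count over the grand total, its PPV is
    tp/(tp+fp).  Shares sum to 100% up to rounding.
    """
    total = sum(fp + tp for fp, tp in counts.values())
    rows = []
    for cat in Category:
        fp, tp = counts.get(cat, (0, 0))
        n = fp + tp
        rows.append(
            {
                "category": cat.value,
                "n": n,
                "share_pct": 100.0 * n / total if total else None,
                "fp": fp,
                "tp": tp,
                "ppv_pct": 100.0 * tp / n if n else None,
            }
        )
    return pd.DataFrame(rows)


def ppv_by_category(
    combined: CombinedCallSet,
    truth: TruthSet,
    regions: IntervalSet,
    gt_mode: str = "strict",
) -> pd.DataFrame:
    """Judge each classified call against the truth set and tabulate
    per-category (share, FP, TP, PPV)."""
    region = regions.intersect(truth.confident_regions)
    if not region:
        raise ValueError("empty analysis region")
    truth_pairs = _as_pairs(truth.calls, decompose=True)
    truth_vars = {v for v, _ in truth_pairs}
    counts: dict[Category, list[int]] = {cat: [0, 0] for cat in Category}
    for call in combined.calls:
        v = call.variant
        if not region.contains(v.chrom, v.pos):
            continue
        if gt_mode == "strict":
            is_tp = (v, call.zygosity) in truth_pairs
        else:
            is_tp = v in truth_vars
        counts[call.category][1 if is_tp else 0] += 1
    return category_share_ppv({cat: (fp, tp) for cat, (fp, tp) in counts.items()})


def restrict_truth(truth: TruthSet, subset: Iterable[CanonicalVariant]) -> TruthSet:
    """Truth restricted to a variant subset (e.g. population-rare variants);
    confident regions are unchanged.  Matching is zygosity-insensitive."""
    wanted = set(subset)
    keep = frozenset((v, z) for v, z in truth.calls if v in wanted)
    return TruthSet(keep, truth.confident_regions, truth.version_label)


def union_calls(combined: CombinedCallSet) -> list[GenotypedVariant]:
    """The combined (union) call set: every classified variant once, with
    role A's zygosity where both platforms called it."""
    return [(c.variant, c.zygosity) for c in combined.calls]
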
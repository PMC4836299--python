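"""Readers/writers for the formats the tool touches and conversion to domain types.

Coordinate conventions: VCF positions are 1-based with anchor-base indels;
BED files are 0-based half-open.  Conversions happen only here at the I/O
boundary — everything internal works with 1-based variant positions and
0-based half-open intervals, explicitly named.

VCF parsing and writing go through :mod:`pysam`; interval set algebra goes
through :mod:`pyranges`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property, reduce
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pyranges as pr
import pysam

from .variant_model import (
    CanonicalVariant,
    PassStatus,
    PlatformCall,
    Zygosity,
    normalize_variant,
)

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]

__all__ = [
    "IntervalSet",
    "CoverageTrack",
    "TruthSet",
    "read_callset",
    "write_callset",
    "read_truthset",
    "intersect_regions",
    "read_coverage",
    "check_contig_compatibility",
]


# ---------------------------------------------------------------------------
# Interval sets


@dataclass(frozen=True)
class IntervalSet:
    """An ordered set of genomic intervals, 0-based half-open, merged and
    sorted at construction."""

    intervals: tuple[Interval, ...]

    @classmethod
    def from_iter(cls, intervals: Iterable[Interval]) -> "IntervalSet":
        ivs = list(intervals)
        if not ivs:
            return cls(())
        df = pd.DataFrame(ivs, columns=["Chromosome", "Start", "End"])
        if (df["Start"] < 0).any() or (df["End"] < df["Start"]).any():
            raise ValueError("malformed interval (negative start or end < start)")
        merged = pr.PyRanges(df).merge().df
        merged = merged.sort_values(["Chromosome", "Start"], kind="mergesort")
        return cls(tuple(zip(merged.Chromosome, merged.Start.astype(int), merged.End.astype(int))))

    @classmethod
    def read_bed(cls, path: Union[str, Path], alias_map: Optional[Mapping[str, str]] = None) -> "IntervalSet":
        ivs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
                chrom = parts[0]
                if alias_map:
                    chrom = alias_map.get(chrom, chrom)
                ivs.append((chrom, int(parts[1]), int(parts[2])))
        return cls.from_iter(ivs)

    def write_bed(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    @cached_property
    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, list[list[int]]] = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, [[], []])
            out[chrom][0].append(start)
            out[chrom][1].append(end)
        return {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in out.items()}

    def contains(self, chrom: str, pos1: int) -> bool:
        """Membership of a 1-based position."""
        idx = self._index.get(chrom)
        if idx is None:
            return False
        starts, ends = idx
        pos0 = pos1 - 1
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        if not self.intervals or not other.intervals:
            return IntervalSet(())
        a = pr.PyRanges(pd.DataFrame(self.intervals, columns=["Chromosome", "Start", "End"]))
        b = pr.PyRanges(pd.DataFrame(other.intervals, columns=["Chromosome", "Start", "End"]))
        out = a.set_intersect(b).df
        if out.empty:
            return IntervalSet(())
        out = out.sort_values(["Chromosome", "Start"], kind="mergesort")
        return IntervalSet(tuple(zip(out.Chromosome, out.Start.astype(int), out.End.astype(int))))

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)


def intersect_regions(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Bases present in every input set; commutative and associative."""
    if not sets:
        raise ValueError("intersect_regions needs at least one IntervalSet")
    return reduce(lambda a, b: a.intersect(b), sets)


# ---------------------------------------------------------------------------
# Coverage tracks


class CoverageTrack:
    """Read depth as constant-depth runs over 0-based half-open intervals.

    Positions absent from every run have depth 0.  Overlapping runs with
    conflicting depths are rejected; exact-duplicate runs collapse.
    """

    def __init__(self, runs: Iterable[tuple[str, int, int, int]], platform_id: Optional[str] = None):
        self.platform_id = platform_id
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, start, end, depth in runs:
            if depth < 0:
                raise ValueError(f"negative depth {depth} at {chrom}:{start}-{end}")
            if end <= start:
                continue
            per_chrom.setdefault(chrom, []).append((int(start), int(end), int(depth)))
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rs in per_chrom.items():
            merged: list[list[int]] = []
            for s, e, d in sorted(set(rs)):
                if merged and s < merged[-1][1]:
                    if d != merged[-1][2]:
                        raise ValueError(
                            f"overlapping depth runs with conflicting depths at "
                            f"{chrom}:{s} ({merged[-1][2]} vs {d})"
                        )
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e, d])
            starts, ends, depths = (np.asarray(x) for x in zip(*merged))
            self._runs[chrom] = (starts, ends, depths)

    @classmethod
    def read(
        cls,
        path: Union[str, Path],
        platform_id: Optional[str] = None,
        contig: Optional[str] = None,
        alias_map: Optional[Mapping[str, str]] = None,
    ) -> "CoverageTrack":
        """Read BED4 depth runs, 3-column per-base (contig, 1-based pos,
        depth), or 2-column per-base (pos, depth; requires ``contig``)."""
        runs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) >= 4:
                    chrom, start, end, depth = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
                elif len(parts) == 3:
                    chrom, pos1, depth = parts[0], int(parts[1]), int(parts[2])
                    start, end = pos1 - 1, pos1
                elif len(parts) == 2:
                    if contig is None:
                        raise ValueError(
                            f"{path}:{lineno}: two-column per-base depth needs an explicit contig"
                        )
                    chrom, start, end, depth = contig, int(parts[0]) - 1, int(parts[0]), int(parts[1])
                else:
                    raise ValueError(f"{path}:{lineno}: cannot parse depth line {line!r}")
                if alias_map:
                    chrom = alias_map.get(chrom, chrom)
                runs.append((chrom, start, end, depth))
        return cls(runs, platform_id=platform_id)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._runs):
                starts, ends, depths = self._runs[chrom]
                for s, e, d in zip(starts, ends, depths):
                    fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")

    def depth_at(self, chrom: str, pos1: int) -> int:
        """Depth at a 1-based position; 0 where no run covers it."""
        rs = self._runs.get(chrom)
        if rs is None:
            return 0
        starts, ends, depths = rs
        pos0 = pos1 - 1
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        while i >= 0 and pos0 >= ends[i]:
            i -= 1  # runs may nest-adjacent after dedup; walk back past shorter ones
        if i >= 0 and starts[i] <= pos0 < ends[i]:
            return int(depths[i])
        return 0

    def sum_depth(self, chrom: str, start0: int, end0: int) -> int:
        """Total depth summed over [start0, end0), 0-based half-open."""
        rs = self._runs.get(chrom)
        if rs is None:
            return 0
        starts, ends, depths = rs
        lo = int(np.searchsorted(ends, start0, side="right"))
        hi = int(np.searchsorted(starts, end0, side="left"))
        total = 0
        for i in range(lo, hi):
            ov = min(int(ends[i]), end0) - max(int(starts[i]), start0)
            if ov > 0:
                total += ov * int(depths[i])
        return total

    def mean_depth(self, chrom: str, start0: int, end0: int) -> float:
        if end0 <= start0:
            raise ValueError("empty interval")
        return self.sum_depth(chrom, start0, end0) / (end0 - start0)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._runs)


def read_coverage(path: Union[str, Path], platform_id: Optional[str] = None, **kw) -> CoverageTrack:
    return CoverageTrack.read(path, platform_id=platform_id, **kw)


# ---------------------------------------------------------------------------
# Call sets and truth sets


def _zygosity_for_alt(gt: tuple, alt_index: int) -> Optional[Zygosity]:
    alleles = [a for a in gt if a is not None]
    if not alleles or all(a == 0 for a in alleles):
        return None
    n = sum(1 for a in alleles if a == alt_index)
    if n == 0:
        return None
    if n == len(alleles) and n > 1:
        return Zygosity.HOM_ALT
    return Zygosity.HET


def read_callset(
    vcf_source: Union[str, Path],
    platform_id: str,
    reference: Optional[Mapping[str, Sequence[str]]] = None,
    alias_map: Optional[Mapping[str, str]] = None,
) -> list[PlatformCall]:
    """Read a single-sample VCF into normalized :class:`PlatformCall`s.

    Multi-allelic records are split into one call per alt allele; hom-ref
    and missing genotypes are skipped (with a logged count).  Missing GQ is
    stored as None.  Without a reference, normalization is trim-only.
    """
    calls: list[PlatformCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_source)) as vf:
        samples = list(vf.header.samples)
        if len(samples) > 1:
            raise ValueError(
                f"{vcf_source}: {len(samples)} samples found; single-sample VCFs only "
                "(subset with `bcftools view -s SAMPLE` first)"
            )
        has_sample = len(samples) == 1
        for rec in vf:
            try:
                chrom = rec.contig
                if alias_map:
                    chrom = alias_map.get(chrom, chrom)
                if not rec.alts:
                    n_skipped += 1
                    continue
                if has_sample:
                    smp = rec.samples[0]
                    gt = smp.get("GT")
                    dp = smp.get("DP")
                    if dp is None:
                        try:  # pysam raises if DP is absent from the header INFO lines
                            dp = rec.info.get("DP")
                        except (KeyError, ValueError):
                            dp = None
                    gq = smp.get("GQ")
                else:  # site-only VCF (e.g. a truth set without genotypes)
                    gt, dp, gq = None, None, None
                filt = list(rec.filter.keys())
                upstream = ";".join(filt) if filt else None
                for alt_index, alt in enumerate(rec.alts, start=1):
                    if alt is None or set(alt.upper()) - set("ACGT"):
                        continue  # symbolic / spanning-deletion alleles out of scope
                    if gt is not None:
                        zyg = _zygosity_for_alt(tuple(gt), alt_index)
                        if zyg is None:
                            n_skipped += 1
                            continue
                    else:
                        zyg = Zygosity.HET
                    variant = normalize_variant(chrom, rec.pos, rec.ref, alt, reference=reference)
                    calls.append(
                        PlatformCall(
                            variant=variant,
                            zygosity=zyg,
                            dp=int(dp) if dp is not None else None,
                            gq=int(gq) if gq is not None else None,
                            upstream_filter=upstream,
                            platform_id=platform_id,
                        )
                    )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{vcf_source}: failed to parse record at {rec.contig}:{rec.pos}: {exc}") from exc
    if n_skipped:
        logger.info("%s: skipped %d hom-ref/missing genotype records", vcf_source, n_skipped)
    return calls


_VCF_FILTERS = ("strand_bias", "recurrent_artifact", "low_quality")


def _vcf_header(contigs: Mapping[str, int], sample: str) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.add_line(f"##contig=<ID={name},length={length}>")
    for filt in _VCF_FILTERS:
        h.filters.add(filt, None, None, "upstream caller filter")
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("DP", 1, "Integer", "Read depth at this position")
    h.formats.add("GQ", 1, "Integer", "Genotype quality")
    h.add_sample(sample)
    return h


def write_callset(
    calls: Sequence[PlatformCall],
    path: Union[str, Path],
    contigs: Mapping[str, int],
    sample: str = "SAMPLE",
) -> None:
    """Write calls as an uncompressed single-sample VCF (sorted)."""
    header = _vcf_header(contigs, sample)
    order = {c: i for i, c in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in sorted(calls, key=lambda c: (order.get(c.variant.chrom, 1 << 30), c.variant.pos)):
            v = call.variant
            rec = vf.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            gt = (1, 1) if call.zygosity is Zygosity.HOM_ALT else (0, 1)
            rec.samples[sample]["GT"] = gt
            rec.samples[sample].phased = False
            if call.dp is not None:
                rec.samples[sample]["DP"] = call.dp
            if call.gq is not None:
                rec.samples[sample]["GQ"] = call.gq
            if call.upstream_filter:
                for f in call.upstream_filter.split(";"):
                    rec.filter.add(f)
            vf.write(rec)


@dataclass(frozen=True)
class TruthSet:
    """High-confidence calls plus the regions in which they are trusted."""

    calls: frozenset[tuple[CanonicalVariant, Zygosity]]
    confident_regions: IntervalSet
    version_label: str = ""

    def __post_init__(self) -> None:
        for v, _ in self.calls:
            if not self.confident_regions.contains(v.chrom, v.pos):
                raise ValueError(f"truth call {v} lies outside the confident regions")

    @property
    def variants(self) -> frozenset[CanonicalVariant]:
        return frozenset(v for v, _ in self.calls)

    def restricted_to(self, regions: IntervalSet) -> "TruthSet":
        keep = frozenset((v, z) for v, z in self.calls if regions.contains(v.chrom, v.pos))
        return TruthSet(keep, self.confident_regions.intersect(regions), self.version_label)


def read_truthset(
    vcf_path: Union[str, Path],
    bed_path: Union[str, Path],
    reference: Optional[Mapping[str, Sequence[str]]] = None,
    version_label: str = "",
    alias_map: Optional[Mapping[str, str]] = None,
) -> TruthSet:
    """Load a truth set through the same VCF path as platform call sets, so
    both sides of any comparison are normalized identically."""
    regions = IntervalSet.read_bed(bed_path, alias_map=alias_map)
    calls = read_callset(vcf_path, platform_id="A", reference=reference, alias_map=alias_map)
    inside = frozenset(
        (c.variant, c.zygosity) for c in calls if regions.contains(c.variant.chrom, c.variant.pos)
    )
    dropped = len(calls) - len(inside)
    if dropped:
        logger.info("%s: %d truth calls outside confident regions dropped", vcf_path, dropped)
    return TruthSet(inside, regions, version_label)


def check_contig_compatibility(names_a: Iterable[str], names_b: Iterable[str]) -> None:
    """Fail loudly on disjoint contig namespaces ('chr1' vs '1') instead of
    silently reporting zero overlap; an alias map resolves the mismatch."""
    a, b = set(names_a), set(names_b)
    if a and b and not (a & b):
        raise ValueError(
            f"contig names are disjoint between inputs ({sorted(a)[:3]} vs {sorted(b)[:3]}); "
            "supply a contig alias map (e.g. {'1': 'chr1'})"
        )
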
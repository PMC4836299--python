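"""Per-exon coverage complementarity between the two platforms.

Each platform's depth track is averaged per exon, globally rescaled so the
exon-base-weighted exome mean is a common target (100x by default), and
every exon is then placed in a quadrant by whether each platform clears a
callability threshold (20x by default).  Exons failing the threshold are
additionally binned by GC content, which exposes the complementary
chemistry biases: amplicon/semiconductor data holds up better in AT-rich
exons, hybrid-capture/reversible-terminator data in GC-rich ones.

The exon table is a pandas DataFrame with columns
``exon_id, chrom, start, end, gc, mean_a, mean_b, norm_a, norm_b``
(``start``/``end`` 0-based half-open).  ``plot_a``/``plot_b`` replace
zeros by 1 for log-scale scatter export only — thresholds always use the
true normalized depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .platform_io import CoverageTrack, IntervalSet

__all__ = [
    "QuadrantCounts",
    "read_exons_bed",
    "pad_exons",
    "compute_gc",
    "exon_mean_depths",
    "normalize_depths",
    "add_plot_depths",
    "quadrant_counts",
    "gc_bin_low_coverage",
    "exon_coverage_table",
]


@dataclass(frozen=True)
class QuadrantCounts:
    """Exon counts by (platform A >= t, platform B >= t)."""

    both_ge: int
    a_only: int
    b_only: int
    neither: int
    threshold: float = 20.0

    @property
    def total(self) -> int:
        return self.both_ge + self.a_only + self.b_only + self.neither

    def percentages(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            raise ValueError("no exons")
        return {
            "both_ge_pct": 100.0 * self.both_ge / t,
            "a_only_pct": 100.0 * self.a_only / t,
            "b_only_pct": 100.0 * self.b_only / t,
            "neither_pct": 100.0 * self.neither / t,
        }


def read_exons_bed(path: Union[str, Path]) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            name = parts[3] if len(parts) >= 4 else f"exon_{lineno}"
            rows.append({"exon_id": name, "chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])})
    return pd.DataFrame(rows)


def pad_exons(exons: pd.DataFrame, flank: int = 10) -> pd.DataFrame:
    """Widen each exon by ``flank`` bases on both sides (clipped at 0), for
    capturing splice-adjacent positions.  The analysis itself never pads
    implicitly — supply a pre-padded BED or call this helper explicitly."""
    out = exons.copy()
    out["start"] = (out["start"] - flank).clip(lower=0)
    out["end"] = out["end"] + flank
    return out


def compute_gc(sequence: str) -> Optional[float]:
    """(G+C)/(A+C+G+T); ambiguous bases are excluded from the denominator,
    an all-ambiguous sequence has no GC fraction."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return gc / acgt


def exon_mean_depths(exons: pd.DataFrame, track: CoverageTrack, platform: str) -> pd.DataFrame:
    """Add a ``mean_<platform>`` column of per-base average depths."""
    col = f"mean_{platform.lower()}"
    out = exons.copy()
    out[col] = [
        track.mean_depth(chrom, start, end)
        for chrom, start, end in zip(out["chrom"], out["start"], out["end"])
    ]
    return out


def normalize_depths(exons: pd.DataFrame, platform: str, target_mean: float = 100.0) -> pd.DataFrame:
    """Rescale one platform's per-exon means so the exon-base-weighted
    exome-wide mean equals ``target_mean``.

    The scale factor is a single global scalar per platform (not
    per-chromosome): target_mean / (sum of mean_i * len_i / sum of len_i).
    Zero depths stay zero.
    """
    p = platform.lower()
    mean_col, norm_col = f"mean_{p}", f"norm_{p}"
    lengths = (exons["end"] - exons["start"]).to_numpy(dtype=float)
    means = exons[mean_col].to_numpy(dtype=float)
    exome_mean = float(np.sum(means * lengths) / np.sum(lengths))
    if exome_mean <= 0:
        raise ValueError(f"exome-wide mean depth for platform {platform} is zero")
    out = exons.copy()
    out[norm_col] = means * (target_mean / exome_mean)
    return out


def add_plot_depths(exons: pd.DataFrame) -> pd.DataFrame:
    """Log-plot export columns: normalized depths with zeros floored to 1.
    Never used for threshold tests."""
    out = exons.copy()
    for p in ("a", "b"):
        out[f"plot_{p}"] = out[f"norm_{p}"].clip(lower=1.0)
    return out


def quadrant_counts(exons: pd.DataFrame, threshold: float = 20.0) -> QuadrantCounts:
    """Classify each exon by whether each platform's normalized depth
    reaches the threshold."""
    a = exons["norm_a"].to_numpy(dtype=float) >= threshold
    b = exons["norm_b"].to_numpy(dtype=float) >= threshold
    return QuadrantCounts(
        both_ge=int(np.sum(a & b)),
        a_only=int(np.sum(a & ~b)),
        b_only=int(np.sum(~a & b)),
        neither=int(np.sum(~a & ~b)),
        threshold=threshold,
    )


def gc_bin_low_coverage(
    exons: pd.DataFrame, threshold: float = 20.0, bin_width: float = 0.05
) -> pd.DataFrame:
    """Histogram of sub-threshold exon counts per GC bin per platform.

    Bins tile [0, 1], right-open except the last (gc = 1.0 falls in the
    final bin).  Requires a ``gc`` column; GC outside [0, 1] is an error.
    """
    gc = exons["gc"].to_numpy(dtype=float)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("gc fractions must lie in [0, 1]")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    rows = []
    for p in ("a", "b"):
        low = exons[f"norm_{p}"].to_numpy(dtype=float) < threshold
        counts, _ = np.histogram(gc[low], bins=edges)
        for i, n in enumerate(counts):
            rows.append(
                {
                    "gc_bin_start": round(float(edges[i]), 10),
                    "gc_bin_end": round(float(edges[i + 1]), 10),
                    "platform": p.upper(),
                    "n_low_coverage": int(n),
                }
            )
    return pd.DataFrame(rows)


def exon_coverage_table(
    exons: pd.DataFrame,
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    reference: Optional[Mapping[str, Sequence[str]]] = None,
    target_mean: float = 100.0,
) -> pd.DataFrame:
    """Full per-exon table: raw means, normalized means, plot depths and
    (when a reference is supplied) GC fractions."""
    out = exon_mean_depths(exons, track_a, "a")
    out = exon_mean_depths(out, track_b, "b")
    out = normalize_depths(out, "a", target_mean)
    out = normalize_depths(out, "b", target_mean)
    out = add_plot_depths(out)
    if reference is not None:
        out["gc"] = [
            compute_gc(str(reference[chrom][start:end]))
            for chrom, start, end in zip(out["chrom"], out["start"], out["end"])
        ]
    return out
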
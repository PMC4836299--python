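"""Synthetic truth sets, platform call sets and coverage tracks.

The generator emulates the statistical structure the confirmation method
assumes, at the call/coverage level the tool consumes (no reads): diploid
truth variants over toy exons; two platform call sets with configurable
per-class sensitivity, false-positive rate and zygosity-error rate; and
GC-biased, dispersed depth tracks.  Default profiles mirror the measured
behaviour of the two platform roles — a hybrid-capture/reversible-
terminator exome (role A: SNV sensitivity 99.6%, indel 95%, ~1.85 FP/Mb,
mean depth 125x, depth loss toward AT-rich exons) and an amplicon/
semiconductor exome (role B: 96.9% / 51%, ~2.66 FP/Mb, 133x, loss toward
GC-rich exons).

What is deliberately simple: variant emission is independent of the drawn
exon depth (depths feed the DP fields and the coverage predicate, not the
emission probability), errors are independent across sites and platforms,
and there are no alignment- or context-dependent artifacts.  Closed-form
expectations therefore hold exactly, e.g. the probability that a shared
truth site ends orthogonally confirmed is
``s_A * s_B * (1 - z_A) * (1 - z_B)`` (ignoring the small NoPass leak).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .platform_io import CoverageTrack, IntervalSet, TruthSet, write_callset
from .variant_model import (
    CanonicalVariant,
    PlatformCall,
    VariantClass,
    Zygosity,
    normalize_variant,
)

__all__ = [
    "PlatformProfile",
    "ToyGenome",
    "NEXTSEQ_LIKE",
    "PROTON_LIKE",
    "generate_truth",
    "simulate_platform_calls",
    "generate_fixture_bundle",
    "oc_probability",
    "TINY_EXPECTED_COUNTS",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlatformProfile:
    """Error/coverage behaviour of one platform role.

    ``gc_dropout`` is (direction, strength): direction "AT" loses depth in
    AT-rich exons, "GC" in GC-rich exons; the multiplicative depth factor
    is linear in |gc - 0.5| on the penalized side.  ``nopass_rate`` (role A
    only) injects sub-threshold DP or GQ values into otherwise good calls.
    """

    platform_id: str
    snv_sensitivity: float = 1.0
    indel_sensitivity: float = 1.0
    fp_per_mb: float = 0.0
    zygosity_error_rate: float = 0.0
    mean_depth: float = 100.0
    depth_dispersion: float = 8.0
    gc_dropout: tuple[str, float] = ("AT", 0.0)
    nopass_rate: float = 0.0
    fp_indel_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("snv_sensitivity", "indel_sensitivity", "zygosity_error_rate",
                     "nopass_rate", "fp_indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fp_per_mb < 0 or self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("fp_per_mb must be >= 0; mean_depth, depth_dispersion > 0")
        if self.gc_dropout[0] not in ("AT", "GC"):
            raise ValueError("gc_dropout direction must be 'AT' or 'GC'")

    def depth_factor(self, gc: float) -> float:
        direction, strength = self.gc_dropout
        dev = max(0.0, 0.5 - gc) if direction == "AT" else max(0.0, gc - 0.5)
        return max(0.0, 1.0 - strength * 2.0 * dev)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gc_dropout"] = list(self.gc_dropout)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlatformProfile":
        d = dict(d)
        d["gc_dropout"] = tuple(d.get("gc_dropout", ("AT", 0.0)))
        return cls(**d)


NEXTSEQ_LIKE = PlatformProfile(
    platform_id="A",
    snv_sensitivity=0.996,
    indel_sensitivity=0.95,
    fp_per_mb=1.85,
    zygosity_error_rate=0.002,
    mean_depth=125.0,
    depth_dispersion=8.0,
    gc_dropout=("AT", 0.5),
    nopass_rate=0.003,
)

PROTON_LIKE = PlatformProfile(
    platform_id="B",
    snv_sensitivity=0.969,
    indel_sensitivity=0.51,
    fp_per_mb=2.66,
    zygosity_error_rate=0.002,
    mean_depth=133.0,
    depth_dispersion=8.0,
    gc_dropout=("GC", 0.5),
    nopass_rate=0.0,
)


def oc_probability(a: PlatformProfile, b: PlatformProfile) -> float:
    """Closed-form probability that a shared truth SNV is orthogonally
    confirmed (both platforms call it, neither flips zygosity), ignoring
    the NoPass leak of role A."""
    return (
        a.snv_sensitivity * b.snv_sensitivity
        * (1 - a.zygosity_error_rate) * (1 - b.zygosity_error_rate)
    )


# ---------------------------------------------------------------------------
# Toy genome


@dataclass
class ToyGenome:
    """Generated contigs with exons of controlled GC composition."""

    sequences: dict[str, str]
    exons: pd.DataFrame  # exon_id, chrom, start, end (0-based half-open), gc_target

    @property
    def exon_regions(self) -> IntervalSet:
        return IntervalSet.from_iter(
            (r.chrom, int(r.start), int(r.end)) for r in self.exons.itertuples()
        )

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def write_fasta(self, path: Union[str, Path], width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_exons_bed(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for r in self.exons.itertuples():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.exon_id}\n")

    @classmethod
    def generate(
        cls,
        rng: np.random.Generator,
        n_contigs: int = 2,
        exons_per_contig: int = 50,
        exon_length: int = 160,
        spacing: int = 100,
        gc_range: tuple[float, float] = (0.25, 0.75),
        intergenic_gc: float = 0.45,
    ) -> "ToyGenome":
        """Exons carry an exactly realized GC fraction (the G+C base count
        is fixed, positions shuffled), so a declared gc_target is met to
        within rounding (< 1/exon_length)."""
        sequences: dict[str, str] = {}
        rows = []
        for ci in range(n_contigs):
            contig = f"ctg{ci + 1}"
            parts: list[str] = []
            cursor = 0
            for ei in range(exons_per_contig):
                parts.append(_random_seq(rng, spacing, intergenic_gc))
                cursor += spacing
                gc = float(rng.uniform(*gc_range))
                parts.append(_exact_gc_seq(rng, exon_length, gc))
                rows.append(
                    {
                        "exon_id": f"{contig}_ex{ei + 1}",
                        "chrom": contig,
                        "start": cursor,
                        "end": cursor + exon_length,
                        "gc_target": gc,
                    }
                )
                cursor += exon_length
            parts.append(_random_seq(rng, spacing, intergenic_gc))
            sequences[contig] = "".join(parts)
        return cls(sequences, pd.DataFrame(rows))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _exact_gc_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    n_gc = int(round(gc * n))
    strong = rng.choice(np.array(["G", "C"]), size=n_gc)
    weak = rng.choice(np.array(["A", "T"]), size=n - n_gc)
    seq = np.concatenate([strong, weak])
    rng.shuffle(seq)
    return "".join(seq)


# ---------------------------------------------------------------------------
# Truth generation


def generate_truth(
    genome: ToyGenome,
    n_snv: int,
    n_indel: int,
    het_fraction: float = 0.6,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    min_spacing: int = 10,
    version_label: str = "synthetic-truth",
) -> TruthSet:
    """Draw canonical, non-overlapping truth variants inside exons.

    Deterministic for a fixed seed.  Indels are 1-3 bp insertions or
    deletions with a retained anchor base, left-aligned against the toy
    genome.  Raises if the requested density is infeasible.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    regions = genome.exon_regions
    exon_bases = regions.total_bases
    if (n_snv + n_indel) > exon_bases / 10:
        raise ValueError(
            f"requested {n_snv + n_indel} variants over {exon_bases} exon bases "
            "exceeds the supported density (1 per 10 bp)"
        )
    margin = 6  # keep indels clear of exon edges
    candidates = [
        (r.chrom, int(p))
        for r in genome.exons.itertuples()
        for p in range(r.start + margin, r.end - margin)
    ]
    order = rng.permutation(len(candidates))
    occupied: dict[str, set[int]] = {}

    def _free(chrom: str, pos: int) -> bool:
        occ = occupied.get(chrom)
        if occ is None:
            return True
        return all((pos + d) not in occ for d in range(-min_spacing, min_spacing + 1))

    def _claim(chrom: str, pos: int) -> None:
        occupied.setdefault(chrom, set()).add(pos)

    kinds = ["SNV"] * n_snv + ["INDEL"] * n_indel
    calls: list[tuple[CanonicalVariant, Zygosity]] = []
    idx = 0
    for kind in kinds:
        variant = None
        while idx < len(order):
            chrom, start0 = candidates[order[idx]]
            idx += 1
            pos = start0 + 1  # 1-based
            if not _free(chrom, pos):
                continue
            seq = genome.sequences[chrom]
            ref_base = seq[pos - 1]
            if kind == "SNV":
                alt = str(rng.choice(_BASES[_BASES != ref_base]))
                cand = normalize_variant(chrom, pos, ref_base, alt, reference=genome.sequences)
            else:
                k = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # insertion
                    ins = "".join(rng.choice(_BASES, size=k))
                    cand = normalize_variant(chrom, pos, ref_base, ref_base + ins, reference=genome.sequences)
                else:  # deletion
                    ref_del = seq[pos - 1 : pos - 1 + 1 + k]
                    if len(ref_del) < 1 + k:
                        continue
                    cand = normalize_variant(chrom, pos, ref_del, ref_base, reference=genome.sequences)
            if not _free(cand.chrom, cand.pos) or not regions.contains(cand.chrom, cand.pos):
                continue
            _claim(cand.chrom, cand.pos)
            if cand.pos != pos:
                _claim(chrom, pos)
            variant = cand
            break
        if variant is None:
            raise ValueError("ran out of candidate positions; lower the variant density")
        zyg = Zygosity.HET if rng.random() < het_fraction else Zygosity.HOM_ALT
        calls.append((variant, zyg))
    return TruthSet(frozenset(calls), regions, version_label)


# ---------------------------------------------------------------------------
# Platform simulation


def simulate_platform_calls(
    truth: TruthSet,
    profile: PlatformProfile,
    genome: ToyGenome,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[list[PlatformCall], CoverageTrack]:
    """Emit one platform's call set and depth track from a truth set.

    Each truth variant is emitted with its class sensitivity and its
    zygosity flipped at ``zygosity_error_rate``; false positives arrive as
    a Poisson process at ``fp_per_mb`` over exon bases; per-exon depth is a
    negative-binomial draw around ``mean_depth`` scaled by the GC-dropout
    factor.  DP/GQ are filled consistently, with sub-threshold injections
    at ``nopass_rate`` for role A.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    exons = genome.exons

    # depth track: one run per exon
    runs = []
    for r in exons.itertuples():
        mu = profile.mean_depth * profile.depth_factor(float(r.gc_target))
        if mu <= 0:
            depth = 0
        else:
            disp = profile.depth_dispersion
            depth = int(rng.negative_binomial(disp, disp / (disp + mu)))
        runs.append((r.chrom, int(r.start), int(r.end), depth))
    track = CoverageTrack(runs, platform_id=profile.platform_id)

    def _dp_gq(chrom: str, pos: int) -> tuple[int, int]:
        site_depth = track.depth_at(chrom, pos)
        dp = max(1, int(rng.poisson(site_depth))) if site_depth > 0 else int(rng.integers(0, 3))
        gq = int(rng.integers(60, 100))
        if profile.platform_id == "A" and rng.random() < profile.nopass_rate:
            if rng.random() < 0.5:
                dp = int(rng.integers(0, 9))
            else:
                gq = int(rng.integers(0, 21))
        return dp, gq

    calls: list[PlatformCall] = []
    truth_positions: dict[str, set[int]] = {}
    for v, _ in truth.calls:
        truth_positions.setdefault(v.chrom, set()).add(v.pos)

    for v, zyg in sorted(truth.calls, key=lambda t: (t[0].chrom, t[0].pos, t[0].ref, t[0].alt)):
        sens = (
            profile.indel_sensitivity
            if v.vclass is VariantClass.INDEL
            else profile.snv_sensitivity
        )
        if rng.random() >= sens:
            continue
        if rng.random() < profile.zygosity_error_rate:
            zyg = Zygosity.HOM_ALT if zyg is Zygosity.HET else Zygosity.HET
        dp, gq = _dp_gq(v.chrom, v.pos)
        calls.append(
            PlatformCall(v, zyg, dp=dp, gq=gq, platform_id=profile.platform_id)
        )

    # false positives: uniform over exon bases, clear of truth positions
    exon_mb = truth.confident_regions.total_bases / 1e6
    n_fp = int(rng.poisson(profile.fp_per_mb * exon_mb))
    exon_list = list(exons.itertuples())
    placed = 0
    guard = 0
    while placed < n_fp and guard < 100 * (n_fp + 1):
        guard += 1
        r = exon_list[int(rng.integers(0, len(exon_list)))]
        pos = int(rng.integers(r.start + 6, r.end - 6)) + 1
        if pos in truth_positions.get(r.chrom, ()):  # do not collide with truth
            continue
        seq = genome.sequences[r.chrom]
        ref_base = seq[pos - 1]
        try:
            if rng.random() < profile.fp_indel_fraction:
                if rng.random() < 0.5:
                    v = normalize_variant(r.chrom, pos, ref_base, ref_base + str(rng.choice(_BASES)), reference=genome.sequences)
                else:
                    v = normalize_variant(r.chrom, pos, seq[pos - 1 : pos + 1], ref_base, reference=genome.sequences)
            else:
                alt = str(rng.choice(_BASES[_BASES != ref_base]))
                v = normalize_variant(r.chrom, pos, ref_base, alt, reference=genome.sequences)
        except ValueError:
            continue
        if v.pos in truth_positions.get(v.chrom, ()):
            continue
        zyg = Zygosity.HET if rng.random() < 0.8 else Zygosity.HOM_ALT
        dp, gq = _dp_gq(v.chrom, v.pos)
        calls.append(PlatformCall(v, zyg, dp=dp, gq=gq, platform_id=profile.platform_id))
        placed += 1

    calls.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt))
    return calls, track


# ---------------------------------------------------------------------------
# Fixture bundles


TINY_EXPECTED_COUNTS = {
    "orthogonally_confirmed": 5,
    "reliable": 2,
    "likely_tp": 3,
    "likely_fp": 2,
}

EXOME_LIKE_CONFIG = {
    "name": "exome-like",
    "genome": {
        "n_contigs": 5,
        "exons_per_contig": 3000,
        "exon_length": 200,
        "spacing": 100,
        "gc_range": [0.25, 0.75],
    },
    "truth": {"n_snv": 1530, "n_indel": 170, "het_fraction": 0.6},
    "profile_a": NEXTSEQ_LIKE.to_dict(),
    "profile_b": PROTON_LIKE.to_dict(),
}


def build_tiny_bundle(seed: int = 0):
    """The hand-checkable 12-site case: every category occurs, with
    predetermined counts (OC=5, Reliable=2, LikelyTP=3, LikelyFP=2).

    Layout on one 6 kb contig with exons [500,1500), [2000,3000),
    [3500,4500) (0-based):

    ========  ====================================  =====================
    site pos  construction                          expected category
    ========  ====================================  =====================
    600-1000  A PASS call matches B call (1000 is   ORTHOGONALLY_CONFIRMED
              hom-alt, 900 is a deletion)           (x5)
    2100      A dp=6 (NoPass) matches B             RELIABLE
    2200      A caller-filtered matches B           RELIABLE
    2400      singleton A PASS (insertion)          LIKELY_TP
    2500      singleton A PASS                      LIKELY_TP
    4000      singleton B, A depth 0 there          LIKELY_TP
    2700      singleton A dp=5 (NoPass)             LIKELY_FP
    4200      singleton B, A covered (depth 50)     LIKELY_FP
    ========  ====================================  =====================

    Truth contains the ten sites meant to be real; the two LikelyFP sites
    are absent from it.  Returns (genome, truth, calls_a, calls_b,
    track_a, track_b).
    """
    rng = np.random.default_rng(seed)
    contig = "tiny1"
    seq = _random_seq(rng, 6000, 0.5)
    exons = pd.DataFrame(
        [
            {"exon_id": "tiny1_ex1", "chrom": contig, "start": 500, "end": 1500, "gc_target": 0.5},
            {"exon_id": "tiny1_ex2", "chrom": contig, "start": 2000, "end": 3000, "gc_target": 0.5},
            {"exon_id": "tiny1_ex3", "chrom": contig, "start": 3500, "end": 4500, "gc_target": 0.5},
        ]
    )
    genome = ToyGenome({contig: seq}, exons)
    ref = genome.sequences

    def snv(pos: int) -> CanonicalVariant:
        base = seq[pos - 1]
        alt = "ACGT"[("ACGT".index(base) + 1) % 4]
        return normalize_variant(contig, pos, base, alt, reference=ref)

    def deletion(pos: int, k: int = 2) -> CanonicalVariant:
        return normalize_variant(contig, pos, seq[pos - 1 : pos + k], seq[pos - 1], reference=ref)

    def insertion(pos: int, ins: str = "TG") -> CanonicalVariant:
        return normalize_variant(contig, pos, seq[pos - 1], seq[pos - 1] + ins, reference=ref)

    HET, HOM = Zygosity.HET, Zygosity.HOM_ALT
    oc = [(snv(600), HET), (snv(700), HET), (snv(800), HET), (deletion(900), HET), (snv(1000), HOM)]
    reliable = [(snv(2100), HET), (snv(2200), HET)]
    ltp_a = [(insertion(2400), HET), (snv(2500), HET)]
    ltp_b = [(snv(4000), HET)]
    lfp_a = [(snv(2700), HET)]
    lfp_b = [(snv(4200), HET)]

    def call(v, z, platform, dp=50, gq=90, filt=None):
        return PlatformCall(v, z, dp=dp, gq=gq, upstream_filter=filt, platform_id=platform)

    calls_a = (
        [call(v, z, "A") for v, z in oc]
        + [call(*reliable[0], "A", dp=6, gq=80), call(*reliable[1], "A", dp=50, gq=90, filt="strand_bias")]
        + [call(v, z, "A", dp=45, gq=88) for v, z in ltp_a]
        + [call(*lfp_a[0], "A", dp=5, gq=85)]
    )
    calls_b = (
        [call(v, z, "B", dp=70, gq=85) for v, z in oc + reliable + ltp_b + lfp_b]
    )
    track_a = CoverageTrack(
        [(contig, 500, 1500, 60), (contig, 2000, 3000, 60), (contig, 3500, 3950, 50), (contig, 4050, 4500, 50)],
        platform_id="A",
    )
    track_b = CoverageTrack(
        [(contig, 500, 1500, 80), (contig, 2000, 3000, 80), (contig, 3500, 4500, 80)],
        platform_id="B",
    )
    truth = TruthSet(frozenset(oc + reliable + ltp_a + ltp_b), genome.exon_regions, "tiny-truth")
    return genome, truth, calls_a, calls_b, track_a, track_b


def generate_fixture_bundle(
    config: Union[str, dict],
    out_dir: Union[str, Path],
    seed: int = 0,
) -> dict:
    """Write a complete fixture bundle to disk and return its manifest.

    ``config`` is either a dict (see ``EXOME_LIKE_CONFIG``) or a bundle
    name: "tiny" (the 12-site hand-checkable case) or "exome-like" (a
    3 Mb exome-scale simulation).  Files written: reference FASTA, exon
    BED, truth VCF+BED, two platform VCFs, two coverage BEDs, and a
    manifest recording the seeds and profiles used.  Byte-identical for a
    fixed config + seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(config, str):
        if config == "tiny":
            config = {"name": "tiny"}
        elif config == "exome-like":
            config = EXOME_LIKE_CONFIG
        else:
            raise ValueError(f"unknown bundle name {config!r}")

    name = config.get("name", "custom")
    if name == "tiny":
        genome, truth, calls_a, calls_b, track_a, track_b = build_tiny_bundle(seed)
        manifest_extra = {"expected_category_counts": dict(TINY_EXPECTED_COUNTS)}
    else:
        ss = np.random.SeedSequence(seed)
        r_genome, r_truth, r_a, r_b = (np.random.default_rng(s) for s in ss.spawn(4))
        g = config["genome"]
        genome = ToyGenome.generate(
            r_genome,
            n_contigs=g.get("n_contigs", 2),
            exons_per_contig=g.get("exons_per_contig", 50),
            exon_length=g.get("exon_length", 160),
            spacing=g.get("spacing", 100),
            gc_range=tuple(g.get("gc_range", (0.25, 0.75))),
        )
        t = config["truth"]
        truth = generate_truth(
            genome, t["n_snv"], t["n_indel"], t.get("het_fraction", 0.6), rng=r_truth
        )
        prof_a = PlatformProfile.from_dict(config["profile_a"])
        prof_b = PlatformProfile.from_dict(config["profile_b"])
        calls_a, track_a = simulate_platform_calls(truth, prof_a, genome, rng=r_a)
        calls_b, track_b = simulate_platform_calls(truth, prof_b, genome, rng=r_b)
        manifest_extra = {}

    contigs = genome.contig_lengths
    genome.write_fasta(out / "reference.fa")
    genome.write_exons_bed(out / "exons.bed")
    truth_calls = [
        PlatformCall(v, z, dp=100, gq=99, platform_id="A")
        for v, z in sorted(truth.calls, key=lambda t: (t[0].chrom, t[0].pos, t[0].ref, t[0].alt))
    ]
    write_callset(truth_calls, out / "truth.vcf", contigs, sample="TRUTH")
    truth.confident_regions.write_bed(out / "truth_regions.bed")
    write_callset(calls_a, out / "platform_a.vcf", contigs, sample="SAMPLE")
    write_callset(calls_b, out / "platform_b.vcf", contigs, sample="SAMPLE")
    track_a.write(out / "coverage_a.bed")
    track_b.write(out / "coverage_b.bed")

    manifest = {
        "bundle": name,
        "seed": seed,
        "config": _plain(config),
        "n_truth": len(truth.calls),
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.yaml"),
        **manifest_extra,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
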
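"""Canonical small-variant representation.

Two sequencing platforms (and two upstream callers) routinely express the
same variant differently: padded alleles, right-shifted indels, or a
multi-nucleotide variant (MNV) reported whole by one caller and as its
component SNVs by the other.  Everything downstream — cross-platform
matching, truth-set comparison — relies on mapping every call to a single
canonical form first: alleles trimmed of shared bases and indels
left-aligned against the reference, per the usual VCF convention of one
retained anchor base.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

__all__ = [
    "VariantClass",
    "Zygosity",
    "PassStatus",
    "CanonicalVariant",
    "PlatformCall",
    "NormalizationError",
    "ReferenceMismatchError",
    "NotAVariantError",
    "NormalizationWindowError",
    "normalize_variant",
    "decompose_mnv",
    "decompose_call",
    "calls_match",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 200

_VALID_BASES = frozenset("ACGT")


class NormalizationError(ValueError):
    """Base class for variant-normalization failures."""


class ReferenceMismatchError(NormalizationError):
    """The stated REF allele does not match the reference sequence."""


class NotAVariantError(NormalizationError):
    """REF and ALT are identical after trimming: not a variant."""


class NormalizationWindowError(NormalizationError):
    """Left-alignment would shift past the allowed window or contig start."""


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    MNV = "MNV"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM_ALT = "hom_alt"


class PassStatus(str, enum.Enum):
    PASS = "pass"
    NOPASS = "nopass"
    CALLER_FILTERED = "caller_filtered"


@dataclass(frozen=True, order=True)
class CanonicalVariant:
    """A normalized small variant: trimmed alleles, leftmost position.

    ``pos`` is 1-based.  ``trim_only`` marks variants normalized without a
    reference context (trimmed but not guaranteed left-aligned); it is
    excluded from equality so that a trim-only variant still matches its
    fully normalized twin when their coordinates agree.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    trim_only: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise NotAVariantError(f"empty allele in {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise NotAVariantError(
                f"REF == ALT ({self.ref}) at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise NormalizationError(f"position must be >= 1, got {self.pos}")

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNV
        if len(self.ref) == len(self.alt):
            return VariantClass.MNV
        return VariantClass.INDEL

    @property
    def end(self) -> int:
        """Last 1-based reference position spanned by REF."""
        return self.pos + len(self.ref) - 1

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class PlatformCall:
    """One platform's call at a site.

    ``platform_id`` is role-based: "A" is the hybrid-capture /
    reversible-terminator role (subject to DP/GQ pass filtering), "B" the
    amplicon / semiconductor role (arrives pre-filtered by its caller).
    ``pass_status`` is None until the pass filter has been applied, except
    that calls carrying a non-PASS upstream FILTER are CALLER_FILTERED from
    the moment they are read and are never upgraded.
    """

    variant: CanonicalVariant
    zygosity: Zygosity
    dp: Optional[int] = None
    gq: Optional[int] = None
    upstream_filter: Optional[str] = None
    platform_id: str = "A"
    pass_status: Optional[PassStatus] = None

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise ValueError(f"negative DP {self.dp}")
        if self.platform_id not in ("A", "B"):
            raise ValueError(f"platform_id must be 'A' or 'B', got {self.platform_id!r}")
        if _filter_is_fail(self.upstream_filter) and self.pass_status != PassStatus.CALLER_FILTERED:
            object.__setattr__(self, "pass_status", PassStatus.CALLER_FILTERED)

    @property
    def key(self) -> tuple[CanonicalVariant, Zygosity]:
        return (self.variant, self.zygosity)


def _filter_is_fail(upstream_filter: Optional[str]) -> bool:
    return upstream_filter not in (None, "", ".", "PASS")


def _fetch(reference: Mapping[str, Sequence[str]], chrom: str, start0: int, end0: int) -> str:
    """Fetch reference bases [start0, end0) (0-based); works for dict-of-str
    and pyfaidx.Fasta alike."""
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise ReferenceMismatchError(f"contig {chrom!r} not in reference") from exc
    out = str(seq[start0:end0]).upper()
    if len(out) != end0 - start0:
        raise NormalizationWindowError(
            f"reference context for {chrom} does not cover [{start0}, {end0})"
        )
    return out


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Optional[Mapping[str, Sequence[str]]] = None,
    window: int = DEFAULT_WINDOW,
) -> CanonicalVariant:
    """Return the unique trimmed, left-aligned representation of a variant.

    Parameters
    ----------
    chrom, pos, ref, alt
        The variant as expressed upstream; ``pos`` is 1-based.
    reference
        Mapping of contig name to sequence (a plain dict of strings or a
        ``pyfaidx.Fasta``).  When omitted only allele trimming is performed
        and the result is flagged ``trim_only``.
    window
        Maximum number of bases the variant may be shifted left; shifting
        further raises :class:`NormalizationWindowError` rather than
        silently stopping.

    The algorithm is the standard one: repeatedly truncate a shared
    trailing base, extending both alleles leftward with the previous
    reference base whenever one allele would empty; finally trim shared
    leading bases.  It is idempotent.
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise NotAVariantError(f"empty allele at {chrom}:{pos}")
    for allele in (ref, alt):
        if not set(allele) <= _VALID_BASES:
            raise NormalizationError(
                f"allele {allele!r} at {chrom}:{pos} contains non-ACGT characters"
            )
    if ref == alt:
        raise NotAVariantError(f"REF == ALT ({ref}) at {chrom}:{pos}")

    if reference is not None:
        ctx = _fetch(reference, chrom, pos - 1, pos - 1 + len(ref))
        if ctx != ref:
            raise ReferenceMismatchError(
                f"REF {ref!r} does not match reference {ctx!r} at {chrom}:{pos}"
            )
        orig_pos = pos
        while ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    raise NormalizationWindowError(
                        f"left-alignment of {chrom}:{orig_pos} ran off the contig start"
                    )
                if orig_pos - pos >= window:
                    raise NormalizationWindowError(
                        f"left-alignment of {chrom}:{orig_pos} exceeded window of {window} bp"
                    )
                prev = _fetch(reference, chrom, pos - 2, pos - 1)
                ref = prev + ref
                alt = prev + alt
                pos -= 1
            ref = ref[:-1]
            alt = alt[:-1]
            if ref == alt:
                raise NotAVariantError(f"REF == ALT after trimming at {chrom}:{orig_pos}")
        trim_only = False
    else:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref = ref[:-1]
            alt = alt[:-1]
        trim_only = True

    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    if ref == alt:
        raise NotAVariantError(f"REF == ALT after trimming at {chrom}:{pos}")
    # trim-only mode can still expose a shared leading base on a pure SNV
    # hidden by padding, e.g. AT>AC
    return CanonicalVariant(chrom, pos, ref, alt, trim_only=trim_only)


def decompose_mnv(v: CanonicalVariant) -> list[CanonicalVariant]:
    """Split an MNV into its per-base SNVs; SNVs and indels pass through.

    Positions where REF and ALT agree emit nothing.  Applying every emitted
    SNV to the reference reconstructs the same haplotype as applying the
    MNV whole.
    """
    if v.vclass is not VariantClass.MNV:
        return [v]
    return [
        CanonicalVariant(v.chrom, v.pos + i, r, a, trim_only=v.trim_only)
        for i, (r, a) in enumerate(zip(v.ref, v.alt))
        if r != a
    ]


def decompose_call(call: PlatformCall) -> list[PlatformCall]:
    """Atomic decomposition of a call: one PlatformCall per component SNV,
    inheriting zygosity, depth, quality and filter state."""
    parts = decompose_mnv(call.variant)
    if len(parts) == 1 and parts[0] == call.variant:
        return [call]
    return [replace(call, variant=p) for p in parts]


def calls_match(a: PlatformCall, b: PlatformCall) -> bool:
    """True iff the two platforms called the same canonical variant with the
    same zygosity.  Symmetric; requires calls from different platforms."""
    if a.platform_id == b.platform_id:
        raise ValueError("calls_match compares calls from different platforms")
    return a.variant == b.variant and a.zygosity == b.zygosity
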
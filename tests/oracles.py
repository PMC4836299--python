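"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and coded from first principles
(enumeration, per-base scans, quadratic matching) so it shares no logic
with the package implementation it checks.
"""

from __future__ import annotations


def apply_edit(seq: str, pos1: int, ref: str, alt: str) -> str:
    """Apply one substitution/indel to a sequence (1-based pos)."""
    i = pos1 - 1
    assert seq[i : i + len(ref)] == ref, "oracle: ref does not match sequence"
    return seq[:i] + alt + seq[i + len(ref) :]


def apply_edits(seq: str, edits) -> str:
    """Apply multiple non-overlapping edits (any order), right-to-left."""
    for pos1, ref, alt in sorted(edits, reverse=True):
        seq = apply_edit(seq, pos1, ref, alt)
    return seq


def enumerate_canonical(context: str, pos1: int, ref: str, alt: str, max_len: int = 8):
    """Exhaustive-search canonical representation of a variant.

    Builds the alternate haplotype of ``context`` and enumerates every
    (pos, ref, alt) edit of the context that reproduces it; the canonical
    form is the representation with the smallest total allele length,
    leftmost position breaking ties.  ``pos1`` is 1-based within context.
    """
    hap = apply_edit(context, pos1, ref, alt)
    valid = []
    for p in range(1, len(context) + 1):
        for rl in range(0, max_len + 1):
            if p - 1 + rl > len(context):
                continue
            r = context[p - 1 : p - 1 + rl]
            tail = len(context) - (p - 1 + rl)
            al = len(hap) - (p - 1) - tail
            if al < 0:
                continue
            a = hap[p - 1 : p - 1 + al]
            if not r or not a or r == a:
                continue
            if context[: p - 1] + a + context[p - 1 + rl :] == hap:
                valid.append((p, r, a))
    assert valid, "oracle: no representation found"
    return min(valid, key=lambda t: (len(t[1]) + len(t[2]), t[0]))


def per_base_intersection(interval_sets):
    """Per-base membership intersection of interval lists (0-based
    half-open), returned as a sorted set of (chrom, base)."""
    base_sets = []
    for ivs in interval_sets:
        s = set()
        for chrom, start, end in ivs:
            for b in range(start, end):
                s.add((chrom, b))
        base_sets.append(s)
    out = base_sets[0]
    for s in base_sets[1:]:
        out &= s
    return out


def quadratic_match(calls_a, calls_b):
    """All-pairs matching oracle: returns (pairs, singletons_a, singletons_b)
    where calls are (variant_key, zygosity) tuples and a pair requires both
    equal."""
    used_b = set()
    pairs = []
    singles_a = []
    for ka in calls_a:
        hit = None
        for j, kb in enumerate(calls_b):
            if j in used_b:
                continue
            if ka == kb:
                hit = j
                break
        if hit is None:
            singles_a.append(ka)
        else:
            used_b.add(hit)
            pairs.append(ka)
    singles_b = [kb for j, kb in enumerate(calls_b) if j not in used_b]
    return pairs, singles_a, singles_b


def naive_classify(calls_a, calls_b, depth_a, depth_b, min_dp=8, min_gq=20, covered_depth=8):
    """Independent implementation of the confidence decision table.

    ``calls_*`` are dicts key=(chrom,pos,ref,alt,zyg) ->
    (dp, gq, caller_filtered); ``depth_*`` map (chrom, pos) -> depth.
    Returns dict key -> category string.
    """

    def a_passes(key):
        dp, gq, filtered = calls_a[key]
        if filtered:
            return False
        return dp is not None and gq is not None and dp > min_dp and gq > min_gq

    loci_a = {(k[0], k[1]) for k in calls_a}
    loci_b = {(k[0], k[1]) for k in calls_b}
    out = {}
    for key in calls_a:
        if key in calls_b:
            out[key] = "orthogonally_confirmed" if a_passes(key) else "reliable"
        else:
            out[key] = "likely_tp" if a_passes(key) else "likely_fp"
    for key in calls_b:
        if key in calls_a:
            continue
        locus = (key[0], key[1])
        covered = depth_a.get(locus, 0) >= covered_depth or locus in loci_a
        out[key] = "likely_fp" if covered else "likely_tp"
    return out


def naive_confusion(call_pairs, truth_pairs, gt_strict=True):
    """Naive TP/FP/FN counting on (variant_key, zygosity) pairs."""
    if gt_strict:
        tp = [c for c in call_pairs if c in truth_pairs]
        fp = [c for c in call_pairs if c not in truth_pairs]
        fn = [t for t in truth_pairs if t not in call_pairs]
    else:
        tv = {t[0] for t in truth_pairs}
        cv = {c[0] for c in call_pairs}
        tp = [c for c in call_pairs if c[0] in tv]
        fp = [c for c in call_pairs if c[0] not in tv]
        fn = [t for t in truth_pairs if t[0] not in cv]
    return len(tp), len(fp), len(fn)
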
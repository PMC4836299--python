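"""Pass filtering, cross-platform matching and category classification."""

import numpy as np
import pytest

from oracles import naive_classify, quadratic_match
from orthocombine.combinator import (
    Category,
    CoveredPredicate,
    MatchedSite,
    PassThresholds,
    apply_pass_filter,
    classify_site,
    combine_calls,
    match_callsets,
)
from orthocombine.platform_io import CoverageTrack, IntervalSet
from orthocombine.variant_model import (
    CanonicalVariant,
    PassStatus,
    PlatformCall,
    Zygosity,
)


def make_call(pos, ref="A", alt="T", zyg=Zygosity.HET, platform="A", dp=50, gq=90,
              filt=None, chrom="c1"):
    return PlatformCall(
        CanonicalVariant(chrom, pos, ref, alt), zyg, dp=dp, gq=gq,
        upstream_filter=filt, platform_id=platform,
    )


class TestPassFilter:
    @pytest.mark.parametrize(
        "dp,gq,expected",
        [
            (9, 21, PassStatus.PASS),     # strictly above both bounds
            (8, 99, PassStatus.NOPASS),   # DP bound is strict: 8 fails
            (100, 20, PassStatus.NOPASS), # GQ bound is strict: 20 fails
            (9, 20, PassStatus.NOPASS),
            (100, 99, PassStatus.PASS),
        ],
    )
    def test_strict_bounds(self, dp, gq, expected):
        out = apply_pass_filter(make_call(10, dp=dp, gq=gq), PassThresholds())
        assert out.pass_status is expected

    def test_missing_gq_is_nopass_not_error(self):
        out = apply_pass_filter(make_call(10, gq=None))
        assert out.pass_status is PassStatus.NOPASS

    def test_caller_filtered_never_upgraded(self):
        out = apply_pass_filter(make_call(10, dp=100, gq=99, filt="strand_bias"))
        assert out.pass_status is PassStatus.CALLER_FILTERED


class TestMatchCallsets:
    def test_identical_sets_all_pair(self):
        a = [make_call(p, platform="A") for p in (10, 20, 30, 40, 50)]
        b = [make_call(p, platform="B") for p in (10, 20, 30, 40, 50)]
        sites = match_callsets(a, b)
        assert len(sites) == 5
        assert all(s.call_a and s.call_b for s in sites)

    def test_disjoint_sets_all_singletons(self):
        a = [make_call(p, platform="A") for p in (10, 20, 30)]
        b = [make_call(p, platform="B") for p in (40, 50)]
        sites = match_callsets(a, b)
        assert len(sites) == 5
        assert sum(s.call_a is not None and s.call_b is None for s in sites) == 3
        assert sum(s.call_b is not None and s.call_a is None for s in sites) == 2

    def test_zygosity_discordance_yields_conflicting_singletons(self):
        a = [make_call(10, zyg=Zygosity.HET, platform="A")]
        b = [make_call(10, zyg=Zygosity.HOM_ALT, platform="B")]
        sites = match_callsets(a, b)
        assert len(sites) == 2
        sa = next(s for s in sites if s.call_a)
        sb = next(s for s in sites if s.call_b)
        assert sa.conflict_b and sb.conflict_a

    def test_duplicate_calls_deduplicated(self):
        a = [make_call(10, platform="A"), make_call(10, platform="A")]
        sites = match_callsets(a, [])
        assert len(sites) == 1

    def test_every_call_in_exactly_one_site(self, rng):
        """Pairing equals the quadratic all-pairs oracle on random instances
        with a configurable shared fraction."""
        for trial in range(20):
            shared = [make_call(int(p)) for p in rng.choice(np.arange(10, 5000, 7), 60, replace=False)]
            only_a = [make_call(int(p)) for p in rng.choice(np.arange(6000, 9000, 7), 40, replace=False)]
            only_b = [make_call(int(p)) for p in rng.choice(np.arange(10000, 13000, 7), 40, replace=False)]
            import dataclasses

            a = [dataclasses.replace(c, platform_id="A") for c in shared + only_a]
            b = [dataclasses.replace(c, platform_id="B") for c in shared + only_b]
            sites = match_callsets(a, b)
            n_pairs = sum(1 for s in sites if s.call_a and s.call_b)
            n_sa = sum(1 for s in sites if s.call_b is None)
            n_sb = sum(1 for s in sites if s.call_a is None)
            keys_a = [(c.variant, c.zygosity) for c in a]
            keys_b = [(c.variant, c.zygosity) for c in b]
            pairs, sa, sb = quadratic_match(keys_a, keys_b)
            assert (n_pairs, n_sa, n_sb) == (len(pairs), len(sa), len(sb))
            assert n_pairs + n_sa + n_sb == len(sites)

    def test_symmetry_under_swap(self):
        a = [make_call(p, platform="A") for p in (10, 20, 30)]
        b = [make_call(p, platform="B") for p in (20, 30, 40)]
        fwd = match_callsets(a, b)
        import dataclasses

        rev = match_callsets(
            [dataclasses.replace(c, platform_id="A") for c in b],
            [dataclasses.replace(c, platform_id="B") for c in a],
        )
        def shape(sites):
            return sorted(
                (s.variant.pos, s.call_a is not None, s.call_b is not None) for s in sites
            )
        assert sorted((p, x or y) for p, x, y in shape(fwd)) == sorted(
            (p, x or y) for p, x, y in shape(rev)
        )
        # pairing structure is identical; only the platform labels swap
        paired_fwd = {s.variant.pos for s in fwd if s.call_a and s.call_b}
        paired_rev = {s.variant.pos for s in rev if s.call_a and s.call_b}
        assert paired_fwd == paired_rev


FULL = CoverageTrack([("c1", 0, 10000, 60)], platform_id="A")
EMPTY = CoverageTrack([], platform_id="A")


class TestClassify:
    def _classify(self, site, cov_a=FULL, cov_b=FULL):
        return classify_site(site, cov_a, cov_b, CoveredPredicate(), PassThresholds())

    def test_pass_match_is_orthogonally_confirmed(self):
        a = apply_pass_filter(make_call(100, platform="A"))
        b = make_call(100, platform="B")
        out = self._classify(MatchedSite(a.variant, call_a=a, call_b=b))
        assert out.category is Category.ORTHOGONALLY_CONFIRMED

    def test_nopass_match_is_reliable(self):
        a = apply_pass_filter(make_call(100, dp=6, platform="A"))
        b = make_call(100, platform="B")
        out = self._classify(MatchedSite(a.variant, call_a=a, call_b=b))
        assert out.category is Category.RELIABLE

    def test_caller_filtered_match_is_reliable(self):
        a = make_call(100, platform="A", filt="strand_bias")
        b = make_call(100, platform="B")
        out = self._classify(MatchedSite(a.variant, call_a=a, call_b=b))
        assert out.category is Category.RELIABLE

    def test_singleton_a_pass_is_likely_tp(self):
        a = apply_pass_filter(make_call(100, platform="A"))
        out = self._classify(MatchedSite(a.variant, call_a=a))
        assert out.category is Category.LIKELY_TP

    def test_singleton_a_nopass_is_likely_fp(self):
        a = apply_pass_filter(make_call(100, dp=6, platform="A"))
        out = self._classify(MatchedSite(a.variant, call_a=a))
        assert out.category is Category.LIKELY_FP

    def test_singleton_b_without_a_coverage_is_likely_tp(self):
        b = make_call(100, platform="B")
        out = self._classify(MatchedSite(b.variant, call_b=b), cov_a=EMPTY)
        assert out.category is Category.LIKELY_TP
        assert not out.covered_a

    def test_singleton_b_with_a_coverage_is_likely_fp(self):
        b = make_call(100, platform="B")
        out = self._classify(MatchedSite(b.variant, call_b=b), cov_a=FULL)
        assert out.category is Category.LIKELY_FP

    def test_singleton_b_with_conflicting_a_call_is_likely_fp_even_uncovered(self):
        b = make_call(100, platform="B")
        out = self._classify(
            MatchedSite(b.variant, call_b=b, conflict_a=True), cov_a=EMPTY
        )
        assert out.category is Category.LIKELY_FP

    def test_covered_boundary_is_inclusive(self):
        thin = CoverageTrack([("c1", 0, 10000, 8)], platform_id="A")
        b = make_call(100, platform="B")
        out = self._classify(MatchedSite(b.variant, call_b=b), cov_a=thin)
        assert out.covered_a  # depth 8 >= min_covered_depth 8
        assert out.category is Category.LIKELY_FP

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            MatchedSite(CanonicalVariant("c1", 1, "A", "T"))


def _random_instance(rng, n_a=120, n_b=110, n_shared=70):
    positions = rng.choice(np.arange(10, 9000), size=400, replace=False)
    it = iter(int(p) for p in positions)
    shared = []
    for _ in range(n_shared):
        p = next(it)
        zyg = Zygosity.HET if rng.random() < 0.7 else Zygosity.HOM_ALT
        shared.append((p, zyg))
    calls_a, calls_b = [], []
    for p, zyg in shared:
        calls_a.append(make_call(p, zyg=zyg, platform="A",
                                 dp=int(rng.integers(0, 100)), gq=int(rng.integers(0, 99)),
                                 filt="strand_bias" if rng.random() < 0.05 else None))
        calls_b.append(make_call(p, zyg=zyg, platform="B", dp=int(rng.integers(5, 100)), gq=80))
    for _ in range(n_a - n_shared):
        p = next(it)
        calls_a.append(make_call(p, platform="A",
                                 dp=int(rng.integers(0, 100)), gq=int(rng.integers(0, 99))))
    for _ in range(n_b - n_shared):
        p = next(it)
        calls_b.append(make_call(p, platform="B", dp=int(rng.integers(5, 100)), gq=80))
    depth_a = {}
    track_runs = []
    for start in range(0, 9500, 250):
        d = int(rng.choice([0, 0, 5, 30, 80]))
        track_runs.append(("c1", start, start + 250, d))
        for pos0 in range(start, start + 250):
            depth_a[("c1", pos0 + 1)] = d
    return calls_a, calls_b, CoverageTrack(track_runs, "A"), depth_a


class TestAgainstBruteForce:
    def test_classification_equals_naive_decision_table(self, rng):
        """Full pipeline output equals an independently coded naive
        implementation of the category decision table."""
        for trial in range(10):
            calls_a, calls_b, track_a, depth_a = _random_instance(rng)
            combined = combine_calls(calls_a, calls_b, track_a, FULL)
            got = {
                (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt,
                 (c.call_a or c.call_b).zygosity): c.category.value
                for c in combined.calls
            }
            na = {
                (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt, c.zygosity):
                (c.dp, c.gq, c.upstream_filter is not None)
                for c in calls_a
            }
            nb = {
                (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt, c.zygosity):
                (c.dp, c.gq, c.upstream_filter is not None)
                for c in calls_b
            }
            expected = naive_classify(na, nb, {(c, p): d for (c, p), d in depth_a.items()}, {})
            expected = {(k[0], k[1], k[2], k[3], k[4]): v for k, v in expected.items()}
            assert got == expected


class TestCombineInvariants:
    def test_empty_inputs_empty_output(self):
        combined = combine_calls([], [], EMPTY, EMPTY)
        assert combined.calls == []
        assert all(v == 0 for v in combined.category_counts().values())

    def test_partition_over_categories(self, rng):
        calls_a, calls_b, track_a, _ = _random_instance(rng)
        combined = combine_calls(calls_a, calls_b, track_a, FULL)
        counts = combined.category_counts()
        assert sum(counts.values()) == len(combined.calls)
        keys = [(c.variant, (c.call_a or c.call_b).zygosity) for c in combined.calls]
        assert len(keys) == len(set(keys))  # no call in two categories

    def test_region_restriction_is_position_based(self):
        a = [make_call(100, platform="A"), make_call(900, platform="A")]
        regions = IntervalSet.from_iter([("c1", 0, 500)])
        combined = combine_calls(a, [], FULL, FULL, regions=regions)
        assert [c.variant.pos for c in combined.calls] == [100]

    def test_raising_min_dp_only_demotes(self, rng):
        """OC can only move to RELIABLE and LIKELY_TP only to LIKELY_FP as
        min_dp rises."""
        calls_a, calls_b, track_a, _ = _random_instance(rng)
        lo = combine_calls(calls_a, calls_b, track_a, FULL, thresholds=PassThresholds(8, 20))
        hi = combine_calls(calls_a, calls_b, track_a, FULL, thresholds=PassThresholds(30, 20))
        lo_map = {(c.variant, (c.call_a or c.call_b).zygosity): c.category for c in lo.calls}
        hi_map = {(c.variant, (c.call_a or c.call_b).zygosity): c.category for c in hi.calls}
        allowed = {
            (Category.ORTHOGONALLY_CONFIRMED, Category.RELIABLE),
            (Category.LIKELY_TP, Category.LIKELY_FP),
        }
        for key, cat_lo in lo_map.items():
            cat_hi = hi_map[key]
            assert cat_lo == cat_hi or (cat_lo, cat_hi) in allowed

    def test_mnv_atomic_vs_whole_mode(self):
        mnv_a = PlatformCall(
            CanonicalVariant("c1", 100, "AG", "TC"), Zygosity.HET, dp=50, gq=90, platform_id="A"
        )
        snvs_b = [
            make_call(100, "A", "T", platform="B"),
            make_call(101, "G", "C", platform="B"),
        ]
        atomic = combine_calls([mnv_a], snvs_b, FULL, FULL, mnv_mode="atomic")
        assert all(c.category is Category.ORTHOGONALLY_CONFIRMED for c in atomic.calls)
        assert len(atomic.calls) == 2
        whole = combine_calls([mnv_a], snvs_b, FULL, FULL, mnv_mode="whole")
        cats = sorted(c.category.value for c in whole.calls)
        # the whole MNV no longer matches the component SNVs
        assert len(whole.calls) == 3
        assert Category.ORTHOGONALLY_CONFIRMED.value not in cats
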
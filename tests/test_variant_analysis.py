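"""HGVS parsing, topology annotation, regional tallies, hotspot detection
and tolerance-score binning."""

import bisect

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crt1kit.io_formats import Classification
from crt1kit.topology import RegionClass
from crt1kit.variant_analysis import (
    AnnotatedVariant,
    HgvsParseError,
    ToleranceCategory,
    VariantKind,
    annotate_variant,
    bin_tolerance,
    detect_hotspots,
    parse_hgvs_p,
    tally_by_region_class,
)


class TestParseHgvsP:
    @pytest.mark.parametrize(
        "text,kind,start,end,ref,alt",
        [
            ("p.Pro544Leu", VariantKind.MISSENSE, 544, 544, "P", "L"),
            ("p.P544L", VariantKind.MISSENSE, 544, 544, "P", "L"),
            ("p.Trp107Ter", VariantKind.NONSENSE, 107, 107, "W", "*"),
            ("p.W107*", VariantKind.NONSENSE, 107, 107, "W", "*"),
            ("p.Gly132del", VariantKind.DELETION, 132, 132, "G", ""),
            ("p.Val476_Ile520del", VariantKind.DELETION, 476, 520, "VI", ""),
            ("p.Met235dup", VariantKind.DUPLICATION, 235, 235, "M", ""),
            ("p.Ala259_Gln261dup", VariantKind.DUPLICATION, 259, 261, "AQ", ""),
            ("p.Asn336Lysfs*11", VariantKind.FRAMESHIFT, 336, 336, "N", ""),
            ("p.N336fs", VariantKind.FRAMESHIFT, 336, 336, "N", ""),
            ("p.(Cys491Tyr)", VariantKind.MISSENSE, 491, 491, "C", "Y"),
        ],
    )
    def test_grammar(self, text, kind, start, end, ref, alt):
        d = parse_hgvs_p(text)
        assert (d.kind, d.start, d.end, d.ref_aa, d.alt_aa) == (
            kind, start, end, ref, alt,
        )

    def test_truncating_flag(self):
        assert parse_hgvs_p("p.Trp107Ter").truncating
        assert parse_hgvs_p("p.Asn336Lysfs*11").truncating
        assert not parse_hgvs_p("p.Pro544Leu").truncating
        assert not parse_hgvs_p("p.Gly132del").truncating

    @pytest.mark.parametrize(
        "bad,code",
        [
            ("p.???", "unsupported"),
            ("Pro544Leu", "no_p_prefix"),
            ("", "empty"),
            ("p.Pro544Pro", "synonymous"),
            ("p.Xyz100Leu", "unsupported"),
        ],
    )
    def test_rejects_with_reason_code(self, bad, code):
        with pytest.raises(HgvsParseError) as exc:
            parse_hgvs_p(bad)
        assert exc.value.code == code


class TestAnnotateVariant:
    def test_missense_in_tm8(self, topo):
        v = annotate_variant(parse_hgvs_p("p.Phe405Cys"), Classification.PATHOGENIC, topo)
        assert v.affected_regions == ("TM8",)
        assert v.primary_region_class is RegionClass.TM

    def test_nonsense_in_el6_loses_tail(self, topo):
        """A stop inside the last extracellular loop removes part of that
        loop, all of TM12, and the C-terminus."""
        v = annotate_variant(parse_hgvs_p("p.Trp540Ter"), Classification.PATHOGENIC, topo)
        assert v.affected_regions == ("EL6", "TM12", "C_TERM")

    def test_frameshift_before_tm6_loses_tm6_through_tm12(self, topo):
        el3 = next(r for r in topo.regions if r.name == "EL3")
        v = annotate_variant(
            parse_hgvs_p(f"p.Asn{el3.start + 2}fs"), Classification.PATHOGENIC, topo
        )
        for tm in [f"TM{i}" for i in range(6, 13)]:
            assert tm in v.affected_regions
        assert v.affected_regions[-1] == "C_TERM"

    def test_multiregion_deletion_lists_regions_in_order(self, topo):
        v = annotate_variant(
            parse_hgvs_p("p.Val470_Ile500del"), Classification.PATHOGENIC, topo
        )
        assert v.affected_regions == ("EL5", "TM10", "IL5")
        assert v.primary_region_class is RegionClass.LOOP

    def test_truncation_start_earlier_never_shrinks_regions(self, topo):
        prev = None
        for pos in range(600, 0, -25):
            v = annotate_variant(
                parse_hgvs_p(f"p.Gly{pos}fs"), Classification.UNKNOWN, topo
            )
            if prev is not None:
                assert set(prev) <= set(v.affected_regions)
            prev = v.affected_regions

    def test_out_of_range_position_rejected(self, topo):
        with pytest.raises(ValueError):
            annotate_variant(parse_hgvs_p("p.Gly700Arg"), Classification.UNKNOWN, topo)


class TestTally:
    def test_curated_catalog_reproduces_reported_fractions(self, annotated_catalog):
        """Terminus 100% benign; loop 64% and TM 70% pathogenic."""
        t = tally_by_region_class(annotated_catalog, missense_only=True)
        term = t.by_class[RegionClass.TERMINUS]
        loop = t.by_class[RegionClass.LOOP]
        tm = t.by_class[RegionClass.TM]
        assert (term.benign, term.pathogenic, term.benign_pct) == (8, 0, 100)
        assert (loop.total, loop.pathogenic, loop.pathogenic_pct) == (25, 16, 64)
        assert (tm.total, tm.pathogenic, tm.pathogenic_pct) == (10, 7, 70)

    def test_totals_conserved(self, annotated_catalog):
        t = tally_by_region_class(annotated_catalog)
        assert (
            sum(c.total + c.unknown for c in t.by_class.values()) == t.n_variants == 43
        )

    def test_empty_input_gives_na_percentages(self):
        t = tally_by_region_class([])
        assert t.n_variants == 0
        for c in t.by_class.values():
            assert c.pathogenic_pct is None and c.benign_pct is None

    def test_missense_only_filters_truncating(self, topo):
        variants = [
            annotate_variant(parse_hgvs_p("p.Gly80Arg"), Classification.PATHOGENIC, topo),
            annotate_variant(parse_hgvs_p("p.Trp107Ter"), Classification.PATHOGENIC, topo),
        ]
        assert tally_by_region_class(variants, missense_only=True).n_variants == 1
        assert tally_by_region_class(variants, missense_only=False).n_variants == 2


def _missense_at(positions, topo):
    out = []
    for p in positions:
        d = parse_hgvs_p(f"p.Ala{p}Gly")
        out.append(annotate_variant(d, Classification.UNKNOWN, topo))
    return out


def brute_force_windows(positions, L, w, min_count):
    """Direct recount over every window start (independent of the sliding
    implementation): returns the set of qualifying window starts."""
    return {
        s
        for s in range(1, L - w + 2)
        if sum(1 for p in positions if s <= p <= s + w - 1) >= min_count
    }


class TestHotspots:
    def test_uniform_spread_below_threshold_gives_nothing(self, topo):
        vs = _missense_at(range(10, 636, 60), topo)
        assert detect_hotspots(vs, 635, window_size=50, min_count=5) == []

    def test_single_cluster_flagged(self, topo):
        positions = list(np.linspace(305, 415, 10).astype(int))
        vs = _missense_at(positions, topo)
        hs = detect_hotspots(vs, 635, window_size=111, min_count=8)
        assert len(hs) == 1
        assert hs[0].start <= 305 and hs[0].end >= 415
        assert hs[0].variant_count == 10

    def test_two_separated_clusters_give_two_windows(self, topo):
        positions = [50, 52, 54, 56, 58, 500, 502, 504, 506, 508]
        vs = _missense_at(positions, topo)
        hs = detect_hotspots(vs, 635, window_size=20, min_count=5)
        assert len(hs) == 2
        assert hs[0].end < hs[1].start

    def test_reported_counts_match_direct_recount(self, topo):
        rng = np.random.default_rng(7)
        positions = sorted(rng.integers(1, 636, size=60).tolist())
        vs = _missense_at(positions, topo)
        for h in detect_hotspots(vs, 635, window_size=40, min_count=6):
            direct = sum(1 for p in positions if h.start <= p <= h.end)
            assert h.variant_count == direct
            assert h.density == pytest.approx(direct / (h.end - h.start + 1))

    def test_qualifying_windows_match_brute_force(self, topo):
        rng = np.random.default_rng(11)
        positions = sorted(rng.integers(1, 636, size=40).tolist())
        vs = _missense_at(positions, topo)
        w, mc = 30, 4
        expected = brute_force_windows(positions, 635, w, mc)
        spans = [(h.start, h.end) for h in detect_hotspots(vs, 635, w, mc)]
        # every qualifying window start lies inside a reported merged span
        covered = set()
        for s in expected:
            assert any(lo <= s and s + w - 1 <= hi for lo, hi in spans)
            covered.add(s)
        # and every reported span is a union of qualifying windows
        for lo, hi in spans:
            assert any(lo <= s <= hi - w + 1 for s in expected)

    def test_default_min_count_is_twice_mean_density(self, topo):
        # 20 variants in one tight cluster among sparse background
        positions = list(range(300, 320)) + [50, 150, 550]
        vs = _missense_at(positions, topo)
        hs = detect_hotspots(vs, 635, window_size=50)
        assert len(hs) == 1
        assert hs[0].start <= 300 and hs[0].end >= 319


class TestToleranceBins:
    @pytest.mark.parametrize(
        "score,cat",
        [
            (0.30, ToleranceCategory.HIGHLY_INTOLERANT),
            (0.49999, ToleranceCategory.HIGHLY_INTOLERANT),
            (0.5, ToleranceCategory.MODERATELY_INTOLERANT),
            (0.69, ToleranceCategory.MODERATELY_INTOLERANT),
            (0.7, ToleranceCategory.INTERMEDIATE_TOLERANCE),
            (1.0, ToleranceCategory.INTERMEDIATE_TOLERANCE),
            (1.2, ToleranceCategory.TOLERANT),
            (0.0, ToleranceCategory.HIGHLY_INTOLERANT),
        ],
    )
    def test_bin_boundaries(self, score, cat):
        assert bin_tolerance(score) is cat

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            bin_tolerance(-0.1)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(min_value=0, max_value=5, allow_nan=False))
    def test_bins_partition_the_nonnegative_line(self, score):
        assert bin_tolerance(score) in ToleranceCategory
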
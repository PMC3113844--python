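"""Variant-table parsing, trimming, distances and FASTA round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtcr.haplotypes import (
    HVR1_NETWORK,
    FULL_RANGE,
    HaploPanel,
    Haplotype,
    Region,
    Variant,
    diff_against_reference,
    export_fasta,
    pairwise_distance,
    parse_variant_table,
    serialize_variant_table,
    trim_to_regions,
)

from conftest import hap_from_bits, synth_ref


class TestParsing:
    def test_kp079_variants_and_missing_hvr2(self, uruguay_panel):
        h = uruguay_panel.get("KP079")
        assert sorted(v.label for v in h.variants) == [
            "16051G", "16223T", "16298C", "16325C", "16327T", "7697A",
        ]
        # the HVR-II columns (np 64..350) are blank: one missing interval
        assert not h.covers(64) and not h.covers(194) and not h.covers(350)
        assert h.covers(7697) and h.covers(16051)

    def test_all_dots_row_is_reference(self):
        text = (
            "Sample ID\t100\t200\n"
            "rCRS\tA\tC\n"
            "S1\t.\t.\n"
        )
        panel = parse_variant_table(text)
        h = panel.get("S1")
        assert h.variants == frozenset()
        assert h.covered_regions == (FULL_RANGE,)

    def test_kc161_vs_kc163_differ_at_two_keys(self, uruguay_panel):
        d, keys = pairwise_distance(
            uruguay_panel.get("KC161"), uruguay_panel.get("KC163")
        )
        assert d == 2
        assert keys == [("sub", 195), ("ins", 310, 1)]

    def test_unknown_symbol_names_row_and_column(self):
        text = "Sample ID\t100\nrCRS\tA\nS1\t?\n"
        with pytest.raises(ValueError, match="row S1, column 100"):
            parse_variant_table(text)

    def test_duplicate_position_column_rejected(self):
        text = "Sample ID\t100\t100\nrCRS\tA\tA\nS1\t.\t.\n"
        with pytest.raises(ValueError, match="duplicate position column"):
            parse_variant_table(text)

    def test_cell_equal_to_reference_warns_without_variant(self):
        text = "Sample ID\t100\nrCRS\tA\nS1\tA\n"
        with pytest.warns(UserWarning, match="equals the reference"):
            panel = parse_variant_table(text)
        assert panel.get("S1").variants == frozenset()

    def test_parse_serialize_parse_idempotent(self, uruguay_panel):
        once = serialize_variant_table(uruguay_panel)
        again = serialize_variant_table(parse_variant_table(once))
        assert once == again
        reparsed = parse_variant_table(once)
        for h in uruguay_panel.haplotypes:
            r = reparsed.get(h.id)
            assert r.variants == h.variants
            assert r.covered_regions == h.covered_regions

    def test_json_round_trip_lossless(self, uruguay_panel):
        clone = HaploPanel.from_json(uruguay_panel.to_json())
        assert clone.columns == uruguay_panel.columns
        for h in uruguay_panel.haplotypes:
            c = clone.get(h.id)
            assert (c.variants, c.covered_regions, c.population_id) == (
                h.variants, h.covered_regions, h.population_id
            )


class TestTrim:
    def test_kc004_trimmed_to_network_window(self, uruguay_panel):
        trimmed = trim_to_regions(uruguay_panel, [HVR1_NETWORK])
        h = trimmed.get("KC004")
        assert sorted(v.label for v in h.variants) == [
            "16051G", "16223T", "16287T", "16298C", "16311C", "16325C", "16327T",
        ]
        assert h.covered_regions == (HVR1_NETWORK,)

    def test_trim_to_full_range_is_identity(self, uruguay_panel):
        trimmed = trim_to_regions(uruguay_panel, [FULL_RANGE])
        for h in uruguay_panel.haplotypes:
            t = trimmed.get(h.id)
            assert t.variants == h.variants
            assert t.covered_regions == h.covered_regions

    def test_fully_missing_haplotype_retained_and_flagged(self):
        h = Haplotype("gone", frozenset(), (Region(100, 200),))
        panel = HaploPanel([h])
        trimmed = trim_to_regions(panel, [Region(300, 400)])
        t = trimmed.get("gone")
        assert t.flagged and t.fully_missing and not t.variants

    def test_trim_composes_as_intersection(self, uruguay_panel):
        r1, r2 = Region(16000, 16365), Region(16051, 16500)
        via_two = trim_to_regions(trim_to_regions(uruguay_panel, [r1]), [r2])
        direct = trim_to_regions(uruguay_panel, [Region(16051, 16365)])
        for h in direct.haplotypes:
            assert via_two.get(h.id).variants == h.variants
            assert via_two.get(h.id).covered_regions == h.covered_regions

    def test_empty_region_list_rejected(self, uruguay_panel):
        with pytest.raises(ValueError):
            trim_to_regions(uruguay_panel, [])


class TestDistance:
    def test_self_distance_zero(self, uruguay_panel):
        for h in uruguay_panel.haplotypes:
            d, keys = pairwise_distance(h, h)
            assert d == 0 and keys == []

    def test_kc043_vs_kc150_uniform_weights(self, uruguay_panel):
        d, keys = pairwise_distance(
            uruguay_panel.get("KC043"), uruguay_panel.get("KC150")
        )
        # 290-291 deletions are shared, hence merged runs produce no key;
        # the five differing keys found by column-wise diff of the table
        assert keys == [
            ("sub", 350), ("sub", 16259), ("sub", 16266),
            ("sub", 16271), ("sub", 16311),
        ]
        assert d == len(keys)

    def test_contiguous_deletion_run_counts_once(self):
        base = Haplotype("a", frozenset())
        two_dels = Haplotype(
            "b",
            frozenset(
                {
                    Variant(290, "deletion", ref_allele="A"),
                    Variant(291, "deletion", ref_allele="A"),
                }
            ),
        )
        d, keys = pairwise_distance(base, two_dels)
        assert d == 1 and keys == [("del", 290, 291)]
        d2, keys2 = pairwise_distance(
            base, two_dels, merge_contiguous_deletions=False
        )
        assert d2 == 2 and keys2 == [("del", 290, 290), ("del", 291, 291)]

    def test_comparison_restricted_to_joint_coverage(self, uruguay_panel):
        # KP079 lacks HVR-II data, so its many HVR-II differences from KC004
        # must not count; only covered differing sites remain
        d, keys = pairwise_distance(
            uruguay_panel.get("KP079"), uruguay_panel.get("KC004")
        )
        assert all(k[1] >= 7697 for k in keys)

    def test_excluded_sites_are_ignored(self, uruguay_panel):
        a, b = uruguay_panel.get("KC043"), uruguay_panel.get("KC150")
        d, keys = pairwise_distance(a, b, excluded={16311, 350})
        assert ("sub", 16311) not in keys and ("sub", 350) not in keys
        assert d == 3

    @settings(derandomize=True, max_examples=60)
    @given(
        st.tuples(
            st.text(alphabet="01", min_size=6, max_size=6),
            st.text(alphabet="01", min_size=6, max_size=6),
            st.text(alphabet="01", min_size=6, max_size=6),
        )
    )
    def test_metric_properties_on_substitution_haplotypes(self, bits):
        h1, h2, h3 = (hap_from_bits(f"h{i}", b) for i, b in enumerate(bits))
        d12, k12 = pairwise_distance(h1, h2)
        d21, _ = pairwise_distance(h2, h1)
        d13, _ = pairwise_distance(h1, h3)
        d23, _ = pairwise_distance(h2, h3)
        assert d12 == d21 >= 0
        assert (d12 == 0) == (bits[0] == bits[1])
        assert d13 <= d12 + d23


class TestFasta:
    REF = "".join(synth_ref(p) for p in range(101, 111))
    REGION = Region(101, 110)

    def test_reference_haplotype_round_trips_verbatim(self):
        panel = HaploPanel([Haplotype("ref_like", frozenset())])
        out = export_fasta(panel, self.REF, self.REGION)
        assert out.splitlines()[1] == self.REF

    def test_single_substitution_at_region_start(self):
        v = Variant(101, "substitution", synth_ref(101), "T")
        panel = HaploPanel([Haplotype("s", frozenset({v}))])
        seq = export_fasta(panel, self.REF, self.REGION).splitlines()[1]
        assert seq[0] == "T" and seq[1:] == self.REF[1:]

    def test_indels_and_missing_data(self):
        vs = {
            Variant(103, "deletion", ref_allele=synth_ref(103)),
            Variant(105, "insertion", derived_allele="C"),
        }
        h = Haplotype("x", frozenset(vs), (Region(101, 108),))
        seq = export_fasta(HaploPanel([h]), self.REF, self.REGION).splitlines()[1]
        expect = (
            self.REF[:2] + self.REF[3:5] + "C" + self.REF[5:8] + "NN"
        )
        assert seq == expect

    def test_round_trip_recovers_substitution_variants(self):
        h = hap_from_bits("rt", "010011", sites=list(range(101, 107)))
        panel = HaploPanel([h])
        ref = "".join(synth_ref(p) for p in range(101, 107))
        region = Region(101, 106)
        seq = export_fasta(panel, ref, region).splitlines()[1]
        assert diff_against_reference(seq, ref, region) == h.variants

    def test_variant_outside_region_is_an_error(self):
        h = hap_from_bits("bad", "1", sites=[200])
        with pytest.raises(ValueError, match="outside"):
            export_fasta(HaploPanel([h]), self.REF, self.REGION)
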
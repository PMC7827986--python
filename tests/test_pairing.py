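"""Replicate pair extraction filters, concordance, and the discordance
tables, including the published-count arithmetic they must reproduce."""

import numpy as np
import pytest

from teaudit import (
    AMBIGUOUS,
    GenomeInterval,
    SegmentAlignment,
    TEAnnotation,
    extract_te_pairs,
    label_concordance,
    pair_by_overlap,
    summarize_discordance,
)


def _anno(chrom, start, end, subfamily, family="Alu", source_id=""):
    return TEAnnotation(
        GenomeInterval(chrom, start, end), family, subfamily, source_id=source_id
    )


def _gapless_segment(length=1000, seed=0):
    rng = np.random.default_rng(seed)
    row = "".join(rng.choice(list("ACGT"), size=length))
    return SegmentAlignment(
        "seg",
        GenomeInterval("segA", 0, length),
        GenomeInterval("segB", 0, length),
        row,
        row,
    )


class TestExtractTePairs:
    def test_no_annotations_no_pairs(self):
        assert extract_te_pairs(_gapless_segment(), [], []) == []

    def test_filters_drop_short_and_low_coverage(self):
        seg = _gapless_segment()
        annos_a = [
            _anno("segA", 100, 400, "AluSx", source_id="full_a"),
            _anno("segA", 450, 490, "AluSz", source_id="short_a"),
            _anno("segA", 600, 700, "AluY", source_id="shift_a"),
        ]
        annos_b = [
            _anno("segB", 100, 400, "AluSx", source_id="full_b"),
            _anno("segB", 450, 490, "AluSz", source_id="short_b"),
            _anno("segB", 640, 740, "AluY", source_id="shift_b"),  # 60% coverage
        ]
        dropped = []
        kept = extract_te_pairs(seg, annos_a, annos_b, dropped=dropped)
        assert [p.anno_a.source_id for p in kept] == ["full_a"]
        failures = {p.anno_a.source_id: p.failed_rules() for p in dropped}
        assert failures["short_a"] == ["min_length"]
        assert failures["shift_a"] == ["coverage"]

    def test_multiplicity_excludes_locus(self):
        seg = _gapless_segment()
        annos_a = [_anno("segA", 100, 500, "AluSx")]
        annos_b = [
            _anno("segB", 100, 290, "AluSx"),
            _anno("segB", 310, 500, "AluSz"),
        ]
        dropped = []
        kept = extract_te_pairs(seg, annos_a, annos_b, dropped=dropped)
        assert kept == []
        assert all("multiplicity" in p.failed_rules() for p in dropped)

    def test_ambiguous_member_dropped(self):
        seg = _gapless_segment()
        kept = extract_te_pairs(
            seg,
            [_anno("segA", 100, 400, "AluY")],
            [_anno("segB", 100, 400, AMBIGUOUS)],
        )
        assert kept == []

    def test_contiguity_interrupted_by_long_indel_block(self):
        # 35-column insertion in row_a inside the TE span: row_b gapped there
        rng = np.random.default_rng(3)
        left = "".join(rng.choice(list("ACGT"), size=200))
        insert = "".join(rng.choice(list("ACGT"), size=35))
        right = "".join(rng.choice(list("ACGT"), size=200))
        seg = SegmentAlignment(
            "seg",
            GenomeInterval("segA", 0, 435),
            GenomeInterval("segB", 0, 400),
            left + insert + right,
            left + "-" * 35 + right,
        )
        annos_a = [_anno("segA", 50, 400, "AluSx")]
        annos_b = [_anno("segB", 50, 365, "AluSx")]
        dropped = []
        kept = extract_te_pairs(seg, annos_a, annos_b, dropped=dropped)
        assert kept == []
        assert "contiguity" in dropped[0].failed_rules()
        # a 30-column block is tolerated at the default threshold
        seg_ok = SegmentAlignment(
            "seg",
            GenomeInterval("segA", 0, 430),
            GenomeInterval("segB", 0, 400),
            left + insert[:30] + right,
            left + "-" * 30 + right,
        )
        assert len(extract_te_pairs(seg_ok, [_anno("segA", 50, 400, "AluSx")],
                                    [_anno("segB", 50, 365, "AluSx")])) == 1

    def test_annotation_outside_segment_rejected(self):
        seg = _gapless_segment(length=500)
        with pytest.raises(ValueError, match="outside"):
            extract_te_pairs(seg, [_anno("segA", 400, 600, "AluY")], [])

    def test_filter_order_independence(self):
        """Rules are conjunctive: permuting annotation order does not
        change the retained pair set."""
        seg = _gapless_segment()
        annos_a = [
            _anno("segA", 100, 400, "AluSx", source_id="p1a"),
            _anno("segA", 420, 460, "AluSz", source_id="p2a"),
            _anno("segA", 500, 800, "AluY", source_id="p3a"),
        ]
        annos_b = [
            _anno("segB", 100, 400, "AluSz", source_id="p1b"),
            _anno("segB", 420, 460, "AluSz", source_id="p2b"),
            _anno("segB", 500, 800, "AluY", source_id="p3b"),
        ]
        reference = {
            (p.anno_a.source_id, p.anno_b.source_id)
            for p in extract_te_pairs(seg, annos_a, annos_b)
        }
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm_a = [annos_a[i] for i in rng.permutation(3)]
            perm_b = [annos_b[i] for i in rng.permutation(3)]
            got = {
                (p.anno_a.source_id, p.anno_b.source_id)
                for p in extract_te_pairs(seg, perm_a, perm_b)
            }
            assert got == reference


class TestPairByOverlap:
    def test_identical_sets_all_pair(self):
        annos = [_anno("chr1", 100, 400, "AluSx"), _anno("chr1", 600, 900, "AluY")]
        kept = pair_by_overlap(annos, list(annos))
        assert len(kept) == 2
        assert all(p.anno_a.interval == p.anno_b.interval for p in kept)

    def test_no_overlap_unpaired(self):
        kept = pair_by_overlap(
            [_anno("chr1", 100, 400, "AluSx")], [_anno("chr1", 500, 800, "AluSx")]
        )
        assert kept == []

    def test_one_to_many_excluded_by_multiplicity(self):
        mapped = [_anno("chr1", 100, 600, "AluSx")]
        targets = [
            _anno("chr1", 100, 400, "AluSx"),  # 60% of mapped
            _anno("chr1", 400, 600, "AluSz"),  # 40% of mapped
        ]
        dropped = []
        assert pair_by_overlap(mapped, targets, dropped=dropped) == []
        assert all("multiplicity" in p.failed_rules() for p in dropped)


class TestLabelConcordance:
    def test_same_subfamily_concordant(self):
        pair = extract_te_pairs(
            _gapless_segment(),
            [_anno("segA", 100, 400, "AluSx")],
            [_anno("segB", 100, 400, "AluSx")],
        )[0]
        assert label_concordance(pair).concordant is True

    def test_different_subfamilies_discordant(self):
        pair = extract_te_pairs(
            _gapless_segment(),
            [_anno("segA", 100, 400, "AluSx")],
            [_anno("segB", 100, 400, "AluSz")],
        )[0]
        assert label_concordance(pair).concordant is False

    def test_ambiguous_member_is_an_error(self):
        from teaudit.pairing import TEPair

        pair = TEPair(_anno("a", 0, 10, "AluY"), _anno("b", 0, 10, AMBIGUOUS))
        with pytest.raises(ValueError, match="AMBIGUOUS"):
            label_concordance(pair)


def _synthetic_pairs(spec):
    """Build labeled pairs from (subfamily_a, subfamily_b, count) triples."""
    from teaudit.pairing import TEPair

    pairs = []
    for sub_a, sub_b, count in spec:
        for _ in range(count):
            pair = TEPair(_anno("a", 0, 300, sub_a), _anno("b", 0, 300, sub_b))
            pairs.append(label_concordance(pair))
    return pairs


class TestSummarizeDiscordance:
    def test_published_family_rate_arithmetic(self):
        # 6,615 L1 pairs of which 933 discordant -> 14.1%
        pairs = _synthetic_pairs(
            [("L1PA2", "L1PA2", 6615 - 933), ("L1PA2", "L1PA3", 933)]
        )
        family_map = {"L1PA2": "L1", "L1PA3": "L1"}
        type_map = {"L1PA2": "L1", "L1PA3": "L1"}
        summary = summarize_discordance(pairs, family_map, type_map)
        row = summary.by_family.iloc[0]
        assert row.n_pairs == 6615
        assert row.n_discordant == 933
        assert round(row.percent_discordant, 1) == 14.1

    def test_cross_table_row_percent_and_symmetry(self):
        # two types with one within-type discordant class each plus
        # symmetric cross-type counts
        spec = [
            ("J1", "J1", 40),   # concordant J
            ("S1", "S1", 60),   # concordant S
            ("J1", "J2", 10),   # within-type J discordant
            ("J1", "S1", 5),    # cross-type
            ("J1", "X1", 3),    # other
            ("S1", "S2", 20),
        ]
        type_map = {"J1": "J", "J2": "J", "S1": "S", "S2": "S", "X1": "X"}
        family_map = {k: "Alu" for k in type_map}
        summary = summarize_discordance(
            pairs := _synthetic_pairs(spec), family_map, type_map, types=["J", "S"]
        )
        table = summary.cross_table.set_index("type")
        assert table.loc["J", "nonmatch_J"] == 10
        assert table.loc["J", "nonmatch_S"] == 5
        assert table.loc["S", "nonmatch_J"] == 5  # symmetric cross-type cell
        assert table.loc["J", "other"] == 3
        assert table.loc["J", "mismatch_percent"] == pytest.approx(
            100 * (10 + 5 + 3) / (40 + 10 + 5 + 3)
        )

    def test_empty_group_row_omitted(self):
        pairs = _synthetic_pairs([("J1", "J1", 5)])
        summary = summarize_discordance(
            pairs, {"J1": "Alu"}, {"J1": "J"}, types=["J", "S"]
        )
        assert list(summary.cross_table["type"]) == ["J"]

    def test_unmapped_subfamily_raises_with_name(self):
        pairs = _synthetic_pairs([("J1", "J1", 1)])
        with pytest.raises(KeyError, match="J1"):
            summarize_discordance(pairs, {}, {"J1": "J"})
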
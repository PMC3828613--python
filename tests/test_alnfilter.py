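"""Alignment block extraction, filtering funnel and compartments."""

import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from intervaltree import IntervalTree

from exorna.alnfilter import (
    AlignmentRecord,
    FilterFunnel,
    apply_quality_length_filters,
    assign_compartment,
    blocks_from_cigar,
    build_exon_index,
    compartment_counts,
    filter_funnel_report,
    load_alignments,
    remove_multimapped,
    run_filters,
)
from exorna.annotation import TranscriptModel

HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"


def sam_line(name, pos, cigar, mapq=60, flag=0, tags=""):
    return (
        f"{name}\t{flag}\tchr1\t{pos + 1}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*{tags}\n"
    )


def write_sam(tmp_path, lines, name="t.sam"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(lines))
    return str(path)


def cigar_walk_oracle(cigar, pos):
    """Independent CIGAR walker over the text representation."""
    blocks, start, cur = [], pos, pos
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        length = int(length)
        if op in "MD=X":
            cur += length
        elif op == "N":
            if cur > start:
                blocks.append((start, cur))
            start = cur = cur + length
    if cur > start:
        blocks.append((start, cur))
    return blocks


class TestLoadAlignments:
    def test_spliced_cigar_splits_blocks(self, tmp_path):
        path = write_sam(tmp_path, [sam_line("r1", 0, "10M100N10M")])
        (rec,) = load_alignments(path)
        assert rec.blocks == ((0, 10), (110, 120))

    def test_deletion_stays_in_block(self, tmp_path):
        path = write_sam(tmp_path, [sam_line("r1", 0, "5M2D5M")])
        (rec,) = load_alignments(path)
        assert rec.blocks == ((0, 12),)

    def test_header_only_file_empty(self, tmp_path):
        assert load_alignments(write_sam(tmp_path, [])) == []

    def test_soft_clips_and_insertions_ignored(self, tmp_path):
        path = write_sam(tmp_path, [sam_line("r1", 10, "3S5M2I5M4S")])
        (rec,) = load_alignments(path)
        assert rec.blocks == ((10, 20),) and rec.aligned_length == 10

    def test_nh_tag_sets_multiplicity(self, tmp_path):
        path = write_sam(tmp_path, [sam_line("r1", 0, "30M", tags="\tNH:i:2")])
        (rec,) = load_alignments(path)
        assert rec.multiplicity == 2

    def test_multiplicity_inferred_by_grouping(self, tmp_path):
        path = write_sam(
            tmp_path, [sam_line("r1", 0, "30M"), sam_line("r1", 500, "30M", flag=256)]
        )
        recs = load_alignments(path)
        assert [r.multiplicity for r in recs] == [2, 2]

    def test_random_cigars_match_walker_oracle(self, tmp_path):
        rng = np.random.default_rng(4)
        ops = ["M", "I", "D", "N", "S", "=", "X"]
        lines, expected = [], []
        for i in range(1000):
            parts, mid = [], []
            # S only allowed at the ends
            if rng.random() < 0.3:
                parts.append(f"{rng.integers(1, 5)}S")
            mid.append(f"{rng.integers(1, 50)}M")
            for _ in range(int(rng.integers(0, 4))):
                op = ops[int(rng.integers(0, 4))]  # M I D N
                mid.append(f"{rng.integers(1, 50)}{op}")
                mid.append(f"{rng.integers(1, 50)}M")
            parts.extend(mid)
            if rng.random() < 0.3:
                parts.append(f"{rng.integers(1, 5)}S")
            cigar = "".join(parts)
            pos = int(rng.integers(0, 1000))
            lines.append(sam_line(f"r{i}", pos, cigar))
            expected.append(tuple(cigar_walk_oracle(cigar, pos)))
        recs = load_alignments(write_sam(tmp_path, lines))
        assert len(recs) == 1000
        for rec, exp in zip(recs, expected):
            assert rec.blocks == exp
            assert rec.aligned_length == sum(e - s for s, e in exp)


def record(name="r", blocks=((0, 30),), mapq=60, mult=1):
    return AlignmentRecord(name, "chr1", "+", tuple(blocks), mapq, mult)


class TestFilters:
    def test_multimapped_removed_entirely(self):
        kept, removed = remove_multimapped([record(mult=2), record("r2", mult=2)])
        assert kept == [] and len(removed) == 2

    def test_unique_record_kept(self):
        kept, removed = remove_multimapped([record(mult=1)])
        assert len(kept) == 1 and removed == []

    @pytest.mark.parametrize(
        "aligned_len,mapq,expect_kept,expect_short,expect_lowq",
        [
            (19, 60, 0, 1, 0),
            (20, 60, 1, 0, 0),
            (30, 9, 0, 0, 1),
            (30, 10, 1, 0, 0),
            (19, 9, 0, 1, 0),  # both failures count once, under the length stage
        ],
    )
    def test_length_and_mapq_boundaries(
        self, aligned_len, mapq, expect_kept, expect_short, expect_lowq
    ):
        recs = [record(blocks=((0, aligned_len),), mapq=mapq)]
        kept, n_short, n_lowq = apply_quality_length_filters(recs)
        assert (len(kept), n_short, n_lowq) == (expect_kept, expect_short, expect_lowq)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 3),  # multiplicity - 1 capped
                st.integers(1, 40),  # aligned length
                st.integers(0, 60),  # mapq
            ),
            max_size=60,
        )
    )
    def test_funnel_conservation_property(self, raw):
        recs = [
            record(f"r{i}", blocks=((0, ln),), mapq=q, mult=m + 1)
            for i, (m, ln, q) in enumerate(raw)
        ]
        _, funnel = run_filters(recs)
        funnel.validate()
        assert funnel.input_records == len(recs)


EXON_MODEL = TranscriptModel(
    "T1", "G1", "chr1", "+", "lincRNA", exons=((140, 200), (300, 400))
)


class TestCompartments:
    @pytest.fixture()
    def index(self):
        return build_exon_index([EXON_MODEL])

    def test_one_base_overlap_is_known_gene(self, index):
        assert assign_compartment(record(blocks=((100, 150),)), index) == "known_gene"

    def test_half_open_adjacency_is_unknown(self, index):
        model = TranscriptModel("T2", "G2", "chr1", "+", "lincRNA", exons=((150, 200),))
        idx = build_exon_index([model])
        assert assign_compartment(record(blocks=((100, 150),)), idx) == "unknown"

    def test_any_block_rule_for_spliced_records(self, index):
        rec = record(blocks=((10, 40), (150, 180)))
        assert assign_compartment(rec, index) == "known_gene"

    def test_rrna_partition_membership_wins(self, index):
        rec = record(name="rr1", blocks=((150, 180),))
        assert assign_compartment(rec, index, frozenset({"rr1"})) == "rRNA"

    def test_labels_partition_records(self, index):
        rng = np.random.default_rng(8)
        recs = [
            record(f"r{i}", blocks=((int(s), int(s) + 30),))
            for i, s in enumerate(rng.integers(0, 900, size=50))
        ]
        df = compartment_counts(recs, index)
        assert df["reads"].sum() == len(recs)


class TestFunnelReport:
    def test_counts_and_percentages(self):
        funnel = FilterFunnel(100, 10, 5, 5, 80)
        df = filter_funnel_report(funnel).set_index("stage")
        assert df.loc["kept", "records"] == 80
        assert df.loc["kept", "percent_of_input"] == 80.0

    def test_empty_input_reports_zero(self):
        df = filter_funnel_report(FilterFunnel()).set_index("stage")
        assert (df["percent_of_input"] == 0.0).all()

    def test_inconsistent_funnel_rejected(self):
        with pytest.raises(ValueError, match="conserve"):
            filter_funnel_report(FilterFunnel(100, 1, 1, 1, 80))

    def test_percentages_account_for_all_removals(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            recs = [
                record(
                    f"r{i}",
                    blocks=((0, int(rng.integers(1, 40))),),
                    mapq=int(rng.integers(0, 40)),
                    mult=int(rng.integers(1, 3)),
                )
                for i in range(int(rng.integers(0, 30)))
            ]
            _, funnel = run_filters(recs)
            df = filter_funnel_report(funnel).set_index("stage")
            removed = df.loc[
                ["removed_multimapped", "removed_short", "removed_low_mapq", "kept"],
                "records",
            ].sum()
            assert removed == funnel.input_records
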
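"""Coverage fractions, detection rules and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exorna.annotation import TranscriptModel
from exorna.covdetect import (
    CoverageResult,
    DetectionCall,
    biotype_summary,
    detect_cellular,
    detect_exosomal,
    gene_level_detect,
    overlap_sets,
    transcript_coverage,
)

CODING = TranscriptModel(
    "T1", "G1", "chr1", "+", "protein_coding",
    exons=((50, 250),), cds=((100, 200),),
)
NONCODING = TranscriptModel(
    "N1", "G2", "chr1", "+", "lincRNA", exons=((100, 200), (300, 400)),
)


def per_base_oracle(blocks, targets):
    """Boolean per-base union coverage."""
    hi = max(e for _, e in targets)
    mask = np.zeros(hi, dtype=bool)
    tgt = np.zeros(hi, dtype=bool)
    for s, e in targets:
        tgt[s:e] = True
    for s, e in blocks:
        mask[s:min(e, hi)] = True
    return int((mask & tgt).sum())


class TestTranscriptCoverage:
    def test_partial_block_fraction(self):
        cov = transcript_coverage([(100, 191)], CODING, "CDS")
        assert cov.covered == 91 and cov.fraction == pytest.approx(0.91)

    def test_no_blocks_zero_fraction(self):
        assert transcript_coverage([], CODING, "CDS").fraction == 0.0

    def test_overlapping_blocks_counted_once(self):
        cov = transcript_coverage([(100, 150), (140, 200)], CODING, "CDS")
        assert cov.covered == 100 and cov.fraction == 1.0

    def test_cds_target_for_noncoding_rejected(self):
        with pytest.raises(ValueError, match="non-coding"):
            transcript_coverage([(100, 150)], NONCODING, "CDS")

    def test_random_fixtures_match_per_base_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n_ex = int(rng.integers(1, 5))
            cursor, exons = 0, []
            for _ in range(n_ex):
                cursor += int(rng.integers(1, 200))
                length = int(rng.integers(1, 300))
                exons.append((cursor, cursor + length))
                cursor += length
            model = TranscriptModel(
                "T", "G", "chr1", "+", "lincRNA", exons=tuple(exons)
            )
            blocks = []
            for _ in range(int(rng.integers(0, 12))):
                s = int(rng.integers(0, cursor))
                blocks.append((s, s + int(rng.integers(1, 120))))
            cov = transcript_coverage(blocks, model, "exon")
            assert cov.covered == per_base_oracle(blocks, exons)

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)), max_size=15
        )
    )
    def test_monotonicity_adding_blocks(self, raw):
        blocks = [(s, s + ln) for s, ln in raw]
        prev = 0.0
        for i in range(len(blocks) + 1):
            frac = transcript_coverage(blocks[:i], CODING, "CDS").fraction
            assert frac >= prev - 1e-12
            prev = frac


def cov(tid, fraction, target="CDS", length=1000):
    return CoverageResult(tid, target, length, int(round(fraction * length)))


class TestDetectionRules:
    def test_cellular_above_threshold_detected(self):
        assert detect_cellular(cov("T1", 0.91), "cell").detected

    def test_cellular_low_coverage_not_detected(self):
        assert not detect_cellular(cov("T1", 0.22), "cell").detected

    def test_cellular_boundary_is_strict(self):
        assert not detect_cellular(cov("T1", 0.90), "cell").detected

    def test_exosomal_pooled_gate_and_sample_gate(self):
        calls = detect_exosomal(
            cov("T1", 0.92), {"s1": cov("T1", 0.6), "s2": cov("T1", 0.3)}
        )
        assert {c.sample: c.detected for c in calls} == {"s1": True, "s2": False}

    def test_exosomal_pooled_gate_fails(self):
        calls = detect_exosomal(
            cov("T1", 0.85), {"s1": cov("T1", 0.8), "s2": cov("T1", 0.8)}
        )
        assert not any(c.detected for c in calls)

    def test_exosomal_both_detected(self):
        calls = detect_exosomal(
            cov("T1", 1.0), {"s1": cov("T1", 0.51), "s2": cov("T1", 0.51)}
        )
        assert all(c.detected for c in calls)

    def test_pooled_below_sample_rejected(self):
        with pytest.raises(ValueError, match="dominate"):
            detect_exosomal(cov("T1", 0.5), {"s1": cov("T1", 0.8)})


def call(tid, detected, frac, sample="s"):
    return DetectionCall(tid, sample, detected, "cellular_90", frac)


MODELS = [
    TranscriptModel("A1", "GA", "chr1", "+", "protein_coding",
                    exons=((0, 100),), cds=((10, 90),)),
    TranscriptModel("A2", "GA", "chr1", "+", "protein_coding",
                    exons=((0, 100),), cds=((20, 80),)),
    TranscriptModel("A3", "GA", "chr1", "+", "protein_coding",
                    exons=((0, 100),), cds=((30, 70),)),
    TranscriptModel("B1", "GB", "chr1", "+", "snoRNA", exons=((200, 300),)),
    TranscriptModel("B2", "GB", "chr1", "+", "snRNA", exons=((200, 320),)),
]


class TestGeneLevel:
    def test_any_isoform_detects_gene(self):
        calls = [call("A1", True, 0.95), call("A2", False, 0.2)]
        df = gene_level_detect(calls, MODELS)
        assert df["gene_id"].tolist() == ["GA"]

    def test_all_isoforms_below_threshold(self):
        calls = [call("A1", False, 0.1), call("A2", False, 0.2)]
        assert gene_level_detect(calls, MODELS).empty

    def test_max_over_isoforms_governs(self):
        fractions = {"A1": 0.4, "A2": 0.95, "A3": 0.6}
        calls = [call(t, f > 0.9, f) for t, f in fractions.items()]
        detected = not gene_level_detect(calls, MODELS).empty
        assert detected == (max(fractions.values()) > 0.9)

    def test_conflicting_noncoding_biotypes_warn_and_pick_smallest(self):
        calls = [call("B1", True, 1.0), call("B2", True, 1.0)]
        with pytest.warns(UserWarning, match="conflicting"):
            df = gene_level_detect(calls, MODELS)
        assert df.loc[0, "biotype"] == "snRNA"  # lexicographically smallest


def gene_df(n_coding, n_noncoding, biotype="snoRNA"):
    rows = [
        {"gene_id": f"c{i}", "gene_name": f"c{i}", "biotype": "protein_coding"}
        for i in range(n_coding)
    ] + [
        {"gene_id": f"n{i}", "gene_name": f"n{i}", "biotype": biotype}
        for i in range(n_noncoding)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "biotype"])


class TestBiotypeSummary:
    def test_published_cellular_split(self):
        class_table, _ = biotype_summary({"cell": gene_df(3115, 317)})
        row = class_table.set_index("transcript_type")["cell"]
        assert row["protein_coding"] == 90.8
        assert row["non_coding"] == 9.2

    def test_single_coding_gene(self):
        class_table, nc = biotype_summary({"s": gene_df(1, 0)})
        row = class_table.set_index("transcript_type")["s"]
        assert row["protein_coding"] == 100.0 and row["non_coding"] == 0.0
        assert nc.empty

    def test_even_split(self):
        class_table, _ = biotype_summary({"s": gene_df(50, 50)})
        row = class_table.set_index("transcript_type")["s"]
        assert row["protein_coding"] == 50.0 and row["non_coding"] == 50.0

    def test_noncoding_counts_sorted_descending(self):
        df = pd.concat([gene_df(0, 5, "snoRNA"), gene_df(0, 2, "miRNA")])
        df["gene_id"] = [f"g{i}" for i in range(len(df))]
        _, nc = biotype_summary({"s": df})
        assert nc["biotype"].tolist() == ["snoRNA", "miRNA"]
        assert nc["s"].tolist() == [5, 2]


class TestOverlapSets:
    def test_identical_sets_full_overlap(self):
        out = overlap_sets({"cell": {"a", "b"}, "exo": {"a", "b"}}, cellular="cell")
        assert out["pct_in_cellular"]["exo"] == 100.0

    def test_disjoint_sets_zero_overlap(self):
        out = overlap_sets({"cell": {"a"}, "exo": {"b"}}, cellular="cell")
        assert out["pairwise"][("cell", "exo")] == 0
        assert out["pct_in_cellular"]["exo"] == 0.0

    def test_subset_arithmetic(self):
        out = overlap_sets(
            {"cell": {"a", "b", "c", "d"}, "exo": {"a", "b", "c"}}, cellular="cell"
        )
        assert out["pairwise"][("cell", "exo")] == 3
        assert out["pct_in_cellular"]["exo"] == 100.0

    def test_threeway_intersection(self):
        out = overlap_sets(
            {"cell": {"a", "b"}, "e1": {"a", "b"}, "e2": {"a"}}, cellular="cell"
        )
        assert out["threeway"] == 1
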
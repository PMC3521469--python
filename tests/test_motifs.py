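from collections import Counter

import pytest

from srpmotif.motifs import (
    ConservationProfile,
    InterfaceMSA,
    build_msa,
    consistency_percent,
    conservation_grades,
    emit_pattern,
    motifs_per_complex,
    overlapped_ratio,
    pattern_matches,
    prosite_to_regex,
    read_rate4site_grades,
)


def msa_from_rows(rows, start=0):
    """One-segment MSA literal for tests; first row is the query."""
    length = len(rows[0])
    row_ids = [f"r{i}" for i in range(len(rows))]
    return InterfaceMSA(
        query_id="r0",
        segments=[(start, start + length - 1)],
        row_ids=row_ids,
        rows={rid: [row] for rid, row in zip(row_ids, rows)},
    )


class TestBuildMSA:
    def test_self_target_gives_identical_rows(self, pipeline_result):
        msa = pipeline_result.msa
        query_row = msa.rows[msa.query_id]
        assert msa.rows["query0"] == query_row
        assert all("-" not in seg for seg in query_row)

    def test_missing_segment_row_is_all_gaps(self, synthetic_world):
        from srpmotif.superpose import PolypharmTarget, SegmentAlignment
        import numpy as np

        query, _, db_complexes, _ = synthetic_world
        from srpmotif.binding_interface import contact_residues, extract_segments

        interface = extract_segments(contact_residues(query), len(query.chain))
        lengths = [len(s) for s in interface.segments]
        alignment = SegmentAlignment(
            pairs_per_segment=[
                [(p, p) for p in interface.segments[0].positions],
                [],
                [],
            ],
            segment_lengths=lengths,
        )
        target = PolypharmTarget(
            db_id="partial", rmsd=0.0, avg_aligned_ratio=alignment.avg_aligned_ratio,
            seq_identity_pct=100.0, rotation=np.eye(3), translation=np.zeros(3),
            alignment=alignment,
        )
        msa = build_msa(interface, query.chain, [target], {"partial": query.chain})
        assert set(msa.rows["partial"][1]) == {"-"}
        assert set(msa.rows["partial"][2]) == {"-"}

    def test_columns_match_recount_from_pairings(self, pipeline_result, synthetic_world):
        """Column residue multisets equal a brute-force recount from the
        stored residue pairings."""
        _, _, db_complexes, _ = synthetic_world
        msa = pipeline_result.msa
        for k, (start, end) in enumerate(msa.segments):
            expected = [Counter() for _ in range(end - start + 1)]
            qrow = msa.rows[msa.query_id][k]
            for i, c in enumerate(qrow):
                expected[i][c] += 1
            for target in pipeline_result.targets:
                chain = db_complexes[target.db_id].chain
                covered = set()
                for q_pos, t_pos in target.alignment.pairs_per_segment[k]:
                    expected[q_pos - start][chain.residues[t_pos].aa] += 1
                    covered.add(q_pos - start)
                for i in range(end - start + 1):
                    if i not in covered:
                        expected[i]["-"] += 1
            got = [Counter(col) for col in msa.columns(k)]
            assert got == expected

    def test_zero_targets_rejected(self, synthetic_world):
        from srpmotif.binding_interface import contact_residues, extract_segments

        query, _, _, _ = synthetic_world
        interface = extract_segments(contact_residues(query), len(query.chain))
        with pytest.raises(ValueError, match="no pharma-interface"):
            build_msa(interface, query.chain, [], {})


class TestConservationGrades:
    def test_identical_column_gets_grade_9(self):
        msa = msa_from_rows(["K", "K", "K", "K"])
        assert conservation_grades(msa).grades[0] == 9

    def test_uniform_random_column_gets_low_grade(self, rng):
        rows = ["A"] + ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 1)) for _ in range(40)]
        msa = msa_from_rows([r[0] for r in rows])
        assert conservation_grades(msa).grades[0] <= 2

    def test_adding_query_identical_row_never_lowers_grades(self, pipeline_result):
        msa = pipeline_result.msa
        before = conservation_grades(msa).grades
        extra = InterfaceMSA(
            query_id=msa.query_id,
            segments=msa.segments,
            row_ids=msa.row_ids + ["extra_query_copy"],
            rows={**msa.rows, "extra_query_copy": msa.rows[msa.query_id]},
        )
        after = conservation_grades(extra).grades
        for pos in before:
            assert after[pos] >= before[pos]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            conservation_grades(msa_from_rows(["K"]))

    def test_rate4site_import_round_trips(self):
        text = "# rates\n1 K 9\n2 M 3\n3 S 7\n"
        profile = read_rate4site_grades(text, positions=[10, 11, 12])
        assert profile.method_tag == "rate4site-import"
        assert profile.grades == {10: 9, 11: 3, 12: 7}


class TestEmitPattern:
    def _profile(self, grades):
        return ConservationProfile(grades=grades)

    def test_kmsks_columns_render_published_pattern(self, synthetic_world):
        """Column sets {K},{M},{S},{K},{S,T},{L,K},{G},{N} at conserved
        grades render the classic ATP-binding loop pattern."""
        query, _, _, _ = synthetic_world
        rows = [
            "KMSKSLGN",
            "KMSKSLGN",
            "KMSKTLGN",
            "KMSKSKGN",
            "KMSKTLGN",
        ]
        msa = msa_from_rows(rows)
        from srpmotif.binding_interface import BindingInterface, BindingSegment

        interface = BindingInterface(
            complex_id="q",
            segments=[
                BindingSegment(chain_id="A", start=0, end=7,
                               contact_positions=frozenset({3}), truncated=True)
            ],
        )
        profile = self._profile({i: 9 for i in range(8)})
        (motif,) = emit_pattern(msa, profile, interface)
        assert motif.pattern == "K-M-S-K-[ST]-[LK]-G-N"

    def test_low_grades_compress_to_xn(self):
        msa = msa_from_rows(["A" * 15, "A" * 15])
        from srpmotif.binding_interface import BindingInterface, BindingSegment

        interface = BindingInterface(
            complex_id="q",
            segments=[BindingSegment(chain_id="A", start=0, end=14,
                                     contact_positions=frozenset({7}))],
        )
        profile = self._profile({i: 1 for i in range(15)})
        (motif,) = emit_pattern(msa, profile, interface)
        assert motif.pattern == "x(15)"

    def test_single_x_not_compressed(self):
        msa = msa_from_rows(["AGA", "AGA"], start=0)
        from srpmotif.binding_interface import BindingInterface, BindingSegment

        interface = BindingInterface(
            complex_id="q",
            segments=[BindingSegment(chain_id="A", start=0, end=2,
                                     contact_positions=frozenset({1}), truncated=True)],
        )
        profile = self._profile({0: 9, 1: 1, 2: 9})
        (motif,) = emit_pattern(msa, profile, interface)
        assert motif.pattern == "A-x-A"

    def test_every_emitted_pattern_matches_its_query_sequence(self, pipeline_result):
        """Self-consistency: the query's own sequence must satisfy every
        motif emitted from its interface."""
        query_seq = pipeline_result.query.chain.sequence()
        assert pipeline_result.motifs
        for motif in pipeline_result.motifs:
            start, end = motif.span
            assert pattern_matches(motif.pattern, query_seq[start : end + 1])

    def test_interacting_positions_inside_span(self, pipeline_result):
        for motif in pipeline_result.motifs:
            for p in motif.interacting_positions:
                assert motif.span[0] <= p <= motif.span[1]

    def test_element_count_equals_segment_length(self, pipeline_result):
        for motif in pipeline_result.motifs:
            assert len(motif.elements) == motif.length


class TestPrositeSyntax:
    @pytest.mark.parametrize("pattern,sequence,ok", [
        ("K-M-S-K-[ST]-[LK]-G-N", "KMSKSLGN", True),
        ("K-M-S-K-[ST]-[LK]-G-N", "KMSKTKGN", True),
        ("K-M-S-K-[ST]-[LK]-G-N", "KMSKALGN", False),
        ("x(3)-W", "ABCW", True),
        ("{P}-G", "AG", True),
        ("{P}-G", "PG", False),
    ])
    def test_matcher(self, pattern, sequence, ok):
        assert pattern_matches(pattern, sequence) is ok

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            prosite_to_regex("K-[st]-G")


class TestOverlappedRatio:
    def test_identical_spans(self):
        assert overlapped_ratio((5, 20), (5, 20)) == 1.0

    def test_disjoint_spans(self):
        assert overlapped_ratio((0, 9), (20, 30)) == 0.0

    def test_max_of_both_fractions(self):
        """len 10 vs len 20 with 8 overlapping -> max(0.8, 0.4) = 0.8,
        consistent at the 50% cutoff."""
        ratio = overlapped_ratio((10, 19), (12, 31))
        assert ratio == pytest.approx(0.8)
        assert ratio >= 0.5


class TestSummaries:
    def test_consistency_counter_43_of_66(self):
        flags = [True] * 43 + [False] * 23
        assert consistency_percent(flags) == 65

    def test_motifs_per_complex_rounds_to_nearest(self):
        counts = [4] * 89
        counts[0] = 4 + (356 - 4 * 89)
        assert sum(counts) == 356
        assert motifs_per_complex(counts) == 4
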
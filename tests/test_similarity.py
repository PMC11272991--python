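import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acroid.refdb import ReferenceDB
from acroid.similarity import (
    UNKNOWN_LOCUS,
    AlignmentParams,
    HitTable,
    bit_score,
    local_align,
    read_tabular_hits,
    rotate_to_anchor,
    search,
    verify_locus,
    write_tabular_hits,
)
from conftest import label, make_hit, make_record

DNA_ALPHABET = list("ACGT")


def random_seq(rng, length):
    return "".join(rng.choice(DNA_ALPHABET, length))


def mutate(rng, seq, n_subs):
    out = list(seq)
    for pos in rng.choice(len(seq), n_subs, replace=False):
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


class TestLocalAlign:
    @pytest.mark.parametrize(
        "query, subject, expected",
        [
            ("ACGT", "ACGT", (8, 4, 4)),      # identical
            ("ACGT", "ACGA", (6, 3, 3)),      # local trims terminal mismatch
            ("AAAA", "TTTT", (0, 0, 0)),      # nothing positive
        ],
    )
    def test_hand_checked_alignments(self, query, subject, expected):
        assert local_align(query, subject) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_ambiguity_codes_never_count_as_identity(self):
        # N vs N scores as a mismatch, so the optimum trims it
        raw, ident, length = local_align("ACGTN", "ACGTN")
        assert (raw, ident, length) == (8, 4, 4)

    def test_gap_costs_open_plus_extend_per_column(self):
        # one deletion: 11 matches (22) minus (5 + 1*2); the gapped path
        # ties the ungapped 10-match/1-mismatch path at 17, either is fine
        raw, _, _ = local_align("AAACCCGGGTTT", "AAACCCGGTTT")
        assert raw == 17

    def test_agrees_with_reference_dp_engine(self):
        """Cross-check against an independent exact aligner (scikit-bio's
        pair_align, which uses the same BLAST gap convention)."""
        pair_align = pytest.importorskip("skbio.alignment").pair_align
        from skbio.sequence import DNA, SubstitutionMatrix

        data = np.full((5, 5), -3.0, dtype="float32")
        np.fill_diagonal(data, 2.0)
        data[4, 4] = -3.0
        sub = SubstitutionMatrix("ACGTN", data)
        rng = np.random.default_rng(202)
        for _ in range(60):
            if rng.random() < 0.5:  # equal length, few substitutions
                seq_a = random_seq(rng, int(rng.integers(40, 300)))
                seq_b = mutate(rng, seq_a, int(rng.integers(0, 12)))
            else:  # unrelated, unequal lengths
                seq_a = random_seq(rng, int(rng.integers(10, 150)))
                seq_b = random_seq(rng, int(rng.integers(10, 150)))
            ref = pair_align(
                DNA(seq_a), DNA(seq_b), mode="local", sub_score=sub,
                gap_cost=(5, 2), max_paths=1, atol=0,
            )
            raw, ident, length = local_align(seq_a, seq_b)
            assert raw == int(round(ref.score))
            assert 0 <= ident <= length


class TestBitScore:
    def test_closed_form(self):
        p = AlignmentParams()
        assert bit_score(100, p) == pytest.approx(
            (0.625 * 100 - math.log(0.41)) / math.log(2), abs=1e-9
        )
        assert bit_score(100, p) == pytest.approx(91.455, abs=1e-3)
        assert bit_score(0, p) == pytest.approx(1.286, abs=1e-3)

    @given(s1=st.integers(0, 5000), s2=st.integers(0, 5000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing_in_raw_score(self, s1, s2):
        p = AlignmentParams()
        if s1 < s2:
            assert bit_score(s1, p) < bit_score(s2, p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(match_reward=0)
        with pytest.raises(ValueError):
            AlignmentParams(K=1.5)


class TestSearch:
    def test_identical_record_is_rank_one_at_100(self, tiny_db):
        query = make_record("q", "ACGTACGTACGTACGTACGT", label("xenia"))
        table = search(query, tiny_db)
        assert table.hits[0].pct_identity == 100.0
        assert table.hits[0].subject_id == "a1"

    def test_tied_perfect_hits_ordered_by_subject_id(self, tiny_db):
        query = make_record("q", "ACGTACGTACGTACGTACGT", label("xenia"))
        table = search(query, tiny_db)
        top_bits = table.hits[0].bit_score
        tied = [h for h in table if h.bit_score == top_bits]
        assert [h.subject_id for h in tied] == ["a1", "a2"]
        assert all(h.pct_identity == 100.0 for h in tied)

    def test_exclusion_removes_own_record(self, tiny_db):
        query = tiny_db.get("a1")
        table = search(query, tiny_db, exclude={"a1"})
        assert "a1" not in {h.subject_id for h in table}
        assert table.hits[0].subject_id == "a2"

    def test_empty_db_rejected(self):
        query = make_record("q", "ACGT", label("xenia"))
        with pytest.raises(ValueError):
            search(query, ReferenceDB("L", []))

    def test_matches_brute_force_on_random_dbs(self):
        """Oracle: align against every record independently, keep positive
        scores, sort by the documented key."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            base = random_seq(rng, 150)
            recs = [
                make_record(
                    f"r{i}",
                    mutate(rng, base, int(rng.integers(0, 20))),
                    label(f"sp{i % 3}"),
                )
                for i in range(int(rng.integers(2, 9)))
            ]
            db = ReferenceDB("L", recs)
            query = make_record("q", mutate(rng, base, 3), label("sp0"))
            got = search(query, db, max_hits=100)

            expected = []
            for rec in recs:
                raw, ident, length = local_align(query.sequence, rec.sequence)
                if raw > 0:
                    bits = round(bit_score(raw), 1)
                    pct = round(100.0 * ident / length, 3)
                    expected.append((-bits, -pct, rec.record_id))
            expected.sort()
            assert [
                (-h.bit_score, -h.pct_identity, h.subject_id) for h in got
            ] == expected

    def test_total_order_is_stable_under_permutation(self):
        rng = np.random.default_rng(99)
        base = random_seq(rng, 120)
        recs = [
            make_record(f"r{i}", mutate(rng, base, i % 4), label(f"sp{i % 2}"))
            for i in range(6)
        ]
        query = make_record("q", base, label("sp0"))
        first = search(query, ReferenceDB("L", recs))
        for _ in range(5):
            perm = [recs[i] for i in rng.permutation(len(recs))]
            again = search(query, ReferenceDB("L", perm))
            assert [h.subject_id for h in again] == [
                h.subject_id for h in first
            ]


class TestHitTable:
    def test_duplicate_subject_rejected(self):
        hits = [
            make_hit(label("alpha"), 100.0, 500.0, "s1"),
            make_hit(label("beta"), 99.0, 480.0, "s1"),
        ]
        with pytest.raises(ValueError):
            HitTable("q1", hits)


class TestReadTabularHits:
    HEADER_ROW = "q1\tref|Acropora_millepora\t99.500\t700\t3\t0\t1\t700\t1\t700\t1e-100\t500.0\n"

    def test_best_hsp_per_subject_kept(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1|Acropora_millepora\t99.5\t700\t3\t0\t1\t700\t1\t700\t1e-100\t500.0\n"
            "q1\ts1|Acropora_millepora\t98.0\t650\t9\t0\t1\t650\t1\t650\t1e-90\t480.0\n"
        )
        (table,) = read_tabular_hits(path)
        assert len(table) == 1
        assert table.hits[0].bit_score == 500.0

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert read_tabular_hits(path) == []

    def test_groups_by_query_and_sorts(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1|Acropora_millepora\t99.5\t700\t3\t0\t1\t700\t1\t700\t1e-100\t480.0\n"
            "q1\ts2|Acropora_tenuis\t100.0\t700\t0\t0\t1\t700\t1\t700\t1e-110\t500.0\n"
            "q2\ts1|Acropora_millepora\t97.0\t700\t21\t0\t1\t700\t1\t700\t1e-80\t450.0\n"
        )
        tables = read_tabular_hits(path)
        assert [t.query_id for t in tables] == ["q1", "q2"]
        assert [h.subject_id for h in tables[0]] == [
            "s2|Acropora_tenuis", "s1|Acropora_millepora",
        ]

    def test_species_lookup_beats_header_fallback(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.HEADER_ROW)
        (table,) = read_tabular_hits(
            path, {"ref|Acropora_millepora": label("tenuis")}
        )
        assert table.hits[0].subject_species == label("tenuis")

    def test_unresolved_subject_is_an_error(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\tmystery_subject\t99.5\t700\t3\t0\t1\t700\t1\t700\t1e-100\t500.0\n"
        )
        with pytest.raises(ValueError, match="mystery_subject"):
            read_tabular_hits(path)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            self.HEADER_ROW
            + "q1\tref|Acropora_tenuis\tabc\t700\t3\t0\t1\t700\t1\t700\t1e-100\t500.0\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_tabular_hits(path)

    def test_write_read_roundtrip(self, tmp_path):
        table = HitTable(
            "q1",
            [
                make_hit(label("millepora"), 99.5, 500.0, "s1|Acropora_millepora"),
                make_hit(label("tenuis"), 100.0, 480.0, "s2|Acropora_tenuis"),
            ],
        )
        path = tmp_path / "hits.tsv"
        write_tabular_hits([table], path)
        (back,) = read_tabular_hits(path)
        assert [
            (h.subject_id, h.pct_identity, h.bit_score) for h in back
        ] == [(h.subject_id, h.pct_identity, h.bit_score) for h in table]


class TestVerifyLocus:
    @pytest.fixture
    def locus_refs(self):
        rng = np.random.default_rng(5)
        mtcr = random_seq(rng, 300)
        paxc = random_seq(rng, 300)
        return {
            "mtCR": ReferenceDB(
                "mtCR", [make_record("m1", mtcr, label("alpha"), "mtCR")]
            ),
            "PaxC": ReferenceDB(
                "PaxC", [make_record("p1", paxc, label("alpha"), "PaxC")]
            ),
        }

    def test_recognises_copied_reference(self, locus_refs):
        query = locus_refs["mtCR"].records[0].sequence
        assert verify_locus(query, locus_refs) == "mtCR"

    def test_unrelated_sequence_is_unknown(self, locus_refs):
        rng = np.random.default_rng(1234)
        assert verify_locus(random_seq(rng, 60), locus_refs) == UNKNOWN_LOCUS

    def test_equal_best_scores_are_unresolved(self):
        seq = "ACGT" * 50
        refs = {
            "A": ReferenceDB("A", [make_record("a", seq, label("alpha"), "A")]),
            "B": ReferenceDB("B", [make_record("b", seq, label("alpha"), "B")]),
        }
        assert verify_locus(seq, refs) == UNKNOWN_LOCUS


class TestRotateToAnchor:
    def test_enumerated_rotation(self):
        rotated, offset = rotate_to_anchor(
            "TTGGAACC", "AACC", min_anchor_bits=0.0
        )
        assert (rotated, offset) == ("AACCTTGG", 4)

    def test_identity_rotation(self):
        seq = "AACCTTGG"
        rotated, offset = rotate_to_anchor(seq, "AACC", min_anchor_bits=0.0)
        assert (rotated, offset) == (seq, 0)

    def test_absent_anchor_raises(self):
        with pytest.raises(ValueError, match="anchor"):
            rotate_to_anchor("AAAAAAAA", "CCCC", min_anchor_bits=0.0)

    def test_random_rotation_recovered(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            seq = random_seq(rng, 400)
            anchor = seq[:40]
            shift = int(rng.integers(1, 399))
            shifted = seq[shift:] + seq[:shift]
            recovered, offset = rotate_to_anchor(shifted, anchor)
            assert recovered == seq
            assert 0 <= offset < len(seq)
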
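import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acroid.refdb import (
    Qualifier,
    SpeciesLabel,
    build_reference_db,
    parse_species_label,
    read_records,
    write_records,
)
from conftest import label, make_record


class TestParseSpeciesLabel:
    @pytest.mark.parametrize(
        "raw, genus, epithet, qualifier",
        [
            ("Acropora millepora", "Acropora", "millepora", Qualifier.NONE),
            ("Acropora sp.", "Acropora", "", Qualifier.SP),
            ("Acropora sp", "Acropora", "", Qualifier.SP),
            ("Acropora cf. tenuis", "Acropora", "tenuis", Qualifier.CF),
            ("Acropora aff. hyacinthus", "Acropora", "hyacinthus", Qualifier.AFF),
            ("A. abrotanoides", "Acropora", "abrotanoides", Qualifier.NONE),
            ("acropora MILLEPORA", "Acropora", "millepora", Qualifier.NONE),
            ("  Acropora   digitifera  ", "Acropora", "digitifera", Qualifier.NONE),
            ("Montipora sp.", "Montipora", "", Qualifier.SP),
            # named hybrids are ordinary binomials
            ("Acropora prolifera", "Acropora", "prolifera", Qualifier.NONE),
            # non-binomial decorations are OTHER (and ambiguous)
            ("Acropora", "Acropora", "", Qualifier.OTHER),
            ("Acropora millepora isolate ZB1", "Acropora", "", Qualifier.OTHER),
            ("Acropora sp. 2", "Acropora", "", Qualifier.SP),
        ],
    )
    def test_parsing(self, raw, genus, epithet, qualifier):
        got = parse_species_label(raw)
        assert (got.genus, got.epithet, got.qualifier) == (genus, epithet, qualifier)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            parse_species_label("   ")

    def test_unambiguity_follows_qualifier(self):
        assert parse_species_label("Acropora millepora").is_unambiguous()
        for raw in ("Acropora sp.", "Acropora cf. tenuis",
                    "Acropora aff. tenuis", "Acropora millepora var x"):
            assert not parse_species_label(raw).is_unambiguous()

    def test_species_identity_ignores_qualifier(self):
        plain = parse_species_label("Acropora tenuis")
        cf = parse_species_label("Acropora cf. tenuis")
        assert plain.key() == cf.key()
        assert not cf.is_unambiguous()

    def test_unqualified_label_requires_epithet(self):
        with pytest.raises(ValueError):
            SpeciesLabel("Acropora", "", Qualifier.NONE)
        with pytest.raises(ValueError):
            SpeciesLabel("Acropora", "sp", Qualifier.NONE)

    @given(
        genus=st.sampled_from(["Acropora", "Montipora"]),
        # no real epithet is spelled like an open-nomenclature token,
        # and such a string could not survive a text round-trip
        epithet=st.from_regex(r"[a-z][a-z]{2,12}", fullmatch=True).filter(
            lambda e: e not in {"sp", "spp", "cf", "aff", "var"}
        ),
        qualifier=st.sampled_from(
            [Qualifier.NONE, Qualifier.SP, Qualifier.CF, Qualifier.AFF]
        ),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_parse_format_roundtrip(self, genus, epithet, qualifier):
        if qualifier is Qualifier.SP:
            epithet = ""
        original = SpeciesLabel(genus, epithet, qualifier)
        reparsed = parse_species_label(original.text())
        assert reparsed == original
        # idempotence of a second round
        assert parse_species_label(reparsed.text()) == reparsed


class TestReferenceRecord:
    def test_sequence_uppercased_and_validated(self):
        rec = make_record("r1", "acgtn", label("alpha"))
        assert rec.sequence == "ACGTN"
        with pytest.raises(ValueError):
            make_record("r2", "ACGTX", label("alpha"))
        with pytest.raises(ValueError):
            make_record("r3", "", label("alpha"))


class TestBuildReferenceDB:
    def test_species_counts_and_singletons(self):
        x, y = label("xenia"), label("ypsilon")
        db, dropped = build_reference_db(
            [
                make_record("r1", "ACGT", x),
                make_record("r2", "ACGT", x),
                make_record("r3", "ACGT", y),
            ]
        )
        assert dropped == 0
        assert db.species_counts == {x.key(): 2, y.key(): 1}
        assert db.singleton(y) and not db.singleton(x)

    def test_empty_input_gives_empty_db(self):
        db, _ = build_reference_db([])
        assert len(db) == 0 and db.species_counts == {}

    def test_genus_filter_drops_other_genera(self):
        recs = [
            make_record("r1", "ACGT", label("alpha")),
            make_record("r2", "ACGT", label("beta")),
            make_record("r3", "ACGT", label("gamma")),
            make_record("r4", "ACGT", label("", "Montipora", Qualifier.SP)),
        ]
        db, dropped = build_reference_db(recs, genus_filter="Acropora")
        assert len(db) == 3 and dropped == 1

    def test_duplicate_id_and_mixed_locus_rejected(self):
        with pytest.raises(ValueError, match="r1"):
            build_reference_db(
                [
                    make_record("r1", "ACGT", label("alpha")),
                    make_record("r1", "ACGT", label("beta")),
                ]
            )
        with pytest.raises(ValueError, match="locus"):
            build_reference_db(
                [
                    make_record("r1", "ACGT", label("alpha"), locus="A"),
                    make_record("r2", "ACGT", label("beta"), locus="B"),
                ]
            )

    @given(perm=st.permutations(list(range(5))))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_order_invariance(self, perm):
        recs = [
            make_record(f"r{i}", "ACGTACGT",
                        label("alpha" if i < 3 else "beta"))
            for i in range(5)
        ]
        base, _ = build_reference_db(recs)
        shuffled, _ = build_reference_db([recs[i] for i in perm])
        assert base.species_counts == shuffled.species_counts
        assert [r.record_id for r in base.records] == [
            r.record_id for r in shuffled.records
        ]


class TestReadWriteRecords:
    def test_fasta_header_species_and_case(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">r1 Acropora millepora\nacgt\n")
        (rec,) = read_records(fa, locus_tag="mtCR")
        assert rec.sequence == "ACGT"
        assert rec.species == label("millepora")
        assert rec.locus_tag == "mtCR"

    def test_metadata_takes_precedence_and_parses_qualifiers(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">r1 Acropora millepora\nACGT\n")
        meta = tmp_path / "meta.tsv"
        meta.write_text(
            "record_id\tspecies\tlocus\nr1\tAcropora aff. hyacinthus\tPaxC\n"
        )
        (rec,) = read_records(fa, meta)
        assert rec.species.qualifier is Qualifier.AFF
        assert rec.species.epithet == "hyacinthus"
        assert rec.locus_tag == "PaxC"

    def test_metadata_fasta_mismatch_lists_ids(self, tmp_path):
        fa = tmp_path / "ref.fa"
        fa.write_text(">r1 Acropora millepora\nACGT\n")
        meta = tmp_path / "meta.tsv"
        meta.write_text(
            "record_id\tspecies\tlocus\nr9\tAcropora millepora\tmtCR\n"
        )
        with pytest.raises(ValueError, match="r9"):
            read_records(fa, meta)

    def test_roundtrip_preserves_id_sequence_species(self, tmp_path):
        records = [
            make_record("r1", "ACGT" * 40, label("millepora"), locus="mtCR"),
            make_record("r2", "TTGGCCAA", label("", qualifier=Qualifier.SP),
                        locus="mtCR"),
        ]
        fa, meta = tmp_path / "out.fa", tmp_path / "out.tsv"
        write_records(records, fa, meta)
        back = read_records(fa, meta)
        assert [(r.record_id, r.sequence, r.species.text()) for r in back] == [
            (r.record_id, r.sequence, r.species.text()) for r in records
        ]
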
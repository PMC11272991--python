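import pytest

from acroid.refdb import Qualifier, ReferenceDB, ReferenceRecord, SpeciesLabel
from acroid.similarity import Hit, HitTable


def label(epithet: str, genus: str = "Acropora",
          qualifier: Qualifier = Qualifier.NONE) -> SpeciesLabel:
    return SpeciesLabel(genus, epithet, qualifier)


def make_hit(species: SpeciesLabel, pct: float, bits: float,
             subject_id: str, query_id: str = "q1",
             aln_length: int = 500) -> Hit:
    return Hit(
        query_id=query_id,
        subject_id=subject_id,
        subject_species=species,
        pct_identity=round(pct, 3),
        aln_length=aln_length,
        raw_score=int(bits),
        bit_score=round(bits, 1),
    )


def make_table(rows, query_id: str = "q1") -> HitTable:
    """rows: iterable of (species, pct, bits); subject ids auto-numbered."""
    hits = [
        make_hit(sp, pct, bits, subject_id=f"s{i}", query_id=query_id)
        for i, (sp, pct, bits) in enumerate(rows, start=1)
    ]
    return HitTable(query_id, hits)


def make_record(record_id: str, sequence: str, species: SpeciesLabel,
                locus: str = "L") -> ReferenceRecord:
    return ReferenceRecord(record_id=record_id, locus_tag=locus,
                           sequence=sequence, species=species)


@pytest.fixture
def tiny_db():
    """3 records, 2 of species X (identical), 1 divergent singleton Y."""
    x = label("xenia")
    y = label("ypsilon")
    recs = [
        make_record("a1", "ACGTACGTACGTACGTACGT", x),
        make_record("a2", "ACGTACGTACGTACGTACGT", x),
        make_record("b1", "TTTTTTTTTTGGGGGGGGGG", y),
    ]
    return ReferenceDB("L", recs)
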
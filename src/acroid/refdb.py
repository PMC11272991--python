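"""Species-labelled reference sequence collections.

Open-nomenclature qualifiers (``sp.``, ``cf.``, ``aff.``) mark a label as
ambiguous: such records participate in searches as ordinary subjects, but an
ambiguous label never counts as an identified species in assignment tallies.
Species identity is compared at binomial level (genus + epithet), ignoring
the qualifier.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Qualifier",
    "SpeciesLabel",
    "ReferenceRecord",
    "ReferenceDB",
    "parse_species_label",
    "build_reference_db",
    "read_records",
    "write_records",
]

# IUPAC nucleotide codes, unambiguous + degenerate
IUPAC_DNA = set("ACGTNRYWSMKHBVD")

_SP_TOKENS = {"sp", "sp."}
_CF_TOKENS = {"cf", "cf."}
_AFF_TOKENS = {"aff", "aff."}
_EPITHET_RE = re.compile(r"^[a-z][a-z-]*$")


class Qualifier(enum.Enum):
    NONE = "none"
    SP = "sp."
    CF = "cf."
    AFF = "aff."
    OTHER = "other"


@dataclass(frozen=True)
class SpeciesLabel:
    """A parsed genus/epithet pair with an open-nomenclature qualifier.

    Two labels denote the same species iff their normalised genus and epithet
    match; the qualifier is ignored for equality but makes a label ambiguous,
    and an ambiguous label never counts as an identified species.
    """

    genus: str
    epithet: str = ""
    qualifier: Qualifier = Qualifier.NONE
    #: original text, kept for OTHER labels so formatting round-trips
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.qualifier is Qualifier.NONE and (
            not self.epithet or self.epithet == "sp"
        ):
            raise ValueError(
                f"unqualified label requires a proper epithet: {self!r}"
            )

    def is_unambiguous(self) -> bool:
        return self.qualifier is Qualifier.NONE

    def key(self) -> tuple[str, str]:
        """Binomial identity key (genus, epithet), qualifier ignored."""
        return (self.genus, self.epithet)

    def text(self) -> str:
        if self.qualifier is Qualifier.NONE:
            return f"{self.genus} {self.epithet}"
        if self.qualifier is Qualifier.SP:
            return f"{self.genus} sp."
        if self.qualifier in (Qualifier.CF, Qualifier.AFF):
            return f"{self.genus} {self.qualifier.value} {self.epithet}"
        return self.raw or f"{self.genus} {self.epithet}".strip()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text()


def _norm_genus(token: str, default_genus: str) -> str:
    token = token.strip(",;")
    if re.fullmatch(r"[A-Za-z]\.", token):
        return default_genus
    return token.capitalize()


def parse_species_label(raw: str, default_genus: str = "Acropora") -> SpeciesLabel:
    """Parse free-text species annotations into a :class:`SpeciesLabel`.

    Normalisation: the genus is capitalised and the epithet lowercased;
    internal whitespace collapses. ``sp``/``sp.`` yields qualifier SP with an
    empty epithet; ``cf.``/``aff.`` between genus and epithet yield CF/AFF.
    A single-letter abbreviation ("A.") expands to *default_genus*. Anything
    else that is not a clean binomial (bare genus, trailing decorations such
    as isolate or strain tags, malformed epithets) becomes qualifier OTHER,
    which is ambiguous like SP/CF/AFF.
    """
    text = " ".join(raw.split())
    if not text:
        raise ValueError("empty species label")
    tokens = text.split(" ")
    genus = _norm_genus(tokens[0], default_genus)
    rest = tokens[1:]

    def other() -> SpeciesLabel:
        return SpeciesLabel(genus, "", Qualifier.OTHER, raw=text)

    if not rest:
        return other()
    t1 = rest[0].lower()
    if t1 in _SP_TOKENS:
        # "Acropora sp.", possibly with trailing numbering -- all ambiguous
        return SpeciesLabel(genus, "", Qualifier.SP, raw=text)
    if t1 in _CF_TOKENS or t1 in _AFF_TOKENS:
        qual = Qualifier.CF if t1 in _CF_TOKENS else Qualifier.AFF
        if len(rest) >= 2 and _EPITHET_RE.match(rest[1].lower()):
            return SpeciesLabel(genus, rest[1].lower(), qual, raw=text)
        return other()
    epithet = t1
    if len(rest) == 1 and _EPITHET_RE.match(epithet):
        return SpeciesLabel(genus, epithet, Qualifier.NONE, raw=text)
    return other()


@dataclass(frozen=True)
class ReferenceRecord:
    """One sequence record: id, locus, uppercase IUPAC DNA, species label."""

    record_id: str
    locus_tag: str
    sequence: str
    species: SpeciesLabel
    source: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.record_id}: empty sequence")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.record_id}: non-IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


class ReferenceDB:
    """An indexed, single-locus collection of reference records.

    ``species_counts`` maps the binomial key of each label to the number of
    records carrying it (ambiguous labels counted under their own raw-keyed
    label). A species with exactly one record is a *singleton*: the
    leave-one-out evaluation excludes singletons as queries (they cannot be
    self-identified) while keeping them as possible hit subjects.
    """

    def __init__(self, locus_tag: str, records: list[ReferenceRecord]):
        self.locus_tag = locus_tag
        self.records = list(records)
        self._by_id: dict[str, ReferenceRecord] = {}
        counts: dict[tuple[str, str], int] = {}
        for rec in self.records:
            if rec.locus_tag != locus_tag:
                raise ValueError(
                    f"record {rec.record_id} has locus {rec.locus_tag!r}, "
                    f"db is {locus_tag!r}"
                )
            if rec.record_id in self._by_id:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            self._by_id[rec.record_id] = rec
            counts[rec.species.key()] = counts.get(rec.species.key(), 0) + 1
        self.species_counts = counts

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def get(self, record_id: str) -> ReferenceRecord:
        return self._by_id[record_id]

    def singleton(self, species: SpeciesLabel) -> bool:
        return self.species_counts.get(species.key(), 0) == 1

    def species_lookup(self) -> dict[str, SpeciesLabel]:
        return {r.record_id: r.species for r in self.records}

    @property
    def total_length(self) -> int:
        return sum(len(r.sequence) for r in self.records)


def build_reference_db(
    records: Iterable[ReferenceRecord],
    genus_filter: str | None = None,
) -> tuple[ReferenceDB, int]:
    """Index records into a :class:`ReferenceDB`; returns (db, n_dropped).

    All records must share one locus tag; duplicate ids are rejected. With
    *genus_filter*, records of other genera are dropped and counted.
    """
    records = list(records)
    n_dropped = 0
    if genus_filter is not None:
        kept = [r for r in records if r.species.genus == genus_filter.capitalize()]
        n_dropped = len(records) - len(kept)
        records = kept
    tags = sorted({r.locus_tag for r in records})
    if len(tags) > 1:
        raise ValueError(f"mixed locus tags in one database: {tags}")
    locus = tags[0] if tags else ""
    return ReferenceDB(locus, sorted(records, key=lambda r: r.record_id)), n_dropped


def read_records(
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
    locus_tag: str = "",
    default_genus: str = "Acropora",
) -> list[ReferenceRecord]:
    """Read FASTA (+ optional ``record_id/species/locus`` TSV metadata).

    Metadata takes precedence over species text parsed from the FASTA header
    (the text after the first whitespace). Sequences are uppercased. A
    mismatch between metadata ids and FASTA ids is an error listing the ids.
    """
    seqs: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        descr = rec.description[len(rec.id):].strip() if rec.description else ""
        seqs[rec.id] = (str(rec.seq), descr)
        order.append(rec.id)

    meta: dict[str, tuple[str, str]] = {}
    if metadata_path is not None:
        df = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
        required = {"record_id", "species", "locus"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        meta = {
            row.record_id: (row.species, row.locus) for row in df.itertuples()
        }
        only_meta = sorted(set(meta) - set(seqs))
        only_fasta = sorted(set(seqs) - set(meta))
        if only_meta or only_fasta:
            raise ValueError(
                "metadata/FASTA id mismatch: "
                f"metadata-only={only_meta} fasta-only={only_fasta}"
            )

    out = []
    for rid in order:
        seq, header_species = seqs[rid]
        if rid in meta:
            species_text, locus = meta[rid]
        else:
            species_text, locus = header_species, locus_tag
        label = parse_species_label(species_text, default_genus=default_genus)
        out.append(
            ReferenceRecord(
                record_id=rid,
                locus_tag=locus or locus_tag,
                sequence=seq,
                species=label,
                source=str(fasta_path),
            )
        )
    return out


def write_records(
    records: Iterable[ReferenceRecord],
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
    wrap: int = 60,
) -> None:
    """Write FASTA (wrapped at *wrap* columns) and optional metadata TSV.

    Round-trips with :func:`read_records`: id, sequence and species label
    text are preserved.
    """
    records = list(records)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description=r.species.text())
        for r in records
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap or None)
        writer.write_file(seq_records)
    if metadata_path is not None:
        df = pd.DataFrame(
            {
                "record_id": [r.record_id for r in records],
                "species": [r.species.text() for r in records],
                "locus": [r.locus_tag for r in records],
            }
        )
        df.to_csv(metadata_path, sep="\t", index=False)
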
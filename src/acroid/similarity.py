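"""Ranked hit tables by local alignment, plus locus checks and rotation.

The search here is a transparent stand-in for a megablast search against a
curated local database: every query/subject pair is aligned exactly
(Smith-Waterman with affine gaps, no heuristic seeding), the raw score is
rescaled to a bit score with Karlin-Altschul parameters, and hits are ranked
the way the downstream assignment rules expect (bit score first, then percent
identity, then subject id for a stable total order).

Scoring conventions: a gap of length k costs ``gap_open + k * gap_extend``
(the BLASTN convention); ambiguity codes (N and friends) score as mismatches
and never count as identities; percent identity is 100 * identities /
alignment columns (gap columns included), rounded to 3 decimals; bit scores
are rounded to 1 decimal wherever two hits are compared for a tie.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._sw import encode, sw_align
from .refdb import ReferenceDB, ReferenceRecord, SpeciesLabel, parse_species_label

__all__ = [
    "AlignmentParams",
    "Hit",
    "HitTable",
    "local_align",
    "bit_score",
    "e_value",
    "search",
    "read_tabular_hits",
    "write_tabular_hits",
    "verify_locus",
    "rotate_to_anchor",
    "UNKNOWN_LOCUS",
]

UNKNOWN_LOCUS = "UNKNOWN"

_OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme + Karlin-Altschul parameters.

    Defaults are the classic blastn scheme (match +2, mismatch -3, gap
    existence 5, extension 2) with lambda = 0.625 nats per score unit and
    K = 0.41, under which the bit score is strictly increasing in the raw
    score.
    """

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.625
    K: float = 0.41

    def __post_init__(self) -> None:
        if self.match_reward < 1:
            raise ValueError("match_reward must be >= 1")
        if self.mismatch_penalty > -1:
            raise ValueError("mismatch_penalty must be <= -1")
        if self.gap_open < 0 or self.gap_extend < 1:
            raise ValueError("invalid gap penalties")
        if self.lam <= 0 or not (0 < self.K < 1):
            raise ValueError("invalid Karlin-Altschul parameters")


def _align(
    query: str,
    subject: str,
    params: AlignmentParams,
) -> tuple[int, int, int, tuple[int, int]]:
    """Core SW call: (raw_score, identities, aln_length, subject_range)."""
    raw, ident, length, sstart, send = sw_align(
        encode(query.upper()),
        encode(subject.upper()),
        params.match_reward,
        params.mismatch_penalty,
        params.gap_open,
        params.gap_extend,
    )
    return raw, ident, length, (sstart, send)


def local_align(
    query: str,
    subject: str,
    params: AlignmentParams = AlignmentParams(),
) -> tuple[int, int, int]:
    """Optimal local alignment of two DNA strings.

    Returns ``(raw_score, identities, aln_length)`` where *aln_length*
    counts aligned columns including gap columns. A pair with no
    positive-scoring local alignment returns ``(0, 0, 0)``.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    raw, ident, length, _ = _align(query, subject, params)
    return raw, ident, length


def bit_score(raw_score: int, params: AlignmentParams = AlignmentParams()) -> float:
    """Karlin-Altschul bit score, (lambda * S - ln K) / ln 2, unrounded."""
    return (params.lam * raw_score - math.log(params.K)) / math.log(2)


def e_value(bits: float, query_length: int, db_length: int) -> float:
    """Expected chance hits: m * n * 2^(-bits)."""
    return query_length * db_length * 2.0 ** (-bits)


@dataclass(frozen=True)
class Hit:
    """One query-vs-reference match at species-level granularity.

    ``pct_identity`` is stored rounded to 3 decimals and ``bit_score`` to 1
    decimal; equality tests in the assignment rules happen at exactly these
    precisions (the granularity of the reports the decisions model).
    """

    query_id: str
    subject_id: str
    subject_species: SpeciesLabel
    pct_identity: float
    aln_length: int
    raw_score: int
    bit_score: float
    e_value: float = 0.0

    @staticmethod
    def from_alignment(
        query_id: str,
        subject: ReferenceRecord,
        raw_score: int,
        identities: int,
        aln_length: int,
        params: AlignmentParams,
        query_length: int,
        db_length: int,
    ) -> "Hit":
        bits = bit_score(raw_score, params)
        return Hit(
            query_id=query_id,
            subject_id=subject.record_id,
            subject_species=subject.species,
            pct_identity=round(100.0 * identities / aln_length, 3),
            aln_length=aln_length,
            raw_score=raw_score,
            bit_score=round(bits, 1),
            e_value=e_value(bits, query_length, db_length),
        )

    def sort_key(self) -> tuple[float, float, str]:
        return (-self.bit_score, -self.pct_identity, self.subject_id)


@dataclass
class HitTable:
    """Per-query hits, sorted by (bit score desc, identity desc, subject id).

    At most one hit per subject (the best-raw-score HSP is retained before
    construction); the third sort key makes the ordering a total order.
    """

    query_id: str
    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self) -> None:
        subjects = [h.subject_id for h in self.hits]
        if len(subjects) != len(set(subjects)):
            raise ValueError(f"duplicate subject in hit table {self.query_id}")
        self.hits = sorted(self.hits, key=Hit.sort_key)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)


def search(
    query: ReferenceRecord,
    db: ReferenceDB,
    params: AlignmentParams = AlignmentParams(),
    max_hits: int = 100,
    exclude: frozenset[str] | set[str] | None = None,
) -> HitTable:
    """Align *query* against every db record and rank the hits.

    Records whose id is in *exclude* are skipped (the leave-one-out hook).
    Only positive-scoring pairs become hits; the table is truncated to
    *max_hits* after sorting.
    """
    if len(db) == 0:
        raise ValueError("cannot search an empty reference database")
    exclude = exclude or frozenset()
    db_length = db.total_length
    hits = []
    for rec in db.records:
        if rec.record_id in exclude:
            continue
        raw, ident, length = local_align(query.sequence, rec.sequence, params)
        if raw > 0:
            hits.append(
                Hit.from_alignment(
                    query.record_id, rec, raw, ident, length,
                    params, len(query.sequence), db_length,
                )
            )
    table = HitTable(query.record_id, hits)
    table.hits = table.hits[:max_hits]
    return table


def read_tabular_hits(
    path: str | Path,
    species_lookup: Mapping[str, SpeciesLabel] | None = None,
    default_genus: str = "Acropora",
) -> list[HitTable]:
    """Read a 12-column tabular hit file (the BLAST outfmt-6 dialect).

    One :class:`HitTable` per distinct query, in order of first appearance;
    per subject only the best-bit-score row is kept. Subject species come
    from *species_lookup*, falling back to parsing the text after the last
    ``|`` in the subject id (underscores read as spaces). Unresolvable
    subjects and non-numeric pident/bitscore cells are errors.
    """
    species_lookup = dict(species_lookup or {})
    try:
        df = pd.read_csv(
            path, sep="\t", names=_OUTFMT6_COLUMNS, dtype=str, header=None,
        )
    except pd.errors.EmptyDataError:
        return []
    for col in ("pident", "bitscore", "evalue"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric {col} at line {int(bad[0]) + 1} of {path}"
            )
        df[col] = converted
    df["length"] = df["length"].astype(int)

    def resolve(sid: str) -> SpeciesLabel | None:
        if sid in species_lookup:
            return species_lookup[sid]
        if "|" in sid:
            text = sid.rsplit("|", 1)[1].replace("_", " ")
            try:
                return parse_species_label(text, default_genus=default_genus)
            except ValueError:
                return None
        return None

    unresolved = sorted(
        {sid for sid in df["sseqid"].unique() if resolve(sid) is None}
    )
    if unresolved:
        raise ValueError(f"no species resolution for subjects: {unresolved}")

    tables = []
    for qid in df["qseqid"].unique():
        sub = df[df["qseqid"] == qid]
        best = sub.sort_values("bitscore", ascending=False).drop_duplicates(
            "sseqid", keep="first"
        )
        hits = [
            Hit(
                query_id=qid,
                subject_id=row.sseqid,
                subject_species=resolve(row.sseqid),
                pct_identity=round(float(row.pident), 3),
                aln_length=int(row.length),
                raw_score=0,  # not recoverable from tabular output
                bit_score=round(float(row.bitscore), 1),
                e_value=float(row.evalue),
            )
            for row in best.itertuples()
        ]
        tables.append(HitTable(qid, hits))
    return tables


def write_tabular_hits(tables: Iterable[HitTable], path: str | Path) -> None:
    """Write hit tables in the 12-column dialect (pident 3dp, bitscore 1dp).

    Coordinate columns not tracked by this engine are written as zeros;
    mismatch/gapopen likewise. Round-trips through read_tabular_hits on the
    fields the assignment rules consume.
    """
    with open(path, "w") as fh:
        for table in tables:
            for h in table:
                fh.write(
                    f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.3f}\t"
                    f"{h.aln_length}\t0\t0\t0\t0\t0\t0\t"
                    f"{h.e_value:.2e}\t{h.bit_score:.1f}\n"
                )


def verify_locus(
    query: str,
    locus_refs: Mapping[str, ReferenceDB],
    params: AlignmentParams = AlignmentParams(),
    min_bits: float = 50.0,
) -> str:
    """Identify which locus a sequence comes from, or ``UNKNOWN``.

    The best bit score against each locus database is compared (at 1-decimal
    precision); the winning locus must clear *min_bits* and must win
    outright — a tie between loci is unresolved.
    """
    if not locus_refs:
        raise ValueError("at least one locus reference database required")
    best: dict[str, float] = {}
    for tag in sorted(locus_refs):
        db = locus_refs[tag]
        top = 0.0
        for rec in db.records:
            raw, _, _ = local_align(query, rec.sequence, params)
            if raw > 0:
                top = max(top, round(bit_score(raw, params), 1))
        best[tag] = top
    top_score = max(best.values())
    if top_score < min_bits:
        return UNKNOWN_LOCUS
    winners = [tag for tag, b in best.items() if b == top_score]
    return winners[0] if len(winners) == 1 else UNKNOWN_LOCUS


def rotate_to_anchor(
    circular_seq: str,
    anchor: str,
    params: AlignmentParams = AlignmentParams(),
    min_anchor_bits: float = 50.0,
) -> tuple[str, int]:
    """Rotate a circular sequence so *anchor*'s best match starts at 0.

    The anchor is locally aligned against the doubled sequence, so matches
    spanning the origin are found; the rotation offset is the aligned start
    modulo the sequence length. An anchor whose best alignment scores below
    *min_anchor_bits* raises (anchor not found). This is an anchor-seeded
    approximation of exact cyclic-rotation alignment: it fixes the origin
    from one conserved marker rather than minimising a full cyclic edit
    distance.
    """
    seq = circular_seq.upper()
    if len(anchor) >= len(seq):
        raise ValueError("anchor must be shorter than the circular sequence")
    raw, _, _, (sstart, _) = _align(anchor.upper(), seq + seq, params)
    if raw <= 0 or round(bit_score(raw, params), 1) < min_anchor_bits:
        raise ValueError("anchor not found in circular sequence")
    offset = sstart % len(seq)
    return seq[offset:] + seq[:offset], offset
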
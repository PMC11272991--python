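"""Hierarchical species-assignment rules and two-locus concordance.

The decision tree, applied per query and per locus over the distinct species
in its hit table:

1. (barcode mode only) If exactly one species has a 100.000%-identity hit,
   assign it.
2. Otherwise rank all hits by bit score; if the top (1-decimal) bit score
   belongs to a single species, assign it.
3. Otherwise, among the bit-score-tied hits, if the highest (3-decimal)
   percent identity belongs to a single species, assign it.
4. Otherwise no species is assigned (an irresolvable tie).

Genome mode drops step 1: for whole-mitogenome queries the 100%-identity
shortcut is not prioritised and ranking starts at the bit score.

Multiple hits to the *same* species never constitute a tie; ties are over
distinct species only. A winning label that carries an open-nomenclature
qualifier (sp./cf./aff. or other decoration) yields ASSIGNED_AMBIGUOUS,
which is excluded from every "assigned" tally downstream.

A specimen sequenced at two loci gets a final identity only when both loci
independently assign the same species (concordance).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .refdb import SpeciesLabel
from .similarity import HitTable

__all__ = [
    "Status",
    "RulePath",
    "Final",
    "AssignmentResult",
    "ConcordanceResult",
    "assign_species",
    "concord",
]


class Status(enum.Enum):
    ASSIGNED = "assigned"
    ASSIGNED_AMBIGUOUS = "assigned_ambiguous"
    UNASSIGNED_TIE = "unassigned_tie"
    NO_HITS = "no_hits"


class RulePath(enum.Enum):
    UNIQUE_100 = "unique_100"
    BITSCORE_TOP = "bitscore_top"
    IDENTITY_TIEBREAK = "identity_tiebreak"
    NONE = "none"


class Final(enum.Enum):
    CONCORDANT_SPECIES = "concordant_species"
    DISCORDANT = "discordant"
    PRELIMINARY_MT_ONLY = "preliminary_mt_only"
    PRELIMINARY_NUC_ONLY = "preliminary_nuc_only"
    NONE = "none"


@dataclass(frozen=True)
class AssignmentResult:
    query_id: str
    locus_tag: str
    status: Status
    species: SpeciesLabel | None
    rule_path: RulePath
    top_identity: float | None
    n_species_at_100: int

    def is_assigned(self) -> bool:
        return self.status is Status.ASSIGNED


def _distinct_species(hits) -> dict[tuple[str, str], SpeciesLabel]:
    """Distinct species keys in hit order; first label encountered wins."""
    out: dict[tuple[str, str], SpeciesLabel] = {}
    for h in hits:
        out.setdefault(h.subject_species.key(), h.subject_species)
    return out


def assign_species(
    hits: HitTable,
    mode: str = "barcode",
    locus_tag: str = "",
    min_aln_length: int = 0,
) -> AssignmentResult:
    """Run the decision tree on one query's hit table.

    *mode* is ``"barcode"`` (100%-identity rule first) or ``"genome"``
    (bit-score ranking only). *min_aln_length* filters out hits shorter
    than the given alignment length before any rule fires (default keeps
    everything: the rules state no coverage threshold).
    """
    if mode not in ("barcode", "genome"):
        raise ValueError(f"unknown mode {mode!r}")
    usable = [h for h in hits if h.aln_length >= min_aln_length]

    def result(status, species, rule, top, n100):
        return AssignmentResult(
            query_id=hits.query_id,
            locus_tag=locus_tag,
            status=status,
            species=species,
            rule_path=rule,
            top_identity=top,
            n_species_at_100=n100,
        )

    if not usable:
        return result(Status.NO_HITS, None, RulePath.NONE, None, 0)

    top_identity = max(h.pct_identity for h in usable)
    at_100 = _distinct_species(h for h in usable if h.pct_identity == 100.0)
    n100 = len(at_100)

    def assigned(label: SpeciesLabel, rule: RulePath) -> AssignmentResult:
        status = (
            Status.ASSIGNED if label.is_unambiguous()
            else Status.ASSIGNED_AMBIGUOUS
        )
        return result(status, label, rule, top_identity, n100)

    # (1) unique perfect-identity species (barcode mode only)
    if mode == "barcode" and n100 == 1:
        return assigned(next(iter(at_100.values())), RulePath.UNIQUE_100)

    # (2) unique species at the top bit score, over ALL hits
    best_bits = max(h.bit_score for h in usable)
    bit_tied = [h for h in usable if h.bit_score == best_bits]
    at_best_bits = _distinct_species(bit_tied)
    if len(at_best_bits) == 1:
        return assigned(next(iter(at_best_bits.values())), RulePath.BITSCORE_TOP)

    # (3) identity tie-break within the bit-score-tied hits
    best_pct = max(h.pct_identity for h in bit_tied)
    at_best_pct = _distinct_species(
        h for h in bit_tied if h.pct_identity == best_pct
    )
    if len(at_best_pct) == 1:
        return assigned(
            next(iter(at_best_pct.values())), RulePath.IDENTITY_TIEBREAK
        )

    # (4) irresolvable tie between species
    return result(Status.UNASSIGNED_TIE, None, RulePath.NONE, top_identity, n100)


@dataclass(frozen=True)
class ConcordanceResult:
    sample_id: str
    mt: AssignmentResult
    nuc: AssignmentResult
    final: Final
    final_species: SpeciesLabel | None


def concord(mt: AssignmentResult, nuc: AssignmentResult) -> ConcordanceResult:
    """Combine the mitochondrial and nuclear calls for one specimen.

    A final species requires both loci ASSIGNED to the same species;
    ambiguous assignments never concur. Exactly one assigned locus gives a
    preliminary, single-marker identity.
    """
    if mt.query_id != nuc.query_id:
        raise ValueError(
            f"mismatched sample ids: {mt.query_id!r} vs {nuc.query_id!r}"
        )
    mt_ok, nuc_ok = mt.is_assigned(), nuc.is_assigned()
    if mt_ok and nuc_ok:
        if mt.species.key() == nuc.species.key():
            final, species = Final.CONCORDANT_SPECIES, mt.species
        else:
            final, species = Final.DISCORDANT, None
    elif mt_ok:
        final, species = Final.PRELIMINARY_MT_ONLY, None
    elif nuc_ok:
        final, species = Final.PRELIMINARY_NUC_ONLY, None
    else:
        final, species = Final.NONE, None
    return ConcordanceResult(mt.query_id, mt, nuc, final, species)
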
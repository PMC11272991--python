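"""Readers for per-sample identification tables and summary recounting.

Two layouts are supported, mirroring how such results are published as
supplementary spreadsheets: a two-locus table (one row per specimen with
the matched species and percent identity per locus) and a whole-mitogenome
table (one row per database record with its supposed and matched species).
Column names are not standardised across journals, so the mapping from
logical fields to spreadsheet headers is external configuration with a
best-effort default.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .evaluate import Verdict, success_rate
from .refdb import SpeciesLabel, parse_species_label

__all__ = [
    "LocusCall", "SampleRow", "MitoRow",
    "DEFAULT_S1_MAPPING", "DEFAULT_S2_MAPPING",
    "read_mapping", "read_s1", "read_s2", "recompute_results",
]

DEFAULT_S1_MAPPING = {
    "sample_id": "sample_id",
    "mtcr_species": "mtcr_matched_species",
    "mtcr_identity": "mtcr_pct_identity",
    "paxc_species": "paxc_matched_species",
    "paxc_identity": "paxc_pct_identity",
}

DEFAULT_S2_MAPPING = {
    "record_id": "record_id",
    "supposed_species": "supposed_species",
    "matched_species": "matched_species",
    "excluded": "excluded_singleton",
}


class CallStatus(enum.Enum):
    ASSIGNED = "assigned"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"
    NO_SEQUENCE = "no_sequence"


@dataclass(frozen=True)
class LocusCall:
    matched_species_raw: str
    species: SpeciesLabel | None
    pct_identity: float | None
    status: CallStatus


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    mtcr: LocusCall
    paxc: LocusCall

    @property
    def has_mtcr(self) -> bool:
        return self.mtcr.status is not CallStatus.NO_SEQUENCE

    @property
    def has_paxc(self) -> bool:
        return self.paxc.status is not CallStatus.NO_SEQUENCE


@dataclass(frozen=True)
class MitoRow:
    record_id: str
    supposed_species: SpeciesLabel
    matched_species: SpeciesLabel | None
    excluded_singleton: bool

    def verdict(self) -> Verdict:
        if self.excluded_singleton:
            return Verdict.EXCLUDED_SINGLETON
        if self.matched_species is None or not self.matched_species.is_unambiguous():
            return Verdict.UNASSIGNED
        if self.matched_species.key() == self.supposed_species.key():
            return Verdict.CORRECT
        return Verdict.INCORRECT


_MISSING = {"", "na", "n/a", "nan", "-", "none"}


def _parse_identity(cell) -> float | None:
    if cell is None:
        return None
    text = str(cell).strip().rstrip("%")
    if text.lower() in _MISSING:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    return None if math.isnan(value) else value


def _parse_species(cell) -> tuple[str, SpeciesLabel | None]:
    text = "" if cell is None else str(cell).strip()
    if text.lower() in _MISSING:
        return "", None
    try:
        return text, parse_species_label(text)
    except ValueError:
        return text, None


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a flat ``logical_field=column_header`` mapping file."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path, dtype=str).fillna("")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str).fillna("")


def _require(df: pd.DataFrame, mapping: Mapping[str, str], fields) -> None:
    missing = [
        f"{field} (column {mapping[field]!r})"
        for field in fields
        if mapping.get(field) not in df.columns
    ]
    if missing:
        raise ValueError(f"unmapped required columns: {missing}")


def _locus_call(species_cell, identity_cell) -> LocusCall:
    raw, label = _parse_species(species_cell)
    ident = _parse_identity(identity_cell)
    if not raw and ident is None:
        return LocusCall("", None, None, CallStatus.NO_SEQUENCE)
    if label is None:
        # sequence present but no species matched / unparseable label
        status = CallStatus.UNASSIGNED
    elif label.is_unambiguous():
        status = CallStatus.ASSIGNED
    else:
        status = CallStatus.AMBIGUOUS
    return LocusCall(raw, label, ident, status)


def read_s1(
    path: str | Path, mapping: Mapping[str, str] | None = None
) -> list[SampleRow]:
    """Read a two-locus per-sample identification table (xlsx/csv/tsv)."""
    mapping = {**DEFAULT_S1_MAPPING, **(mapping or {})}
    df = _read_table(path)
    _require(df, mapping, ["sample_id", "mtcr_species", "paxc_species"])
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            SampleRow(
                sample_id=str(rec[mapping["sample_id"]]),
                mtcr=_locus_call(
                    rec.get(mapping["mtcr_species"]),
                    rec.get(mapping.get("mtcr_identity", "")),
                ),
                paxc=_locus_call(
                    rec.get(mapping["paxc_species"]),
                    rec.get(mapping.get("paxc_identity", "")),
                ),
            )
        )
    return rows


_TRUTHY = {"1", "true", "yes", "y", "excluded"}


def read_s2(
    path: str | Path, mapping: Mapping[str, str] | None = None
) -> list[MitoRow]:
    """Read a whole-mitogenome identification table (xlsx/csv/tsv)."""
    mapping = {**DEFAULT_S2_MAPPING, **(mapping or {})}
    df = _read_table(path)
    _require(df, mapping, ["record_id", "supposed_species", "matched_species"])
    rows = []
    for rec in df.to_dict("records"):
        _, supposed = _parse_species(rec[mapping["supposed_species"]])
        if supposed is None:
            raise ValueError(
                f"unparseable supposed species in row "
                f"{rec[mapping['record_id']]!r}"
            )
        _, matched = _parse_species(rec.get(mapping["matched_species"]))
        excl_col = mapping.get("excluded", "")
        excl_cell = str(rec.get(excl_col, "") or "").strip().lower()
        rows.append(
            MitoRow(
                record_id=str(rec[mapping["record_id"]]),
                supposed_species=supposed,
                matched_species=matched,
                excluded_singleton=excl_cell in _TRUTHY,
            )
        )
    return rows


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    mean = sum(values) / len(values)
    if len(values) < 2:
        return mean, None
    var = sum((x - mean) ** 2 for x in values) / (len(values) - 1)
    return mean, math.sqrt(var)


def recompute_results(rows: list[SampleRow] | list[MitoRow]) -> dict[str, float]:
    """Recount the headline statistics from parsed supplementary rows.

    For two-locus rows: recovery and assignment counts per locus, identity
    moments among assigned samples, the over-99% count, the mtCR-only
    assigned count, and the two-locus concordance count. For mitogenome
    rows: the leave-one-out verdict tally and success percentage.
    """
    if not rows:
        return {}
    if isinstance(rows[0], MitoRow):
        verdicts = [(r.record_id, r.verdict()) for r in rows]
        tally = {v: 0 for v in Verdict}
        for _, v in verdicts:
            tally[v] += 1
        return {
            "n_records": len(rows),
            "n_excluded_singleton": tally[Verdict.EXCLUDED_SINGLETON],
            "n_evaluated": len(rows) - tally[Verdict.EXCLUDED_SINGLETON],
            "n_correct": tally[Verdict.CORRECT],
            "n_incorrect": tally[Verdict.INCORRECT],
            "n_unassigned": tally[Verdict.UNASSIGNED],
            "loo_success_pct": success_rate(verdicts),
        }

    out: dict[str, float] = {}
    out["n_samples"] = len(rows)
    out["n_mtcr_recovered"] = sum(r.has_mtcr for r in rows)
    out["n_paxc_recovered"] = sum(r.has_paxc for r in rows)
    out["n_both_loci"] = sum(r.has_mtcr and r.has_paxc for r in rows)

    mt_assigned = [r for r in rows if r.mtcr.status is CallStatus.ASSIGNED]
    px_assigned = [r for r in rows if r.paxc.status is CallStatus.ASSIGNED]
    out["n_mtcr_assigned"] = len(mt_assigned)
    out["n_paxc_assigned"] = len(px_assigned)

    mt_ident = [r.mtcr.pct_identity for r in mt_assigned
                if r.mtcr.pct_identity is not None]
    px_ident = [r.paxc.pct_identity for r in px_assigned
                if r.paxc.pct_identity is not None]
    out["n_mtcr_assigned_gt99"] = sum(1 for x in mt_ident if x > 99.0)
    mean, sd = _mean_sd(mt_ident)
    out["mtcr_identity_mean"], out["mtcr_identity_sd"] = mean, sd
    mean, sd = _mean_sd(px_ident)
    out["paxc_identity_mean"], out["paxc_identity_sd"] = mean, sd
    out["paxc_identity_min"] = min(px_ident) if px_ident else None

    out["n_mtcr_only"] = sum(r.has_mtcr and not r.has_paxc for r in rows)
    out["n_mtcr_only_assigned"] = sum(
        1 for r in rows
        if r.has_mtcr and not r.has_paxc
        and r.mtcr.status is CallStatus.ASSIGNED
    )
    out["n_concordant"] = sum(
        1 for r in rows
        if r.mtcr.status is CallStatus.ASSIGNED
        and r.paxc.status is CallStatus.ASSIGNED
        and r.mtcr.species.key() == r.paxc.species.key()
    )
    return out
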
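"""Representative-assembly selection from NCBI assembly_summary files.

One genome per species is chosen by a fixed ranking: assemblies flagged
``excluded_from_refseq`` are dropped outright, then RefSeq category
(reference genome > representative genome > na) dominates assembly level
(Complete Genome > Chromosome > Scaffold > Contig), and remaining ties go
to the most recent release date. A species with no usable assembly can
fall back to any congener's assembly, ranked the same way.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

from .errors import ParseError, ValidationError

REFSEQ_CATEGORY_ORDER = ("reference genome", "representative genome", "na")
ASSEMBLY_LEVEL_ORDER = ("Complete Genome", "Chromosome", "Scaffold", "Contig")

_CATEGORY_RANK = {c: i for i, c in enumerate(REFSEQ_CATEGORY_ORDER)}
_LEVEL_RANK = {l: i for i, l in enumerate(ASSEMBLY_LEVEL_ORDER)}


@dataclass(frozen=True)
class AssemblyRecord:
    accession: str
    species_tax_id: int
    refseq_category: str  # normalized: "" and "NA" collapse to "na"
    assembly_level: str
    release_date: _dt.date
    excluded_from_refseq: bool = False
    genus_tax_id: Optional[int] = None


def _normalize_category(raw: str) -> str:
    token = raw.strip()
    if not token or token.lower() == "na":
        return "na"
    return token


def _ranking_key(record: AssemblyRecord) -> tuple:
    """Lexicographic key: smaller is better."""
    try:
        cat = _CATEGORY_RANK[_normalize_category(record.refseq_category)]
    except KeyError:
        raise ValidationError(
            f"unknown refseq_category token {record.refseq_category!r}"
        ) from None
    try:
        level = _LEVEL_RANK[record.assembly_level.strip()]
    except KeyError:
        raise ValidationError(
            f"unknown assembly_level token {record.assembly_level!r}"
        ) from None
    # latest date wins, so negate via ordinal; accession ascending breaks
    # exact-date ties reproducibly
    return (cat, level, -record.release_date.toordinal(), record.accession)


def select_representative(
    candidates: Sequence[AssemblyRecord], species_id: int
) -> Optional[AssemblyRecord]:
    """Pick the best assembly for one species, or ``None`` if all are excluded."""
    pool = [
        r
        for r in candidates
        if r.species_tax_id == species_id and not r.excluded_from_refseq
    ]
    if not pool:
        return None
    return min(pool, key=_ranking_key)


def select_with_genus_fallback(
    candidates_by_species: dict[int, Sequence[AssemblyRecord]],
    target_species: int,
    congeners: Iterable[int],
) -> tuple[Optional[AssemblyRecord], Optional[int]]:
    """Select for ``target_species``; on failure, pool the congeners.

    Returns ``(record, source_species)`` where ``source_species`` is the
    species the chosen assembly actually belongs to.
    """
    chosen = select_representative(
        candidates_by_species.get(target_species, ()), target_species
    )
    if chosen is not None:
        return chosen, target_species
    pooled = [
        r
        for sp in congeners
        for r in candidates_by_species.get(sp, ())
        if not r.excluded_from_refseq
    ]
    if not pooled:
        return None, None
    best = min(pooled, key=_ranking_key)
    return best, best.species_tax_id


def _parse_date(raw: str) -> _dt.date:
    token = raw.strip()
    for fmt in ("%Y/%m/%d", "%Y-%m-%d"):
        try:
            return _dt.datetime.strptime(token, fmt).date()
        except ValueError:
            continue
    raise ParseError(f"unparseable release date {raw!r}")


def read_assembly_summary(source: Union[str, IO[str]]) -> list[AssemblyRecord]:
    """Read an NCBI assembly_summary tab-delimited file.

    The header is the last ``#``-prefixed line before the data; columns are
    addressed by name so column reordering across NCBI releases is harmless.
    """
    lines = source.splitlines() if isinstance(source, str) else list(source)
    header: Optional[list[str]] = None
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            candidate = line.lstrip("#").strip()
            if "\t" in candidate:
                header = candidate.split("\t")
            data_start = i + 1
        else:
            break
    if header is None:
        raise ParseError("no '#'-prefixed header line found")
    col = {name.strip(): i for i, name in enumerate(header)}
    required = (
        "assembly_accession",
        "species_taxid",
        "refseq_category",
        "assembly_level",
        "seq_rel_date",
        "excluded_from_refseq",
    )
    for name in required:
        if name not in col:
            raise ParseError(f"missing required column {name!r}")

    records: list[AssemblyRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(
        csv.reader(lines[data_start:], delimiter="\t"), start=data_start + 1
    ):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < len(header):
            raise ParseError(
                f"line {lineno}: {len(row)} fields, header has {len(header)}"
            )
        accession = row[col["assembly_accession"]].strip()
        if not accession:
            raise ParseError(f"line {lineno}: empty accession")
        if accession in seen:
            raise ValidationError(f"line {lineno}: duplicate accession {accession}")
        seen.add(accession)
        records.append(
            AssemblyRecord(
                accession=accession,
                species_tax_id=int(row[col["species_taxid"]]),
                refseq_category=_normalize_category(row[col["refseq_category"]]),
                assembly_level=row[col["assembly_level"]].strip(),
                release_date=_parse_date(row[col["seq_rel_date"]]),
                excluded_from_refseq=bool(
                    row[col["excluded_from_refseq"]].strip()
                ),
            )
        )
    return records
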
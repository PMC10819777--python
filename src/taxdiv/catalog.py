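"""Sequence catalog: the root multi-FASTA joined to its taxID table.

Filtering this catalog by a keep-list yields the project-specific
library, emitted either with classifier-style taxid-embedded headers
(``>seq|kraken:taxid|853``) or as a plain FASTA plus a seqid2taxid map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from typing import IO, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError
from .profiles import KeepList

logger = logging.getLogger(__name__)

FASTA_WRAP = 80  # output line width


@dataclass
class SequenceCatalog:
    records: list[tuple[str, str]]  # (header_id, sequence)
    correspondence: dict[str, tuple[int, Optional[int]]]  # id -> (species, genus)

    def __post_init__(self) -> None:
        missing = [h for h, _ in self.records if h not in self.correspondence]
        if missing:
            raise ValidationError(
                "records without correspondence entry: " + ", ".join(missing)
            )

    def __len__(self) -> int:
        return len(self.records)

    def species_ids(self) -> set[int]:
        return {self.correspondence[h][0] for h, _ in self.records}


def read_catalog(
    fasta_source: Union[str, IO[str]],
    correspondence_source: Union[str, IO[str]],
) -> SequenceCatalog:
    """Join a multi-FASTA with its (header, species_taxid[, genus_taxid])
    table. The header key is the first whitespace-delimited token."""
    correspondence: dict[str, tuple[int, Optional[int]]] = {}
    lines = (
        correspondence_source.splitlines()
        if isinstance(correspondence_source, str)
        else correspondence_source
    )
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError(
                f"correspondence line {lineno}: expected header<TAB>species_taxid"
            )
        header_id = parts[0].strip()
        if header_id in correspondence:
            raise ValidationError(
                f"correspondence line {lineno}: duplicate header {header_id!r}"
            )
        try:
            species = int(parts[1])
            genus = int(parts[2]) if len(parts) > 2 and parts[2].strip() else None
        except ValueError as exc:
            raise ParseError(f"correspondence line {lineno}: non-integer taxID") from exc
        correspondence[header_id] = (species, genus)

    if isinstance(fasta_source, str):
        fasta_source = StringIO(fasta_source)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(fasta_source, "fasta"):
        header_id = rec.id  # biopython takes the first whitespace token
        if header_id in seen:
            raise ValidationError(f"duplicate FASTA header {header_id!r}")
        seen.add(header_id)
        records.append((header_id, str(rec.seq)))
    orphans = [h for h, _ in records if h not in correspondence]
    if orphans:
        raise ValidationError(
            "FASTA headers missing from correspondence table: "
            + ", ".join(sorted(orphans))
        )
    return SequenceCatalog(records, correspondence)


def filter_catalog(catalog: SequenceCatalog, keep: KeepList) -> SequenceCatalog:
    """Retain exactly the records whose species taxID is in the keep-list,
    preserving input order."""
    kept = [
        (h, s)
        for h, s in catalog.records
        if catalog.correspondence[h][0] in keep.tax_ids
    ]
    if not kept:
        logger.warning("keep-list matched no catalog records")
    return SequenceCatalog(kept, dict(catalog.correspondence))


def write_library(
    catalog: SequenceCatalog, style: str = "map-file"
) -> tuple[str, str]:
    """Emit the filtered library as ``(fasta_text, seqid2taxid_text)``.

    ``header-embedded`` rewrites each header to the classifier dialect
    ``<id>|kraken:taxid|<species_taxid>`` (the map text is then empty);
    ``map-file`` leaves headers intact and fills the tab-delimited map.
    """
    if style not in ("header-embedded", "map-file"):
        raise ValueError(f"unknown style {style!r}")
    if not catalog.records:
        logger.warning("writing an empty library")
    fasta = StringIO()
    map_lines: list[str] = []
    seq_records = []
    for header_id, sequence in catalog.records:
        species = catalog.correspondence[header_id][0]
        if style == "header-embedded":
            out_id = f"{header_id}|kraken:taxid|{species}"
        else:
            out_id = header_id
            map_lines.append(f"{header_id}\t{species}")
        seq_records.append(SeqRecord(Seq(sequence), id=out_id, description=""))
    writer = SeqIO.FastaIO.FastaWriter(fasta, wrap=FASTA_WRAP)
    writer.write_file(seq_records)
    map_text = "\n".join(map_lines) + "\n" if map_lines else ""
    return fasta.getvalue(), map_text


def audit_library(
    catalog: SequenceCatalog, map_text: str
) -> list[str]:
    """Consistency audit: every map line's taxID must equal the catalog's
    correspondence entry for its header. Returns a list of discrepancies
    (empty when consistent)."""
    problems: list[str] = []
    for line in map_text.splitlines():
        if not line.strip():
            continue
        header_id, tax_str = line.split("\t")
        expected = catalog.correspondence.get(header_id)
        if expected is None:
            problems.append(f"map header {header_id!r} not in catalog")
        elif expected[0] != int(tax_str):
            problems.append(
                f"map taxID {tax_str} != correspondence {expected[0]} "
                f"for {header_id!r}"
            )
    return problems
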
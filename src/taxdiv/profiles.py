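"""MetaPhlAn-style merged profile parsing and keep-list derivation.

The merged profile (one clade row per taxon, one column per sample,
relative abundances in percent) is the boundary between upstream marker
classification and database construction: the species detected in it
define which taxIDs the project-specific database keeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import numpy as np

from .errors import ParseError
from .taxonomy import Taxonomy, resolve_genus

logger = logging.getLogger(__name__)


@dataclass
class MergedProfile:
    """Clade rows by sample, as parsed from a merged-abundance table."""

    clade_rows: list[tuple[str, np.ndarray]]
    sample_ids: list[str]

    def species_rows(self) -> list[tuple[str, np.ndarray]]:
        """Rows resolved to species level: an ``s__`` component present,
        no strain (``t__``) component."""
        out = []
        for clade, values in self.clade_rows:
            parts = clade.split("|")
            if any(p.startswith("s__") for p in parts) and not any(
                p.startswith("t__") for p in parts
            ):
                out.append((clade, values))
        return out


@dataclass
class NameTaxidMap:
    """Species-name token (``s__Genus_species``) to species taxID."""

    entries: dict[str, int]

    @staticmethod
    def _normalize(name: str) -> str:
        token = name.strip().replace(" ", "_")
        if not token.startswith("s__"):
            token = "s__" + token
        return token

    def lookup(self, name: str) -> Optional[int]:
        return self.entries.get(self._normalize(name))

    @classmethod
    def read(cls, source: Union[str, IO[str]]) -> "NameTaxidMap":
        """Read tab-delimited (name, tax_id) rows; ``#`` lines are comments."""
        entries: dict[str, int] = {}
        lines = source.splitlines() if isinstance(source, str) else source
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected name<TAB>tax_id")
            token = cls._normalize(parts[0])
            try:
                tax_id = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer tax_id") from exc
            if token in entries and entries[token] != tax_id:
                raise ParseError(f"line {lineno}: conflicting entry for {token}")
            entries[token] = tax_id
        return cls(entries)


@dataclass
class KeepList:
    """Species taxIDs to retain in the filtered database."""

    tax_ids: set[int]
    level: str  # "species" | "genus"
    unmatched: list[str] = field(default_factory=list)

    def write(self) -> str:
        """One taxID per line (the txids-list file shape)."""
        return "\n".join(str(t) for t in sorted(self.tax_ids)) + "\n"

    @classmethod
    def read(cls, source: Union[str, IO[str]], level: str = "species") -> "KeepList":
        lines = source.splitlines() if isinstance(source, str) else source
        ids = {int(line) for line in lines if line.strip()}
        return cls(ids, level)


def read_merged_profile(source: Union[str, IO[str]]) -> MergedProfile:
    """Parse a merged-abundance table.

    Lines starting with ``#`` are comments; the first remaining line is a
    header whose first column names the clade and the rest name samples.
    """
    lines = [
        ln
        for ln in (source.splitlines() if isinstance(source, str) else source)
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ParseError("empty profile: no header line")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError("header has no sample columns")
    sample_ids = [h.strip() for h in header[1:]]
    rows: list[tuple[str, np.ndarray]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"line {lineno}: {len(parts)} fields, expected {len(header)}"
            )
        try:
            values = np.array([float(v) for v in parts[1:]], dtype=float)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric abundance") from exc
        if (values < 0).any():
            raise ParseError(f"line {lineno}: negative abundance")
        rows.append((parts[0].strip(), values))
    return MergedProfile(rows, sample_ids)


def detected_species(
    profile: MergedProfile, min_abundance: float = 0.0
) -> set[str]:
    """Species tokens with relative abundance > ``min_abundance`` in at
    least one sample."""
    out: set[str] = set()
    for clade, values in profile.species_rows():
        if (values > min_abundance).any():
            token = next(p for p in clade.split("|") if p.startswith("s__"))
            out.add(token)
    return out


def build_keep_list(
    profile: MergedProfile,
    names: NameTaxidMap,
    tax: Taxonomy,
    catalog_species: Iterable[int],
    level: str = "species",
    min_abundance: float = 0.0,
) -> KeepList:
    """Derive the taxID keep-list at species or genus granularity.

    Species level keeps exactly the detected species that are present in
    the sequence catalog. Genus level additionally keeps every catalog
    species whose resolved genus matches the genus of any detected
    species, even when that species itself went undetected. Detected
    names with no taxID mapping are reported in ``KeepList.unmatched``
    and skipped.
    """
    if level not in ("species", "genus"):
        raise ValueError(f"level must be 'species' or 'genus', got {level!r}")
    catalog = set(catalog_species)
    unmatched: list[str] = []
    detected_ids: set[int] = set()
    for token in sorted(detected_species(profile, min_abundance)):
        tax_id = names.lookup(token)
        if tax_id is None:
            unmatched.append(token)
            logger.warning("no taxID mapping for detected species %s", token)
        else:
            detected_ids.add(tax_id)

    keep = detected_ids & catalog
    if level == "genus":
        def genus_of(tax_id: int) -> Optional[int]:
            # tolerate catalog rows that are not species in this taxonomy
            if tax_id not in tax or tax[tax_id].rank != "species":
                return None
            return resolve_genus(tax, tax_id)

        detected_genera = set()
        for tax_id in detected_ids:
            genus = genus_of(tax_id)
            if genus is None:
                logger.info(
                    "species %d has no resolvable genus; not expanded", tax_id
                )
            else:
                detected_genera.add(genus)
        for tax_id in catalog:
            if genus_of(tax_id) in detected_genera:
                keep.add(tax_id)
    return KeepList(keep, level, unmatched)
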
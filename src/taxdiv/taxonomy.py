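"""NCBI-style taxonomy: dump parsing, lineage walks and genus resolution.

The taxonomy is the backbone of database subsetting and tree augmentation.
Species are grouped into "genera" in an operational sense: the nearest
ancestor explicitly ranked ``genus``, or — where NCBI provides none — an
unranked grouping node (rank ``no rank`` or ``clade``) sitting between the
species and its family-level ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Optional, Union

from .errors import LookupError_, ParseError, ValidationError

#: ranks that terminate the genus search upward from a species
FAMILY_LEVEL_RANKS = frozenset({"family", "subfamily", "tribe", "subtribe"})

#: unranked tokens that may stand in for a genus below a family-level node
GENUS_SURROGATE_RANKS = frozenset({"no rank", "clade"})


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy (a row of a nodes dump)."""

    tax_id: int
    parent_id: int
    rank: str
    name: str = ""


class Taxonomy:
    """A rooted forest of :class:`TaxonNode` keyed by taxID.

    The root is the unique node whose parent is itself (taxID 1 in real
    NCBI dumps). Every lineage walk terminates at the root.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        root_id: Optional[int] = None
        for node in nodes:
            if node.tax_id in self.nodes:
                raise ValidationError(f"duplicate tax_id {node.tax_id}")
            self.nodes[node.tax_id] = node
            if node.parent_id == node.tax_id:
                if root_id is not None:
                    raise ValidationError(
                        f"multiple roots: {root_id} and {node.tax_id}"
                    )
                root_id = node.tax_id
        if not self.nodes:
            raise ValidationError("empty taxonomy")
        if root_id is None:
            raise ValidationError("no root node (parent_id == tax_id) found")
        self.root_id = root_id
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise ValidationError(
                    f"node {node.tax_id} has unknown parent {node.parent_id}"
                )
        # cycle check: every walk must reach the root in <= |nodes| steps
        bound = len(self.nodes)
        for start in self.nodes:
            current, steps = start, 0
            while current != self.root_id:
                current = self.nodes[current].parent_id
                steps += 1
                if steps > bound:
                    raise ValidationError(f"cycle detected through tax_id {start}")

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def __getitem__(self, tax_id: int) -> TaxonNode:
        try:
            return self.nodes[tax_id]
        except KeyError:
            raise LookupError_(f"unknown tax_id {tax_id}") from None

    def name_of(self, tax_id: int) -> str:
        return self[tax_id].name


def _dump_fields(line: str, lineno: int, min_fields: int) -> list[str]:
    # dump dialect: fields separated by "\t|\t", line terminated "\t|"
    stripped = line.rstrip("\n")
    if stripped.endswith("\t|"):
        stripped = stripped[: -len("\t|")]
    fields = stripped.split("\t|\t")
    if len(fields) < min_fields:
        raise ParseError(
            f"line {lineno}: expected >= {min_fields} '\\t|\\t'-separated "
            f"fields, got {len(fields)}"
        )
    return fields


def _as_lines(source: Union[str, IO[str]]) -> Iterable[str]:
    if isinstance(source, str):
        return source.splitlines()
    return source


def parse_taxonomy(
    nodes_source: Union[str, IO[str]],
    names_source: Union[str, IO[str], None] = None,
) -> Taxonomy:
    """Parse nodes/names dump text into a :class:`Taxonomy`.

    ``names_source`` is optional; only ``scientific name`` entries are
    used, and nodes without one keep an empty name. All downstream
    computation keys on taxIDs, so names are purely cosmetic.
    """
    names: dict[int, str] = {}
    if names_source is not None:
        for lineno, line in enumerate(_as_lines(names_source), start=1):
            if not line.strip():
                continue
            fields = _dump_fields(line, lineno, 4)
            if fields[3].strip() == "scientific name":
                names[int(fields[0])] = fields[1].strip()

    nodes: list[TaxonNode] = []
    seen: set[int] = set()
    for lineno, line in enumerate(_as_lines(nodes_source), start=1):
        if not line.strip():
            continue
        fields = _dump_fields(line, lineno, 3)
        try:
            tax_id = int(fields[0])
            parent_id = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer tax_id field") from exc
        rank = fields[2].strip()
        if not rank:
            raise ParseError(f"line {lineno}: empty rank token")
        if tax_id in seen:
            raise ValidationError(f"line {lineno}: duplicate tax_id {tax_id}")
        seen.add(tax_id)
        nodes.append(TaxonNode(tax_id, parent_id, rank, names.get(tax_id, "")))
    if not nodes:
        raise ParseError("empty nodes dump")
    return Taxonomy(nodes)


def write_nodes_dump(tax: Taxonomy) -> str:
    """Serialize back to the nodes-dump dialect (inverse of parsing)."""
    return "".join(
        f"{n.tax_id}\t|\t{n.parent_id}\t|\t{n.rank}\t|\n"
        for n in tax.nodes.values()
    )


def write_names_dump(tax: Taxonomy) -> str:
    """Serialize scientific names to the names-dump dialect."""
    return "".join(
        f"{n.tax_id}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n"
        for n in tax.nodes.values()
        if n.name
    )


def lineage_of(tax: Taxonomy, tax_id: int) -> list[TaxonNode]:
    """Ordered lineage from the node itself up to (and including) the root."""
    node = tax[tax_id]
    lineage = [node]
    while node.tax_id != tax.root_id:
        node = tax[node.parent_id]
        lineage.append(node)
    return lineage


def resolve_genus(tax: Taxonomy, species_id: int) -> Optional[int]:
    """Resolve the operational genus of a species.

    Walking from the species upward: the first ancestor ranked ``genus``
    wins. If a family-level ancestor (family/subfamily/tribe/subtribe) is
    reached first, the ``no rank``/``clade`` ancestor closest to the
    species (the most specific unranked grouping) is returned instead;
    ``None`` if there is no such surrogate, or if the walk reaches the
    root without meeting either a genus or a family-level barrier.
    """
    node = tax[species_id]
    if node.rank != "species":
        raise ValidationError(
            f"tax_id {species_id} has rank {node.rank!r}, expected 'species'"
        )
    surrogate: Optional[int] = None
    current = node
    while current.tax_id != tax.root_id:
        current = tax[current.parent_id]
        if current.rank == "genus":
            return current.tax_id
        if current.rank in FAMILY_LEVEL_RANKS:
            return surrogate
        if current.rank in GENUS_SURROGATE_RANKS and surrogate is None:
            if current.tax_id != tax.root_id:
                surrogate = current.tax_id
    return None
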
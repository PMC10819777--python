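"""Placement of species without reference sequences into an existing tree.

A species absent from the 16S tree is placed using its taxonomy: walking
up its lineage, the first ancestor with any leaves already in the tree
defines the reference group G. A single-member group is handled by the
midpoint rule (split the anchor's branch in half and hang the new leaf
off the new inner node at the same half-length). Larger groups select an
attachment node by scanning every node of the tree and maximizing

    purity(n) + inclusiveness(n)

subject to inclusiveness(n) strictly above a floor (default 60%), where
purity is the fraction of n's descendant leaves that belong to G and
inclusiveness is the fraction of G found under n. The new leaf joins the
selected node with a branch equal to the mean distance from that node to
the G members below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from skbio import TreeNode

from .errors import ValidationError
from .taxonomy import TaxonNode, Taxonomy, lineage_of
from .tree import PhyloTree


@dataclass(frozen=True)
class GraftConfig:
    """Tunables of the placement scan."""

    inclusiveness_floor: float = 0.6

    def __post_init__(self) -> None:
        if not (0 <= self.inclusiveness_floor < 1):
            raise ValueError("inclusiveness_floor must be in [0, 1)")

    @property
    def floor_fraction(self) -> Fraction:
        # via the decimal string so 0.6 means exactly 3/5
        return Fraction(str(self.inclusiveness_floor))


@dataclass(frozen=True)
class GraftReport:
    species_id: int
    node_id: int
    purity: float
    inclusiveness: float
    new_edge_length: float
    mechanism: str  # "midpoint" | "maximization"
    rank_used: Optional[str] = None


def reports_to_tsv(reports: Sequence[GraftReport]) -> str:
    header = (
        "species_id\tnode_id\tpurity\tinclusiveness\t"
        "new_edge_length\tmechanism\trank_used"
    )
    lines = [header]
    for r in reports:
        lines.append(
            f"{r.species_id}\t{r.node_id}\t{r.purity:.6g}\t"
            f"{r.inclusiveness:.6g}\t{r.new_edge_length:.6g}\t"
            f"{r.mechanism}\t{r.rank_used or ''}"
        )
    return "\n".join(lines) + "\n"


# -- reference group ---------------------------------------------------------


def _leaf_ancestor_index(
    tax: Taxonomy, leaf_labels: Sequence[str], leaf_taxids: Mapping[str, int]
) -> dict[int, set[str]]:
    index: dict[int, set[str]] = {}
    for label in leaf_labels:
        tax_id = leaf_taxids[label]
        if tax_id not in tax:
            continue
        for anc in lineage_of(tax, tax_id):
            index.setdefault(anc.tax_id, set()).add(label)
    return index


def _default_leaf_taxids(tree: PhyloTree) -> dict[str, int]:
    out: dict[str, int] = {}
    for label in tree.leaf_labels():
        try:
            out[label] = int(label)
        except ValueError:
            raise ValidationError(
                f"leaf label {label!r} is not a taxID; pass leaf_taxids explicitly"
            ) from None
    return out


def reference_group(
    tax: Taxonomy,
    tree: PhyloTree,
    missing_species: int,
    leaf_taxids: Optional[Mapping[str, int]] = None,
) -> tuple[set[str], TaxonNode]:
    """Leaves related to ``missing_species`` at the lowest taxonomic level
    represented in the tree, plus the ancestor that defined them."""
    if leaf_taxids is None:
        leaf_taxids = _default_leaf_taxids(tree)
    labels = tree.leaf_labels()
    if missing_species in {leaf_taxids[l] for l in labels}:
        raise ValidationError(f"species {missing_species} is already a leaf")
    index = _leaf_ancestor_index(tax, labels, leaf_taxids)
    for anc in lineage_of(tax, missing_species)[1:]:
        members = index.get(anc.tax_id)
        if members:
            return set(members), anc
    raise ValidationError(
        f"no ancestor of species {missing_species} has any leaf in the tree"
    )


# -- scoring -----------------------------------------------------------------


def _score(leafset: frozenset[str], group: frozenset[str]) -> tuple[Fraction, Fraction]:
    overlap = len(leafset & group)
    return Fraction(overlap, len(leafset)), Fraction(overlap, len(group))


def score_node(
    tree: PhyloTree, node: TreeNode, group: set[str]
) -> tuple[float, float]:
    """(purity, inclusiveness) of one node against a leaf group."""
    if not group:
        raise ValidationError("empty reference group")
    leafset = tree.leaf_sets()[node.node_id]
    purity, incl = _score(leafset, frozenset(group))
    return float(purity), float(incl)


# -- grafting mechanisms ------------------------------------------------------


def _graft_midpoint_inplace(
    tree: PhyloTree, anchor_label: str, new_label: str, species_id: int = -1,
    rank_used: Optional[str] = None,
) -> GraftReport:
    if new_label in tree.leaf_labels():
        raise ValidationError(f"label {new_label!r} already in tree")
    anchor = tree.find_leaf(anchor_label)
    if not anchor.is_tip():
        raise ValidationError(f"{anchor_label!r} is not a leaf")
    parent = anchor.parent
    if parent is None:
        raise ValidationError("cannot midpoint-graft onto a single-node tree")
    half = anchor.length / 2.0
    anchor_id = anchor.node_id
    parent.remove(anchor)
    midnode = TreeNode(length=half)
    anchor.length = half
    midnode.append(anchor)
    midnode.append(TreeNode(name=new_label, length=half))
    parent.append(midnode)
    tree.root.clear_caches()
    tree._reindex()
    return GraftReport(
        species_id=species_id,
        node_id=anchor_id,
        purity=1.0,
        inclusiveness=1.0,
        new_edge_length=half,
        mechanism="midpoint",
        rank_used=rank_used,
    )


def graft_midpoint(
    tree: PhyloTree, anchor_label: str, new_label: str
) -> tuple[PhyloTree, GraftReport]:
    """Hang ``new_label`` next to ``anchor_label``, splitting its branch
    at the midpoint. Returns a new tree; the input is untouched."""
    out = tree.copy()
    report = _graft_midpoint_inplace(out, anchor_label, new_label)
    return out, report


def _select_node(
    tree: PhyloTree, group: frozenset[str], cfg: GraftConfig
) -> tuple[TreeNode, Fraction, Fraction]:
    """Scan every node; maximize purity + inclusiveness subject to the
    strict inclusiveness floor. Ties: higher purity, then fewer
    descendant leaves, then smallest canonical node_id."""
    leaf_sets = tree.leaf_sets()
    floor = cfg.floor_fraction
    best = None
    best_key = None
    for node in tree.nodes():
        leafset = leaf_sets[node.node_id]
        purity, incl = _score(leafset, group)
        if incl <= floor:
            continue
        key = (purity + incl, purity, -len(leafset), -node.node_id)
        if best_key is None or key > best_key:
            best, best_key = (node, purity, incl), key
    if best is None:  # unreachable for floor < 1: the root has incl == 1
        raise ValidationError("no node satisfies the inclusiveness floor")
    return best


def graft_maximize(
    tree: PhyloTree,
    group: set[str],
    new_label: str,
    cfg: Optional[GraftConfig] = None,
    species_id: int = -1,
    rank_used: Optional[str] = None,
) -> tuple[PhyloTree, GraftReport]:
    """Place ``new_label`` at the node maximizing purity + inclusiveness
    over the reference group. Returns a new tree; the input is untouched."""
    cfg = cfg or GraftConfig()
    missing = set(group) - set(tree.leaf_labels())
    if missing:
        raise ValidationError(f"group members not in tree: {sorted(missing)}")
    out = tree.copy()
    report = _graft_maximize_inplace(
        out, frozenset(group), new_label, cfg, species_id, rank_used
    )
    return out, report


def _graft_maximize_inplace(
    tree: PhyloTree,
    group: frozenset[str],
    new_label: str,
    cfg: GraftConfig,
    species_id: int = -1,
    rank_used: Optional[str] = None,
) -> GraftReport:
    if new_label in tree.leaf_labels():
        raise ValidationError(f"label {new_label!r} already in tree")
    node, purity, incl = _select_node(tree, group, cfg)
    if node.is_tip():
        rep = _graft_midpoint_inplace(
            tree, node.name, new_label, species_id, rank_used
        )
        return GraftReport(
            species_id=species_id,
            node_id=rep.node_id,
            purity=float(purity),
            inclusiveness=float(incl),
            new_edge_length=rep.new_edge_length,
            mechanism="midpoint",
            rank_used=rank_used,
        )
    # mean distance from the selected node down to its G members
    members = tree.leaf_sets()[node.node_id] & group
    node_depth = tree.depth_of(node)
    dists = [tree.depth_of(tree.find_leaf(m)) - node_depth for m in members]
    edge = sum(dists) / len(dists)
    node_id = node.node_id
    node.append(TreeNode(name=new_label, length=edge))
    tree.root.clear_caches()
    tree._reindex()
    return GraftReport(
        species_id=species_id,
        node_id=node_id,
        purity=float(purity),
        inclusiveness=float(incl),
        new_edge_length=edge,
        mechanism="maximization",
        rank_used=rank_used,
    )


# -- batch augmentation -------------------------------------------------------


def augment_tree(
    tree: PhyloTree,
    tax: Taxonomy,
    missing: Sequence[int],
    cfg: Optional[GraftConfig] = None,
    leaf_taxids: Optional[Mapping[str, int]] = None,
) -> tuple[PhyloTree, list[GraftReport]]:
    """Graft every species in ``missing`` into the tree.

    Species are processed in ascending taxID order and each grafted leaf
    immediately becomes available as a reference-group member for the
    species placed after it. New leaves are labeled with their taxID.
    """
    cfg = cfg or GraftConfig()
    out = tree.copy()
    taxids = dict(leaf_taxids) if leaf_taxids else _default_leaf_taxids(out)
    present = set(taxids.values())
    reports: list[GraftReport] = []
    for species_id in sorted(missing):
        if species_id in present:
            raise ValidationError(f"species {species_id} is already a leaf")
        if species_id not in tax:
            raise ValidationError(f"species {species_id} not in taxonomy")
        group, anc = reference_group(tax, out, species_id, taxids)
        new_label = str(species_id)
        if len(group) == 1:
            report = _graft_midpoint_inplace(
                out, next(iter(group)), new_label, species_id, anc.rank
            )
        else:
            report = _graft_maximize_inplace(
                out, frozenset(group), new_label, cfg, species_id, anc.rank
            )
        reports.append(report)
        taxids[new_label] = species_id
        present.add(species_id)
    return out, reports
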
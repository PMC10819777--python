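"""Synthetic taxonomies, trees, profiles and abundance tables.

Every generator is a pure function of its seed, so fixtures are built at
test time instead of being shipped. The community simulator mirrors the
standard log-normal parameterization of metagenomic read simulators:
per-species abundances are drawn log-normally (underlying normal mean 1
by default) and normalized within each sample; read counts are then
multinomial at a fixed depth, which is the part of read simulation that
matters to count-based downstream statistics.

The low/high taxonomic diversity contrast (LD-18 vs HD-18) keeps species
richness and abundance spread identical — 18 species per sample, same
sigma — and varies only how those species distribute over genera: LD
draws them from 2 genera (10 + 8 species), HD from 18 distinct genera.
Phylogeny-blind metrics see two statistically identical designs;
phylogeny-aware metrics see shallow clades against deep ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .profiles import NameTaxidMap
from .taxonomy import Taxonomy, TaxonNode, lineage_of
from .tree import PhyloTree

# -- designs -----------------------------------------------------------------


@dataclass(frozen=True)
class CommunityDesign:
    """One group of samples over a fixed species pool."""

    n_species: int
    genus_partition: tuple[int, ...]
    n_samples: int
    lognormal_mu: float = 1.0
    lognormal_sigma: float = 2.0
    depth: int = 100_000
    seed: int = 0
    mean_is_log: bool = True  # mu is the underlying normal's mean

    def __post_init__(self) -> None:
        if sum(self.genus_partition) != self.n_species:
            raise ValueError("genus_partition must sum to n_species")
        if any(s <= 0 for s in self.genus_partition):
            raise ValueError("genus sizes must be positive")
        if self.lognormal_sigma < 0 or self.depth < 0:
            raise ValueError("sigma and depth must be non-negative")


@dataclass(frozen=True)
class LdHdDesign:
    """The paired low/high taxonomic-diversity study design."""

    n_samples: int = 50
    sigma: float = 2.0
    depth: int = 100_000
    seed: int = 0
    ld_genus_sizes: tuple[int, ...] = (10, 8)
    hd_n_genera: int = 18
    lognormal_mu: float = 1.0


# -- abundance simulation ----------------------------------------------------


def simulate_abundances(
    design: CommunityDesign, species_ids: Optional[Sequence] = None
) -> pd.DataFrame:
    """Relative-abundance table (species × samples), columns summing to 1."""
    rng = np.random.default_rng(design.seed)
    if design.mean_is_log:
        mean = design.lognormal_mu
    else:
        # interpret mu as the log-normal expectation instead
        if design.lognormal_mu <= 0:
            raise ValueError("expectation parameterization needs mu > 0")
        mean = np.log(design.lognormal_mu) - design.lognormal_sigma**2 / 2
    raw = rng.lognormal(
        mean=mean,
        sigma=design.lognormal_sigma,
        size=(design.n_species, design.n_samples),
    )
    rel = raw / raw.sum(axis=0)
    index = (
        list(species_ids)
        if species_ids is not None
        else [f"sp{i + 1}" for i in range(design.n_species)]
    )
    columns = [f"sample{j + 1}" for j in range(design.n_samples)]
    return pd.DataFrame(rel, index=index, columns=columns)


def simulate_counts(
    rel_abundances: pd.DataFrame, depth: int, seed: int = 0
) -> pd.DataFrame:
    """Multinomial read counts at fixed depth per sample."""
    totals = rel_abundances.sum(axis=0)
    if not np.allclose(totals, 1.0):
        raise ValueError("columns must sum to 1")
    rng = np.random.default_rng(seed)
    counts = np.column_stack(
        [
            rng.multinomial(depth, rel_abundances[c] / totals[c])
            for c in rel_abundances.columns
        ]
    )
    return pd.DataFrame(
        counts, index=rel_abundances.index, columns=rel_abundances.columns
    )


# -- taxonomy / tree generators ----------------------------------------------


def random_taxonomy(
    genus_sizes: Sequence[int], seed: int = 0, p_no_rank: float = 0.0
) -> tuple[Taxonomy, list[list[int]]]:
    """A taxonomy of one family + one genus per group, each genus holding
    the requested number of species. With probability ``p_no_rank`` a
    species sits under an extra unranked node inside its genus. Returns
    the taxonomy and the species taxIDs grouped by genus."""
    rng = np.random.default_rng(seed)
    nodes = [TaxonNode(1, 1, "no rank", "root")]
    next_id = 2
    species_by_genus: list[list[int]] = []
    for gi, size in enumerate(genus_sizes):
        family_id = next_id
        nodes.append(TaxonNode(family_id, 1, "family", f"Family{gi + 1}"))
        next_id += 1
        genus_id = next_id
        nodes.append(TaxonNode(genus_id, family_id, "genus", f"Genus{gi + 1}"))
        next_id += 1
        ids = []
        for si in range(size):
            parent = genus_id
            if rng.random() < p_no_rank:
                nodes.append(TaxonNode(next_id, genus_id, "no rank", ""))
                parent = next_id
                next_id += 1
            nodes.append(
                TaxonNode(next_id, parent, "species", f"Genus{gi + 1} sp{si + 1}")
            )
            ids.append(next_id)
            next_id += 1
        species_by_genus.append(ids)
    return Taxonomy(nodes), species_by_genus


def random_tree(
    species_by_genus: Sequence[Sequence[int]],
    seed: int = 0,
    max_within_depth: float = 0.1,
    min_genus_depth: float = 0.5,
) -> PhyloTree:
    """A genus-clade tree: congeners coalesce at shallow depth (at most
    ``max_within_depth``), distinct genera only near the root (leaf depth
    around 1, genus stems at least ``min_genus_depth``)."""
    rng = np.random.default_rng(seed)
    root = TreeNode(length=0.0)
    for ids in species_by_genus:
        total_depth = rng.uniform(max(0.8, min_genus_depth), 1.0)
        if len(ids) == 1:
            root.append(TreeNode(name=str(ids[0]), length=total_depth))
            continue
        within = rng.uniform(0.02, max_within_depth)
        clade = TreeNode(length=total_depth - within)
        for tax_id in ids:
            leaf_len = within * rng.uniform(0.5, 1.0)
            clade.append(TreeNode(name=str(tax_id), length=leaf_len))
        root.append(clade)
    return PhyloTree(root)


# -- the LD/HD study ---------------------------------------------------------


def simulate_ld_hd(
    design: LdHdDesign = LdHdDesign(),
) -> tuple[pd.DataFrame, list[str], PhyloTree, Taxonomy]:
    """Simulate the paired LD-18 / HD-18 experiment.

    Returns (counts, labels, tree, taxonomy): a species × sample count
    table over both groups' species pools (a group's absent species sit
    at 0), per-sample group labels, and the genus-clade tree/taxonomy
    covering all species.
    """
    genus_sizes = tuple(design.ld_genus_sizes) + (1,) * design.hd_n_genera
    tax, by_genus = random_taxonomy(genus_sizes, seed=design.seed)
    tree = random_tree(by_genus, seed=design.seed)
    n_ld_genera = len(design.ld_genus_sizes)
    ld_species = [s for g in by_genus[:n_ld_genera] for s in g]
    hd_species = [s for g in by_genus[n_ld_genera:] for s in g]

    rng = np.random.default_rng(design.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    tables = []
    labels: list[str] = []
    for group, species, s_ab, s_ct in (
        ("LD", ld_species, seeds[0], seeds[1]),
        ("HD", hd_species, seeds[2], seeds[3]),
    ):
        cd = CommunityDesign(
            n_species=len(species),
            genus_partition=(len(species),),
            n_samples=design.n_samples,
            lognormal_mu=design.lognormal_mu,
            lognormal_sigma=design.sigma,
            depth=design.depth,
            seed=int(s_ab),
        )
        rel = simulate_abundances(cd, species_ids=species)
        counts = simulate_counts(rel, design.depth, seed=int(s_ct))
        counts.columns = [f"{group}_{j + 1}" for j in range(design.n_samples)]
        tables.append(counts)
        labels.extend([group] * design.n_samples)
    combined = (
        pd.concat(tables, axis=1)
        .reindex(ld_species + hd_species)
        .fillna(0)
        .astype(int)
    )
    combined.index = [str(i) for i in combined.index]
    return combined, labels, tree, tax


# -- fixture writers ---------------------------------------------------------


def species_name_map(tax: Taxonomy) -> NameTaxidMap:
    """Name→taxID map over every species in a (synthetic) taxonomy."""
    entries = {}
    for node in tax.nodes.values():
        if node.rank == "species" and node.name:
            entries["s__" + node.name.replace(" ", "_")] = node.tax_id
    return NameTaxidMap(entries)


def _clade_string(tax: Taxonomy, species_id: int) -> str:
    names = {n.rank: n.name for n in lineage_of(tax, species_id)}
    family = names.get("family", "unclassified")
    genus = names.get("genus", "unclassified")
    species = names.get("species", str(species_id)).replace(" ", "_")
    return f"k__Bacteria|f__{family}|g__{genus}|s__{species}"


def write_fixture_profile(
    rel_table: pd.DataFrame, tax: Taxonomy
) -> str:
    """Merged-profile text (percent units) for a relative-abundance table
    whose index holds species taxIDs of ``tax``."""
    lines = ["#synthetic merged taxonomic profile"]
    lines.append("clade_name\t" + "\t".join(str(c) for c in rel_table.columns))
    for tax_id, row in rel_table.iterrows():
        clade = _clade_string(tax, int(tax_id))
        values = "\t".join(f"{100 * v:.6f}" for v in row)
        lines.append(f"{clade}\t{values}")
    return "\n".join(lines) + "\n"


def random_catalog_text(
    species_ids: Sequence[int],
    seed: int = 0,
    seqs_per_species: int = 1,
    seq_length: int = 60,
) -> tuple[str, str]:
    """(fasta_text, correspondence_text) with random nucleotide sequences,
    one or more per species."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    fasta_lines: list[str] = []
    corr_lines: list[str] = []
    for sp in species_ids:
        for k in range(seqs_per_species):
            header = f"seq_{sp}_{k + 1}"
            seq = "".join(rng.choice(alphabet, size=seq_length))
            fasta_lines.append(f">{header}")
            fasta_lines.append(seq)
            corr_lines.append(f"{header}\t{sp}")
    return "\n".join(fasta_lines) + "\n", "\n".join(corr_lines) + "\n"
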
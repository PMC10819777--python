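"""Alpha/beta diversity, count normalization and group statistics.

The metrics come in phylogeny-blind / phylogeny-aware pairs — Shannon
entropy vs Faith's phylogenetic diversity for alpha, Bray–Curtis vs
normalized weighted UniFrac for beta — so that the gain in statistical
power from a phylogeny can be measured on the same samples. Counts feed
alpha diversity raw; beta diversity consumes counts scaled by
median-of-ratios size factors.

Tables are plain :class:`pandas.DataFrame` objects with species on the
rows and samples on the columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .tree import PhyloTree

# -- alpha -------------------------------------------------------------------


def shannon(counts: Iterable[float], base: Optional[float] = None) -> float:
    """Shannon entropy H = −Σ pᵢ log pᵢ over positive entries (nats by
    default; pass ``base`` for other units)."""
    x = np.asarray(list(counts), dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundance")
    total = x.sum()
    if total <= 0:
        raise ValidationError("all-zero sample")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def faiths_pd(
    tree: PhyloTree, present: Iterable[str], rooted: bool = True
) -> float:
    """Faith's phylogenetic diversity of a set of leaves.

    Rooted convention (default): sum of branch lengths of the minimal
    subtree connecting the leaves *and the root*, so a single species
    contributes its full root-to-leaf path. The unrooted variant counts
    only branches on paths between the leaves themselves.
    """
    targets = set(present)
    if not targets:
        raise ValidationError("empty species set")
    unknown = targets - set(tree.leaf_labels())
    if unknown:
        raise ValidationError(f"species not in tree: {sorted(unknown)}")
    leaf_sets = tree.leaf_sets()
    total = 0.0
    n = len(targets)
    root_id = tree.root.node_id
    for node in tree.nodes():
        if node.node_id == root_id:
            continue
        overlap = len(leaf_sets[node.node_id] & targets)
        if (rooted and overlap > 0) or (not rooted and 0 < overlap < n):
            total += node.length
    return total


# -- beta --------------------------------------------------------------------


def bray_curtis(x: Iterable[float], y: Iterable[float]) -> float:
    """Bray–Curtis dissimilarity Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)."""
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    if a.shape != b.shape:
        raise ValidationError("length mismatch")
    denom = (a + b).sum()
    if denom <= 0:
        raise ValidationError("both samples are all-zero")
    return float(np.abs(a - b).sum() / denom)


class _BranchSystem:
    """Branch lengths and branch × species incidence for fast UniFrac."""

    def __init__(self, tree: PhyloTree, species: Sequence[str]):
        labels = set(tree.leaf_labels())
        unknown = [s for s in species if s not in labels]
        if unknown:
            raise ValidationError(f"species not in tree: {sorted(unknown)}")
        col = {s: j for j, s in enumerate(species)}
        leaf_sets = tree.leaf_sets()
        lengths = []
        rows = []
        root_id = tree.root.node_id
        for node in tree.nodes():
            if node.node_id == root_id:
                continue
            lengths.append(node.length)
            row = np.zeros(len(species))
            for s in leaf_sets[node.node_id] & col.keys():
                row[col[s]] = 1.0
            rows.append(row)
        self.lengths = np.array(lengths)  # (n_branches,)
        self.incidence = np.array(rows)  # (n_branches, n_species)

    def branch_fractions(self, matrix: np.ndarray) -> np.ndarray:
        """(n_branches, n_samples) fraction of each sample's total
        abundance sitting under each branch."""
        totals = matrix.sum(axis=0)
        if (totals <= 0).any():
            raise ValidationError("sample with non-positive total abundance")
        return self.incidence @ (matrix / totals)


def weighted_unifrac(
    tree: PhyloTree,
    x: Iterable[float],
    y: Iterable[float],
    species: Sequence[str],
    normalized: bool = True,
) -> float:
    """Weighted UniFrac between two samples over a shared species order.

    Raw form: Σ_b l_b |p_x(b) − p_y(b)| where p_s(b) is the fraction of
    sample s's abundance on leaves under branch b. The normalized form
    divides by Σ_b l_b (p_x(b) + p_y(b)) and lies in [0, 1].
    """
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    if not (len(a) == len(b) == len(species)):
        raise ValidationError("sample vectors and species list disagree in length")
    system = _BranchSystem(tree, species)
    p = system.branch_fractions(np.column_stack([a, b]))
    raw = float((system.lengths * np.abs(p[:, 0] - p[:, 1])).sum())
    if not normalized:
        return raw
    denom = float((system.lengths * (p[:, 0] + p[:, 1])).sum())
    return raw / denom if denom > 0 else 0.0


def beta_matrix(
    table: pd.DataFrame,
    metric: str,
    tree: Optional[PhyloTree] = None,
) -> DistanceMatrix:
    """All-pairs distance matrix over the samples (columns) of a table.

    ``metric`` is ``braycurtis`` or ``wunifrac`` (the latter needs a tree
    whose leaves cover the table's species index).
    """
    matrix = table.to_numpy(dtype=float)
    if (matrix < 0).any():
        raise ValidationError("negative abundance in table")
    n = table.shape[1]
    out = np.zeros((n, n))
    if metric == "braycurtis":
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = bray_curtis(matrix[:, i], matrix[:, j])
    elif metric == "wunifrac":
        if tree is None:
            raise ValidationError("wunifrac requires a tree")
        system = _BranchSystem(tree, list(table.index))
        p = system.branch_fractions(matrix)
        weighted = system.lengths[:, None] * p
        for i in range(n):
            for j in range(i + 1, n):
                raw = np.abs(weighted[:, i] - weighted[:, j]).sum()
                denom = (weighted[:, i] + weighted[:, j]).sum()
                out[i, j] = out[j, i] = raw / denom if denom > 0 else 0.0
    else:
        raise ValueError(f"unknown beta metric {metric!r}")
    return DistanceMatrix(out, ids=[str(c) for c in table.columns])


def alpha_diversity(
    table: pd.DataFrame,
    metric: str,
    tree: Optional[PhyloTree] = None,
    base: Optional[float] = None,
) -> pd.Series:
    """Per-sample alpha diversity: ``shannon`` or ``pd`` (Faith's)."""
    if metric == "shannon":
        values = [shannon(table[c], base=base) for c in table.columns]
    elif metric == "pd":
        if tree is None:
            raise ValidationError("Faith's PD requires a tree")
        values = []
        for c in table.columns:
            present = set(table.index[table[c] > 0].astype(str))
            values.append(faiths_pd(tree, present))
    else:
        raise ValueError(f"unknown alpha metric {metric!r}")
    return pd.Series(values, index=table.columns, name=metric)


# -- normalization -----------------------------------------------------------


def size_factors(
    table: pd.DataFrame, positive_fallback: bool = False
) -> pd.Series:
    """Median-of-ratios size factors.

    Each feature's geometric mean across samples forms a pseudo-reference;
    a sample's factor is the median of its count/reference ratios over
    features with all-positive counts. ``positive_fallback=True`` computes
    each geometric mean over the feature's positive entries only and takes
    the median over features positive in the given sample — for sparse
    tables where no feature is positive everywhere.
    """
    counts = table.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative counts")
    if positive_fallback:
        with np.errstate(divide="ignore"):
            logs = np.where(counts > 0, np.log(counts), np.nan)
        geo = np.exp(np.nanmean(logs, axis=1))
        factors = []
        for j in range(counts.shape[1]):
            mask = counts[:, j] > 0
            if not mask.any():
                raise ValidationError(f"sample {table.columns[j]!r} is all-zero")
            factors.append(np.median(counts[mask, j] / geo[mask]))
    else:
        all_positive = (counts > 0).all(axis=1)
        if not all_positive.any():
            raise ValidationError(
                "no feature has positive counts in every sample; "
                "use positive_fallback=True for sparse tables"
            )
        ref = counts[all_positive]
        geo = np.exp(np.log(ref).mean(axis=1))
        factors = np.median(ref / geo[:, None], axis=0)
    out = pd.Series(np.asarray(factors, dtype=float), index=table.columns)
    if (out <= 0).any():
        raise ValidationError("non-positive size factor")
    return out


def normalize_counts(
    table: pd.DataFrame, factors: Optional[pd.Series] = None, **kwargs
) -> pd.DataFrame:
    """Divide each sample by its size factor."""
    if factors is None:
        factors = size_factors(table, **kwargs)
    return table / factors


# -- statistics --------------------------------------------------------------


def mann_whitney_u(
    group_a: Iterable[float], group_b: Iterable[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact null enumeration for small tie-free inputs (combined n ≤ 20),
    otherwise the normal approximation with tie and continuity
    corrections. Returns (U of group_a, two-sided p).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("empty group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupComparison:
    """Outcome of one two-group metric comparison."""

    metric: str
    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str
    label_b: str
    u_statistic: float
    p_value: float
    p_adjusted: Optional[float] = None


def compare_groups(
    values: Iterable[float],
    labels: Iterable[str],
    metric: str = "",
) -> GroupComparison:
    """Mann–Whitney comparison of per-sample values between two groups."""
    v = np.asarray(list(values), dtype=float)
    lab = np.asarray(list(labels))
    classes = sorted(set(lab))
    if len(classes) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {classes}")
    a, b = v[lab == classes[0]], v[lab == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    u, p = mann_whitney_u(a, b)
    return GroupComparison(metric, a, b, classes[0], classes[1], u, p)


def compare_beta(
    dm: DistanceMatrix, labels: Iterable[str], metric: str = ""
) -> GroupComparison:
    """Contrast within-group pairwise distances between two groups.

    The units of the test are the within-group sample pairs (between-group
    pairs are not used). Pairs sharing a sample are not independent; the
    Mann–Whitney p-value is therefore approximate and anti-conservative.
    """
    lab = np.asarray(list(labels))
    if len(lab) != dm.shape[0]:
        raise ValidationError("labels length must match matrix size")
    classes = sorted(set(lab))
    if len(classes) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {classes}")
    data = dm.data
    pools = []
    for cls in classes:
        idx = np.flatnonzero(lab == cls)
        if len(idx) < 2:
            raise ValidationError(f"group {cls!r} needs at least 2 samples")
        pools.append(data[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)])
    u, p = mann_whitney_u(pools[0], pools[1])
    return GroupComparison(metric, pools[0], pools[1], classes[0], classes[1], u, p)


def diversity_power_comparison(
    counts: pd.DataFrame,
    labels: Iterable[str],
    tree: PhyloTree,
    positive_fallback: bool = True,
) -> dict[str, GroupComparison]:
    """The paired-metric power analysis on one labeled count table.

    Alpha metrics (Shannon, Faith's PD) run on raw counts; beta metrics
    (Bray–Curtis, weighted UniFrac) on size-factor-normalized counts.
    BH adjustment is applied across the four tests as one family.
    """
    labels = list(labels)
    comparisons: dict[str, GroupComparison] = {}
    for metric in ("shannon", "pd"):
        values = alpha_diversity(counts, metric, tree=tree)
        comparisons[metric] = compare_groups(values, labels, metric)
    normalized = normalize_counts(counts, positive_fallback=positive_fallback)
    for metric in ("braycurtis", "wunifrac"):
        dm = beta_matrix(normalized, metric, tree=tree)
        comparisons[metric] = compare_beta(dm, labels, metric)
    adjusted = bh_fdr([comparisons[m].p_value for m in comparisons])
    for m, adj in zip(comparisons, adjusted):
        comparisons[m].p_adjusted = float(adj)
    return comparisons


# -- io ----------------------------------------------------------------------


def read_table(source: Union[str, IO[str]]) -> pd.DataFrame:
    """Tab-delimited species × sample table (header row of sample ids)."""
    from io import StringIO

    if isinstance(source, str):
        source = StringIO(source)
    return pd.read_csv(source, sep="\t", index_col=0)


def write_table(table: pd.DataFrame) -> str:
    return table.to_csv(sep="\t")
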
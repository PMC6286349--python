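"""Abundance tables, taxonomy aggregation, alpha diversity and UniFrac.

The central object is :class:`OtuTable`, a samples x OTUs count matrix with a
Greengenes-style lineage string per OTU ("k__...;p__...;c__...;o__...;f__...;g__...").
All downstream stages (ordination, stratification, association testing) consume
either this object or the :class:`AbundanceTable` views derived from it.

Phylogeny-aware metrics (Faith's PD, UniFrac) take a rooted
:class:`skbio.TreeNode` whose tips are named by OTU ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "RANKS",
    "OtuTable",
    "AbundanceTable",
    "parse_lineage",
    "relative_abundance",
    "aggregate_taxonomy",
    "alpha_diversity",
    "faith_pd",
    "unifrac",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_PREFIXES = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__")))
UNCLASSIFIED = "Unclassified"


def parse_lineage(lineage: str) -> dict:
    """Parse a semicolon-delimited lineage string into a rank -> name dict.

    Empty or prefix-only fields (e.g. ``g__``) yield an empty string for that
    rank, meaning the OTU is unclassified at it.
    """
    out = {r: "" for r in RANKS}
    for part in str(lineage).split(";"):
        part = part.strip()
        for rank, pfx in _PREFIXES.items():
            if part.startswith(pfx):
                out[rank] = part[len(pfx):].strip()
                break
    return out


@dataclass
class OtuTable:
    """Samples x OTUs count matrix plus per-OTU taxonomy lineages."""

    counts: pd.DataFrame          # samples x OTUs, non-negative integers
    taxonomy: pd.Series           # OTU id -> lineage string

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dup}")
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        extra = set(self.taxonomy.index) - set(self.counts.columns)
        if extra:
            raise ValueError(f"taxonomy refers to unknown OTU ids: {sorted(extra)[:5]}")
        # every OTU gets a (possibly empty) lineage
        self.taxonomy = self.taxonomy.reindex(self.counts.columns, fill_value="")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    def lineage_at(self, level: str) -> pd.Series:
        """Taxon name of every OTU at `level`, ``Unclassified`` when empty."""
        if level not in RANKS:
            raise ValueError(f"unknown rank {level!r}; expected one of {RANKS}")
        names = self.taxonomy.map(lambda s: parse_lineage(s)[level])
        return names.replace("", UNCLASSIFIED)


@dataclass
class AbundanceTable:
    """Samples x features real-valued matrix at a chosen taxonomic level.

    ``normalization`` is ``"counts"`` or ``"relative"``; relative rows sum to 1.
    """

    values: pd.DataFrame
    level: str = "otu"
    normalization: str = "counts"

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.normalization == "relative":
            sums = vals.sum(axis=1)
            bad = self.values.index[np.abs(sums - 1.0) > 1e-9]
            if len(bad):
                raise ValueError(f"relative rows not summing to 1: {list(bad)[:5]}")


def relative_abundance(table: OtuTable | AbundanceTable) -> AbundanceTable:
    """Divide each sample row by its total.  Errors on zero-total samples."""
    if isinstance(table, OtuTable):
        values, level = table.counts, "otu"
    else:
        values, level = table.values, table.level
    totals = values.sum(axis=1)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero)}")
    rel = values.div(totals, axis=0).astype(float)
    return AbundanceTable(rel, level=level, normalization="relative")


def aggregate_taxonomy(table: OtuTable, level: str) -> AbundanceTable:
    """Sum OTU counts by taxon at `level` (phylum/family/genus).

    OTUs unclassified at that rank are pooled into a reserved ``Unclassified``
    feature; per-sample totals are conserved exactly.
    """
    if level not in ("phylum", "family", "genus"):
        raise ValueError(f"unknown aggregation rank {level!r}")
    names = table.lineage_at(level)
    agg = table.counts.T.groupby(names).sum().T
    return AbundanceTable(agg, level=level, normalization="counts")


def _proportions(row: np.ndarray) -> np.ndarray:
    tot = row.sum()
    if tot <= 0:
        raise ValueError("empty sample")
    return row / tot


def shannon(row: np.ndarray, base: float = 2.0) -> float:
    p = _proportions(np.asarray(row, dtype=float))
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def _tree_index(tree: TreeNode, otu_ids: list) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Branch incidence structure of a rooted tree.

    Returns ``(lengths, incidence, tip_depths)`` where ``incidence[b, j]`` is
    True when tip j (ordered as `otu_ids`) descends through branch b.  The
    root's own (usually absent) branch is excluded.  Raises if any requested
    OTU id is not a tip.
    """
    tips = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        raise ValueError(f"OTU ids absent from tree: {missing[:10]}")
    col = {o: j for j, o in enumerate(otu_ids)}
    lengths, rows = [], []
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        mask = np.zeros(len(otu_ids), dtype=bool)
        if node.is_tip():
            if node.name in col:
                mask[col[node.name]] = True
        else:
            for child in node.children:
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if node is not tree:  # root carries no branch
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    incidence = np.array(rows, dtype=bool)
    lengths = np.asarray(lengths, dtype=float)
    # root-to-tip distances for the Lozupone weighted-UniFrac normaliser
    depths = np.zeros(len(otu_ids))
    for tip in tree.tips():
        if tip.name in col:
            d, node = 0.0, tip
            while node is not tree:
                d += float(node.length or 0.0)
                node = node.parent
            depths[col[tip.name]] = d
    return lengths, incidence, depths


def faith_pd(table: OtuTable, tree: TreeNode) -> pd.Series:
    """Faith's phylogenetic diversity ("PD whole tree").

    Sum of branch lengths of the minimal rooted subtree spanning the observed
    tips *and the root*, i.e. every branch with at least one observed
    descendant tip contributes its length.
    """
    lengths, incidence, _ = _tree_index(tree, list(table.counts.columns))
    pres = (table.counts.to_numpy() > 0)
    # branch b counted for sample i iff any observed tip descends through it
    branch_obs = pres @ incidence.T.astype(float) > 0  # samples x branches
    pd_vals = branch_obs @ lengths
    return pd.Series(pd_vals, index=table.counts.index, name="faith_pd")


def alpha_diversity(
    table: OtuTable | AbundanceTable,
    metric: str,
    tree: TreeNode | None = None,
    base: float = 2.0,
) -> pd.Series:
    """Per-sample alpha diversity: ``shannon`` (log base 2 by default),
    ``observed`` feature count, or ``faith_pd`` (requires `tree`).
    """
    values = table.counts if isinstance(table, OtuTable) else table.values
    if metric == "shannon":
        out = values.apply(lambda r: shannon(r.to_numpy(), base=base), axis=1)
        out.name = "shannon"
        return out
    if metric == "observed":
        out = (values > 0).sum(axis=1).astype(float)
        out.name = "observed"
        return out
    if metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a phylogenetic tree")
        if not isinstance(table, OtuTable):
            raise ValueError("faith_pd requires an OtuTable (OTU-level counts)")
        return faith_pd(table, tree)
    raise ValueError(f"unknown alpha-diversity metric {metric!r}")


_VARIANTS = ("unweighted", "weighted_raw", "weighted_normalized")


def unifrac(
    table: OtuTable,
    tree: TreeNode,
    variant: str = "unweighted",
) -> DistanceMatrix:
    """Pairwise UniFrac distances between all samples of `table`.

    unweighted
        fraction of branch length unique to either sample, over branch length
        leading to tips observed in either.
    weighted_raw
        sum over branches of ``b_i * |p_A(i) - p_B(i)|`` with ``p_X(i)`` the
        proportion of sample X's reads descending through branch i.
    weighted_normalized
        raw value divided by ``sum_j d_j (p_A(j) + p_B(j))`` over tips, with
        ``d_j`` the tip's root distance (Lozupone normaliser).

    ``"weighted"`` is accepted as an alias for ``weighted_normalized``.
    """
    if variant == "weighted":
        variant = "weighted_normalized"
    if variant not in _VARIANTS:
        raise ValueError(f"unknown UniFrac variant {variant!r}")
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    empty = table.counts.index[totals <= 0]
    if len(empty):
        raise ValueError(f"empty sample(s): {list(empty)}")
    lengths, incidence, depths = _tree_index(tree, list(table.counts.columns))
    n = counts.shape[0]
    dist = np.zeros((n, n))
    inc = incidence.T.astype(float)  # tips x branches
    if variant == "unweighted":
        pres = (counts > 0).astype(float)
        B = (pres @ inc) > 0                      # samples x branches present
        W = B * lengths                            # length-weighted presence
        shared = W @ B.T                           # sum l over (i and j)
        self_len = np.diag(shared).copy()
        union = self_len[:, None] + self_len[None, :] - shared
        uniq = union - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(union > 0, uniq / union, 0.0)
        np.fill_diagonal(dist, 0.0)
    else:
        props = counts / totals[:, None]
        P = props @ inc                            # samples x branches
        for i in range(n):
            diff = np.abs(P[i + 1:] - P[i])        # pairs at once
            raw = diff @ lengths
            if variant == "weighted_normalized":
                norm = (props[i + 1:] + props[i]) @ depths
                with np.errstate(invalid="ignore", divide="ignore"):
                    raw = np.where(norm > 0, raw / norm, 0.0)
            dist[i, i + 1:] = raw
            dist[i + 1:, i] = raw
    # numerical guard: exact symmetry for skbio's validator
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, ids=[str(s) for s in table.counts.index])


def check_library_size_spread(table: OtuTable, factor: float = 10.0) -> None:
    """Warn when library sizes vary more than `factor`-fold (alpha metrics are
    computed on full counts; no rarefaction is applied)."""
    totals = table.counts.sum(axis=1).to_numpy(dtype=float)
    if totals.min() > 0 and totals.max() / totals.min() > factor:
        warnings.warn(
            f"library sizes vary {totals.max() / totals.min():.1f}-fold; "
            "alpha diversities are computed on unrarefied counts",
            UserWarning,
            stacklevel=2,
        )
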
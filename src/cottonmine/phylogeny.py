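"""Region phylogeny: identity-by-state distances and UPGMA trees.

For a genomic interval (e.g. a QTL-bearing chromosome arm) the pairwise
genotype distance between lines is 1 minus mean identity-by-state (IBS)
allele sharing over the loci both lines were called at.  UPGMA clustering of
that matrix yields a rooted ultrametric tree, serialized as Newick; an
outgroup line may be added to orient the root.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair locus counts.

    IBS distances lie in [0, 1] (``unit_scale=True`` enforces that); UPGMA
    itself accepts any nonnegative dissimilarity.
    """

    taxa: list[str]
    d: np.ndarray
    n_loci_compared: np.ndarray
    unit_scale: bool = False

    def __post_init__(self) -> None:
        n = len(self.taxa)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T) or np.diag(self.d).any():
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")
        if self.unit_scale and (self.d > 1 + 1e-12).any():
            raise ValueError("IBS distances must lie in [0, 1]")


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; leaves have height 0."""

    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]


# IBS allele-sharing similarity for unordered diploid genotype pairs, indexed
# by ALT dosage.  het-vs-het defaults to 1.0 (identical allele multisets);
# strict half-sharing (0.5) is selectable for TASSEL-style emulation.
def _similarity_table(het_het: float) -> np.ndarray:
    s = np.array(
        [
            [1.0, 0.5, 0.0],
            [0.5, het_het, 0.5],
            [0.0, 0.5, 1.0],
        ]
    )
    return s


def ibs_distance(
    genotypes: pd.DataFrame,
    het_het_similarity: float = 1.0,
) -> DistanceMatrix:
    """1 − mean IBS allele sharing between all pairs of lines.

    ``genotypes`` is lines x loci of ALT dosages {0, 1, 2}, with -1 or NaN
    marking missing calls; a missing call in either line drops that locus
    from the pair's comparison.  Identical homozygotes share both alleles
    (similarity 1), a het shares one allele with either homozygote (0.5),
    and opposite homozygotes share none (0).
    """
    if genotypes.shape[0] < 2 or genotypes.shape[1] < 1:
        raise ValueError("need >= 2 taxa and >= 1 locus")
    taxa = [str(t) for t in genotypes.index]
    g = genotypes.to_numpy(dtype=float)
    g[np.isnan(g)] = -1
    g = g.astype(int)
    sim = _similarity_table(het_het_similarity)
    n = len(taxa)
    d = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = int((g[i] >= 0).sum())
        for j in range(i + 1, n):
            ok = (g[i] >= 0) & (g[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable loci between {taxa[i]!r} and {taxa[j]!r}")
            mean_sim = sim[g[i, ok], g[j, ok]].mean()
            d[i, j] = d[j, i] = 1.0 - mean_sim
            counts[i, j] = counts[j, i] = m
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(taxa=taxa, d=d, n_loci_compared=counts, unit_scale=True)


def with_outgroup(
    genotypes: pd.DataFrame,
    outgroup_genotypes: Sequence[float] | pd.Series,
    outgroup_label: str = "outgroup",
    het_het_similarity: float = 1.0,
) -> DistanceMatrix:
    """Append an outgroup line over the same loci and recompute distances.

    UPGMA trees are inherently rooted; the outgroup's late merge provides
    the reference orientation for interpreting the root.
    """
    og = np.asarray(outgroup_genotypes, dtype=float)
    if og.shape != (genotypes.shape[1],):
        raise ValueError(
            f"outgroup has {og.shape[0] if og.ndim else 0} loci, expected {genotypes.shape[1]}"
        )
    extended = pd.concat(
        [genotypes, pd.DataFrame([og], index=[outgroup_label], columns=genotypes.columns)]
    )
    return ibs_distance(extended, het_het_similarity=het_het_similarity)


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Build the UPGMA tree: iteratively merge the closest pair of clusters.

    Inter-cluster distances are size-weighted averages (standard UPGMA); a
    merge at distance d creates a node at height d/2, so leaves sit at
    height 0 and heights are non-decreasing toward the root.  Ties are
    broken by the lexicographically smallest pair of cluster labels (a
    cluster is labelled by its smallest member leaf), making output
    deterministic under taxon reordering.
    """
    n = len(dist.taxa)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 taxa")
    nodes = {i: TreeNode(height=0.0, label=t) for i, t in enumerate(dist.taxa)}
    labels = {i: dist.taxa[i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {frozenset((i, j)): dist.d[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for pair, dij in d.items():
            i, j = sorted(pair, key=lambda k: labels[k])
            key = (dij, labels[i], labels[j])
            if best is None or key < best[0]:
                best = (key, i, j)
        (dij, _, _), i, j = best
        node = TreeNode(height=dij / 2.0, children=[nodes[i], nodes[j]])
        nodes[next_id] = node
        labels[next_id] = min(labels[i], labels[j])
        sizes[next_id] = sizes[i] + sizes[j]
        active -= {i, j}
        for k in active:
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            d[frozenset((next_id, k))] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        del d[frozenset((i, j))]
        active.add(next_id)
        next_id += 1
    return nodes[next_id - 1]


_NEEDS_QUOTE = re.compile(r"[\s()\[\]:;,'\"]")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths (parent height − child height), ';'-terminated."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = _format_label(node.label or "")
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
            if node.label:
                body += _format_label(node.label)
        if parent_height is None:
            return body
        return f"{body}:{float(parent_height - node.height)}"

    return render(tree, None) + ";"


def cophenetic_distance(tree: TreeNode) -> pd.DataFrame:
    """Pairwise tree distances between leaves (2 x merge height for ultrametric trees)."""
    leaves = [leaf.label for leaf in tree.leaves()]
    df = pd.DataFrame(0.0, index=leaves, columns=leaves)

    def visit(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        below = [visit(c) for c in node.children]
        for a_idx in range(len(below)):
            for b_idx in range(a_idx + 1, len(below)):
                for la in below[a_idx]:
                    for lb in below[b_idx]:
                        df.loc[la, lb] = df.loc[lb, la] = 2.0 * node.height
        return [leaf for grp in below for leaf in grp]

    visit(tree)
    return df
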
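"""Poisson-corrected distances and UPGMA dendrograms for protein sequences.

Given a multiple alignment, the observed proportion of differing sites p is
computed per pair (pairwise-deletion by default: positions gapped in either
member of the pair are ignored), corrected for multiple hits with the
Poisson model d = -ln(1 - p), and clustered with UPGMA (unweighted pair
group method with arithmetic mean): the closest pair merges, heights are
half the merge distance and cluster distances are size-weighted arithmetic
means.  The output is an ultrametric rooted tree exportable as newick.

UPGMA trees are inherently rooted; a designated outgroup is only *checked*
to sit at the deepest split, with a warning when it does not.  Ties between
equally close pairs break on the lexicographically smallest pair so the
result is deterministic under any input order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass
class DistanceMatrix:
    taxa: list
    matrix: np.ndarray  # symmetric, zero diagonal, finite
    mode: str = "pairwise-deletion"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix entries must be finite")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def get(self, a, b) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class DendrogramNode:
    """Ultrametric tree node: leaves at height 0, parents above children."""

    height: float = 0.0
    label: str | None = None  # leaves only
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [leaf for c in self.children for leaf in c.leaves()]

    def newick(self, digits: int = 6) -> str:
        def fmt(node: DendrogramNode, parent_height: float) -> str:
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{branch:.{digits}f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{branch:.{digits}f}"

        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});" if self.children else f"{self.label};"


# ---------------------------------------------------------------------------
# distances

def pdistance_matrix(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]],
    mode: str = "pairwise-deletion",
) -> DistanceMatrix:
    """Proportion of differing sites per pair of aligned rows.

    ``alignment`` maps taxon -> aligned sequence (equal lengths, '-' gaps).
    ``pairwise-deletion`` ignores positions gapped in either member of the
    pair; ``complete-deletion`` drops columns gapped in *any* row first.
    A pair with no comparable site is an error naming the pair.
    """
    items = list(alignment.items()) if hasattr(alignment, "items") else list(alignment)
    if len(items) < 2:
        raise ValueError("need at least two taxa")
    lengths = {len(seq) for _, seq in items}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    if mode not in ("pairwise-deletion", "complete-deletion"):
        raise ValueError(f"unknown gap mode {mode!r}")
    taxa = [t for t, _ in items]
    rows = [seq for _, seq in items]
    if mode == "complete-deletion":
        keep = [
            i for i in range(len(rows[0])) if all(r[i] != "-" for r in rows)
        ]
        rows = ["".join(r[i] for i in keep) for r in rows]
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = compared = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "-" or b == "-":
                    continue
                compared += 1
                if a != b:
                    diff += 1
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {taxa[i]!r} and {taxa[j]!r}"
                )
            mat[i, j] = mat[j, i] = diff / compared
    return DistanceMatrix(taxa=taxa, matrix=mat, mode=mode)


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p); requires 0 <= p < 1."""
    if not 0 <= p < 1:
        raise ValueError(f"proportion {p} saturated or out of range [0, 1)")
    return -math.log(1.0 - p)


def poisson_matrix(dist: DistanceMatrix) -> DistanceMatrix:
    corrected = np.vectorize(poisson_correct)(dist.matrix)
    return DistanceMatrix(taxa=dist.taxa, matrix=corrected, mode=dist.mode)


# ---------------------------------------------------------------------------
# UPGMA

def upgma(dist: DistanceMatrix, outgroup: str | None = None) -> DendrogramNode:
    """UPGMA clustering; ties break on the lexicographically smallest pair.

    Node heights are half the merge distance; merged distances are
    size-weighted arithmetic means.  When an ``outgroup`` is named it is
    checked to be a child of the deepest split (warning otherwise).
    """
    if len(dist.taxa) < 2:
        raise ValueError("need at least two taxa")
    if outgroup is not None and outgroup not in dist.taxa:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")

    clusters: dict[str, DendrogramNode] = {
        str(t): DendrogramNode(label=str(t)) for t in dist.taxa
    }
    sizes = {str(t): 1 for t in dist.taxa}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(dist.taxa):
        for j in range(i + 1, len(dist.taxa)):
            b = dist.taxa[j]
            key = tuple(sorted((str(a), str(b))))
            d[key] = float(dist.matrix[i, j])

    while len(clusters) > 1:
        (a, b), dmin = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        node = DendrogramNode(
            height=dmin / 2.0, children=[clusters[a], clusters[b]]
        )
        name = f"({a},{b})"
        for other in clusters:
            if other in (a, b):
                continue
            da = d[tuple(sorted((a, other)))]
            db = d[tuple(sorted((b, other)))]
            d[tuple(sorted((name, other)))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        for other in list(clusters):
            d.pop(tuple(sorted((a, other))), None)
            d.pop(tuple(sorted((b, other))), None)
        del clusters[a], clusters[b]
        sizes[name] = sizes.pop(a) + sizes.pop(b)
        clusters[name] = node

    root = next(iter(clusters.values()))
    if outgroup is not None:
        deepest = [set(c.leaves()) for c in root.children]
        if not any(leafset == {outgroup} for leafset in deepest):
            warnings.warn(
                f"outgroup {outgroup!r} is not the deepest split of the UPGMA tree"
            )
    return root


def is_ultrametric(node: DendrogramNode, tol: float = 1e-9) -> bool:
    """All leaves of every subtree sit at the same depth below the root."""
    ok = True

    def check(n: DendrogramNode):
        nonlocal ok
        for c in n.children:
            if c.height > n.height + tol:
                ok = False
            check(c)

    check(node)
    depths = []

    def walk(n: DendrogramNode, acc: float):
        if n.is_leaf:
            depths.append(acc + n.height)
        for c in n.children:
            walk(c, acc)

    walk(node, 0.0)
    return ok and (max(depths) - min(depths) <= tol if depths else True)


def class2_dendrogram(
    aligned: Mapping[str, str],
    mode: str = "pairwise-deletion",
    outgroup: str | None = None,
) -> tuple[DendrogramNode, str]:
    """Poisson distances + UPGMA on one aligned set; returns (tree, newick)."""
    tree = upgma(poisson_matrix(pdistance_matrix(aligned, mode=mode)),
                 outgroup=outgroup)
    return tree, tree.newick()
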
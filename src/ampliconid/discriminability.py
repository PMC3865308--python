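"""Species discriminability of the target region.

How well does the mini-barcode separate species? This module computes the
pairwise difference matrix over a reference database (unit-cost global edit
distance, so substitutions and single-base indels each count 1), builds an
ultrametric UPGMA tree with Newick output, and summarises target-length and
difference distributions together with groups of species that share an
identical target (those cannot be told apart by this assay).

Edit distance is computed with edlib in global (Needleman–Wunsch) mode;
terminal gaps count, since the target region is delimited by primer sites
on both ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from .amplicondb import ReferenceDB

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "DiscriminabilitySummary",
    "pairwise_difference",
    "distance_matrix",
    "upgma",
    "summarize",
]


def pairwise_difference(seq_a: str, seq_b: str) -> int:
    """Unit-cost global edit distance between two target sequences.

    Substitution, insertion and deletion each cost 1; the measure is
    symmetric and satisfies the triangle inequality.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    return edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-difference matrix over labelled sequences."""

    labels: list[str]
    d: np.ndarray  # (n, n) int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def __len__(self) -> int:
        return len(self.labels)

    def to_phylip(self) -> str:
        """Square PHYLIP serialization."""
        lines = [f" {len(self.labels)}"]
        for label, row in zip(self.labels, self.d):
            name = label.replace(" ", "_")[:30]
            lines.append(name + "  " + "  ".join(str(int(x)) for x in row))
        return "\n".join(lines) + "\n"

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.d):
                fh.write(label + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def distance_matrix(db: ReferenceDB | Sequence[tuple[str, str]]) -> DistanceMatrix:
    """All-vs-all pairwise differences; label order = input order."""
    if isinstance(db, ReferenceDB):
        items = [(e.species, e.target) for e in db.entries]
    else:
        items = list(db)
    if not items:
        raise ValueError("empty reference set")
    labels = [lab for lab, _ in items]
    seqs = [s for _, s in items]
    n = len(seqs)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_difference(seqs[i], seqs[j])
    return DistanceMatrix(labels=labels, d=d)


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; ``height`` is the node's distance
    above the leaves (UPGMA merge distance / 2; 0 at leaves)."""

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def _newick(self, parent_height: float) -> str:
        blen = parent_height - self.height
        if self.is_leaf:
            name = (self.name or "").replace(" ", "_")
            return f"{name}:{blen:.6f}"
        inner = ",".join(c._newick(self.height) for c in self.children)
        return f"({inner}):{blen:.6f}"

    def to_newick(self) -> str:
        """Newick string with branch lengths, root branch omitted."""
        if self.is_leaf:
            return f"{(self.name or '').replace(' ', '_')};"
        inner = ",".join(c._newick(self.height) for c in self.children)
        return f"({inner});"

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (all equal on an ultrametric tree)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            if node.is_leaf:
                depths[node.name or ""] = acc
                return
            for c in node.children:
                walk(c, acc + (node.height - c.height))

        walk(self, 0.0)
        return depths


def upgma(matrix: DistanceMatrix) -> TreeNode:
    """UPGMA clustering (arithmetic-average linkage) of a distance matrix.

    Node heights are half the merge distance, so the tree is ultrametric.
    Ties in the minimum inter-cluster distance are broken toward the lowest
    (i, j) pair in label order, which makes the topology deterministic.
    """
    n = len(matrix)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    # active clusters: (node, size); distances kept in a dict keyed by
    # frozen pair of cluster ids, ids assigned in creation order
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=matrix.labels[i]) for i in range(n)
    }
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    first_leaf: dict[int, int] = {i: i for i in range(n)}  # for child ordering
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(matrix.d[i, j])
    next_id = n
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (i, j) if i < j else (j, i)
                d = dist[key]
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best  # type: ignore[misc]
        if first_leaf[j] < first_leaf[i]:
            children = [nodes[j], nodes[i]]
        else:
            children = [nodes[i], nodes[j]]
        merged = TreeNode(height=d / 2.0, children=children)
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        first_leaf[next_id] = min(first_leaf[i], first_leaf[j])
        for k in active:
            if k in (i, j):
                continue
            ki = (k, i) if k < i else (i, k)
            kj = (k, j) if k < j else (j, k)
            dk = (sizes[i] * dist[ki] + sizes[j] * dist[kj]) / (sizes[i] + sizes[j])
            dist[(k, next_id)] = dk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    return nodes[active[0]]


@dataclass
class DiscriminabilitySummary:
    n_species: int
    length_mean: float
    length_sd: float
    differences_mean: float
    differences_sd: float
    fraction_identical_pairs: float
    identical_groups: list[list[str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_species": self.n_species,
                "length_mean": self.length_mean,
                "length_sd": self.length_sd,
                "differences_mean": self.differences_mean,
                "differences_sd": self.differences_sd,
                "fraction_identical_pairs": self.fraction_identical_pairs,
                "identical_groups": self.identical_groups,
            },
            indent=2,
        )


def summarize(db: ReferenceDB, matrix: DistanceMatrix | None = None) -> DiscriminabilitySummary:
    """Length and pairwise-difference statistics plus identical-target groups.

    ``fraction_identical_pairs`` is the share of all n(n−1)/2 species pairs
    whose targets are byte-identical — the pairs the assay cannot resolve.
    SDs are sample standard deviations (ddof=1); 0 for n < 2.
    """
    if matrix is None:
        matrix = distance_matrix(db)
    lengths = np.array([len(e.target) for e in db.entries], dtype=float)
    n = len(db)
    iu = np.triu_indices(n, k=1)
    offdiag = matrix.d[iu].astype(float)
    n_pairs = offdiag.size
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return DiscriminabilitySummary(
        n_species=n,
        length_mean=float(lengths.mean()),
        length_sd=sd(lengths),
        differences_mean=float(offdiag.mean()) if n_pairs else 0.0,
        differences_sd=sd(offdiag),
        fraction_identical_pairs=float((offdiag == 0).sum() / n_pairs) if n_pairs else 0.0,
        identical_groups=db.identical_groups(),
    )
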
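"""Genotype-call similarity statistics and UPGMA clustering.

Identity-by-state percent similarity between accessions over arbitrary
marker subsets (e.g. the markers spanning a called coverage drop), the
derived pairwise distance matrix, and an average-linkage (UPGMA) dendrogram
serializable to Newick. Heterozygote calls are their own category by
default: a HET vs HOM_REF pair counts as a mismatch.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .synthcohort import MISSING, GenotypeMatrix


@dataclass
class SimilarityReport:
    """Percent of identical non-missing calls between two call vectors."""

    accession: str
    other: str
    subset_label: str
    n_comparable: int
    percent: float | None  # None when no comparable markers (UNDEFINED)

    @property
    def defined(self) -> bool:
        return self.percent is not None


def similarity(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    accession: str = "a",
    other: str = "b",
    subset_label: str = "all",
) -> SimilarityReport:
    """100 x identical / comparable, over pairs where both calls are present."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError("call vectors must be aligned")
    comparable = (a != MISSING) & (b != MISSING)
    n = int(comparable.sum())
    if n == 0:
        return SimilarityReport(accession, other, subset_label, 0, None)
    pct = 100.0 * float((a[comparable] == b[comparable]).sum()) / n
    return SimilarityReport(accession, other, subset_label, n, pct)


def similarity_to_reference(
    gm: GenotypeMatrix,
    reference_accession: str,
    marker_subset: list[str] | None = None,
    subset_label: str = "all",
) -> pd.DataFrame:
    """Each accession's percent similarity to a designated reference accession."""
    calls = gm.calls if marker_subset is None else gm.calls.loc[marker_subset]
    ref = calls[reference_accession].to_numpy()
    rows = []
    for acc in gm.accessions:
        if acc == reference_accession:
            continue
        rep = similarity(calls[acc].to_numpy(), ref, acc, reference_accession, subset_label)
        rows.append((acc, subset_label, rep.n_comparable, rep.percent))
    return pd.DataFrame(rows, columns=["accession", "subset", "n_comparable", "percent"])


def distance_matrix(
    gm: GenotypeMatrix, marker_subset: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise d(a,b) = 100 - similarity(a,b); NaN where undefined."""
    accs = gm.accessions
    if len(accs) < 2:
        raise ValueError("need at least 2 accessions")
    calls = gm.calls if marker_subset is None else gm.calls.loc[marker_subset]
    n = len(accs)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        rep = similarity(calls[accs[i]].to_numpy(), calls[accs[j]].to_numpy())
        d = np.nan if rep.percent is None else 100.0 - rep.percent
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=accs, columns=accs)


@dataclass
class _Node:
    name: str | None  # leaf name, None for internal
    height: float
    children: list["_Node"] = field(default_factory=list)

    @property
    def leaves(self) -> list[str]:
        if self.name is not None:
            return [self.name]
        return [leaf for c in self.children for leaf in c.leaves]


@dataclass
class Dendrogram:
    """Rooted ultrametric tree over accessions (UPGMA output)."""

    root: _Node

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves

    def to_newick(self) -> str:
        def fmt(node: _Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.name is not None:
                return f"{node.name}:{bl:g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:g}"

        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def cophenetic(self) -> pd.DataFrame:
        """Tree distance between every leaf pair (2 x LCA height)."""
        leaves = sorted(self.leaf_names)
        dist = pd.DataFrame(0.0, index=leaves, columns=leaves)

        def visit(node: _Node) -> None:
            for c in node.children:
                visit(c)
            for a, b in combinations(node.children, 2):
                for la in a.leaves:
                    for lb in b.leaves:
                        dist.loc[la, lb] = dist.loc[lb, la] = 2.0 * node.height

        visit(self.root)
        return dist

    def root_split(self) -> list[set[str]]:
        """Leaf sets of the root's children ("main clusters")."""
        return [set(c.leaves) for c in self.root.children]


def check_triangle_inequality(dist: pd.DataFrame, log=None) -> list[tuple]:
    """Report (not reject) triangle-inequality violations in a distance matrix."""
    names = list(dist.index)
    bad = []
    for a, b, c in combinations(names, 3):
        for x, y, z in ((a, b, c), (b, c, a), (c, a, b)):
            if dist.loc[x, y] > dist.loc[x, z] + dist.loc[z, y] + 1e-9:
                bad.append((x, y, z))
    if bad and log is not None:
        log(f"{len(bad)} triangle-inequality violations in distance matrix")
    return bad


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration; node heights = half the merge distance.

    Ties are broken deterministically by the lexicographically smallest pair
    of cluster keys (a cluster's key is its sorted leaf-name tuple).
    """
    if dist.isna().to_numpy().any():
        raise ValueError("distance matrix has undefined entries")
    if not np.allclose(dist.to_numpy(), dist.to_numpy().T):
        raise ValueError("distance matrix must be symmetric")
    names = list(dist.index)
    if len(names) < 2:
        raise ValueError("need at least 2 accessions")

    clusters: dict[tuple, _Node] = {(n,): _Node(n, 0.0) for n in names}
    sizes: dict[tuple, int] = {(n,): 1 for n in names}
    d: dict[frozenset, float] = {}
    for a, b in combinations(clusters, 2):
        d[frozenset((a, b))] = float(dist.loc[a[0], b[0]])

    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            val = d[frozenset((a, b))]
            if best is None or val < best[0] - 1e-12:
                best = (val, a, b)
        val, a, b = best
        merged_key = tuple(sorted(a + b))
        node = _Node(None, val / 2.0, [clusters[a], clusters[b]])
        na, nb = sizes[a], sizes[b]
        for other in list(clusters):
            if other in (a, b):
                continue
            new_d = (
                na * d[frozenset((a, other))] + nb * d[frozenset((b, other))]
            ) / (na + nb)
            d[frozenset((merged_key, other))] = new_d
        for other in list(clusters):
            d.pop(frozenset((a, other)), None)
            d.pop(frozenset((b, other)), None)
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[merged_key] = node
        sizes[merged_key] = na + nb
    return Dendrogram(next(iter(clusters.values())))


def write_newick(path, tree: Dendrogram) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
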
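import numpy as np
import pytest

from hievi.mpr import DistanceMatrix
from hievi.synthetic import TaxonomyDesign, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic taxonomy (3 families x 2 subfamilies x 3 genera
    x 8 genomes, d=64, K=200, kappa=50, seed 11)."""
    return generate_dataset(TaxonomyDesign())


@pytest.fixture(scope="session")
def small_dataset():
    """A cheaper dataset for plumbing tests."""
    return generate_dataset(
        TaxonomyDesign(
            n_genera_per_subfamily=2, n_genomes_per_genus=3, m_range=(15, 25), seed=7
        )
    )


def random_distance_matrix(n: int, rng: np.random.Generator) -> DistanceMatrix:
    """Euclidean distances between n random points (valid metric by construction)."""
    points = rng.standard_normal((n, 3))
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(
        [f"A{i:03d}" for i in range(n)], squareform(pdist(points))
    )


# --- independent oracles used across hierarchy/acceptance tests -------------


def single_linkage_mst_heights(D: np.ndarray) -> np.ndarray:
    """Merge heights of single-linkage clustering via Prim's MST algorithm.

    Single-linkage dendrogram heights equal the sorted edge weights of the
    minimum spanning tree of the complete distance graph.
    """
    n = D.shape[0]
    in_tree = np.zeros(n, dtype=bool)
    best = np.full(n, np.inf)
    in_tree[0] = True
    best = D[0].copy()
    best[0] = np.inf
    edges = []
    for _ in range(n - 1):
        j = int(np.argmin(np.where(in_tree, np.inf, best)))
        edges.append(best[j])
        in_tree[j] = True
        best = np.minimum(best, D[j])
    return np.sort(np.asarray(edges))


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def connected_components_partition(D: np.ndarray, eps: float) -> list[frozenset[int]]:
    """Partition by union-find over all edges with distance <= eps."""
    n = D.shape[0]
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= eps:
                uf.union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]
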
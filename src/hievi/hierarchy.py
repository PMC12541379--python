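"""Density hierarchy over MPRs, flat eps cuts, and taxon branch extraction.

The published workflow runs HDBSCAN with minPts = 2 and minimum cluster size
2 and reads its condensed tree as the phage hierarchy.  With minPts = 2 the
core distance of every point is its nearest-neighbour distance, so the mutual
reachability distance equals the raw distance and the density hierarchy's
merge heights coincide exactly with single-linkage dendrogram heights.  The
implementation therefore builds the hierarchy with single linkage (scipy) and
cuts flat DBSCAN*-style clusters at a distance threshold eps: clusters are
the connected components of the graph whose edges are pairs at distance
<= eps, and singleton components are labeled noise.

scipy's linkage on a condensed distance matrix is deterministic; ties are
resolved by the stable order of the condensed entries, i.e. by (distance,
lexicographic position) — the same rule the tests' independent MST oracle
uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from hievi.io_store import UNCLASSIFIED, AnnotationTable
from hievi.mpr import DistanceMatrix

#: Label assigned to singleton components under an eps cut.
NOISE = -1

#: HDBSCAN-style parameters the hierarchy realizes.
MIN_PTS = 2
MIN_CLUSTER_SIZE = 2


@dataclass
class CondensedHierarchy:
    """Merge tree over n leaves with the distance scale of every merge.

    ``Z`` is a scipy linkage matrix: row i merges nodes ``Z[i,0]`` and
    ``Z[i,1]`` at height ``Z[i,2]`` into node ``n + i``; leaves are nodes
    ``0..n-1`` in ``accessions`` order.  Heights are non-decreasing from the
    leaves to the root.
    """

    accessions: list[str]
    Z: np.ndarray
    parameters: dict = field(
        default_factory=lambda: {"min_pts": MIN_PTS, "min_cluster_size": MIN_CLUSTER_SIZE}
    )

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        n = len(self.accessions)
        if self.Z.shape != (n - 1, 4):
            raise ValueError(f"linkage shape {self.Z.shape} != ({n - 1}, 4)")

    @property
    def n(self) -> int:
        return len(self.accessions)

    @property
    def merge_heights(self) -> np.ndarray:
        """The n-1 merge distances in scipy order (sorted non-decreasing)."""
        return self.Z[:, 2].copy()

    def leaves_under(self, node: int) -> list[int]:
        """Leaf indices beneath a node id (leaves are their own leaf set)."""
        n = self.n
        stack, leaves = [int(node)], []
        while stack:
            cur = stack.pop()
            if cur < n:
                leaves.append(cur)
            else:
                row = self.Z[cur - n]
                stack.extend((int(row[0]), int(row[1])))
        return sorted(leaves)

    def iter_nodes(self) -> Iterator[dict]:
        """Flat node records for network export.

        Cluster node ids are ``"C<k>"`` for merge node ``n + k``; the root is
        the final merge.  Each cluster node carries its size and the height
        (distance scale) at which its children join; each leaf carries its
        accession.  Parent links point root -> leaves.
        """
        n = self.n
        parent = {}
        for i in range(n - 1):
            for child in (int(self.Z[i, 0]), int(self.Z[i, 1])):
                parent[child] = n + i
        for i in reversed(range(n - 1)):
            node = n + i
            yield {
                "id": f"C{i}",
                "kind": "cluster",
                "size": int(self.Z[i, 3]),
                "height": float(self.Z[i, 2]),
                "parent": f"C{parent[node] - n}" if node in parent else None,
            }
        for leaf in range(n):
            yield {
                "id": self.accessions[leaf],
                "kind": "leaf",
                "accession": self.accessions[leaf],
                "parent": f"C{parent[leaf] - n}",
            }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "accessions": self.accessions,
            "linkage": self.Z.tolist(),
            "parameters": self.parameters,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CondensedHierarchy":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            accessions=list(payload["accessions"]),
            Z=np.asarray(payload["linkage"], dtype=np.float64),
            parameters=dict(payload.get("parameters", {})),
        )


def build_hierarchy(D: DistanceMatrix) -> CondensedHierarchy:
    """Single-linkage merge tree over the distance matrix (minPts = 2 semantics)."""
    if D.n < 2:
        raise ValueError("need at least two points to build a hierarchy")
    Z = linkage(D.condensed(), method="single")
    return CondensedHierarchy(list(D.accessions), Z)


@dataclass
class FlatClustering:
    """A flat eps cut: cluster labels per accession, singletons as noise."""

    eps: float
    labels: dict[str, int]
    n_clusters: int

    def labels_array(self, accessions: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[a] for a in accessions], dtype=int)

    def partition(self) -> dict[int, frozenset[str]]:
        """Cluster id -> member set; each noise point is its own singleton."""
        groups: dict[int, set[str]] = {}
        noise_id = -1
        for acc, lab in self.labels.items():
            if lab == NOISE:
                groups[noise_id] = {acc}
                noise_id -= 1
            else:
                groups.setdefault(lab, set()).add(acc)
        return {k: frozenset(v) for k, v in groups.items()}


def cut_at_eps(h: CondensedHierarchy | DistanceMatrix, eps: float) -> FlatClustering:
    """Flat DBSCAN*-style clusters at distance threshold eps.

    Clusters are the connected components of the pairs-at-distance <= eps
    graph; in single linkage that is exactly ``fcluster(Z, eps, "distance")``.
    Components of size one are labeled :data:`NOISE`.  Cluster ids are
    contiguous, ordered by first appearance along the accession order.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    hierarchy = build_hierarchy(h) if isinstance(h, DistanceMatrix) else h
    raw = fcluster(hierarchy.Z, t=eps, criterion="distance")
    sizes = np.bincount(raw)
    labels: dict[str, int] = {}
    remap: dict[int, int] = {}
    for acc, r in zip(hierarchy.accessions, raw):
        if sizes[r] < 2:
            labels[acc] = NOISE
        else:
            if r not in remap:
                remap[r] = len(remap)
            labels[acc] = remap[r]
    return FlatClustering(eps=float(eps), labels=labels, n_clusters=len(remap))


@dataclass
class BranchReport:
    """The best-matching hierarchy node for an annotated taxon."""

    rank: str
    taxon: str
    node: str  # "C<k>" cluster id, or a leaf accession in degenerate cases
    height: float
    leaves: list[str]
    n_in_taxon: int
    n_other: int
    precision: float
    recall: float
    f1: float

    @property
    def size(self) -> int:
        return len(self.leaves)


def extract_branch(
    h: CondensedHierarchy,
    annotations: AnnotationTable,
    rank: str,
    taxon: str,
) -> tuple[CondensedHierarchy | None, BranchReport]:
    """Find the hierarchy branch that best captures an annotated taxon.

    Scans every node and selects the one whose leaf set maximizes the F1
    score against the set of genomes annotated ``taxon`` at ``rank`` (ties:
    smaller node, then lower height).  This operationalizes reading off "the
    top node of the taxon and all its successors" while staying robust to a
    few strays.  Returns the sub-hierarchy over the branch's leaves (None
    when the best node is a single leaf) and a membership report with
    in-taxon / other counts.
    """
    target = {
        a
        for a, lab in zip(
            h.accessions, annotations.rank_labels(rank, h.accessions)
        )
        if lab == taxon and lab != UNCLASSIFIED
    }
    if not target:
        raise ValueError(f"taxon {taxon!r} not present at rank {rank!r}")

    n = h.n
    best = None  # (f1, -size, -height, node_id, leaves)
    for node in range(2 * n - 1):
        leaves = h.leaves_under(node)
        members = {h.accessions[i] for i in leaves}
        tp = len(members & target)
        if tp == 0:
            continue
        precision = tp / len(members)
        recall = tp / len(target)
        f1 = 2 * precision * recall / (precision + recall)
        height = float(h.Z[node - n, 2]) if node >= n else 0.0
        key = (f1, -len(members), -height)
        if best is None or key > best[0]:
            best = (key, node, leaves, members, precision, recall, f1, height)

    _, node, leaves, members, precision, recall, f1, height = best
    accessions = [h.accessions[i] for i in leaves]
    report = BranchReport(
        rank=rank,
        taxon=taxon,
        node=f"C{node - n}" if node >= n else h.accessions[node],
        height=height,
        leaves=accessions,
        n_in_taxon=len(members & target),
        n_other=len(members - target),
        precision=precision,
        recall=recall,
        f1=f1,
    )
    subtree = _subtree_over(h, leaves) if len(leaves) >= 2 else None
    return subtree, report


def _subtree_over(h: CondensedHierarchy, leaf_indices: list[int]) -> CondensedHierarchy:
    """Re-linkage restricted to a leaf subset, using cophenetic sub-distances."""
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform

    coph = squareform(cophenet(h.Z))
    idx = np.asarray(leaf_indices, dtype=np.intp)
    sub = coph[np.ix_(idx, idx)]
    Z = linkage(squareform(sub, checks=False), method="single")
    return CondensedHierarchy([h.accessions[i] for i in idx], Z, dict(h.parameters))


def write_flat_clustering(fc: FlatClustering, path: str | Path) -> Path:
    """TSV of (accession, cluster, is_noise)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("accession\tcluster\tis_noise\n")
        for acc in sorted(fc.labels):
            lab = fc.labels[acc]
            fh.write(f"{acc}\t{lab}\t{lab == NOISE}\n")
    return path
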
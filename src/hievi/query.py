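"""Placement of new proteomes against a precomputed MPR store.

Workflow for a query genome: embed its proteins, average into an MPR, search
the store for nearest neighbours (exact, by default), and gate on the nearest
distance — beyond the threshold the phage is deemed unclassified; otherwise
the neighbourhood plus the query is re-clustered and its condensed tree
returned, positioning the query among its closest relatives without relying
on any annotation.  Neighbours' labels are reported for context, never
asserted for the query.

The unclassified gate has no universal value; it must be supplied explicitly,
typically calibrated from a within/between threshold analysis at the rank of
interest (:func:`hievi.evaluation.threshold_analysis`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from hievi.embedding import EmbeddingBackend, embed_proteome
from hievi.hierarchy import CondensedHierarchy, build_hierarchy
from hievi.io_store import AnnotationTable, ProteinRecord, VectorStore
from hievi.mpr import MPRVector, Proteome, compute_mpr, pairwise_distances


def nearest_neighbours(
    query_mpr: MPRVector | np.ndarray,
    store: VectorStore,
    k: int,
) -> list[tuple[str, float]]:
    """The k nearest store entries by Euclidean distance, exact full scan.

    Ties are broken lexicographically by accession so results are stable
    across platforms.  Asking for more neighbours than the store holds
    truncates with a warning.
    """
    if store.n == 0:
        raise ValueError("empty vector store")
    if k < 1:
        raise ValueError("k must be >= 1")
    q = query_mpr.phi if isinstance(query_mpr, MPRVector) else np.asarray(query_mpr)
    q = np.asarray(q, dtype=np.float64)
    if q.shape != (store.dimension,):
        raise ValueError(
            f"query dimension {q.shape} does not match store dimension "
            f"({store.dimension})"
        )
    if k > store.n:
        warnings.warn(
            f"k={k} exceeds store size {store.n}; returning all entries",
            stacklevel=2,
        )
        k = store.n
    diffs = store.matrix.astype(np.float64) - q[None, :]
    dists = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    order = sorted(range(store.n), key=lambda i: (dists[i], store.accessions[i]))
    return [(store.accessions[i], float(dists[i])) for i in order[:k]]


@dataclass
class QueryResult:
    """Outcome of placing one query proteome against a store."""

    query_accession: str
    neighbours: list[tuple[str, float]]
    status: str  # "placed" | "unclassified"
    subtree: CondensedHierarchy | None
    neighbour_annotations: dict[str, dict] | None
    parameters: dict

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "query_accession": self.query_accession,
            "status": self.status,
            "neighbours": [
                {"accession": a, "distance": d} for a, d in self.neighbours
            ],
            "neighbour_annotations": self.neighbour_annotations,
            "parameters": self.parameters,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return path


def place_query(
    store: VectorStore,
    threshold: float,
    records: Sequence[ProteinRecord] | None = None,
    backend: EmbeddingBackend | None = None,
    query_vector: np.ndarray | None = None,
    query_accession: str = "query",
    annotations: AnnotationTable | None = None,
    k: int = 50,
) -> QueryResult:
    """Embed, search, gate, and re-cluster one query proteome.

    Provide either ``records`` plus a ``backend`` (the query is embedded and
    averaged into an MPR) or a precomputed ``query_vector``.  The query is
    ``unclassified`` iff its nearest neighbour lies farther than
    ``threshold``; otherwise the k-neighbourhood plus the query is
    re-clustered and the condensed subtree returned, with the query as a leaf
    under its own accession.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if (records is None) == (query_vector is None):
        raise ValueError("give exactly one of records(+backend) or query_vector")
    if records is not None:
        if not records:
            raise ValueError("empty query proteome")
        if backend is None:
            raise ValueError("a backend is required to embed records")
        if backend.dimension != store.dimension:
            raise ValueError(
                f"backend dimension {backend.dimension} != store dimension "
                f"{store.dimension}"
            )
        reps, failures = embed_proteome(records, backend)
        mpr = compute_mpr(Proteome(query_accession, tuple(reps)))
        q = mpr.phi
        embed_failures = len(failures)
    else:
        q = np.asarray(query_vector, dtype=np.float64)
        if q.shape != (store.dimension,):
            raise ValueError(
                f"query dimension {q.shape} != store dimension ({store.dimension})"
            )
        embed_failures = 0

    neighbours = nearest_neighbours(q, store, k)
    parameters = {
        "k": k,
        "unclassified_threshold": threshold,
        "embed_failures": embed_failures,
        "search": "exact",
    }
    if neighbours[0][1] > threshold:
        return QueryResult(
            query_accession=query_accession,
            neighbours=neighbours,
            status="unclassified",
            subtree=None,
            neighbour_annotations=_annotate(annotations, neighbours),
            parameters=parameters,
        )

    accs = [a for a, _ in neighbours]
    matrix = np.vstack(
        [store.matrix[store.accessions.index(a)].astype(np.float64) for a in accs]
        + [q]
    )
    D = pairwise_distances(matrix, accs + [query_accession])
    subtree = build_hierarchy(D)
    return QueryResult(
        query_accession=query_accession,
        neighbours=neighbours,
        status="placed",
        subtree=subtree,
        neighbour_annotations=_annotate(annotations, neighbours),
        parameters=parameters,
    )


def _annotate(
    annotations: AnnotationTable | None, neighbours: list[tuple[str, float]]
) -> dict[str, dict] | None:
    if annotations is None:
        return None
    return {a: annotations.row(a) for a, _ in neighbours}
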
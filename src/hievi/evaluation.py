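"""Agreement between MPR clusters and taxonomy: AMI, silhouette, thresholds, atlas.

All evaluation respects two conventions of the published analyses:
genomes carrying the ``"unclassified"`` sentinel are ignored, and genomes
whose label is a singleton still receive a silhouette score (zero, by the
definition's degenerate case) so that every classified phage counts toward
the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

from hievi.hierarchy import NOISE, CondensedHierarchy, build_hierarchy, cut_at_eps
from hievi.io_store import UNCLASSIFIED, AnnotationTable
from hievi.mpr import DistanceMatrix


def silhouette_scores(
    D: DistanceMatrix,
    labels: Sequence[str],
    sentinel: str = UNCLASSIFIED,
) -> tuple[np.ndarray, float]:
    """Per-sample silhouettes s(i) = (b - a) / max(a, b) and their mean.

    ``labels`` align with ``D.accessions``.  Sentinel-labeled samples are
    excluded from both the scores and every a/b computation; samples in
    singleton clusters score 0.  Returns (per-sample array over the evaluated
    subset in ``D`` order, mean).
    """
    labels = np.asarray([str(l) for l in labels], dtype=object)
    if labels.shape[0] != D.n:
        raise ValueError("labels must align with the distance matrix")
    keep = labels != sentinel
    sub = D.D[np.ix_(keep, keep)]
    sub_labels = labels[keep]
    classes, inv = np.unique(sub_labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("silhouette needs at least two distinct labels")

    n = sub.shape[0]
    scores = np.zeros(n)
    counts = np.bincount(inv)
    # mean distance of each sample to each class, vectorized over classes
    class_sums = np.zeros((n, classes.size))
    for c in range(classes.size):
        class_sums[:, c] = sub[:, inv == c].sum(axis=1)
    for i in range(n):
        c = inv[i]
        if counts[c] == 1:
            scores[i] = 0.0  # singleton cluster: degenerate case scores zero
            continue
        a = class_sums[i, c] / (counts[c] - 1)
        other = [
            class_sums[i, o] / counts[o] for o in range(classes.size) if o != c
        ]
        b = min(other)
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return scores, float(scores.mean())


def ami(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted mutual information between two labelings.

    Chance-corrected with the exact hypergeometric expected MI and the
    arithmetic mean of the entropies in the denominator (the standard
    normalization in the AMI literature).  1.0 for identical partitions and
    invariant to label permutation.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(f"length mismatch: {len(labels_a)} vs {len(labels_b)}")
    if len(labels_a) == 0:
        raise ValueError("empty labelings")
    return float(
        adjusted_mutual_info_score(
            list(labels_a), list(labels_b), average_method="arithmetic"
        )
    )


@dataclass
class AMIProfile:
    """AMI against one taxonomic rank across a grid of eps cuts."""

    rank: str
    eps_grid: np.ndarray
    ami: np.ndarray
    n_evaluated: int

    @property
    def max_ami(self) -> float:
        return float(np.max(self.ami))

    @property
    def best_eps(self) -> float:
        return float(self.eps_grid[int(np.argmax(self.ami))])

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "eps_grid": self.eps_grid.tolist(),
            "ami": self.ami.tolist(),
            "n_evaluated": self.n_evaluated,
            "max_ami": self.max_ami,
            "best_eps": self.best_eps,
        }


def default_eps_grid(D: DistanceMatrix, n_points: int = 64) -> np.ndarray:
    """Logarithmic grid spanning [min positive distance, max distance]."""
    cond = D.condensed()
    positive = cond[cond > 0]
    if positive.size == 0:
        raise ValueError("all pairwise distances are zero")
    return np.geomspace(positive.min(), cond.max(), n_points)


def ami_vs_eps(
    data: CondensedHierarchy | DistanceMatrix,
    annotations: AnnotationTable,
    rank: str,
    eps_grid: Sequence[float] | None = None,
) -> AMIProfile:
    """AMI between rank labels and the flat clustering at each eps.

    At each grid point the hierarchy is cut, sentinel-labeled genomes are
    dropped, each noise point becomes its own singleton cluster (so stray
    points are not spuriously merged into one class), and AMI is computed
    against the annotation labels.
    """
    if isinstance(data, DistanceMatrix):
        hierarchy = build_hierarchy(data)
        grid = (
            np.asarray(eps_grid, dtype=float)
            if eps_grid is not None
            else default_eps_grid(data)
        )
    else:
        hierarchy = data
        if eps_grid is None:
            heights = hierarchy.merge_heights
            positive = heights[heights > 0]
            if positive.size == 0:
                raise ValueError("degenerate hierarchy: all merge heights zero")
            grid = np.geomspace(positive.min(), heights.max(), 64)
        else:
            grid = np.asarray(eps_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty eps grid")

    ranks = annotations.rank_labels(rank, hierarchy.accessions)
    keep = [i for i, lab in enumerate(ranks) if lab != UNCLASSIFIED]
    true_labels = [ranks[i] for i in keep]
    if len(set(true_labels)) < 2:
        raise ValueError(f"rank {rank!r} has fewer than two non-sentinel labels")

    scores = np.empty(grid.size)
    for j, eps in enumerate(grid):
        fc = cut_at_eps(hierarchy, float(eps))
        flat = fc.labels_array(hierarchy.accessions)
        pred = []
        singleton = -1
        for i in keep:
            if flat[i] == NOISE:
                pred.append(singleton)
                singleton -= 1
            else:
                pred.append(int(flat[i]))
        scores[j] = ami(true_labels, pred)
    return AMIProfile(rank=rank, eps_grid=grid, ami=scores, n_evaluated=len(keep))


@dataclass
class ThresholdReport:
    """Within- vs between-taxon distance separation at one rank.

    Distances of randomly sampled within-taxon and between-taxa pairs, their
    histograms, and the threshold maximizing Youden's J = TPR - FPR where a
    pair is called "within" when its distance <= threshold.
    """

    rank: str
    n_pairs_within: int
    n_pairs_between: int
    within_distances: np.ndarray = field(repr=False)
    between_distances: np.ndarray = field(repr=False)
    best_threshold: float = 0.0
    tpr: float = 0.0
    fpr: float = 0.0
    criterion: str = "youden-j"
    histogram_bins: np.ndarray = field(default=None, repr=False)
    histogram_within: np.ndarray = field(default=None, repr=False)
    histogram_between: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "n_pairs_within": self.n_pairs_within,
            "n_pairs_between": self.n_pairs_between,
            "best_threshold": self.best_threshold,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "criterion": self.criterion,
            "histogram_bins": self.histogram_bins.tolist(),
            "histogram_within": self.histogram_within.tolist(),
            "histogram_between": self.histogram_between.tolist(),
        }


def threshold_analysis(
    D: DistanceMatrix,
    annotations: AnnotationTable,
    rank: str,
    n_pairs: int = 10_000,
    seed: int = 0,
    n_bins: int = 50,
) -> ThresholdReport:
    """Sample within/between pairs at a rank and find the best distance gate.

    ``n_pairs`` pairs are drawn uniformly with replacement from each pool
    (same non-sentinel label at ``rank`` = within; different non-sentinel
    labels = between).  Candidate thresholds are midpoints between adjacent
    observed distances; the reported one maximizes TPR - FPR, with TPR the
    fraction of within-pairs at distance <= threshold and FPR the fraction of
    between-pairs there.  Deterministic given the seed; TPR/FPR are exact
    functions of the sampled pairs.
    """
    labels = np.asarray(annotations.rank_labels(rank, D.accessions), dtype=object)
    ok = labels != UNCLASSIFIED
    same = (labels[:, None] == labels[None, :]) & ok[:, None] & ok[None, :]
    diff = (labels[:, None] != labels[None, :]) & ok[:, None] & ok[None, :]
    iu = np.triu_indices(D.n, k=1)
    within_pool = np.nonzero(same[iu])[0]
    between_pool = np.nonzero(diff[iu])[0]
    if within_pool.size == 0:
        raise ValueError(f"no within-taxon pairs at rank {rank!r}")
    if between_pool.size == 0:
        raise ValueError(f"no between-taxa pairs at rank {rank!r}")

    rng = np.random.default_rng(seed)
    cond = D.D[iu]
    within = cond[rng.choice(within_pool, size=n_pairs, replace=True)]
    between = cond[rng.choice(between_pool, size=n_pairs, replace=True)]

    # candidate gates: midpoints of the pooled sorted distances, plus ends
    pooled = np.unique(np.concatenate([within, between]))
    if pooled.size > 1:
        candidates = np.concatenate(
            [[pooled[0] / 2], (pooled[:-1] + pooled[1:]) / 2, [pooled[-1] * 1.01]]
        )
    else:
        candidates = pooled
    tpr = (within[None, :] <= candidates[:, None]).mean(axis=1)
    fpr = (between[None, :] <= candidates[:, None]).mean(axis=1)
    j = tpr - fpr
    best = int(np.argmax(j))  # first (smallest) threshold at the maximum

    lo = min(within.min(), between.min())
    hi = max(within.max(), between.max())
    bins = np.linspace(lo, hi, n_bins + 1)
    return ThresholdReport(
        rank=rank,
        n_pairs_within=n_pairs,
        n_pairs_between=n_pairs,
        within_distances=within,
        between_distances=between,
        best_threshold=float(candidates[best]),
        tpr=float(tpr[best]),
        fpr=float(fpr[best]),
        histogram_bins=bins,
        histogram_within=np.histogram(within, bins=bins)[0],
        histogram_between=np.histogram(between, bins=bins)[0],
    )


@dataclass
class AtlasCoordinates:
    """2-D UMAP projection of MPRs.  Visualization only: never fed back into
    clustering or distances, which stay in the original space."""

    accessions: list[str]
    coordinates: np.ndarray
    parameters: dict

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.shape != (len(self.accessions), 2):
            raise ValueError("coordinates must be (n, 2)")


def atlas_project(
    vectors: np.ndarray,
    accessions: Sequence[str],
    n_neighbors: int = 16,
    min_dist: float = 0.6,
    seed: int = 0,
) -> AtlasCoordinates:
    """Project MPRs to a 2-D atlas with UMAP (defaults of the published atlas).

    Deterministic given the seed (single-threaded fit).
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.shape[0] <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} samples, got {vectors.shape[0]}"
        )
    import umap  # deferred: numba-backed import is slow

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
        n_jobs=1,
    )
    coords = reducer.fit_transform(vectors)
    return AtlasCoordinates(
        accessions=list(accessions),
        coordinates=np.asarray(coords, dtype=np.float64),
        parameters={
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "seed": seed,
            "visualization_only": True,
        },
    )
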
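"""Synthetic embedding-space datasets with phage-like multi-scale structure.

Real protein embeddings cluster angularly by protein family; proteomes are
bags drawn from family repertoires that overlap more for related phages.  The
generator reproduces exactly that statistical skeleton: K protein-family
directions on the unit sphere, von Mises-Fisher (vMF) angular clusters of
tunable concentration kappa around them, and a strictly nested
family > subfamily > genus taxonomy realized by hierarchical sharing of
family repertoires.  No amino-acid sequences are simulated — the synthetic
path enters the pipeline at the embedding layer.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from hievi.io_store import RANKS, AnnotationTable
from hievi.theory import FamilyModel

#: Constant coarse ranks stamped on synthetic annotation tables.
_SYNTH_UPPER = {"realm": "Synthviria", "kingdom": "Simulavirae", "class": "Testoviricetes"}


def random_unit_vectors(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform unit vectors in R^d (Gaussian normalization)."""
    x = rng.standard_normal((n, d))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def sample_vmf(
    mu: np.ndarray,
    kappa: float,
    n: int,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n unit vectors from vMF(mu, kappa) by the tangent-normal (Wood) construction.

    The cosine w of the angle to mu is drawn by Wood's beta-envelope rejection
    sampler; the tangential part is an independent uniform direction in the
    orthogonal complement.  kappa = 0 gives the uniform distribution on the
    sphere; the mean resultant length increases with kappa.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    mu = np.asarray(mu, dtype=np.float64)
    d = mu.shape[0]
    if abs(np.linalg.norm(mu) - 1.0) > 1e-9:
        raise ValueError("mu must be a unit vector")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if kappa == 0:
        return random_unit_vectors(n, d, rng)
    if d == 1:
        # sphere in R^1 is {-1, +1}; vMF reduces to a two-point distribution
        p = 1.0 / (1.0 + np.exp(-2.0 * kappa * mu[0]))
        return np.where(rng.uniform(size=(n, 1)) < p, 1.0, -1.0)

    # Wood (1994) envelope for the radial cosine
    b = (-2.0 * kappa + np.sqrt(4.0 * kappa**2 + (d - 1) ** 2)) / (d - 1)
    x0 = (1.0 - b) / (1.0 + b)
    c = kappa * x0 + (d - 1) * np.log(1.0 - x0**2)

    w = np.empty(n)
    filled = 0
    while filled < n:
        todo = n - filled
        batch = max(todo, 64)
        z = rng.beta((d - 1) / 2.0, (d - 1) / 2.0, size=batch)
        cand = (1.0 - (1.0 + b) * z) / (1.0 - (1.0 - b) * z)
        u = rng.uniform(size=batch)
        accept = kappa * cand + (d - 1) * np.log(1.0 - x0 * cand) - c >= np.log(u)
        good = cand[accept][:todo]
        w[filled : filled + good.size] = good
        filled += good.size

    # uniform tangential direction orthogonal to mu
    v = rng.standard_normal((n, d))
    v -= np.outer(v @ mu, mu)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    samples = w[:, None] * mu[None, :] + np.sqrt(np.maximum(0.0, 1.0 - w**2))[:, None] * v
    # renormalize away accumulated rounding
    return samples / np.linalg.norm(samples, axis=1, keepdims=True)


def sample_family_proteins(
    model: FamilyModel, assignment: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Unit protein vectors for an assignment of proteins to model families.

    Samples family-by-family (vectorized) and scatters the draws back into
    protein order, so the cost scales with the number of distinct families.
    """
    if model.kappa is None:
        raise ValueError("model.kappa is required for sampling")
    assignment = np.asarray(assignment, dtype=np.intp)
    out = np.empty((assignment.size, model.dimension))
    for k in np.unique(assignment):
        idx = np.nonzero(assignment == k)[0]
        out[idx] = sample_vmf(model.mu[k], float(model.kappa[k]), idx.size, rng)
    return out


@dataclass(frozen=True)
class TaxonomyDesign:
    """Specification of a nested synthetic taxonomy in embedding space.

    The per-genome repertoire holds ``repertoire_size`` distinct protein
    families; the fractions state how much of that repertoire is common to
    every member of the same genus / subfamily / family (descending, since
    closer relatives share more of their gene content).  Proteome sizes are
    uniform over ``m_range``, so each family module is represented by several
    proteins — the bag weights repertoire entries by multiplicity.
    """

    n_families_taxa: int = 3
    n_subfamilies_per_family: int = 2
    n_genera_per_subfamily: int = 3
    n_genomes_per_genus: int = 8
    d: int = 64
    K: int = 200
    kappa: float = 50.0
    m_range: tuple[int, int] = (60, 100)
    shared_within_genus: float = 0.9
    shared_within_subfamily: float = 0.5
    shared_within_family: float = 0.25
    repertoire_size: int = 4
    orthogonal_directions: bool = False
    seed: int = 11

    def __post_init__(self) -> None:
        counts = (
            self.n_families_taxa,
            self.n_subfamilies_per_family,
            self.n_genera_per_subfamily,
            self.n_genomes_per_genus,
            self.repertoire_size,
            self.K,
            self.d,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        fracs = (
            self.shared_within_genus,
            self.shared_within_subfamily,
            self.shared_within_family,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("shared fractions must lie in [0, 1]")
        if not (fracs[0] >= fracs[1] >= fracs[2]):
            raise ValueError(
                "shared fractions must descend: genus >= subfamily >= family"
            )
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not (1 <= self.m_range[0] <= self.m_range[1]):
            raise ValueError("m_range must be an increasing pair of positive ints")
        if self.orthogonal_directions and self.K > self.d:
            raise ValueError("cannot force K > d mutually orthogonal directions")

    @property
    def n_genomes(self) -> int:
        return (
            self.n_families_taxa
            * self.n_subfamilies_per_family
            * self.n_genera_per_subfamily
            * self.n_genomes_per_genus
        )

    @classmethod
    def separable(cls, seed: int = 11) -> "TaxonomyDesign":
        """A design whose genera are cleanly separable in MPR distance.

        Tight families (kappa = 1e4), large fixed proteomes (m = 200, so
        composition fractions concentrate) and fully genus-shared,
        cross-family-disjoint repertoires leave a clear gap between all
        within-genus and all between-genus distances.
        """
        return cls(
            kappa=10_000.0,
            m_range=(200, 200),
            shared_within_genus=1.0,
            shared_within_subfamily=0.25,
            shared_within_family=0.0,
            seed=seed,
        )

    def shared_counts(self) -> tuple[int, int, int]:
        """Repertoire slots fixed at family / subfamily / genus level."""
        p = self.repertoire_size
        n_fam = round(self.shared_within_family * p)
        n_sub = round(self.shared_within_subfamily * p)
        n_gen = round(self.shared_within_genus * p)
        if not n_fam <= n_sub <= n_gen <= p:
            raise ValueError("rounded shared counts are not nested")
        return n_fam, n_sub, n_gen


@dataclass
class SyntheticDataset:
    """A generated dataset: mixture model, per-genome proteins, true labels."""

    design: TaxonomyDesign
    model: FamilyModel
    accessions: list[str]
    proteomes: dict[str, np.ndarray]  # accession -> (m, d) unit rows
    compositions: dict[str, np.ndarray]  # accession -> (K,) family counts
    annotations: AnnotationTable = field(repr=False)

    @property
    def mpr_matrix(self) -> np.ndarray:
        """(n, d) matrix of MPRs in accession order."""
        return np.vstack([self.proteomes[a].mean(axis=0) for a in self.accessions])

    def iter_proteomes(self) -> Iterator[tuple[str, np.ndarray]]:
        for a in self.accessions:
            yield a, self.proteomes[a]


def _draw_extra(
    rng: np.random.Generator, pool: np.ndarray, exclude: np.ndarray, count: int
) -> np.ndarray:
    candidates = np.setdiff1d(pool, exclude, assume_unique=False)
    if candidates.size < count:
        raise ValueError(
            "infeasible design: protein-family pool K too small for the repertoire"
        )
    return rng.choice(candidates, size=count, replace=False)


def generate_dataset(design: TaxonomyDesign) -> SyntheticDataset:
    """Generate a dataset under the design; bit-deterministic given its seed.

    Family directions are drawn once (uniformly, or exactly orthogonal when
    ``orthogonal_directions`` is set — the regime where the analytic
    cross-family term vanishes).  Each genus inherits a nested repertoire of
    protein families from its subfamily and family; each genome fills the
    remaining slots privately and samples its proteins uniformly over its
    repertoire, then draws each protein from the corresponding vMF cluster.
    """
    rng = np.random.default_rng(design.seed)
    if design.orthogonal_directions:
        mus = np.zeros((design.K, design.d))
        mus[np.arange(design.K), np.arange(design.K)] = 1.0
    else:
        mus = random_unit_vectors(design.K, design.d, rng)
    alpha = alpha_for(design.kappa, design.d)
    model = FamilyModel(
        mu=mus,
        alpha=np.full(design.K, alpha),
        kappa=np.full(design.K, float(design.kappa)),
    )

    n_fam, n_sub, n_gen = design.shared_counts()
    p = design.repertoire_size
    all_families = np.arange(design.K)

    accessions: list[str] = []
    proteomes: dict[str, np.ndarray] = {}
    compositions: dict[str, np.ndarray] = {}
    ann_rows: dict[str, dict[str, object]] = {}

    genome_idx = 0
    for f in range(design.n_families_taxa):
        fam_core = _draw_extra(rng, all_families, np.empty(0, dtype=np.intp), n_fam)
        for s in range(design.n_subfamilies_per_family):
            sub_core = np.concatenate(
                [fam_core, _draw_extra(rng, all_families, fam_core, n_sub - n_fam)]
            )
            for g in range(design.n_genera_per_subfamily):
                gen_core = np.concatenate(
                    [sub_core, _draw_extra(rng, all_families, sub_core, n_gen - n_sub)]
                )
                for _ in range(design.n_genomes_per_genus):
                    repertoire = np.concatenate(
                        [gen_core, _draw_extra(rng, all_families, gen_core, p - n_gen)]
                    )
                    m = int(rng.integers(design.m_range[0], design.m_range[1] + 1))
                    assignment = rng.choice(repertoire, size=m, replace=True)
                    proteins = sample_family_proteins(model, assignment, rng)
                    accession = f"SYN{genome_idx:06d}"
                    accessions.append(accession)
                    proteomes[accession] = proteins
                    compositions[accession] = np.bincount(
                        assignment, minlength=design.K
                    ).astype(np.float64)
                    ann_rows[accession] = {
                        **_SYNTH_UPPER,
                        "family": f"Family{f}",
                        "subfamily": f"Family{f}_Subfamily{s}",
                        "genus": f"Family{f}_Subfamily{s}_Genus{g}",
                    }
                    genome_idx += 1

    annotations = AnnotationTable.from_records(ann_rows)
    return SyntheticDataset(design, model, accessions, proteomes, compositions, annotations)


def alpha_for(kappa: float, d: int) -> float:
    """Compactness realized by vMF(kappa) in dimension d (cached empirical)."""
    from hievi.theory import alpha_from_kappa

    return alpha_from_kappa(float(kappa), int(d))


def holdout_split(
    dataset: SyntheticDataset, n_holdout_per_genus: int = 1
) -> tuple[list[str], list[str]]:
    """Deterministically split accessions into (reference, held-out) sets.

    The last ``n_holdout_per_genus`` genomes of each genus are held out,
    emulating query genomes whose relatives are present in the store.
    """
    genus = dataset.annotations.rank_labels("genus", dataset.accessions)
    by_genus: dict[str, list[str]] = {}
    for acc, lab in zip(dataset.accessions, genus):
        by_genus.setdefault(lab, []).append(acc)
    held: list[str] = []
    for members in by_genus.values():
        held.extend(members[-n_holdout_per_genus:])
    held_set = set(held)
    reference = [a for a in dataset.accessions if a not in held_set]
    return reference, held


def perturb_labels(
    annotations: AnnotationTable,
    rank: str,
    fraction: float,
    seed: int = 0,
) -> AnnotationTable:
    """Return a copy with ``fraction`` of the rank labels reassigned at random.

    Emulates annotation noise; reassignment draws uniformly from the other
    observed labels at that rank.
    """
    rng = np.random.default_rng(seed)
    table = annotations.table.copy()
    labels = table[rank].to_numpy().astype(object)
    values = pd.unique(labels)
    if len(values) < 2:
        raise ValueError("need at least two labels to perturb")
    n_flip = int(round(fraction * len(labels)))
    flip = rng.choice(len(labels), size=n_flip, replace=False)
    for i in flip:
        others = [v for v in values if v != labels[i]]
        labels[i] = others[rng.integers(len(others))]
    table[rank] = labels
    return AnnotationTable(table)


__all__ = [
    "SyntheticDataset",
    "TaxonomyDesign",
    "alpha_for",
    "generate_dataset",
    "holdout_split",
    "perturb_labels",
    "random_unit_vectors",
    "sample_family_proteins",
    "sample_vmf",
]
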
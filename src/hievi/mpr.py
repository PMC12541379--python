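"""Mean phage representations (MPRs) and the Euclidean metric between them.

The MPR of a proteome Phi = {u_1 ... u_m} of unit protein vectors is the
plain average phi = (1/m) sum_i u_i.  It is deliberately NOT re-normalized:
its norm carries meaning (functional diversity — aligned protein families
yield larger norms, dispersed ones smaller).  Pairs of phages are compared by
the Euclidean distance ||phi_u - phi_v||, which decomposes as
||phi_u||^2 + ||phi_v||^2 - 2 phi_u.phi_v: diversity of each proteome plus
shared protein content.

All arithmetic here is float64 even when stores hold float32: genus-level
distances on real data sit near 1e-3, uncomfortably close to float32
resolution after accumulating thousands of coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from hievi.embedding import ProteinRepresentation


@dataclass(frozen=True)
class Proteome:
    """A genome accession with its bag of unit protein representations.

    A bag, not a set: duplicated proteins are counted with multiplicity, the
    same way family composition counts weight repeated members.
    """

    genome_accession: str
    representations: tuple[ProteinRepresentation, ...]

    def __post_init__(self) -> None:
        reps = tuple(self.representations)
        object.__setattr__(self, "representations", reps)
        if len(reps) == 0:
            raise ValueError(f"proteome {self.genome_accession!r} is empty")
        dims = {rep.u.shape[0] for rep in reps}
        if len(dims) != 1:
            raise ValueError(
                f"proteome {self.genome_accession!r} mixes dimensions {sorted(dims)}"
            )

    @property
    def m(self) -> int:
        return len(self.representations)

    @property
    def dimension(self) -> int:
        return self.representations[0].u.shape[0]


@dataclass(frozen=True)
class MPRVector:
    """phi = (1/m) sum u_i for one genome; ||phi|| <= 1 by Jensen."""

    genome_accession: str
    phi: np.ndarray
    m: int

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=np.float64)
        object.__setattr__(self, "phi", phi)
        norm = float(np.linalg.norm(phi))
        if norm > 1.0 + 1e-6:
            raise ValueError(
                f"MPR for {self.genome_accession!r} has norm {norm} > 1: "
                "inputs were not unit vectors"
            )

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.phi))


def compute_mpr(proteome: Proteome) -> MPRVector:
    """Average the proteome's unit protein vectors (no re-normalization)."""
    mat = np.vstack([rep.u for rep in proteome.representations]).astype(np.float64)
    norms = np.linalg.norm(mat, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(norms - 1.0)))
        raise ValueError(
            f"protein {proteome.representations[bad].protein_id!r} is not unit-norm"
        )
    return MPRVector(proteome.genome_accession, mat.mean(axis=0), proteome.m)


def mpr_from_matrix(genome_accession: str, unit_rows: np.ndarray) -> MPRVector:
    """MPR straight from an (m, d) array of unit rows (synthetic path)."""
    mat = np.asarray(unit_rows, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] == 0:
        raise ValueError("need a non-empty (m, d) array of unit rows")
    return MPRVector(genome_accession, mat.mean(axis=0), mat.shape[0])


def _phi(x) -> np.ndarray:
    vec = x.phi if isinstance(x, MPRVector) else np.asarray(x, dtype=np.float64)
    return np.asarray(vec, dtype=np.float64)


def mpr_norm_sq(mpr) -> float:
    """||phi||^2 (functional-diversity proxy)."""
    phi = _phi(mpr)
    return float(phi @ phi)


def mpr_dot(mpr_u, mpr_v) -> float:
    """phi_u . phi_v (shared-protein-content proxy)."""
    u, v = _phi(mpr_u), _phi(mpr_v)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(u @ v)


def mpr_distance(mpr_u, mpr_v) -> float:
    """Euclidean distance ||phi_u - phi_v||, computed directly.

    The squared distance equals norm_sq(u) + norm_sq(v) - 2 dot(u, v); that
    identity is a cross-check in the tests, not the computation path.
    """
    u, v = _phi(mpr_u), _phi(mpr_v)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


@dataclass
class DistanceMatrix:
    """Symmetric n x n Euclidean distances between named MPRs."""

    accessions: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.float64)
        n = len(self.accessions)
        if self.D.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.D.shape} != ({n}, {n})")
        if len(set(self.accessions)) != n:
            raise ValueError("duplicate accessions in distance matrix")
        if not np.allclose(self.D, self.D.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.D < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.accessions)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        return squareform(self.D, checks=False)

    def between(self, a: str, b: str) -> float:
        return float(self.D[self.accessions.index(a), self.accessions.index(b)])


def pairwise_distances(
    mprs: Sequence[MPRVector] | np.ndarray,
    accessions: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All-versus-all Euclidean distances, in float64.

    Accepts a list of :class:`MPRVector` or an (n, d) array plus accessions.
    """
    if isinstance(mprs, np.ndarray):
        if accessions is None:
            raise ValueError("accessions are required with a raw matrix")
        matrix = np.asarray(mprs, dtype=np.float64)
        names = list(accessions)
    else:
        mprs = list(mprs)
        names = [m.genome_accession for m in mprs]
        dims = {m.phi.shape[0] for m in mprs}
        if len(dims) > 1:
            raise ValueError(f"MPRs mix dimensions {sorted(dims)}")
        matrix = np.vstack([m.phi for m in mprs]).astype(np.float64)
    if matrix.shape[0] < 2:
        raise ValueError("need at least two MPRs for a distance matrix")
    D = squareform(pdist(matrix, metric="euclidean"))
    return DistanceMatrix(names, D)
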
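"""Protein representations: residue embeddings -> mean pool -> unit vector.

The embedding backend is a pluggable contract: anything with a ``name``, a
fixed ``dimension`` and an ``embed(sequence) -> (L, d)`` residue matrix.  The
production backend for the published workflow is ESM-2 3B (d = 2560), which
needs a large GPU; it is exposed only as an on-demand adapter so the method's
core stays exercisable at desk scale with deterministic mock backends.

Normalizing each pooled protein vector to unit length makes every protein
contribute equally to the angular (functional) space, preventing highly
conserved proteins with large embedding norms from dominating the proteome
average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from hievi.io_store import ProteinRecord

#: Tolerance for unit-norm assertions, in float64.
UNIT_NORM_TOL = 1e-9


class ConfigurationError(RuntimeError):
    """A backend is unavailable or misconfigured."""


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract for residue-level embedding providers."""

    name: str
    dimension: int

    def embed(self, sequence: str) -> np.ndarray:
        """Return an (L, d) float matrix of residue embeddings.

        Rows correspond to residues only; adapters for transformer backends
        must strip any begin/end special-token rows before returning (and
        record that in their metadata).
        """
        ...


@dataclass(frozen=True)
class ProteinRepresentation:
    """A unit vector u for one protein (||u|| = 1 within 1e-9)."""

    protein_id: str
    u: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=np.float64)
        object.__setattr__(self, "u", u)
        norm = float(np.linalg.norm(u))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(
                f"protein {self.protein_id!r}: representation norm {norm} is not 1"
            )


def mean_pool(residue_matrix: np.ndarray) -> np.ndarray:
    """Column mean of an (L, d) residue-embedding matrix."""
    mat = np.asarray(residue_matrix, dtype=np.float64)
    if mat.ndim != 2:
        raise ValueError(f"residue matrix must be 2-D, got shape {mat.shape}")
    if mat.shape[0] == 0:
        raise ValueError("empty protein: no residue rows to pool")
    return mat.mean(axis=0)


def normalize(v: np.ndarray) -> np.ndarray:
    """v / ||v||; raises on the zero vector instead of returning NaN."""
    v = np.asarray(v, dtype=np.float64)
    norm = float(np.linalg.norm(v))
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError("degenerate embedding: zero or non-finite norm")
    return v / norm


def represent_protein(record: ProteinRecord, backend: EmbeddingBackend) -> ProteinRepresentation:
    """Embed one protein: residues -> mean pool -> unit vector."""
    residues = backend.embed(record.sequence)
    return ProteinRepresentation(record.protein_id, normalize(mean_pool(residues)))


def embed_proteome(
    records: Sequence[ProteinRecord], backend: EmbeddingBackend
) -> tuple[list[ProteinRepresentation], list[tuple[str, str]]]:
    """One unit representation per record, order preserved.

    Per-protein backend failures are collected as ``(protein_id, message)``
    pairs and reported, never silently dropped.  If every protein fails the
    whole call fails.
    """
    if not records:
        raise ValueError("empty proteome: no records to embed")
    reps: list[ProteinRepresentation] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            reps.append(represent_protein(rec, backend))
        except ConfigurationError:
            raise
        except Exception as exc:  # noqa: BLE001 - per-protein isolation is the contract
            failures.append((rec.protein_id, str(exc)))
    if not reps:
        raise ValueError(
            f"all {len(records)} proteins failed to embed; first error: {failures[0][1]}"
        )
    return reps, failures


# ---------------------------------------------------------------------------
# Backends


class HashedAlphabetBackend:
    """Deterministic mock backend: each amino-acid letter owns a fixed random row.

    ``embed`` is a per-residue table lookup, so equal sequences always map to
    equal matrices.  Useful wherever the pipeline's geometry, not biology, is
    under test.
    """

    def __init__(self, dimension: int = 32, seed: int = 0, name: str = "mock"):
        self.name = name
        self.dimension = int(dimension)
        rng = np.random.default_rng(seed)
        # one row per printable residue code, incl. ambiguity codes and '*'
        alphabet = "ACDEFGHIKLMNPQRSTVWYBJOUXZ*"
        self._rows = {
            ch: rng.standard_normal(self.dimension) for ch in alphabet
        }

    def embed(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("empty sequence")
        try:
            return np.vstack([self._rows[ch] for ch in sequence.upper()])
        except KeyError as exc:
            raise ValueError(f"unknown residue code {exc.args[0]!r}") from exc


class MatrixBackend:
    """Test backend returning preset residue matrices keyed by sequence."""

    def __init__(self, matrices: dict[str, np.ndarray], name: str = "matrix"):
        self.name = name
        self._matrices = {k: np.asarray(v, dtype=np.float64) for k, v in matrices.items()}
        dims = {m.shape[1] for m in self._matrices.values()}
        if len(dims) != 1:
            raise ValueError("all preset matrices must share one dimension")
        self.dimension = dims.pop()

    def embed(self, sequence: str) -> np.ndarray:
        if sequence not in self._matrices:
            raise ValueError(f"no preset matrix for sequence {sequence!r}")
        return self._matrices[sequence]


def _load_esm2_backend(**kwargs):  # pragma: no cover - optional heavy adapter
    try:
        import esm  # type: ignore[import-not-found]  # noqa: F401
    except ImportError as exc:
        raise ConfigurationError(
            "the esm2-3b backend needs the optional 'fair-esm' package and a "
            "large-memory GPU; install fair-esm and retry, or use --backend mock"
        ) from exc
    raise ConfigurationError(
        "esm2-3b adapter present but not configured in this build"
    )


_REGISTRY: dict[str, Callable[..., EmbeddingBackend]] = {
    "mock": HashedAlphabetBackend,
    "esm2-3b": _load_esm2_backend,
}


def register_backend(name: str, factory: Callable[..., EmbeddingBackend]) -> None:
    """Add a backend factory to the plugin registry."""
    _REGISTRY[name] = factory


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    """Instantiate a registered backend by name."""
    if name not in _REGISTRY:
        raise ConfigurationError(
            f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name](**kwargs)
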
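"""Readers and writers for the formats the pipeline touches.

Covers INPHARED-style per-protein FASTA grouped into proteomes by genome
accession, tabular taxonomy annotations, chunked on-disk vector stores (Zarr)
for protein or proteome embeddings, keyword flag extraction from free-text
protein descriptions, and Cytoscape-compatible exports of the cluster
hierarchy.

Vectors are stored float32 on disk (halving storage at d = 2560) and always
promoted to float64 before any distance arithmetic elsewhere in the package.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import zarr
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: ICTV ranks carried on every annotation table, coarsest first.
RANKS = ("realm", "kingdom", "class", "family", "subfamily", "genus")

#: Sentinel used for missing taxonomic assignments. Not a taxon.
UNCLASSIFIED = "unclassified"

#: The 20 standard amino acids; anything else is legal but flagged.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default rule mapping an INPHARED-style protein ID to its genome accession.
PREFIX_GROUPING = "prefix-before-last-underscore"


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence attributed to a genome.

    ``description`` keeps the free-text functional annotation from the FASTA
    header (used for keyword flags); ``nonstandard_residues`` flags characters
    outside the 20-letter alphabet (X, B, Z, ... are kept, not rejected).
    """

    protein_id: str
    genome_accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genome_accession:
            raise ValueError(f"protein {self.protein_id!r}: empty genome accession")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")

    @property
    def nonstandard_residues(self) -> frozenset[str]:
        return frozenset(self.sequence.upper()) - STANDARD_AA


def accession_from_protein_id(protein_id: str) -> str:
    """Genome accession under the prefix rule: strip the last ``_suffix``.

    ``MZ747518_00043`` -> ``MZ747518``.  IDs without an underscore are their
    own accession.
    """
    head, sep, _ = protein_id.rpartition("_")
    return head if sep else protein_id


def read_proteomes(
    fasta_path: str | Path,
    grouping: str | Mapping[str, str] = PREFIX_GROUPING,
) -> tuple[dict[str, list[ProteinRecord]], list[str]]:
    """Read a protein FASTA and group records into proteomes.

    Parameters
    ----------
    fasta_path
        Amino-acid FASTA; record IDs are protein IDs.
    grouping
        Either the string ``"prefix-before-last-underscore"`` (default,
        INPHARED protein-ID convention) or an explicit mapping
        ``protein_id -> genome_accession``.

    Returns
    -------
    (proteomes, rejects)
        ``proteomes`` maps genome accession to its records in file order.
        ``rejects`` lists protein IDs that matched no accession under an
        explicit map; they are reported, never silently dropped.
    """
    fasta_path = Path(fasta_path)
    try:
        seq_records = list(SeqIO.parse(str(fasta_path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise FormatError(f"cannot parse {fasta_path} as FASTA: {exc}") from exc
    if not seq_records:
        raise FormatError(f"{fasta_path}: no FASTA records found")

    explicit = None if isinstance(grouping, str) else dict(grouping)
    if explicit is None and grouping != PREFIX_GROUPING:
        raise ValueError(f"unknown grouping rule {grouping!r}")

    proteomes: dict[str, list[ProteinRecord]] = {}
    rejects: list[str] = []
    seen_ids: set[str] = set()
    for rec in seq_records:
        if rec.id in seen_ids:
            raise FormatError(f"duplicate protein id {rec.id!r}")
        seen_ids.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        if explicit is not None:
            accession = explicit.get(rec.id)
            if accession is None:
                rejects.append(rec.id)
                continue
        else:
            accession = accession_from_protein_id(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        proteomes.setdefault(accession, []).append(
            ProteinRecord(rec.id, accession, seq, desc)
        )
    if rejects:
        logger.warning(
            "%d records matched no accession under the explicit map: %s",
            len(rejects),
            ", ".join(rejects[:10]) + ("..." if len(rejects) > 10 else ""),
        )
    return proteomes, rejects


# ---------------------------------------------------------------------------
# Annotation tables


@dataclass
class AnnotationTable:
    """Per-accession taxonomy (ICTV ranks) plus optional keyword flags.

    Wraps a DataFrame indexed by genome accession.  Every rank column exists;
    missing assignments hold the sentinel ``"unclassified"``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate accessions in annotation table: {dups[:5]}")
        for rank in RANKS:
            if rank not in self.table.columns:
                self.table[rank] = UNCLASSIFIED
        for rank in RANKS:
            col = self.table[rank].astype("string")
            self.table[rank] = col.fillna(UNCLASSIFIED).astype(str)

    @property
    def accessions(self) -> list[str]:
        return list(self.table.index)

    def rank_labels(self, rank: str, accessions: Sequence[str]) -> list[str]:
        """Labels for ``accessions`` at ``rank``; unknown accessions are sentinel."""
        if rank not in self.table.columns:
            raise KeyError(f"rank {rank!r} not in annotation table")
        col = self.table[rank]
        return [
            str(col[a]) if a in self.table.index else UNCLASSIFIED for a in accessions
        ]

    def row(self, accession: str) -> dict[str, object]:
        """All columns for one accession; sentinel row if absent."""
        if accession in self.table.index:
            return {str(k): v for k, v in self.table.loc[accession].items()}
        return {rank: UNCLASSIFIED for rank in RANKS}

    @classmethod
    def from_records(
        cls, records: Mapping[str, Mapping[str, object]]
    ) -> "AnnotationTable":
        df = pd.DataFrame.from_dict(dict(records), orient="index")
        df.index.name = "accession"
        return cls(df)


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a TSV/CSV annotation table; requires an ``accession`` column."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "accession" not in df.columns:
        raise FormatError(f"{path}: annotation table must have an 'accession' column")
    df = df.set_index("accession")
    # keyword flag columns come back as strings; restore booleans
    for col in df.columns:
        if col.startswith("has_"):
            df[col] = df[col].map({"True": True, "False": False, "1": True, "0": False})
    return AnnotationTable(df)


def write_annotations(annotations: AnnotationTable, path: str | Path) -> Path:
    path = Path(path)
    annotations.table.to_csv(path, sep="\t", index_label="accession")
    return path


def extract_keyword_flags(
    protein_annotations: Mapping[str, str],
    keywords: Iterable[str],
    grouping: str | Mapping[str, str] = PREFIX_GROUPING,
) -> pd.DataFrame:
    """Per-accession boolean flags from free-text protein descriptions.

    A flag ``has_<keyword>`` is true for an accession iff any of its proteins'
    descriptions contains the keyword as a case-insensitive substring (the
    convention used to mark integrase, excisionase, RNA polymerase, ...).
    Empty inputs yield an empty frame (all-false semantics).
    """
    keywords = list(keywords)
    explicit = None if isinstance(grouping, str) else dict(grouping)
    rows: dict[str, dict[str, bool]] = {}
    for protein_id, desc in protein_annotations.items():
        if explicit is not None:
            accession = explicit.get(protein_id)
            if accession is None:
                continue
        else:
            accession = accession_from_protein_id(protein_id)
        flags = rows.setdefault(
            accession, {f"has_{k.lower()}": False for k in keywords}
        )
        low = (desc or "").lower()
        for k in keywords:
            if k.lower() in low:
                flags[f"has_{k.lower()}"] = True
    df = pd.DataFrame.from_dict(rows, orient="index").astype(bool)
    df.index.name = "accession"
    return df


# ---------------------------------------------------------------------------
# Vector stores


@dataclass
class VectorStore:
    """An ordered set of named vectors: ``matrix[i]`` belongs to ``accessions[i]``."""

    accessions: list[str]
    matrix: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got shape {self.matrix.shape}")
        if len(self.accessions) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.accessions)} accessions but matrix has "
                f"{self.matrix.shape[0]} rows"
            )
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accessions in vector store")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def vector(self, accession: str) -> np.ndarray:
        return self.matrix[self.accessions.index(accession)]


def write_vector_store(
    path: str | Path,
    accessions: Sequence[str],
    matrix: np.ndarray,
    metadata: Mapping[str, object] | None = None,
    dtype: str = "float32",
) -> Path:
    """Write a chunked array store (Zarr group) with accession order and metadata.

    Data are stored ``float32`` by default; the round trip is bit-exact at the
    stored precision.
    """
    store = VectorStore(list(accessions), np.asarray(matrix), dict(metadata or {}))
    path = Path(path)
    root = zarr.open_group(str(path), mode="w")
    arr = root.create_array(
        "matrix", shape=store.matrix.shape, dtype=dtype, chunks=(min(store.n, 4096), store.dimension)
    )
    arr[:] = store.matrix.astype(dtype)
    root.attrs["accessions"] = store.accessions
    meta = dict(store.metadata)
    meta.setdefault("dimension", store.dimension)
    meta["dtype"] = dtype
    root.attrs["metadata"] = meta
    with open(path / "hievi_store.json", "w") as fh:
        json.dump({"n": store.n, "dimension": store.dimension, "metadata": meta}, fh, indent=2)
    return path


def read_vector_store(path: str | Path) -> VectorStore:
    """Read a store written by :func:`write_vector_store`."""
    root = zarr.open_group(str(Path(path)), mode="r")
    matrix = np.asarray(root["matrix"])
    accessions = [str(a) for a in root.attrs["accessions"]]
    metadata = dict(root.attrs.get("metadata", {}))
    return VectorStore(accessions, matrix, metadata)


# ---------------------------------------------------------------------------
# Tree network export

_EXPORT_FORMATS = ("graphml", "sif", "edge-tsv")


def tree_to_network(hierarchy, annotations: AnnotationTable | None = None) -> nx.DiGraph:
    """Directed rooted tree over cluster nodes and leaves, Cytoscape-ready.

    Cluster nodes carry ``size`` and ``height`` (the distance scale at which
    the cluster appears, i.e. its children merge); leaves carry the accession
    and every annotation column.  Leaves missing from the annotation table get
    sentinel values with a logged warning.
    """
    g = nx.DiGraph()
    missing = []
    for node in hierarchy.iter_nodes():
        if node["kind"] == "leaf":
            attrs = {"kind": "leaf", "accession": node["accession"]}
            if annotations is not None:
                if node["accession"] not in annotations.table.index:
                    missing.append(node["accession"])
                for key, val in (annotations.row(node["accession"])).items():
                    attrs[str(key)] = "" if pd.isna(val) else val
            g.add_node(node["id"], **attrs)
        else:
            g.add_node(
                node["id"], kind="cluster", size=int(node["size"]), height=float(node["height"])
            )
        if node["parent"] is not None:
            g.add_edge(node["parent"], node["id"])
    if missing:
        logger.warning(
            "%d leaves had no annotation row (sentinel values exported)", len(missing)
        )
    roots = [n for n, deg in g.in_degree() if deg == 0]
    if len(roots) != 1:
        raise ValueError(f"exported tree must have exactly one root, found {len(roots)}")
    return g


def export_tree_network(
    hierarchy,
    annotations: AnnotationTable | None,
    path: str | Path,
    format: str = "graphml",
) -> Path:
    """Serialize the cluster hierarchy for viewing in Cytoscape.

    ``graphml`` keeps all node attributes; ``sif`` writes
    ``parent<TAB>contains<TAB>child`` interactions; ``edge-tsv`` writes a
    parent/child edge list plus a ``<path>.nodes.tsv`` attribute sidecar.
    """
    if format not in _EXPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_EXPORT_FORMATS}")
    g = tree_to_network(hierarchy, annotations)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, str(path))
    elif format == "sif":
        with open(path, "w") as fh:
            for parent, child in g.edges():
                fh.write(f"{parent}\tcontains\t{child}\n")
    else:
        with open(path, "w") as fh:
            fh.write("parent\tchild\n")
            for parent, child in g.edges():
                fh.write(f"{parent}\t{child}\n")
        nodes = pd.DataFrame.from_dict(dict(g.nodes(data=True)), orient="index")
        nodes.index.name = "node"
        nodes.to_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t")
    return path


def write_run_metadata(path: str | Path, config: Mapping[str, object]) -> Path:
    """JSON sidecar recording the parameters that produced an artifact."""
    import hievi

    path = Path(path)
    payload = {"hievi_version": hievi.__version__, "config": dict(config)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
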
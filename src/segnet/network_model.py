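"""Data model and I/O for annotated co-occurrence networks.

The central object is :class:`InteractionNetwork`: a simple undirected
graph over opaque barcode identifiers, where each edge carries a
correlation score, a sign derived from that score (``copresence`` for
positive, ``exclusion`` for negative), a driver label (``biotic`` or
``abiotic`` plus the abiotic parameter name), and sampling metadata
(size fraction and depth layer).  The same unordered barcode pair may
appear once per distinct ``(size_fraction, depth_layer)`` stratum; all
counting operations downstream count each retained edge record once.

File formats are plain TSV (see :func:`read_network` /
:func:`write_network`); GraphML export is provided for interoperability
with graph tools.
"""

from __future__ import annotations

import csv
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

__all__ = [
    "SIGN_COPRESENCE",
    "SIGN_EXCLUSION",
    "DRIVER_BIOTIC",
    "DRIVER_ABIOTIC",
    "TROPHIC_MODES",
    "TaxonAnnotation",
    "AnnotatedEdge",
    "InteractionNetwork",
    "AbundanceTable",
    "NetworkFormatError",
    "read_network",
    "write_network",
    "write_graphml",
    "read_abundance",
    "write_abundance",
    "assign_groups",
    "merge_networks",
]

SIGN_COPRESENCE = "copresence"
SIGN_EXCLUSION = "exclusion"
DRIVER_BIOTIC = "biotic"
DRIVER_ABIOTIC = "abiotic"
TROPHIC_MODES = ("autotroph", "heterotroph", "unknown")

UNASSIGNED = "unassigned"


class NetworkFormatError(ValueError):
    """Raised for malformed or inconsistent network input."""


@dataclass(frozen=True, slots=True)
class TaxonAnnotation:
    """Taxonomic annotation of one barcode.

    Parameters
    ----------
    barcode_id
        Opaque identifier, unique within a network.
    lineage
        Ordered rank labels, root to leaf.
    group
        Canonical group label, normally set by :func:`assign_groups`.
    genus, species
        Optional name fields; empty string when unresolved.
    trophic_mode
        One of ``autotroph``, ``heterotroph``, ``unknown``.
    """

    barcode_id: str
    lineage: tuple[str, ...] = ()
    group: str = UNASSIGNED
    genus: str = ""
    species: str = ""
    trophic_mode: str = "unknown"

    def __post_init__(self) -> None:
        if not self.barcode_id:
            raise NetworkFormatError("barcode_id must be non-empty")
        if self.trophic_mode not in TROPHIC_MODES:
            raise NetworkFormatError(
                f"invalid trophic_mode {self.trophic_mode!r} for barcode "
                f"{self.barcode_id!r}; expected one of {TROPHIC_MODES}"
            )
        object.__setattr__(self, "lineage", tuple(self.lineage))


@dataclass(frozen=True, slots=True)
class AnnotatedEdge:
    """One undirected correlation between two barcodes.

    The sign is *derived* from the score: strictly positive scores are
    copresences, strictly negative scores are exclusions.  A score of
    exactly zero is rejected — the input network contains only
    significant nonzero correlations, and a silent third class would be
    an error mask.  ``driver_parameter`` must be present iff the driver
    is ``abiotic``.
    """

    a: str
    b: str
    score: float
    size_fraction: str = ""
    depth_layer: str = ""
    driver: str = DRIVER_BIOTIC
    driver_parameter: str | None = None

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise NetworkFormatError(f"self-edge on barcode {self.a!r}")
        if not (-1.0 <= self.score <= 1.0):
            raise NetworkFormatError(
                f"score {self.score} outside [-1, 1] on edge {self.a!r}-{self.b!r}"
            )
        if self.score == 0.0 or math.isnan(self.score):
            raise NetworkFormatError(
                f"score must be nonzero and finite on edge {self.a!r}-{self.b!r}"
            )
        if self.driver not in (DRIVER_BIOTIC, DRIVER_ABIOTIC):
            raise NetworkFormatError(f"invalid driver {self.driver!r}")
        if (self.driver == DRIVER_ABIOTIC) != bool(self.driver_parameter):
            raise NetworkFormatError(
                f"driver_parameter must be set iff driver is abiotic "
                f"(edge {self.a!r}-{self.b!r})"
            )

    @property
    def sign(self) -> str:
        return SIGN_COPRESENCE if self.score > 0 else SIGN_EXCLUSION

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair in canonical (sorted) order."""
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)

    @property
    def stratum_key(self) -> tuple[str, str, str, str]:
        """Uniqueness key: one edge per pair per (size_fraction, depth_layer)."""
        return (*self.pair, self.size_fraction, self.depth_layer)


@dataclass
class InteractionNetwork:
    """Annotated co-occurrence network: annotations plus edge records."""

    annotations: dict[str, TaxonAnnotation] = field(default_factory=dict)
    edges: list[AnnotatedEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- consistency ---------------------------------------------------
    def validate(self) -> None:
        """Check all type invariants; raise NetworkFormatError on failure."""
        for bid, ann in self.annotations.items():
            if bid != ann.barcode_id:
                raise NetworkFormatError(
                    f"annotation key {bid!r} != barcode_id {ann.barcode_id!r}"
                )
        endpoints = {e.a for e in self.edges} | {e.b for e in self.edges}
        missing = sorted(endpoints - self.annotations.keys())
        if missing:
            raise NetworkFormatError(
                f"edges reference unannotated barcodes: {', '.join(missing)}"
            )
        seen: set[tuple[str, str, str, str]] = set()
        for e in self.edges:
            k = e.stratum_key
            if k in seen:
                raise NetworkFormatError(
                    f"duplicate edge {k[0]!r}-{k[1]!r} in stratum "
                    f"({k[2]!r}, {k[3]!r})"
                )
            seen.add(k)

    # -- views ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.annotations)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def group_of(self, barcode_id: str) -> str:
        return self.annotations[barcode_id].group

    def groups(self) -> set[str]:
        return {a.group for a in self.annotations.values()}

    def to_multigraph(self) -> nx.MultiGraph:
        """Full attribute-preserving view (one parallel edge per record)."""
        g = nx.MultiGraph()
        for ann in self.annotations.values():
            g.add_node(
                ann.barcode_id,
                lineage=";".join(ann.lineage),
                group=ann.group,
                genus=ann.genus,
                species=ann.species,
                trophic_mode=ann.trophic_mode,
            )
        for e in self.edges:
            g.add_edge(
                e.a,
                e.b,
                score=e.score,
                sign=e.sign,
                size_fraction=e.size_fraction,
                depth_layer=e.depth_layer,
                driver=e.driver,
                driver_parameter=e.driver_parameter or "",
            )
        return g


@dataclass
class AbundanceTable:
    """Barcode x station read-count matrix (non-negative integers)."""

    reads: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.reads
        if df.index.has_duplicates:
            raise NetworkFormatError("duplicate barcode rows in abundance table")
        if (df.to_numpy() < 0).any():
            raise NetworkFormatError("negative read counts in abundance table")
        self.reads = df.astype("int64")

    @property
    def barcodes(self) -> list[str]:
        return list(self.reads.index)

    @property
    def stations(self) -> list[str]:
        return list(self.reads.columns)

    def barcode_reads(self, barcode_id: str) -> pd.Series:
        if barcode_id not in self.reads.index:
            raise KeyError(f"barcode {barcode_id!r} absent from abundance table")
        return self.reads.loc[barcode_id]

    def station_totals(self) -> pd.Series:
        return self.reads.sum(axis=0)


# ---------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------

_EDGE_COLUMNS = [
    "node_a",
    "node_b",
    "score",
    "sign",
    "size_fraction",
    "depth_layer",
    "driver",
    "driver_parameter",
]
_ANNOTATION_COLUMNS = ["barcode_id", "lineage", "genus", "species", "trophic_mode"]


def _check_header(header: list[str], required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise NetworkFormatError(
            f"{path}: missing required columns: {', '.join(missing)}"
        )


def read_network(edge_path: str, annotation_path: str) -> InteractionNetwork:
    """Read an annotated network from an edge TSV and an annotation TSV.

    The edge file must carry columns ``node_a, node_b, score,
    size_fraction, depth_layer, driver, driver_parameter``; an optional
    ``sign`` column is cross-checked against the sign recomputed from
    the score.  The annotation file carries ``barcode_id, lineage``
    (semicolon-separated ranks), ``genus, species, trophic_mode``.

    Raises
    ------
    NetworkFormatError
        Malformed rows (with line number), edges referencing unknown
        barcodes, scores outside [-1, 1], or sign/score mismatches.
    """
    annotations: dict[str, TaxonAnnotation] = {}
    with open(annotation_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:  # empty file
            reader_rows: Iterable[dict] = ()
        else:
            _check_header(
                reader.fieldnames, ["barcode_id", "lineage"], annotation_path
            )
            reader_rows = reader
        for row in reader_rows:
            line = reader.line_num
            try:
                ann = TaxonAnnotation(
                    barcode_id=row["barcode_id"],
                    lineage=tuple(
                        t for t in (row.get("lineage") or "").split(";") if t
                    ),
                    group=row.get("group") or UNASSIGNED,
                    genus=row.get("genus") or "",
                    species=row.get("species") or "",
                    trophic_mode=row.get("trophic_mode") or "unknown",
                )
            except (KeyError, NetworkFormatError) as exc:
                raise NetworkFormatError(
                    f"{annotation_path}:{line}: {exc}"
                ) from exc
            if ann.barcode_id in annotations:
                raise NetworkFormatError(
                    f"{annotation_path}:{line}: duplicate barcode "
                    f"{ann.barcode_id!r}"
                )
            annotations[ann.barcode_id] = ann

    edges: list[AnnotatedEdge] = []
    with open(edge_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            rows: Iterable[dict] = ()
        else:
            _check_header(reader.fieldnames, ["node_a", "node_b", "score"], edge_path)
            rows = reader
        for row in rows:
            line = reader.line_num
            try:
                score = float(row["score"])
            except (TypeError, ValueError) as exc:
                raise NetworkFormatError(
                    f"{edge_path}:{line}: unparseable score {row.get('score')!r}"
                ) from exc
            try:
                edge = AnnotatedEdge(
                    a=row["node_a"],
                    b=row["node_b"],
                    score=score,
                    size_fraction=row.get("size_fraction") or "",
                    depth_layer=row.get("depth_layer") or "",
                    driver=row.get("driver") or DRIVER_BIOTIC,
                    driver_parameter=row.get("driver_parameter") or None,
                )
            except NetworkFormatError as exc:
                raise NetworkFormatError(f"{edge_path}:{line}: {exc}") from exc
            declared = row.get("sign")
            if declared and declared != edge.sign:
                raise NetworkFormatError(
                    f"{edge_path}:{line}: sign/score mismatch: score {score} "
                    f"implies {edge.sign!r} but file says {declared!r}"
                )
            edges.append(edge)

    return InteractionNetwork(annotations=annotations, edges=edges)


def write_network(
    network: InteractionNetwork, edge_path: str, annotation_path: str
) -> None:
    """Write the network as the two TSVs accepted by :func:`read_network`."""
    with open(annotation_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ANNOTATION_COLUMNS + ["group"])
        for bid in sorted(network.annotations):
            ann = network.annotations[bid]
            w.writerow(
                [
                    ann.barcode_id,
                    ";".join(ann.lineage),
                    ann.genus,
                    ann.species,
                    ann.trophic_mode,
                    ann.group,
                ]
            )
    with open(edge_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_EDGE_COLUMNS)
        for e in network.edges:
            w.writerow(
                [
                    e.a,
                    e.b,
                    repr(e.score),
                    e.sign,
                    e.size_fraction,
                    e.depth_layer,
                    e.driver,
                    e.driver_parameter or "",
                ]
            )


def write_graphml(network: InteractionNetwork, path: str) -> None:
    """Export nodes, edges and all attributes to GraphML."""
    nx.write_graphml(network.to_multigraph(), path)


def read_abundance(path: str) -> AbundanceTable:
    """Read a barcode x station TSV matrix of read counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(reads=df)


def write_abundance(table: AbundanceTable, path: str) -> None:
    table.reads.to_csv(path, sep="\t", index_label="barcode_id")


# ---------------------------------------------------------------------
# Group assignment and merging
# ---------------------------------------------------------------------


def assign_groups(
    network: InteractionNetwork,
    group_config: Mapping[str, Sequence[str]] | Sequence[tuple[str, Sequence[str]]],
) -> InteractionNetwork:
    """Assign each annotation's group by first-match over an ordered config.

    ``group_config`` maps group label -> lineage tokens.  An annotation
    receives the label of the FIRST config entry for which any token
    matches (case-insensitive, exact token) any rank of its lineage;
    annotations with no match become ``"unassigned"``.  Order matters so
    that nested taxa resolve predictably (list the more specific taxon
    first).  Idempotent: reassignment with the same config is a no-op.
    """
    items = list(
        group_config.items() if isinstance(group_config, Mapping) else group_config
    )
    if not items:
        raise ValueError("group_config must be non-empty")
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate group labels in config: {', '.join(dupes)}")

    lowered = [
        (label, {t.lower() for t in tokens}) for label, tokens in items
    ]

    def classify(ann: TaxonAnnotation) -> str:
        ranks = {r.lower() for r in ann.lineage}
        for label, tokens in lowered:
            if ranks & tokens:
                return label
        return UNASSIGNED

    annotations = {
        bid: replace(ann, group=classify(ann))
        for bid, ann in network.annotations.items()
    }
    return InteractionNetwork(annotations=annotations, edges=list(network.edges))


def merge_networks(networks: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Union of annotations and edges across (size-fraction) networks.

    A shared barcode must carry an identical annotation in every input.
    An unordered pair occurring in several inputs yields one edge record
    per distinct ``(size_fraction, depth_layer)``; byte-identical
    duplicate records are collapsed, conflicting ones are an error.
    """
    annotations: dict[str, TaxonAnnotation] = {}
    edges: dict[tuple[str, str, str, str], AnnotatedEdge] = {}
    for net in networks:
        for bid, ann in net.annotations.items():
            if bid in annotations and annotations[bid] != ann:
                raise NetworkFormatError(
                    f"conflicting annotations for barcode {bid!r}"
                )
            annotations[bid] = ann
        for e in net.edges:
            k = e.stratum_key
            if k in edges and edges[k] != e:
                raise NetworkFormatError(
                    f"conflicting edge records for {k[0]!r}-{k[1]!r} in stratum "
                    f"({k[2]!r}, {k[3]!r})"
                )
            edges[k] = e
    return InteractionNetwork(annotations=annotations, edges=list(edges.values()))
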
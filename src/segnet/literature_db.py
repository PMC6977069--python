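"""Literature interaction database: parsing, normalization, aggregation,
and overlap quantification against a co-occurrence network.

Records are normalized on read: raw interaction labels (GloBI-style,
e.g. ``eatenBy``) map deterministically onto a controlled vocabulary,
habitats are canonicalized, and records describing interactions with
nonliving surfaces (epipsammic/epipelic) are dropped with a warning.

Network matching is at genus level only — a co-occurrence edge carries
no mechanism, so interaction types are reported for interpretation but
ignored during matching.
"""

from __future__ import annotations

import csv
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .genus_barcode import normalize_genus
from .network_model import InteractionNetwork

__all__ = [
    "INTERACTION_TYPES",
    "DEFAULT_LABEL_MAP",
    "REJECTED_LABELS",
    "LiteratureRecord",
    "OverlapReport",
    "LitdbFormatError",
    "read_litdb",
    "aggregate_hierarchy",
    "hierarchy_share",
    "habitat_summary",
    "compare_litdb_network",
    "genus_disparity",
]

INTERACTION_TYPES = (
    "predation",
    "parasitism",
    "symbiosis",
    "epibiosis",
    "allelopathy",
    "competition",
    "mutualism",
)

#: Raw-label -> controlled-vocabulary normalization table.  Canonical
#: names map to themselves so pre-normalized files also load.
DEFAULT_LABEL_MAP: dict[str, str] = {
    "eatenBy": "predation",
    "preysOn": "predation",
    "preyedUponBy": "predation",
    "parasiteOf": "parasitism",
    "hasParasite": "parasitism",
    "parasitizedBy": "parasitism",
    "symbiontOf": "symbiosis",
    "hasSymbiont": "symbiosis",
    "mutualistOf": "mutualism",
    "epibiontOf": "epibiosis",
    "hasEpibiont": "epibiosis",
    "livesOn": "epibiosis",
    "allelopathOf": "allelopathy",
    "competesWith": "competition",
    **{t: t for t in INTERACTION_TYPES},
}

#: Labels for interactions with nonliving surfaces; dropped on read.
REJECTED_LABELS = frozenset({"epipsammic", "epipelic"})

_HABITATS = ("marine", "freshwater", "both", "unknown")

_COLUMNS = [
    "interaction_raw_label",
    "diatom_genus",
    "diatom_species",
    "partner_class",
    "partner_genus",
    "partner_species",
    "habitat",
    "source_ref",
]


class LitdbFormatError(ValueError):
    """Raised for malformed or unmappable literature-database input."""


@dataclass(frozen=True)
class LiteratureRecord:
    """One normalized known-interaction row."""

    interaction_type: str
    raw_label: str
    diatom_genus: str
    partner_class: str
    partner_genus: str
    diatom_species: str = ""
    partner_species: str = ""
    habitat: str = "unknown"
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise LitdbFormatError(
                f"invalid interaction_type {self.interaction_type!r}"
            )
        if self.habitat not in _HABITATS:
            raise LitdbFormatError(f"invalid habitat {self.habitat!r}")

    @property
    def genus_unresolved(self) -> bool:
        return not self.diatom_genus


@dataclass(frozen=True)
class OverlapReport:
    """Recovery of literature interactions in a network, genus level.

    A record is *potential* when both its genera have at least one
    barcode in the network, and *recovered* when at least one edge joins
    a barcode of each genus.  ``n_network_edges_matched`` counts every
    edge record joining a recovered genus pair, deduplicated per record.
    """

    n_literature: int
    n_potential: int
    n_recovered: int
    n_network_edges_matched: int
    n_group_network_edges: int
    matched_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def pct_recovered_of_potential(self) -> float:
        if self.n_potential == 0:
            return float("nan")
        return self.n_recovered / self.n_potential * 100.0

    @property
    def pct_of_group_network_edges(self) -> float:
        if self.n_group_network_edges == 0:
            return float("nan")
        return self.n_network_edges_matched / self.n_group_network_edges * 100.0


def read_litdb(
    path: str,
    label_map: Mapping[str, str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[LiteratureRecord]:
    """Read and normalize a literature interaction CSV.

    ``column_map`` renames foreign columns onto the canonical layout
    (canonical name -> name in the file), so alternate deposit layouts
    load without editing the file.  Unknown raw labels are an error
    naming the label; epipsammic/epipelic rows are skipped with a
    warning.
    """
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    colmap = dict(column_map or {})

    records: list[LiteratureRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        for row in reader:
            line = reader.line_num

            def get(col: str, _row=row) -> str:
                return (_row.get(colmap.get(col, col)) or "").strip()

            raw = get("interaction_raw_label")
            if not raw:
                raise LitdbFormatError(f"{path}:{line}: missing interaction label")
            if raw in REJECTED_LABELS:
                warnings.warn(
                    f"{path}:{line}: skipping nonliving-surface interaction "
                    f"{raw!r}",
                    stacklevel=2,
                )
                continue
            if raw not in label_map:
                raise LitdbFormatError(
                    f"{path}:{line}: unknown interaction label {raw!r}"
                )
            habitat = get("habitat").lower() or "unknown"
            if habitat not in _HABITATS:
                raise LitdbFormatError(
                    f"{path}:{line}: invalid habitat {habitat!r}"
                )
            try:
                records.append(
                    LiteratureRecord(
                        interaction_type=label_map[raw],
                        raw_label=raw,
                        diatom_genus=get("diatom_genus"),
                        diatom_species=get("diatom_species"),
                        partner_class=get("partner_class"),
                        partner_genus=get("partner_genus"),
                        partner_species=get("partner_species"),
                        habitat=habitat,
                        source_ref=get("source_ref"),
                    )
                )
            except LitdbFormatError as exc:
                raise LitdbFormatError(f"{path}:{line}: {exc}") from exc
    return records


def aggregate_hierarchy(
    records: Sequence[LiteratureRecord], levels: Sequence[str]
) -> dict[tuple[str, ...], int]:
    """Count records at every prefix of the given field hierarchy.

    Returns a map from label-path prefix (starting at the empty tuple,
    which holds the grand total) to record count.  Totals are conserved:
    children of any prefix sum to the prefix count.
    """
    for lv in levels:
        if lv not in LiteratureRecord.__dataclass_fields__:
            raise ValueError(f"unknown record field {lv!r}")
    counts: dict[tuple[str, ...], int] = {}
    for rec in records:
        path = tuple(getattr(rec, lv) for lv in levels)
        for depth in range(len(path) + 1):
            prefix = path[:depth]
            counts[prefix] = counts.get(prefix, 0) + 1
    return counts


def hierarchy_share(
    counts: Mapping[tuple[str, ...], int], prefix: tuple[str, ...]
) -> float:
    """Share of a prefix within its parent prefix, as a fraction."""
    parent = counts[prefix[:-1]]
    return counts[prefix] / parent if parent else float("nan")


def habitat_summary(records: Sequence[LiteratureRecord]) -> pd.DataFrame:
    """Record and deduplicated diatom-genus counts per habitat."""
    rows: dict[str, dict] = {}
    for rec in records:
        entry = rows.setdefault(rec.habitat, {"n_records": 0, "genera": set()})
        entry["n_records"] += 1
        if rec.diatom_genus:
            entry["genera"].add(rec.diatom_genus)
    return pd.DataFrame(
        [
            {
                "habitat": hab,
                "n_records": entry["n_records"],
                "n_genera": len(entry["genera"]),
            }
            for hab, entry in sorted(rows.items())
        ],
        columns=["habitat", "n_records", "n_genera"],
    )


def _genus_maps(
    network: InteractionNetwork,
    group: str,
    synonyms: Mapping[str, str] | None,
) -> tuple[dict[str, str], dict[str, str]]:
    """(focal-group barcode -> genus, any barcode -> genus), lowercased."""
    focal: dict[str, str] = {}
    anyg: dict[str, str] = {}
    has_genus = False
    for bid, ann in network.annotations.items():
        g = normalize_genus(ann.genus, synonyms).lower()
        if g:
            has_genus = True
            anyg[bid] = g
            if ann.group == group:
                focal[bid] = g
    if not has_genus:
        raise ValueError("network lacks genus annotations")
    return focal, anyg


def compare_litdb_network(
    records: Sequence[LiteratureRecord],
    network: InteractionNetwork,
    group: str,
    synonyms: Mapping[str, str] | None = None,
) -> OverlapReport:
    """Quantify recovery of literature interactions in the network.

    Matching is case-insensitive at genus level with the synonym map
    applied to both sides.  The diatom genus must match a barcode of the
    focal ``group``; the partner genus may match any barcode.
    """
    focal_genus, any_genus = _genus_maps(network, group, synonyms)
    focal_set = set(focal_genus.values())
    any_set = set(any_genus.values())

    # genus-pair -> set of matching edge record indices
    pair_edges: dict[tuple[str, str], set[int]] = {}
    for i, e in enumerate(network.edges):
        for x, y in ((e.a, e.b), (e.b, e.a)):
            gx = focal_genus.get(x)
            gy = any_genus.get(y)
            if gx and gy:
                pair_edges.setdefault((gx, gy), set()).add(i)

    n_potential = n_recovered = 0
    matched_pairs: list[tuple[str, str]] = []
    matched_edges: set[int] = set()
    for rec in records:
        dg = normalize_genus(rec.diatom_genus, synonyms).lower()
        pg = normalize_genus(rec.partner_genus, synonyms).lower()
        if not dg or not pg:
            continue
        if dg in focal_set and pg in any_set:
            n_potential += 1
            hits = pair_edges.get((dg, pg), set())
            if hits:
                n_recovered += 1
                matched_pairs.append((dg, pg))
                matched_edges |= hits

    ann = network.annotations
    n_group_edges = sum(
        1
        for e in network.edges
        if ann[e.a].group == group or ann[e.b].group == group
    )
    return OverlapReport(
        n_literature=len(records),
        n_potential=n_potential,
        n_recovered=n_recovered,
        n_network_edges_matched=len(matched_edges),
        n_group_network_edges=n_group_edges,
        matched_pairs=matched_pairs,
    )


def genus_disparity(
    records: Sequence[LiteratureRecord],
    network: InteractionNetwork,
    group: str,
    synonyms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Literature vs network interaction counts per diatom genus.

    The genus universe is the union of both sources; a genus is flagged
    ``absent_from_literature`` when it has network edges but no
    literature record.
    """
    focal_genus, _ = _genus_maps(network, group, synonyms)

    lit_counts: dict[str, int] = {}
    for rec in records:
        dg = normalize_genus(rec.diatom_genus, synonyms).lower()
        if dg:
            lit_counts[dg] = lit_counts.get(dg, 0) + 1

    net_counts: dict[str, int] = {}
    for e in network.edges:
        touched = {
            g for g in (focal_genus.get(e.a), focal_genus.get(e.b)) if g
        }
        for g in touched:  # intra-genus edge counts once
            net_counts[g] = net_counts.get(g, 0) + 1

    rows = []
    for genus in sorted(lit_counts.keys() | net_counts.keys()):
        n_lit = lit_counts.get(genus, 0)
        n_net = net_counts.get(genus, 0)
        rows.append(
            {
                "genus": genus,
                "n_literature": n_lit,
                "n_network_edges": n_net,
                "absent_from_literature": n_lit == 0 and n_net > 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["genus", "n_literature", "n_network_edges", "absent_from_literature"],
    )
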
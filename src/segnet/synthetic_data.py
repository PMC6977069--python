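"""Seeded generators for annotated networks, abundance tables, and
literature records with exactly known ground truth.

A single integer seed governs every draw: the seed is split with
``numpy.random.SeedSequence.spawn`` into three independent child
streams, consumed in a fixed documented order — child 0 for the
network, child 1 for the abundance table, child 2 for the literature
records — so the three generators compose reproducibly whether or not
they are all invoked.
"""

from __future__ import annotations

import hashlib
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .literature_db import DEFAULT_LABEL_MAP, LiteratureRecord
from .network_model import (
    DRIVER_ABIOTIC,
    DRIVER_BIOTIC,
    AbundanceTable,
    AnnotatedEdge,
    InteractionNetwork,
    TaxonAnnotation,
)

import pandas as pd

__all__ = [
    "GroupSpec",
    "PairParams",
    "ScoreModel",
    "LitdbOverlap",
    "GeneratorSpec",
    "GroundTruth",
    "generate_network",
    "generate_abundance",
    "generate_litdb",
    "write_litdb",
]

# scores are bounded away from 0 so the sign/score invariant holds
_SCORE_EPS = 1e-6


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_barcodes: int
    genus_pool: tuple[str, ...] = ()
    trophic_mode: str = "unknown"


@dataclass(frozen=True)
class PairParams:
    n_edges: int
    exclusion_probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.exclusion_probability <= 1.0:
            raise ValueError("exclusion_probability must lie in [0, 1]")
        if self.n_edges < 0:
            raise ValueError("n_edges must be non-negative")


@dataclass(frozen=True)
class ScoreModel:
    """Truncated-normal score distributions, one per sign.

    Copresence scores live on (0, 1], exclusion scores on [-1, 0).
    """

    mu_copresence: float = 0.55
    sigma_copresence: float = 0.15
    mu_exclusion: float = -0.60
    sigma_exclusion: float = 0.12


@dataclass(frozen=True)
class LitdbOverlap:
    """Planted literature-overlap counts (all exact by construction)."""

    n_records: int
    n_potential: int
    n_recovered: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_recovered <= self.n_potential <= self.n_records:
            raise ValueError(
                "need 0 <= n_recovered <= n_potential <= n_records"
            )

    @classmethod
    def from_fractions(
        cls, n_records: int, fraction_potential: float, fraction_recovered: float
    ) -> "LitdbOverlap":
        """Build from fractions: potential of records, recovered of potential."""
        n_pot = round(n_records * fraction_potential)
        return cls(n_records, n_pot, round(n_pot * fraction_recovered))


@dataclass
class GeneratorSpec:
    """Full parameterization of one synthetic data set."""

    groups: list[GroupSpec]
    pair_params: dict[tuple[str, str], PairParams]
    score_model: ScoreModel = field(default_factory=ScoreModel)
    abiotic_fraction: float = 0.0
    abiotic_parameters: tuple[str, ...] = ("PO4", "NO3", "MLD", "Temperature")
    n_stations: int = 10
    endemic_barcodes: list[tuple[str, str, int]] = field(default_factory=list)
    # (barcode_id, station_id, read mass)
    litdb_overlap: LitdbOverlap | None = None
    focal_group: str | None = None  # defaults to the first group
    size_fraction: str = "20-180"
    depth_layer: str = "SRF"
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        if not 0.0 <= self.abiotic_fraction <= 1.0:
            raise ValueError("abiotic_fraction must lie in [0, 1]")
        if self.abiotic_fraction > 0 and not self.abiotic_parameters:
            raise ValueError("abiotic_parameters pool is empty")
        if self.focal_group is None:
            self.focal_group = self.groups[0].label if self.groups else None
        known = set(labels)
        for a, b in self.pair_params:
            if a not in known or b not in known:
                raise ValueError(f"pair ({a!r}, {b!r}) references unknown group")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorSpec":
        """Build from a plain (YAML-friendly) mapping."""
        groups = [
            GroupSpec(
                label=g["label"],
                n_barcodes=int(g["n_barcodes"]),
                genus_pool=tuple(g.get("genus_pool", ())),
                trophic_mode=g.get("trophic_mode", "unknown"),
            )
            for g in d["groups"]
        ]
        pair_params = {}
        for p in d["pair_params"]:
            pair_params[(p["group_a"], p["group_b"])] = PairParams(
                n_edges=int(p["n_edges"]),
                exclusion_probability=float(p["exclusion_probability"]),
            )
        sm = d.get("score_model", {})
        lo = d.get("litdb_overlap")
        return cls(
            groups=groups,
            pair_params=pair_params,
            score_model=ScoreModel(**sm),
            abiotic_fraction=float(d.get("abiotic_fraction", 0.0)),
            abiotic_parameters=tuple(
                d.get("abiotic_parameters", ("PO4", "NO3", "MLD", "Temperature"))
            ),
            n_stations=int(d.get("n_stations", 10)),
            endemic_barcodes=[
                (e["barcode"], e["station"], int(e["reads"]))
                for e in d.get("endemic_barcodes", [])
            ],
            litdb_overlap=LitdbOverlap(**lo) if lo else None,
            focal_group=d.get("focal_group"),
            size_fraction=d.get("size_fraction", "20-180"),
            depth_layer=d.get("depth_layer", "SRF"),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class GroundTruth:
    """Planted quantities, consistent with the emitted data by construction."""

    pair_exclusion_probability: dict[tuple[str, str], float]
    expected_group_pn: dict[str, float]
    observed_pair_exclusions: dict[tuple[str, str], int]
    endemic_barcodes: list[tuple[str, str, int]]
    litdb_overlap: LitdbOverlap | None

    def to_jsonable(self) -> dict:
        return {
            "pair_exclusion_probability": {
                f"{a}|{b}": p
                for (a, b), p in self.pair_exclusion_probability.items()
            },
            "expected_group_pn": dict(self.expected_group_pn),
            "observed_pair_exclusions": {
                f"{a}|{b}": k for (a, b), k in self.observed_pair_exclusions.items()
            },
            "endemic_barcodes": [list(e) for e in self.endemic_barcodes],
            "litdb_overlap": (
                None
                if self.litdb_overlap is None
                else {
                    "n_records": self.litdb_overlap.n_records,
                    "n_potential": self.litdb_overlap.n_potential,
                    "n_recovered": self.litdb_overlap.n_recovered,
                }
            ),
        }


def _streams(spec: GeneratorSpec) -> list[np.random.Generator]:
    children = np.random.SeedSequence(spec.seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def _barcode_ids(group: GroupSpec) -> list[str]:
    """Deterministic md5-style opaque identifiers."""
    ids = []
    for i in range(group.n_barcodes):
        ids.append(hashlib.md5(f"{group.label}:{i}".encode()).hexdigest()[:8])
    if len(set(ids)) != len(ids):  # vanishingly unlikely; fail loudly
        raise RuntimeError(f"barcode id collision in group {group.label!r}")
    return ids


def _annotations(spec: GeneratorSpec) -> dict[str, TaxonAnnotation]:
    annotations: dict[str, TaxonAnnotation] = {}
    for group in spec.groups:
        pool = group.genus_pool
        for i, bid in enumerate(_barcode_ids(group)):
            genus = pool[i % len(pool)] if pool else ""
            lineage = ("Eukaryota", group.label) + ((genus,) if genus else ())
            annotations[bid] = TaxonAnnotation(
                barcode_id=bid,
                lineage=lineage,
                group=group.label,
                genus=genus,
                trophic_mode=group.trophic_mode,
            )
    return annotations


def _sample_pairs(
    rng: np.random.Generator, ids_a: list[str], ids_b: list[str], n: int
) -> list[tuple[str, str]]:
    """Draw n distinct unordered cross/intra pairs without replacement."""
    if ids_a is ids_b:
        na = len(ids_a)
        total = na * (na - 1) // 2
        if n > total:
            raise ValueError(f"requested {n} edges but only {total} pairs exist")
        iu, ju = np.triu_indices(na, k=1)
        chosen = rng.choice(total, size=n, replace=False)
        return [(ids_a[iu[c]], ids_a[ju[c]]) for c in chosen]
    total = len(ids_a) * len(ids_b)
    if n > total:
        raise ValueError(f"requested {n} edges but only {total} pairs exist")
    chosen = rng.choice(total, size=n, replace=False)
    nb = len(ids_b)
    return [(ids_a[c // nb], ids_b[c % nb]) for c in chosen]


def _truncnorm(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, n: int
) -> np.ndarray:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def generate_network(spec: GeneratorSpec) -> tuple[InteractionNetwork, GroundTruth]:
    """Generate a group-structured network with planted sign structure.

    For each configured group pair, ``n_edges`` distinct barcode pairs
    are drawn without replacement; each edge is an exclusion with the
    pair's planted probability, its score drawn from the sign-matched
    truncated normal, and its driver abiotic with probability
    ``abiotic_fraction``.
    """
    rng = _streams(spec)[0]
    annotations = _annotations(spec)
    by_group = {
        g.label: [
            bid for bid, a in annotations.items() if a.group == g.label
        ]
        for g in spec.groups
    }
    sm = spec.score_model

    edges: list[AnnotatedEdge] = []
    observed_excl: dict[tuple[str, str], int] = {}
    for (ga, gb), params in spec.pair_params.items():
        ids_a, ids_b = by_group[ga], by_group[gb]
        pairs = _sample_pairs(
            rng, ids_a, ids_a if ga == gb else ids_b, params.n_edges
        )
        n = len(pairs)
        is_excl = rng.random(n) < params.exclusion_probability
        n_ex = int(is_excl.sum())
        ex_scores = _truncnorm(
            rng, sm.mu_exclusion, sm.sigma_exclusion, -1.0, -_SCORE_EPS, n_ex
        )
        co_scores = _truncnorm(
            rng, sm.mu_copresence, sm.sigma_copresence, _SCORE_EPS, 1.0, n - n_ex
        )
        is_abiotic = rng.random(n) < spec.abiotic_fraction
        params_drawn = (
            rng.choice(spec.abiotic_parameters, size=n)
            if spec.abiotic_fraction > 0
            else np.full(n, "", dtype=object)
        )
        i_ex = i_co = 0
        for j, (a, b) in enumerate(pairs):
            if is_excl[j]:
                score = float(ex_scores[i_ex])
                i_ex += 1
            else:
                score = float(co_scores[i_co])
                i_co += 1
            edges.append(
                AnnotatedEdge(
                    a=a,
                    b=b,
                    score=score,
                    size_fraction=spec.size_fraction,
                    depth_layer=spec.depth_layer,
                    driver=DRIVER_ABIOTIC if is_abiotic[j] else DRIVER_BIOTIC,
                    driver_parameter=str(params_drawn[j]) if is_abiotic[j] else None,
                )
            )
        observed_excl[(ga, gb)] = n_ex

    expected_pn: dict[str, float] = {}
    for g in spec.groups:
        exp_co = exp_ex = 0.0
        for (ga, gb), params in spec.pair_params.items():
            if g.label in (ga, gb):
                exp_ex += params.n_edges * params.exclusion_probability
                exp_co += params.n_edges * (1.0 - params.exclusion_probability)
        expected_pn[g.label] = exp_co / exp_ex if exp_ex > 0 else math.inf

    truth = GroundTruth(
        pair_exclusion_probability={
            pair: p.exclusion_probability for pair, p in spec.pair_params.items()
        },
        expected_group_pn=expected_pn,
        observed_pair_exclusions=observed_excl,
        endemic_barcodes=list(spec.endemic_barcodes),
        litdb_overlap=spec.litdb_overlap,
    )
    return InteractionNetwork(annotations=annotations, edges=edges), truth


def generate_abundance(
    spec: GeneratorSpec, network: InteractionNetwork
) -> AbundanceTable:
    """Generate a barcode x station read table.

    Background barcodes receive a log-uniform total read mass spread
    over stations with Dirichlet weights; planted endemic barcodes
    receive their entire mass at the designated station.
    """
    rng = _streams(spec)[1]
    stations = [f"ST{i + 1:03d}" for i in range(spec.n_stations)]
    endemic = {bid: (st, mass) for bid, st, mass in spec.endemic_barcodes}
    barcodes = sorted(network.annotations)
    data = np.zeros((len(barcodes), len(stations)), dtype=np.int64)
    for i, bid in enumerate(barcodes):
        if bid in endemic:
            st, mass = endemic[bid]
            if st not in stations:
                raise ValueError(f"endemic station {st!r} outside station set")
            data[i, stations.index(st)] = mass
            continue
        mass = 10.0 ** rng.uniform(2.0, 5.0)
        shares = rng.dirichlet(np.ones(len(stations)))
        data[i] = np.maximum(np.round(mass * shares), 1).astype(np.int64)
    return AbundanceTable(
        reads=pd.DataFrame(data, index=barcodes, columns=stations)
    )


_RAW_LABEL_CYCLE = tuple(
    sorted(k for k in DEFAULT_LABEL_MAP if k not in DEFAULT_LABEL_MAP.values())
)


def generate_litdb(
    spec: GeneratorSpec, network: InteractionNetwork
) -> list[LiteratureRecord]:
    """Emit literature records with an exactly planted network overlap.

    Of ``n_records`` records, exactly ``n_recovered`` use genus pairs
    joined by at least one network edge, ``n_potential - n_recovered``
    use genus pairs present on both sides but joined by no edge, and the
    remainder use partner genera absent from the network.  Raises when
    the requested counts are infeasible for the given network.
    """
    if spec.litdb_overlap is None:
        raise ValueError("spec.litdb_overlap is not set")
    overlap = spec.litdb_overlap
    rng = _streams(spec)[2]
    focal = spec.focal_group
    ann = network.annotations

    focal_genus = {
        bid: a.genus.lower() for bid, a in ann.items() if a.group == focal and a.genus
    }
    any_genus = {bid: a.genus.lower() for bid, a in ann.items() if a.genus}
    display = {a.genus.lower(): a.genus for a in ann.values() if a.genus}

    edged: set[tuple[str, str]] = set()
    for e in network.edges:
        for x, y in ((e.a, e.b), (e.b, e.a)):
            gx, gy = focal_genus.get(x), any_genus.get(y)
            if gx and gy and gx != gy:
                edged.add((gx, gy))

    focal_set = sorted(set(focal_genus.values()))
    any_set = sorted(set(any_genus.values()))
    unedged = [
        (dg, pg)
        for dg in focal_set
        for pg in any_set
        if dg != pg and (dg, pg) not in edged
    ]
    edged_sorted = sorted(edged)

    n_missing = overlap.n_records - overlap.n_potential
    n_silent = overlap.n_potential - overlap.n_recovered
    if overlap.n_recovered > len(edged_sorted):
        raise ValueError(
            f"requested {overlap.n_recovered} recovered records but the "
            f"network supports only {len(edged_sorted)} edged genus pairs"
        )
    if n_silent > len(unedged):
        raise ValueError(
            f"requested {n_silent} potential-but-unrecovered records but the "
            f"network supports only {len(unedged)} unedged genus pairs"
        )
    if not focal_set and overlap.n_records > 0:
        raise ValueError("focal group has no genus annotations")

    chosen_rec = [
        edged_sorted[i]
        for i in rng.choice(len(edged_sorted), size=overlap.n_recovered, replace=False)
    ]
    chosen_silent = [
        unedged[i] for i in rng.choice(len(unedged), size=n_silent, replace=False)
    ]
    chosen_missing = [
        (focal_set[int(rng.integers(len(focal_set)))], f"absentgenus{i}")
        for i in range(n_missing)
    ]

    pairs = chosen_rec + chosen_silent + chosen_missing
    records = []
    for i, (dg, pg) in enumerate(pairs):
        raw = _RAW_LABEL_CYCLE[i % len(_RAW_LABEL_CYCLE)]
        records.append(
            LiteratureRecord(
                interaction_type=DEFAULT_LABEL_MAP[raw],
                raw_label=raw,
                diatom_genus=display.get(dg, dg),
                partner_class="Synthetic",
                partner_genus=display.get(pg, pg),
                habitat="marine",
                source_ref="generated",
            )
        )
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def write_litdb(records: Sequence[LiteratureRecord], path: str) -> None:
    """Write records as the CSV layout accepted by ``read_litdb``."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            [
                "interaction_raw_label",
                "diatom_genus",
                "diatom_species",
                "partner_class",
                "partner_genus",
                "partner_species",
                "habitat",
                "source_ref",
            ]
        )
        for r in records:
            w.writerow(
                [
                    r.raw_label,
                    r.diatom_genus,
                    r.diatom_species,
                    r.partner_class,
                    r.partner_genus,
                    r.partner_species,
                    r.habitat,
                    r.source_ref,
                ]
            )
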
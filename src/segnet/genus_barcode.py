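"""Genus- and barcode-level profiling.

Connectivity-vs-abundance tables, rank correlation with exact small-n
permutation p-values, per-barcode partner profiles, top-excluder
ranking, and station distributions with an endemicity index (the
maximum station share of a barcode's own reads; 1 = fully endemic).

Genus labels come from the annotation's genus field only — lineage
strings are never re-parsed here — after applying a configurable
synonym map (e.g. Proboscia -> Rhizosolenia) to both sides of any
comparison.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network_model import (
    SIGN_COPRESENCE,
    AbundanceTable,
    InteractionNetwork,
)

__all__ = [
    "GenusConnectivity",
    "BarcodeProfile",
    "DEFAULT_SYNONYMS",
    "normalize_genus",
    "genus_connectivity",
    "rank_correlation",
    "barcode_profile",
    "top_excluders",
    "station_distribution",
]

#: Starter homotypic-synonym map applied before genus aggregation.
DEFAULT_SYNONYMS: dict[str, str] = {"proboscia": "Rhizosolenia"}


def normalize_genus(genus: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Case-normalize a genus and resolve it through a synonym map."""
    if synonyms is None:
        synonyms = {}
    g = genus.strip()
    canon = synonyms.get(g.lower())
    return canon if canon is not None else g


@dataclass(frozen=True)
class GenusConnectivity:
    genus: str
    total_reads: int
    n_edges: int
    n_partner_nodes: int
    n_copresence: int
    n_exclusion: int


@dataclass(frozen=True)
class BarcodeProfile:
    """Sign-split per-partner-group counts for one barcode's edges."""

    barcode_id: str
    partners: dict[str, tuple[int, int]] = field(default_factory=dict)
    # partners: partner group -> (n_copresence, n_exclusion)

    @property
    def total_copresences(self) -> int:
        return sum(c for c, _ in self.partners.values())

    @property
    def total_exclusions(self) -> int:
        return sum(x for _, x in self.partners.values())


def genus_connectivity(
    network: InteractionNetwork,
    abundance: AbundanceTable,
    group: str,
    synonyms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-genus read totals and edge counts for one group's barcodes.

    An edge counts toward a genus iff at least one endpoint is a barcode
    of that genus within the group; an intra-genus edge record counts
    once.  Edges joining two different genera of the group are counted
    by both genera, so the column sum can exceed the group total.
    ``n_partner_nodes`` is the number of distinct non-genus endpoints of
    the counted edges.
    """
    ann = network.annotations
    group_barcodes = {
        bid: normalize_genus(a.genus, synonyms)
        for bid, a in ann.items()
        if a.group == group
    }
    if not group_barcodes:
        raise KeyError(f"group {group!r} has no annotated barcodes")
    genera = sorted({g for g in group_barcodes.values() if g})
    if not genera:
        raise ValueError(f"group {group!r} has no genus annotations")

    rows = []
    for genus in genera:
        members = {b for b, g in group_barcodes.items() if g == genus}
        n_co = n_ex = 0
        partners: set[str] = set()
        for e in network.edges:
            a_in, b_in = e.a in members, e.b in members
            if not (a_in or b_in):
                continue
            if e.sign == SIGN_COPRESENCE:
                n_co += 1
            else:
                n_ex += 1
            if not a_in:
                partners.add(e.a)
            if not b_in:
                partners.add(e.b)
        reads = int(
            sum(
                int(abundance.reads.loc[b].sum())
                for b in members
                if b in abundance.reads.index
            )
        )
        rows.append(
            {
                "genus": genus,
                "total_reads": reads,
                "n_edges": n_co + n_ex,
                "n_partner_nodes": len(partners),
                "n_copresence": n_co,
                "n_exclusion": n_ex,
            }
        )
    return pd.DataFrame(rows).sort_values("genus").reset_index(drop=True)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    return float((rxc * ryc).sum() / denom)


def rank_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use the average-rank convention for ties.  For n <= 8 the
    p-value is exact, from full enumeration of all n! orderings of one
    sample; above that a Student-t approximation is used.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("rank correlation requires n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rho = _spearman_rho(rx, ry)

    if n <= 8:
        target = abs(rho) - 1e-12
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_spearman_rho(rx, ry[list(perm)])) >= target:
                hits += 1
        return rho, hits / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, float(2.0 * stats.t.sf(abs(t), n - 2))


def barcode_profile(network: InteractionNetwork, barcode_id: str) -> BarcodeProfile:
    """Sign-split counts of one barcode's edges, keyed by partner group."""
    if barcode_id not in network.annotations:
        raise KeyError(f"unknown barcode {barcode_id!r}")
    ann = network.annotations
    partners: dict[str, list[int]] = {}
    for e in network.edges:
        if e.a == barcode_id:
            other = e.b
        elif e.b == barcode_id:
            other = e.a
        else:
            continue
        row = partners.setdefault(ann[other].group, [0, 0])
        row[0 if e.sign == SIGN_COPRESENCE else 1] += 1
    return BarcodeProfile(
        barcode_id=barcode_id,
        partners={g: (c, x) for g, (c, x) in partners.items()},
    )


def top_excluders(
    network: InteractionNetwork, group: str, n: int | None = None
) -> list[tuple[str, int]]:
    """Rank a group's barcodes by exclusion count, descending.

    Ties break lexicographically by barcode_id.  Barcodes without
    exclusions are dropped; ``n=None`` returns the full ranking.
    """
    if group not in network.groups():
        raise KeyError(f"group {group!r} not present in network annotations")
    ann = network.annotations
    counts: dict[str, int] = {}
    for e in network.edges:
        if e.sign == SIGN_COPRESENCE:
            continue
        for bid in (e.a, e.b):
            if ann[bid].group == group:
                counts[bid] = counts.get(bid, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if n is None else ranked[:n]


def station_distribution(
    abundance: AbundanceTable, barcode_id: str
) -> tuple[pd.DataFrame, float]:
    """Per-station relative abundance of a barcode, plus endemicity.

    Relative abundance is the barcode's reads divided by the station's
    total reads; the endemicity index is the maximum station share of
    the barcode's OWN reads (1 when all reads sit in one station, 1/k
    when spread uniformly over k stations, NaN for a read-free barcode).
    """
    reads = abundance.barcode_reads(barcode_id).astype(float)
    station_totals = abundance.station_totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = (reads / station_totals).fillna(0.0)
    table = pd.DataFrame(
        {"station": rel.index, "relative_abundance": rel.to_numpy()}
    )
    own_total = float(reads.sum())
    endemicity = float(reads.max() / own_total) if own_total > 0 else math.nan
    return table, endemicity
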
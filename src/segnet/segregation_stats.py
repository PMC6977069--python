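"""Group-level association tallies, segregator classification, partner
breakdowns, binomial exclusion-enrichment tests, and driver partitioning.

An edge counts toward a group iff at least one endpoint belongs to the
group; an intra-group edge counts once.  A group whose
positive-to-negative (P:N) ratio falls below 1 — more exclusions than
copresences — is classified as a *segregator*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network_model import (
    DRIVER_ABIOTIC,
    SIGN_COPRESENCE,
    AnnotatedEdge,
    InteractionNetwork,
)
from ._util import round_percent

__all__ = [
    "GroupAssociationSummary",
    "EnrichmentResult",
    "DriverPartition",
    "summarize_group",
    "pn_ratio",
    "partner_breakdown",
    "binomial_upper_tail",
    "binomial_exclusion_enrichment",
    "benjamini_hochberg",
    "partition_drivers",
]


@dataclass(frozen=True)
class GroupAssociationSummary:
    """Sign tallies and network shares for one taxonomic group."""

    group: str
    n_copresence: int
    n_exclusion: int
    share_of_network_copresences: float
    share_of_network_exclusions: float

    @property
    def n_total(self) -> int:
        return self.n_copresence + self.n_exclusion

    @property
    def pn_ratio(self) -> float:
        """Copresence:exclusion ratio; inf when exclusions are absent,
        NaN when the group has no associations at all."""
        if self.n_exclusion > 0:
            return self.n_copresence / self.n_exclusion
        return math.inf if self.n_copresence > 0 else math.nan

    @property
    def is_segregator(self) -> bool:
        r = self.pn_ratio
        return (not math.isnan(r)) and r < 1.0


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail binomial test of exclusion excess toward one partner."""

    focal_group: str
    partner_group: str
    k: int
    n: int
    p0: float
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class DriverPartition:
    """Biotic vs abiotic driver counts for one group's associations."""

    group: str
    n_biotic: int
    n_abiotic: int
    per_parameter: dict[str, int]

    @property
    def n_total(self) -> int:
        return self.n_biotic + self.n_abiotic

    @property
    def pct_abiotic(self) -> float:
        """Abiotic percentage under the display rounding convention."""
        if self.n_total == 0:
            return math.nan
        return round_percent(self.n_abiotic / self.n_total)

    @property
    def pct_biotic(self) -> float:
        """Complement of pct_abiotic so the pair always sums to 100."""
        if self.n_total == 0:
            return math.nan
        return 100.0 - self.pct_abiotic


def _require_group(network: InteractionNetwork, group: str) -> None:
    if group not in network.groups():
        raise KeyError(f"group {group!r} not present in network annotations")


def _group_edges(network: InteractionNetwork, group: str) -> list[AnnotatedEdge]:
    """Edge records with >=1 endpoint in the group (intra-group once)."""
    ann = network.annotations
    return [
        e
        for e in network.edges
        if ann[e.a].group == group or ann[e.b].group == group
    ]


def summarize_group(network: InteractionNetwork, group: str) -> GroupAssociationSummary:
    """Tally the group's copresences/exclusions and its network shares.

    Shares are the group's per-sign counts divided by the network-wide
    count of that sign, where every edge record is counted exactly once
    in the denominator.  NaN shares indicate an empty denominator.
    """
    _require_group(network, group)
    total_co = sum(1 for e in network.edges if e.sign == SIGN_COPRESENCE)
    total_ex = network.n_edges - total_co
    gedges = _group_edges(network, group)
    n_co = sum(1 for e in gedges if e.sign == SIGN_COPRESENCE)
    n_ex = len(gedges) - n_co
    return GroupAssociationSummary(
        group=group,
        n_copresence=n_co,
        n_exclusion=n_ex,
        share_of_network_copresences=n_co / total_co if total_co else math.nan,
        share_of_network_exclusions=n_ex / total_ex if total_ex else math.nan,
    )


def pn_ratio(summary: GroupAssociationSummary) -> float:
    """Positive-to-negative association ratio of a group summary."""
    return summary.pn_ratio


def partner_breakdown(
    network: InteractionNetwork,
    group: str,
    partner_grouping: str = "group",
) -> pd.DataFrame:
    """Break a group's associations down by partner label.

    Inter-group edges are attributed to the partner label of the OTHER
    endpoint; intra-group edges are attributed to the group itself
    (``partner_grouping="group"``) or to the second endpoint's trophic
    mode (``partner_grouping="trophic_mode"``).  Percentages are
    unrounded and computed over the group's sign-specific totals, so
    each pct column sums to 100 whenever the group has edges of that
    sign.

    Returns
    -------
    DataFrame with columns ``partner, n_copresence, n_exclusion,
    pct_of_group_copresences, pct_of_group_exclusions``, sorted by
    total count descending.
    """
    if partner_grouping not in ("group", "trophic_mode"):
        raise ValueError(
            f"unknown partner_grouping {partner_grouping!r}; "
            "expected 'group' or 'trophic_mode'"
        )
    _require_group(network, group)
    ann = network.annotations
    counts: dict[str, list[int]] = {}
    for e in _group_edges(network, group):
        in_a = ann[e.a].group == group
        in_b = ann[e.b].group == group
        if in_a and in_b:
            other = ann[e.b]
            label = group if partner_grouping == "group" else other.trophic_mode
        else:
            other = ann[e.b] if in_a else ann[e.a]
            label = other.group if partner_grouping == "group" else other.trophic_mode
        row = counts.setdefault(label, [0, 0])
        row[0 if e.sign == SIGN_COPRESENCE else 1] += 1

    df = pd.DataFrame(
        [
            {"partner": label, "n_copresence": c, "n_exclusion": x}
            for label, (c, x) in counts.items()
        ],
        columns=["partner", "n_copresence", "n_exclusion"],
    )
    tot_co = int(df["n_copresence"].sum()) if len(df) else 0
    tot_ex = int(df["n_exclusion"].sum()) if len(df) else 0
    df["pct_of_group_copresences"] = (
        df["n_copresence"] / tot_co * 100.0 if tot_co else math.nan
    )
    df["pct_of_group_exclusions"] = (
        df["n_exclusion"] / tot_ex * 100.0 if tot_ex else math.nan
    )
    df["n_total"] = df["n_copresence"] + df["n_exclusion"]
    df = df.sort_values(
        ["n_total", "partner"], ascending=[False, True], kind="mergesort"
    ).drop(columns="n_total")
    return df.reset_index(drop=True)


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Bin(n, p0)."""
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, p0))


def binomial_exclusion_enrichment(
    network: InteractionNetwork,
    focal: str,
    partner: str,
    p0_mode: str = "focal_global",
    p0: float | None = None,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Test whether focal<->partner exclusions exceed a null expectation.

    ``k`` is the number of exclusion records between the two groups,
    ``n`` the total records between them, and the p-value is the exact
    upper tail P(X >= k) under X ~ Binomial(n, p0).  Under the default
    ``p0_mode="focal_global"``, p0 is the focal group's overall
    exclusion fraction, so the test asks for partner-specific excess
    over the group's own baseline; ``p0_mode="explicit"`` uses the
    supplied ``p0``.  One-sided, uncorrected (see
    :func:`benjamini_hochberg` for an optional FDR adjustment).
    """
    _require_group(network, focal)
    _require_group(network, partner)
    ann = network.annotations
    pair_edges = [
        e
        for e in network.edges
        if {ann[e.a].group, ann[e.b].group} == {focal, partner}
        or (focal == partner and ann[e.a].group == focal and ann[e.b].group == focal)
    ]
    n = len(pair_edges)
    if n == 0:
        raise ValueError(f"no associations between {focal!r} and {partner!r}")
    k = sum(1 for e in pair_edges if e.sign != SIGN_COPRESENCE)

    if p0_mode == "focal_global":
        summ = summarize_group(network, focal)
        if summ.n_total == 0:
            raise ValueError(f"focal group {focal!r} has no associations")
        p0_val = summ.n_exclusion / summ.n_total
    elif p0_mode == "explicit":
        if p0 is None:
            raise ValueError("p0 must be supplied when p0_mode='explicit'")
        p0_val = p0
    else:
        raise ValueError(f"unknown p0_mode {p0_mode!r}")
    if not 0 < p0_val < 1:
        raise ValueError(f"null exclusion probability {p0_val} outside (0, 1)")

    return EnrichmentResult(
        focal_group=focal,
        partner_group=partner,
        k=k,
        n=n,
        p0=p0_val,
        p_value=binomial_upper_tail(k, n, p0_val),
        alpha=alpha,
    )


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out.tolist()


def partition_drivers(network: InteractionNetwork, group: str) -> DriverPartition:
    """Split a group's associations into biotic vs abiotic drivers.

    Abiotic edges are those annotated upstream as best explained by a
    third environmental parameter; their parameter names are tallied in
    ``per_parameter``.
    """
    _require_group(network, group)
    n_biotic = 0
    per_parameter: dict[str, int] = {}
    for e in _group_edges(network, group):
        if e.driver == DRIVER_ABIOTIC:
            per_parameter[e.driver_parameter] = (
                per_parameter.get(e.driver_parameter, 0) + 1
            )
        else:
            n_biotic += 1
    return DriverPartition(
        group=group,
        n_biotic=n_biotic,
        n_abiotic=sum(per_parameter.values()),
        per_parameter=per_parameter,
    )
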
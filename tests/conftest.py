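from __future__ import annotations

import sys
from pathlib import Path

import pytest

from segnet.network_model import (
    AnnotatedEdge,
    InteractionNetwork,
    TaxonAnnotation,
)

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles


def make_annotation(bid: str, group: str = "unassigned", **kw) -> TaxonAnnotation:
    return TaxonAnnotation(barcode_id=bid, group=group, **kw)


def make_network(edge_specs, groups: dict[str, str], **ann_kw) -> InteractionNetwork:
    """Build a network from (a, b, score[, extra-dict]) tuples and a
    barcode -> group map."""
    edges = []
    for spec in edge_specs:
        a, b, score, *rest = spec
        extra = rest[0] if rest else {}
        edges.append(AnnotatedEdge(a=a, b=b, score=score, **extra))
    annotations = {
        bid: TaxonAnnotation(
            barcode_id=bid, group=grp, **ann_kw.get(bid, {})
        )
        for bid, grp in groups.items()
    }
    return InteractionNetwork(annotations=annotations, edges=edges)


@pytest.fixture
def toy_group_network() -> InteractionNetwork:
    """5 edges touching group G (3 copresence, 2 exclusion) + 1 elsewhere."""
    return make_network(
        [
            ("g1", "x1", 0.5),
            ("g1", "x2", 0.6),
            ("g2", "x1", 0.7),
            ("g1", "x3", -0.4),
            ("g2", "x2", -0.6),
            ("x1", "x2", 0.3),
        ],
        {"g1": "G", "g2": "G", "x1": "X", "x2": "X", "x3": "X"},
    )
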
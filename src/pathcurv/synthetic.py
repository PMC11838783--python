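"""Synthetic pathway-scale fixtures with controlled geometric structure.

Real pathway graphs pair a curated interaction network with an external
candidate-edge table carrying 0-1000 confidence scores.  The fixture
generator emulates that pairing at desk scale: it withholds a fraction of a
synthetic graph's edges as "missing" ground truth, plants them in the
candidate table with high scores (>= 800), and pads the table with
distractor non-edges whose scores span the full 0-1000 range so the
minimum-score filter is exercised in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import PathwayGraph, generate_synthetic
from . import manifolds as mf

PLANTED_MIN_SCORE = 800


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    planted_holdout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_holdout <= 0.5:
            raise ValueError("holdout fraction must be in [0, 0.5]")


def make_fixture(spec: FixtureSpec) -> tuple[PathwayGraph, pd.DataFrame, frozenset]:
    """Build (graph, candidate table, withheld true edges).

    The withheld edges are removed from the returned graph and appear in the
    candidate table with scores >= 800; distractor non-edges carry uniform
    scores over 0-1000.  Deterministic under the seed.
    """
    full = generate_synthetic(spec.kind, spec.params, spec.seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31), 37]))
    edges = sorted(full.edges)
    n_hold = int(round(spec.planted_holdout * len(edges)))
    hold_pos = rng.choice(len(edges), size=n_hold, replace=False) if n_hold else []
    withheld = frozenset(edges[i] for i in hold_pos)
    graph = PathwayGraph.from_edges(
        [e for e in edges if e not in withheld], extra_nodes=full.nodes
    )
    rows = []
    for u, v in sorted(withheld):
        rows.append((u, v, int(rng.integers(PLANTED_MIN_SCORE, 1001))))
    nodes = graph.nodes
    n_distract = max(2 * len(withheld), 10)
    seen = set(withheld)
    attempts = 0
    while len(rows) < len(withheld) + n_distract and attempts < 100 * n_distract:
        attempts += 1
        i, j = rng.integers(len(nodes)), rng.integers(len(nodes))
        if i == j:
            continue
        u, v = sorted((nodes[i], nodes[j]))
        if (u, v) in graph.edges or (u, v) in seen:
            continue
        seen.add((u, v))
        rows.append((u, v, int(rng.integers(0, 1001))))
    table = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    return graph, table, withheld


def geometry_suite() -> list[tuple[str, PathwayGraph, str]]:
    """Labeled pathway-scale graphs whose topology favors a known geometry.

    Balanced trees favor hyperbolic components, cycles spherical ones, 2-D
    grids are euclidean-competitive and trees of cycles favor mixtures.
    Labels name the space type a distortion sweep is expected to select.
    """
    return [
        ("balanced_tree", generate_synthetic("balanced_tree", {"branching": 2, "depth": 4}), mf.HYPERBOLIC),
        ("cycle", generate_synthetic("cycle", {"n": 20}), mf.SPHERICAL),
        ("grid", generate_synthetic("grid", {"rows": 5, "cols": 6}), mf.EUCLIDEAN),
        ("tree_of_cycles", generate_synthetic("tree_of_cycles", {"branching": 2, "depth": 2, "cycle_len": 5}), "mixed"),
    ]
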
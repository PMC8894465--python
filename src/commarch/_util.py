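"""Shared helpers: canonical node/edge ordering and seeded RNG streams."""

from __future__ import annotations

import numpy as np


def node_sort_key(n):
    """Stable sort key for possibly mixed-type node labels."""
    return (type(n).__name__, n)


def ordered_nodes(g) -> list:
    return sorted(g.nodes, key=node_sort_key)


def canonical_edge(u, v) -> tuple:
    """Unordered edge as a deterministically ordered tuple."""
    return (u, v) if node_sort_key(u) <= node_sort_key(v) else (v, u)


def ordered_edges(g) -> list:
    """Edges in lexicographic (canonical) order — the tie-break ordering."""
    return sorted((canonical_edge(u, v) for u, v in g.edges), key=lambda e: (node_sort_key(e[0]), node_sort_key(e[1])))


def child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible integer seeds derived from one master seed.

    Drawn sequentially so that a longer stream extends a shorter one
    (prefix property used by best-of-n restart contracts).
    """
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)
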
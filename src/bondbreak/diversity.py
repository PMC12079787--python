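"""Diverse-subset selection of MD snapshots by greedy farthest-point sampling.

Each snapshot is reduced to its sorted vector of pairwise interatomic
distances — cheap, alignment-free, and invariant under rigid motions and atom
relabeling.  Selection is the classic greedy minimax (farthest-point)
heuristic: seed with the first snapshot, then repeatedly add the candidate
whose minimum Euclidean distance to the already-selected set is largest.
This approximates, but does not solve exactly, the max–min dispersion
problem; the greedy semantic is the documented behaviour.
"""
from __future__ import annotations

from typing import List, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .structures import Geometry


def describe(geometry: Geometry) -> np.ndarray:
    """Sorted pairwise-distance descriptor of a geometry (length n(n−1)/2)."""
    if geometry.n_atoms < 2:
        raise ValueError("descriptor requires at least 2 atoms")
    return np.sort(pdist(geometry.coordinates))


def minimax_select(candidates: Sequence[np.ndarray], k: int) -> List[int]:
    """Greedy farthest-point selection of up to ``k`` descriptor indices.

    If there are at most ``k`` candidates, all indices are returned in input
    order.  Otherwise the selection seeds with index 0 and grows greedily;
    ties in the max–min distance break toward the smallest index (argmax on a
    forward scan), so the output is deterministic for a fixed input order.
    """
    n = len(candidates)
    if k < 1:
        if k == 0:
            return []
        raise ValueError("k must be non-negative")
    if n == 0:
        return []
    if n <= k:
        return list(range(n))
    X = np.asarray(candidates, dtype=float)
    chosen = [0]
    # min distance from every candidate to the chosen set
    min_dist = np.linalg.norm(X - X[0], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(min_dist))  # argmax returns first (smallest) index on ties
        chosen.append(nxt)
        d = np.linalg.norm(X - X[nxt], axis=1)
        np.minimum(min_dist, d, out=min_dist)
    return chosen


def select_geometries(geometries: Sequence[Geometry], k: int) -> List[int]:
    """Convenience wrapper: describe then select."""
    return minimax_select([describe(g) for g in geometries], k)
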
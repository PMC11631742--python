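"""Normalized graph adjacency tensors for spatial graph convolution."""

from __future__ import annotations

import numpy as np

from ..skeleton_processing import JointGraph

__all__ = ["build_adjacency", "PARTITION_STRATEGIES"]

PARTITION_STRATEGIES = ("uniform", "distance", "spatial")


def _sym_normalize(m: np.ndarray, deg: np.ndarray) -> np.ndarray:
    """D^(-1/2) M D^(-1/2) with D the full-graph (A + I) degree diagonal.

    Using the global degrees for every partition subset keeps all links of
    a subset present (per-subset degrees would zero out rows that happen
    to be empty in one subset, e.g. the root's inward links).
    """
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return inv_sqrt[:, None] * m * inv_sqrt[None, :]


def build_adjacency(graph: JointGraph, strategy: str = "spatial") -> np.ndarray:
    """Build the ``(K, V, V)`` stack of normalized adjacency matrices.

    Self-loops are included (``A + I`` overall) and each partition subset is
    symmetrically degree-normalized.  Strategies:

    - ``uniform``: one subset holding all edges plus self-loops;
    - ``distance``: self-loops vs. one-hop neighbors (2 subsets);
    - ``spatial``: neighbors split by hop distance to the graph root —
      same distance (incl. self), closer (centripetal), farther
      (centrifugal) — 3 subsets.
    """
    if strategy not in PARTITION_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; use one of {PARTITION_STRATEGIES}")
    v = graph.node_count
    a = graph.adjacency_matrix()
    if v > 1 and not _is_connected(a):
        raise ValueError("graph must be connected")
    eye = np.eye(v)
    if strategy == "uniform":
        subsets = [a + eye]
    elif strategy == "distance":
        subsets = [eye, a]
    else:  # spatial
        hop = graph.hop_distance_to_root()
        full = a + eye
        same = np.zeros((v, v))
        closer = np.zeros((v, v))
        farther = np.zeros((v, v))
        for i in range(v):
            for j in range(v):
                if full[i, j] == 0:
                    continue
                if hop[j] == hop[i]:
                    same[i, j] = 1.0
                elif hop[j] < hop[i]:
                    closer[i, j] = 1.0
                else:
                    farther[i, j] = 1.0
        subsets = [same, closer, farther]
    deg = (a + eye).sum(axis=1)
    return np.stack([_sym_normalize(m, deg) for m in subsets])


def _is_connected(a: np.ndarray) -> bool:
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for w in np.nonzero(a[u])[0]:
            if int(w) not in seen:
                seen.add(int(w))
                stack.append(int(w))
    return len(seen) == a.shape[0]
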
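"""Skeleton gait-sequence ingestion, joint selection, and normalization.

Sequences are ``T x J x 3`` coordinate arrays sampled at 30 fps by default.
Axis semantics: x points to the participant's left, y up, z along the
camera-participant distance (the walking direction in a frontal recording).

The raw capture skeleton has 32 joints; analysis uses a 25-joint subset.
Per frame, all coordinates are divided by the trunk distance — the
Euclidean distance from the sacrum (joint 0) to the shoulder center
(joint 20) — which removes inter-subject height variation and makes every
normalized frame have trunk distance exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RAW32_JOINT_NAMES",
    "SELECTED25_JOINT_NAMES",
    "DEFAULT_RAW32_TO_25",
    "SACRUM",
    "SHOULDER_CENTER",
    "DEFAULT_EDGES",
    "SkeletonSequence",
    "JointGraph",
    "select_joints",
    "trunk_distance",
    "normalize_sequence",
    "joint_velocity",
    "bone_vectors",
    "resample_sequence",
    "read_skeleton_csv",
    "write_skeleton_csv",
    "load_topology",
    "save_topology",
    "DegenerateFrameError",
]

#: 32-joint capture-order names (body-tracking convention).
RAW32_JOINT_NAMES: tuple[str, ...] = (
    "pelvis", "spine_navel", "spine_chest", "neck",
    "clavicle_left", "shoulder_left", "elbow_left", "wrist_left",
    "hand_left", "handtip_left", "thumb_left",
    "clavicle_right", "shoulder_right", "elbow_right", "wrist_right",
    "hand_right", "handtip_right", "thumb_right",
    "hip_left", "knee_left", "ankle_left", "foot_left",
    "hip_right", "knee_right", "ankle_right", "foot_right",
    "head", "nose", "eye_left", "ear_left", "eye_right", "ear_right",
)

#: The 25 analysis joints in index order.
SELECTED25_JOINT_NAMES: tuple[str, ...] = (
    "sacrum",                # 0
    "spine_center",          # 1
    "neck",                  # 2
    "head",                  # 3
    "left_shoulder",         # 4
    "left_elbow",            # 5
    "left_wrist",            # 6
    "left_hand",             # 7  (back of left hand)
    "right_shoulder",        # 8
    "right_elbow",           # 9
    "right_wrist",           # 10
    "right_hand",            # 11 (back of right hand)
    "left_hip",              # 12
    "left_knee",             # 13
    "left_ankle",            # 14
    "left_foot",             # 15
    "right_hip",             # 16
    "right_knee",            # 17
    "right_ankle",           # 18
    "right_foot",            # 19
    "shoulder_center",       # 20
    "left_middle_finger",    # 21
    "left_thumb",            # 22
    "right_middle_finger",   # 23
    "right_thumb",           # 24
)

SACRUM = 0
SHOULDER_CENTER = 20

#: Raw-32 index for each selected joint 0..24.  The seven dropped joints are
#: the nose, both eyes, both ears, and both clavicles.
DEFAULT_RAW32_TO_25: tuple[int, ...] = (
    0, 1, 3, 26, 5, 6, 7, 8, 12, 13, 14, 15,
    18, 19, 20, 21, 22, 23, 24, 25, 2, 9, 10, 16, 17,
)

#: 24-edge anatomical tree over the 25 analysis joints, (parent, child).
DEFAULT_EDGES: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 20), (20, 2), (2, 3),
    (20, 4), (4, 5), (5, 6), (6, 7), (7, 21), (7, 22),
    (20, 8), (8, 9), (9, 10), (10, 11), (11, 23), (11, 24),
    (0, 12), (12, 13), (13, 14), (14, 15),
    (0, 16), (16, 17), (17, 18), (18, 19),
)

DEGENERATE_EPS = 1e-8


class DegenerateFrameError(ValueError):
    """Raised when a frame's trunk distance falls below the epsilon."""

    def __init__(self, frame_indices: Sequence[int], eps: float):
        self.frame_indices = list(frame_indices)
        super().__init__(
            f"trunk distance < {eps} in frames {self.frame_indices[:20]}"
            + ("..." if len(self.frame_indices) > 20 else "")
        )


@dataclass
class SkeletonSequence:
    """A ``T x J x 3`` joint-coordinate time series."""

    coords: np.ndarray
    fps: float = 30.0
    joint_set: str = "raw32"  # "raw32" | "selected25"
    participant_id: str = ""
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be T x J x 3, got {self.coords.shape}")
        expected = {"raw32": 32, "selected25": 25}.get(self.joint_set)
        if expected is not None and self.coords.shape[1] != expected:
            raise ValueError(
                f"joint_set {self.joint_set!r} requires {expected} joints, "
                f"got {self.coords.shape[1]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_joints(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class JointGraph:
    """Skeletal topology: node names plus an undirected spanning tree of edges.

    ``edges`` are (parent, child) pairs; the edge order fixes the bone-vector
    layout downstream.  ``root`` is the tree root used by the spatial
    partitioning strategies (hop distance to root).
    """

    node_names: tuple[str, ...] = SELECTED25_JOINT_NAMES
    edges: tuple[tuple[int, int], ...] = DEFAULT_EDGES
    root: int = SACRUM

    def __post_init__(self) -> None:
        n = self.node_count
        for a, b in self.edges:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a}, {b}) out of range for {n} nodes")
        if len(self.edges) != n - 1 or not self._connected():
            raise ValueError(
                f"edges must form a spanning tree on {n} nodes "
                f"({n - 1} edges, connected); got {len(self.edges)} edges"
            )

    @property
    def node_count(self) -> int:
        return len(self.node_names)

    def _connected(self) -> bool:
        adj = self.adjacency_matrix()
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj[u])[0]:
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        return len(seen) == self.node_count

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.node_count, self.node_count))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def hop_distance_to_root(self) -> np.ndarray:
        """BFS hop count from every node to ``root``."""
        adj = self.adjacency_matrix()
        dist = np.full(self.node_count, -1, dtype=int)
        dist[self.root] = 0
        frontier = [self.root]
        while frontier:
            nxt = []
            for u in frontier:
                for v in np.nonzero(adj[u])[0]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        nxt.append(int(v))
            frontier = nxt
        return dist


# ---------------------------------------------------------------------------
# operations


def select_joints(
    seq: SkeletonSequence,
    index_map: Sequence[int] = DEFAULT_RAW32_TO_25,
) -> SkeletonSequence:
    """Project a raw 32-joint sequence onto the 25 analysis joints.

    Pure index selection: retained coordinates are unchanged; T and fps are
    preserved.  ``index_map[k]`` gives the raw index of selected joint ``k``.
    """
    if seq.n_joints != 32:
        raise ValueError(f"expected 32 joints, got {seq.n_joints}")
    index_map = list(index_map)
    if len(index_map) != 25 or len(set(index_map)) != 25:
        raise ValueError("index_map must contain 25 distinct raw indices")
    return replace(seq, coords=seq.coords[:, index_map, :], joint_set="selected25")


def trunk_distance(frame: np.ndarray, eps: float = DEGENERATE_EPS) -> float:
    """Euclidean distance from joint 0 (sacrum) to joint 20 (shoulder center).

    Raises :class:`DegenerateFrameError` when the distance is below ``eps``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3 or frame.shape[0] <= SHOULDER_CENTER:
        raise ValueError(f"frame must be J x 3 with J > {SHOULDER_CENTER}, got {frame.shape}")
    d = float(np.linalg.norm(frame[SACRUM] - frame[SHOULDER_CENTER]))
    if d < eps:
        raise DegenerateFrameError([0], eps)
    return d


def _trunk_distances(coords: np.ndarray) -> np.ndarray:
    return np.linalg.norm(coords[:, SACRUM] - coords[:, SHOULDER_CENTER], axis=1)


def normalize_sequence(
    seq: SkeletonSequence,
    eps: float = DEGENERATE_EPS,
    drop_degenerate: bool = False,
) -> tuple[SkeletonSequence, np.ndarray]:
    """Divide every coordinate of frame ``t`` by that frame's trunk distance.

    Returns the normalized sequence and the per-frame distances ``d``.
    Degenerate frames (``d < eps``) raise :class:`DegenerateFrameError`
    listing the frame indices, unless ``drop_degenerate`` is set, in which
    case they are removed.
    """
    if seq.joint_set != "selected25":
        raise ValueError("normalize_sequence expects a selected25 sequence")
    d = _trunk_distances(seq.coords)
    bad = np.nonzero(d < eps)[0]
    coords = seq.coords
    if bad.size:
        if not drop_degenerate:
            raise DegenerateFrameError(bad.tolist(), eps)
        keep = d >= eps
        coords, d = coords[keep], d[keep]
    scaled = coords / d[:, None, None]
    return replace(seq, coords=scaled), d


def joint_velocity(seq: SkeletonSequence) -> np.ndarray:
    """Backward-difference velocity, ``T x J x 3``; frame 0 is all zeros.

    Units are coordinate units per frame (fps is not folded in).
    """
    if seq.n_frames < 2:
        raise ValueError(f"need at least 2 frames, got {seq.n_frames}")
    vel = np.zeros_like(seq.coords)
    vel[1:] = seq.coords[1:] - seq.coords[:-1]
    return vel


def bone_vectors(seq: SkeletonSequence, graph: JointGraph | None = None) -> np.ndarray:
    """Per-frame child-minus-parent vector for every edge, ``T x E x 3``."""
    graph = graph or JointGraph()
    for a, b in graph.edges:
        if max(a, b) >= seq.n_joints:
            raise ValueError(f"edge ({a}, {b}) references joint beyond J={seq.n_joints}")
    parents = np.array([e[0] for e in graph.edges])
    children = np.array([e[1] for e in graph.edges])
    return seq.coords[:, children, :] - seq.coords[:, parents, :]


def resample_sequence(seq: SkeletonSequence, target_frames: int) -> SkeletonSequence:
    """Linearly interpolate along time to exactly ``target_frames`` frames.

    Endpoints are preserved; the fps field is rescaled to the effective rate.
    """
    if target_frames < 2:
        raise ValueError(f"target_frames must be >= 2, got {target_frames}")
    t_in = seq.n_frames
    if t_in < 2:
        raise ValueError(f"need at least 2 frames, got {t_in}")
    if target_frames == t_in:
        return replace(seq, coords=seq.coords.copy())
    old = np.arange(t_in, dtype=float)
    new = np.linspace(0.0, t_in - 1, target_frames)
    flat = seq.coords.reshape(t_in, -1)
    out = np.empty((target_frames, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(new, old, flat[:, c])
    fps = seq.fps * (target_frames - 1) / (t_in - 1)
    return replace(seq, coords=out.reshape(target_frames, seq.n_joints, 3), fps=fps)


def multibranch_features(
    seq: SkeletonSequence,
    branches: Sequence[str] = ("position", "velocity", "bone"),
    graph: JointGraph | None = None,
) -> np.ndarray:
    """Stack per-branch features into a ``C x T x J`` array.

    Branches: ``position`` (raw coordinates), ``velocity`` (backward
    differences), ``bone`` (child-minus-parent edge vectors, assigned to
    the child joint; the tree root keeps a zero vector).  Channels are
    concatenated in the order given, 3 per branch.
    """
    graph = graph or JointGraph()
    parts = []
    for branch in branches:
        if branch == "position":
            arr = seq.coords
        elif branch == "velocity":
            arr = joint_velocity(seq)
        elif branch == "bone":
            bones = bone_vectors(seq, graph)
            arr = np.zeros_like(seq.coords)
            for e, (_, child) in enumerate(graph.edges):
                arr[:, child, :] = bones[:, e, :]
        else:
            raise ValueError(f"unknown branch {branch!r}")
        parts.append(np.transpose(arr, (2, 0, 1)))  # -> 3 x T x J
    return np.concatenate(parts, axis=0)


# ---------------------------------------------------------------------------
# file interfaces


def write_skeleton_csv(seq: SkeletonSequence, path: str | Path) -> None:
    """Write one sequence as long-form CSV ``frame,joint,x,y,z`` + JSON sidecar."""
    path = Path(path)
    t, j, _ = seq.coords.shape
    frames = np.repeat(np.arange(t), j)
    joints = np.tile(np.arange(j), t)
    flat = seq.coords.reshape(t * j, 3)
    df = pd.DataFrame(
        {"frame": frames, "joint": joints,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "fps": seq.fps,
        "joint_set": seq.joint_set,
        "participant_id": seq.participant_id,
        "sequence_id": seq.sequence_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_skeleton_csv(path: str | Path) -> SkeletonSequence:
    """Read a long-form skeleton CSV; sidecar metadata is used when present."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"frame", "joint", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"skeleton CSV needs columns {sorted(required)}")
    t = int(df["frame"].max()) + 1
    j = int(df["joint"].max()) + 1
    coords = np.full((t, j, 3), np.nan)
    coords[df["frame"].to_numpy(), df["joint"].to_numpy()] = df[["x", "y", "z"]].to_numpy()
    if np.isnan(coords).any():
        raise ValueError("skeleton CSV has missing (frame, joint) cells")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    joint_set = meta.get("joint_set", {32: "raw32", 25: "selected25"}.get(j, "other"))
    return SkeletonSequence(
        coords=coords,
        fps=float(meta.get("fps", 30.0)),
        joint_set=joint_set,
        participant_id=str(meta.get("participant_id", "")),
        sequence_id=str(meta.get("sequence_id", "")),
    )


def save_topology(path: str | Path, graph: JointGraph | None = None,
                  index_map: Sequence[int] = DEFAULT_RAW32_TO_25) -> None:
    """Write the editable YAML topology (node names, edges, raw->25 map)."""
    graph = graph or JointGraph()
    doc = {
        "node_names": list(graph.node_names),
        "edges": [list(e) for e in graph.edges],
        "root": graph.root,
        "raw32_to_25": list(index_map),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_topology(path: str | Path) -> tuple[JointGraph, list[int]]:
    doc = yaml.safe_load(Path(path).read_text())
    graph = JointGraph(
        node_names=tuple(doc["node_names"]),
        edges=tuple(tuple(e) for e in doc["edges"]),
        root=int(doc.get("root", SACRUM)),
    )
    return graph, list(doc.get("raw32_to_25", DEFAULT_RAW32_TO_25))
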
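"""Skeleton data model: kinematic graph, coordinate sequences, input branches.

Coordinates are stored in **meters** throughout (the convention of depth-camera
skeleton streams); anything user-facing that speaks centimeters converts at the
boundary.

The default graph is the 25-joint Kinect-v2 layout used by the NTU RGB+D
dataset, as an undirected edge list plus a kinematic tree rooted at the
spine-mid joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SkeletonGraph",
    "SkeletonSequence",
    "InputBranches",
    "ntu_graph",
    "compute_branches",
]

# Kinect-v2 joint order as written by NTU RGB+D .skeleton files (0-based).
NTU_JOINT_NAMES = [
    "spine_base",       # 0
    "spine_mid",        # 1  (root of the kinematic tree)
    "neck",             # 2
    "head",             # 3
    "shoulder_left",    # 4
    "elbow_left",       # 5
    "wrist_left",       # 6
    "hand_left",        # 7
    "shoulder_right",   # 8
    "elbow_right",      # 9
    "wrist_right",      # 10
    "hand_right",       # 11
    "hip_left",         # 12
    "knee_left",        # 13
    "ankle_left",       # 14
    "foot_left",        # 15
    "hip_right",        # 16
    "knee_right",       # 17
    "ankle_right",      # 18
    "foot_right",       # 19
    "spine_shoulder",   # 20
    "hand_tip_left",    # 21
    "thumb_left",       # 22
    "hand_tip_right",   # 23
    "thumb_right",      # 24
]

# Standard NTU bone pairs, 0-based.
NTU_EDGES = [
    (0, 1), (1, 20), (2, 20), (3, 2),
    (4, 20), (5, 4), (6, 5), (7, 6),
    (8, 20), (9, 8), (10, 9), (11, 10),
    (12, 0), (13, 12), (14, 13), (15, 14),
    (16, 0), (17, 16), (18, 17), (19, 18),
    (21, 7), (22, 7), (23, 11), (24, 11),
]


@dataclass(frozen=True)
class SkeletonGraph:
    """Undirected skeleton graph with a rooted kinematic tree.

    Parameters
    ----------
    joint_count
        Number of joints V.
    edges
        Undirected bone list as (i, j) index pairs.
    parent
        Kinematic-tree parent per joint; ``parent[root] == root``.
    joint_names
        Length-V joint labels.
    """

    joint_count: int
    edges: tuple[tuple[int, int], ...]
    parent: tuple[int, ...]
    joint_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        V = self.joint_count
        for i, j in self.edges:
            if not (0 <= i < V and 0 <= j < V):
                raise ValueError(f"edge ({i},{j}) out of range for V={V}")
        if len(self.parent) != V:
            raise ValueError("parent map must cover every joint")
        roots = [v for v in range(V) if self.parent[v] == v]
        if len(roots) != 1:
            raise ValueError(f"kinematic tree must have exactly one root, got {roots}")
        # every joint must reach the root by following parents
        root = roots[0]
        for v in range(V):
            seen, cur = set(), v
            while cur != root:
                if cur in seen:
                    raise ValueError(f"parent map has a cycle through joint {v}")
                seen.add(cur)
                cur = self.parent[cur]
        if self.joint_names and len(self.joint_names) != V:
            raise ValueError("joint_names length must equal joint_count")

    @property
    def root(self) -> int:
        return next(v for v in range(self.joint_count) if self.parent[v] == v)

    def neighbors(self, v: int) -> list[int]:
        """Graph neighbors of ``v`` (excluding ``v`` itself)."""
        out = []
        for i, j in self.edges:
            if i == v:
                out.append(j)
            elif j == v:
                out.append(i)
        return sorted(out)

    def adjacency(self, self_loops: bool = True) -> np.ndarray:
        """Dense V×V 0/1 adjacency; with self-loops by default."""
        V = self.joint_count
        A = np.zeros((V, V))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        if self_loops:
            A[np.diag_indices(V)] = 1.0
        return A


def _parents_from_edges(edges, root: int, V: int) -> tuple[int, ...]:
    adj = {v: [] for v in range(V)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    parent = [-1] * V
    parent[root] = root
    stack = [root]
    while stack:
        u = stack.pop()
        for w in adj[u]:
            if parent[w] == -1:
                parent[w] = u
                stack.append(w)
    if any(p == -1 for p in parent):
        raise ValueError("edge list is not connected")
    return tuple(parent)


def ntu_graph() -> SkeletonGraph:
    """The 25-joint Kinect-v2 skeleton graph, rooted at spine-mid."""
    return SkeletonGraph(
        joint_count=25,
        edges=tuple(NTU_EDGES),
        parent=_parents_from_edges(NTU_EDGES, root=1, V=25),
        joint_names=tuple(NTU_JOINT_NAMES),
    )


@dataclass
class SkeletonSequence:
    """A T×V×3 joint-coordinate time series in meters."""

    coords: np.ndarray
    label: int | str | None = None
    instance_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be T×V×3, got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("sequence needs at least one frame")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def frame_count(self) -> int:
        return self.coords.shape[0]

    @property
    def joint_count(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "SkeletonSequence":
        return replace(self, coords=self.coords.copy())


@dataclass
class InputBranches:
    """Joint / velocity / bone input representations of a sequence.

    ``joint`` is root-relative position, ``velocity`` the forward frame
    difference (last frame zero-padded), ``bone`` the parent-relative vector
    (zero at the root). All three share the source T×V×3 shape.
    """

    joint: np.ndarray
    velocity: np.ndarray
    bone: np.ndarray

    def __post_init__(self):
        if not (self.joint.shape == self.velocity.shape == self.bone.shape):
            raise ValueError("branch arrays must share one shape")

    @property
    def names(self) -> tuple[str, str, str]:
        return ("joint", "velocity", "bone")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"joint": self.joint, "velocity": self.velocity, "bone": self.bone}


def compute_branches(seq: SkeletonSequence, graph: SkeletonGraph) -> InputBranches:
    """Derive the joint/velocity/bone branches from raw coordinates.

    joint[t, v]    = coords[t, v] - coords[t, root]
    velocity[t, v] = coords[t+1, v] - coords[t, v], last frame zero
    bone[t, v]     = coords[t, v] - coords[t, parent(v)]

    All three are translation-invariant in the raw coordinates.
    """
    if seq.joint_count != graph.joint_count:
        raise ValueError(
            f"sequence has V={seq.joint_count}, graph has V={graph.joint_count}"
        )
    X = seq.coords
    joint = X - X[:, [graph.root], :]
    velocity = np.zeros_like(X)
    velocity[:-1] = X[1:] - X[:-1]
    bone = X - X[:, list(graph.parent), :]
    return InputBranches(joint=joint, velocity=velocity, bone=bone)
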
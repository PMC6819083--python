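"""Neuron morphometry: Sholl profiles, neurite length, and soma shape.

Trees are standard SWC (7 whitespace-separated columns: id, type, x, y, z,
radius, parent; ``#`` comments; parent -1 marks the root).  Sholl
intersections are counted on concentric spheres centered at the root node:
a parent->child segment crosses the shell at radius ``r`` when its endpoint
distances from the soma straddle ``r``; the boundary rule is half-open
(``min < r <= max``) so a node lying exactly on a shell is counted once,
with its inbound segment, rather than once per incident segment.  A segment
spanning k shells contributes once to each.  Distances are 3D Euclidean by default; ``planar=True`` restricts
to the xy plane for 2D traces.

Soma cross-sections are simple 2D polygons.  Area comes from the shoelace
formula; major/minor axis lengths are the diameters of the ellipse with the
same normalized second central moments as the polygon region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NeuronTree",
    "ShollProfile",
    "SomaContour",
    "read_swc",
    "write_swc",
    "sholl",
    "total_neurite_length",
    "soma_metrics",
]


@dataclass
class NeuronTree:
    """SWC-style rooted tree; the root node is the soma."""

    ids: np.ndarray  # 1-based integer ids
    type_code: np.ndarray
    xyz: np.ndarray  # (n, 3) um
    radius: np.ndarray
    parent_id: np.ndarray  # -1 for root

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.type_code = np.asarray(self.type_code, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent_id = np.asarray(self.parent_id, dtype=int)
        self.validate()

    def __len__(self) -> int:
        return self.ids.size

    def validate(self) -> None:
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite node coordinates")
        if np.unique(self.ids).size != self.ids.size:
            raise ValueError("duplicate node ids")
        roots = self.ids[self.parent_id == -1]
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        known = set(self.ids.tolist())
        index = {i: k for k, i in enumerate(self.ids.tolist())}
        for nid, pid in zip(self.ids, self.parent_id):
            if pid != -1 and pid not in known:
                raise ValueError(f"node {nid} references missing parent {pid}")
        # cycle check by walking each node to the root
        for nid in self.ids:
            seen = set()
            cur = int(nid)
            while cur != -1:
                if cur in seen:
                    raise ValueError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = int(self.parent_id[index[cur]])

    @property
    def root_index(self) -> int:
        return int(np.nonzero(self.parent_id == -1)[0][0])

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.xyz[self.root_index]

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Parent/child coordinate pairs for every non-root node, as two (m,3) arrays."""
        index = {int(i): k for k, i in enumerate(self.ids)}
        child = np.nonzero(self.parent_id != -1)[0]
        parent = np.array([index[int(p)] for p in self.parent_id[child]], dtype=int)
        return self.xyz[parent], self.xyz[child]


def read_swc(path) -> NeuronTree:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"line {lineno}: expected 7 SWC columns, got {len(parts)}")
            rows.append(
                (
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                )
            )
    if not rows:
        raise ValueError(f"empty SWC file: {path}")
    arr = np.array(rows, dtype=float)
    return NeuronTree(
        ids=arr[:, 0].astype(int),
        type_code=arr[:, 1].astype(int),
        xyz=arr[:, 2:5],
        radius=arr[:, 5],
        parent_id=arr[:, 6].astype(int),
    )


def write_swc(tree: NeuronTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(len(tree)):
            fh.write(
                f"{tree.ids[i]} {tree.type_code[i]} "
                f"{tree.xyz[i, 0]:.6g} {tree.xyz[i, 1]:.6g} {tree.xyz[i, 2]:.6g} "
                f"{tree.radius[i]:.6g} {tree.parent_id[i]}\n"
            )


@dataclass
class ShollProfile:
    radii: np.ndarray
    intersections: np.ndarray
    total_length_um: float
    step_um: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"radius_um": self.radii, "intersections": self.intersections}
        )


def _node_distances(tree: NeuronTree, planar: bool) -> tuple[np.ndarray, np.ndarray]:
    p, c = tree.segments()
    soma = tree.soma_xyz
    dims = slice(0, 2) if planar else slice(0, 3)
    dp = np.linalg.norm(p[:, dims] - soma[dims], axis=1)
    dc = np.linalg.norm(c[:, dims] - soma[dims], axis=1)
    return dp, dc


def sholl(tree: NeuronTree, step_um: float = 5.0, planar: bool = False) -> ShollProfile:
    """Intersection counts with concentric shells at ``step_um`` spacing.

    Radii run from ``step_um`` to the smallest multiple of ``step_um`` that
    is >= the maximal node distance (so a trailing shell beyond every node
    reports 0 unless a node sits exactly on it).
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    if len(tree) < 2:
        return ShollProfile(
            radii=np.array([step_um]),
            intersections=np.array([0]),
            total_length_um=0.0,
            step_um=step_um,
        )
    dp, dc = _node_distances(tree, planar)
    max_d = max(dp.max(), dc.max())
    n_shells = max(1, int(np.ceil(max_d / step_um - 1e-12)))
    radii = step_um * np.arange(1, n_shells + 1)
    lo = np.minimum(dp, dc)
    hi = np.maximum(dp, dc)
    counts = np.array(
        [int(np.count_nonzero((lo < r) & (r <= hi))) for r in radii], dtype=int
    )
    return ShollProfile(
        radii=radii,
        intersections=counts,
        total_length_um=total_neurite_length(tree),
        step_um=step_um,
    )


def total_neurite_length(tree: NeuronTree) -> float:
    """Sum of Euclidean parent->child segment lengths (root has no segment)."""
    if len(tree) < 2:
        return 0.0
    p, c = tree.segments()
    return float(np.linalg.norm(p - c, axis=1).sum())


@dataclass
class SomaContour:
    """Ordered 2D polygon vertices in micrometers (closed implicitly)."""

    vertices: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if self.vertices.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments (shared endpoints excluded)."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return np.sign(v)

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return d1 != d2 and d3 != d4 and 0 not in (d1, d2, d3, d4)


def _is_simple(v: np.ndarray) -> bool:
    n = v.shape[0]
    edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True


def soma_metrics(contour: SomaContour) -> dict:
    """Area, equivalent-ellipse axis lengths, and aspect ratio of a contour.

    Axis lengths are the major/minor diameters of the ellipse sharing the
    polygon's normalized second central moments (for an actual ellipse with
    semi-axes a >= b this returns exactly 2a and 2b).
    """
    v = contour.vertices
    if not _is_simple(v):
        raise ValueError("self-intersecting polygon")
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area < 0:  # re-orient counter-clockwise
        return soma_metrics(SomaContour(v[::-1]))
    if area == 0:
        raise ValueError("degenerate (zero-area) polygon")
    cx = ((x + x1) * cross).sum() / (6 * area)
    cy = ((y + y1) * cross).sum() / (6 * area)
    # second moments about the origin of the polygon region
    ixx = ((y**2 + y * y1 + y1**2) * cross).sum() / 12.0  # integral of y^2 dA
    iyy = ((x**2 + x * x1 + x1**2) * cross).sum() / 12.0  # integral of x^2 dA
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    # normalized central second moments = covariance of the uniform region
    var_x = iyy / area - cx**2
    var_y = ixx / area - cy**2
    cov_xy = ixy / area - cx * cy
    cov = np.array([[var_x, cov_xy], [cov_xy, var_y]])
    lam = np.linalg.eigvalsh(cov)  # ascending
    lam = np.clip(lam, 0, None)
    minor = 4.0 * np.sqrt(lam[0])
    major = 4.0 * np.sqrt(lam[1])
    return {
        "area_um2": float(area),
        "major_axis_um": float(major),
        "minor_axis_um": float(minor),
        "aspect_ratio": float(major / minor) if minor > 0 else np.inf,
    }
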
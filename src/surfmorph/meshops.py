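"""Mesh smoothing, rigid alignment, and vertex-wise deviation statistics.

Alignment follows the principal-axes + ICP recipe: candidate rotations from
the principal-axes frames under all proper sign flips, each refined by a
sampled iterative-closest-point loop, keeping the candidate with the lowest
final RMSE.  Deviation mapping measures, for every vertex of a target mesh,
the exact distance to the closest point of a reference surface, signed
positive when the target lies outside the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .mesh import TriangleMesh, write_ply
from .spatial import ClosestPointQuery

__all__ = [
    "RigidTransform",
    "DeviationField",
    "DeviationSummary",
    "rigid_fit",
    "laplacian_smooth",
    "taubin_smooth",
    "principal_axes_align",
    "icp_refine",
    "mesh_signed_distance",
    "deviation_summary",
    "midshaft_max_diameter",
    "export_deviation_mesh",
    "deviation_colors",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=np.float64)
        )
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal to 1e-9")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid motions here (det must be +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def save(self, path) -> None:
        np.savetxt(path, self.as_matrix())

    @classmethod
    def load(cls, path) -> "RigidTransform":
        m = np.loadtxt(path)
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class DeviationField:
    """Per-vertex signed distances (mm) of a target mesh from a reference."""

    distances: np.ndarray
    target: TriangleMesh
    range_mm: float = 2.5
    green_band_mm: float = 0.2

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if len(self.distances) != self.target.n_vertices:
            raise ValueError("one distance per target vertex required")
        if not np.isfinite(self.distances).all():
            raise ValueError("distances must be finite")


@dataclass(frozen=True)
class DeviationSummary:
    """Unsigned deviation statistics; pct_variation = mean / diameter * 100."""

    mean: float
    sd: float
    max: float
    min: float
    pct_variation: float | None = None


def rigid_fit(P: np.ndarray, Q: np.ndarray, weights=None) -> RigidTransform:
    """Least-squares proper rigid motion mapping points P onto Q (Kabsch/SVD)."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if weights is None:
        w = np.full(len(P), 1.0 / len(P))
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    H = (P - cp).T @ ((Q - cq) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


# -- smoothing ---------------------------------------------------------------------


def _laplacian_pass(mesh_faces_adj, vertices: np.ndarray, step: float) -> np.ndarray:
    adj, degree = mesh_faces_adj
    neighbor_mean = adj @ vertices / degree[:, None]
    return vertices + step * (neighbor_mean - vertices)


def _adjacency(mesh: TriangleMesh):
    adj = mesh.vertex_adjacency()
    degree = np.maximum(np.asarray(adj.sum(axis=1)).ravel(), 1.0)
    return adj, degree


def laplacian_smooth(
    mesh: TriangleMesh,
    iterations: float,
    step: float = 1.0,
    preserve_surface: bool = False,
) -> TriangleMesh:
    """Uniform-weight Laplacian smoothing.

    Fractional ``iterations`` in (0, 1) are interpreted as a single pass with
    the step scaled by that fraction (a weaker-than-one-pass smoothing level);
    integer counts are full passes at ``step``.  With ``preserve_surface``,
    vertices are re-projected onto the *original* input surface after every
    pass, bounding the shrink drift.
    """
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    if iterations == 0:
        return mesh.copy()
    if 0 < iterations < 1:
        passes, step = 1, step * float(iterations)
    else:
        passes = int(round(iterations))
    aa = _adjacency(mesh)
    query = ClosestPointQuery(mesh) if preserve_surface else None
    v = mesh.vertices.copy()
    for _ in range(passes):
        v = _laplacian_pass(aa, v, step)
        if query is not None:
            v = query.query(v)[0]
    return mesh.with_vertices(v)


def taubin_smooth(
    mesh: TriangleMesh, iterations: float, lam: float = 0.5, mu: float = -0.53
) -> TriangleMesh:
    """Taubin lambda/mu smoothing (shrink-compensated Laplacian).

    Requires the pass-band condition mu < -lam < 0.  Fractional iteration
    counts scale both factors, mirroring :func:`laplacian_smooth`.
    """
    if lam <= 0 or mu >= -lam:
        raise ValueError("pass-band condition requires 0 < lam and mu < -lam")
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    if iterations == 0:
        return mesh.copy()
    if 0 < iterations < 1:
        passes, scale = 1, float(iterations)
    else:
        passes, scale = int(round(iterations)), 1.0
    aa = _adjacency(mesh)
    v = mesh.vertices.copy()
    for _ in range(passes):
        v = _laplacian_pass(aa, v, lam * scale)
        v = _laplacian_pass(aa, v, mu * scale)
    return mesh.with_vertices(v)


# -- rigid alignment ---------------------------------------------------------------


def _principal_frame(vertices: np.ndarray) -> np.ndarray:
    c = vertices.mean(axis=0)
    cov = np.cov((vertices - c).T)
    evals, evecs = np.linalg.eigh(cov)
    frame = evecs[:, ::-1]  # columns: major, mid, minor axis
    if np.linalg.det(frame) < 0:
        frame[:, 2] *= -1
    return frame


def icp_refine(
    source: TriangleMesh,
    target: TriangleMesh,
    transform0: RigidTransform | None = None,
    n_iter: int = 200,
    n_sample: int = 200,
    seed: int = 0,
    tol: float = 1e-8,
):
    """Sampled point-to-surface ICP from an initial transform.

    Each iteration matches a fixed seeded sample of source vertices to their
    closest points on the target surface and solves the closed-form rigid
    least-squares update.  Returns ``(RigidTransform, rmse)``.
    """
    if transform0 is None:
        transform0 = RigidTransform.identity()
    rng = np.random.default_rng(seed)
    n_sample = min(n_sample, source.n_vertices)
    if n_sample == 0:
        raise ValueError("empty sample")
    idx = rng.choice(source.n_vertices, n_sample, replace=False)
    pts = source.vertices[idx]
    query = ClosestPointQuery(target)
    T = transform0
    prev = np.inf
    rmse = np.inf
    for _ in range(max(n_iter, 1)):
        moved = T.apply(pts)
        closest, dist, _ = query.query(moved, exact=False)
        rmse = float(np.sqrt(np.mean(dist**2)))
        if prev - rmse < tol * max(prev, 1.0):
            break
        prev = rmse
        T = rigid_fit(pts, closest)
    return T, rmse


def principal_axes_align(
    source: TriangleMesh,
    target: TriangleMesh,
    n_icp_iter: int = 200,
    n_sample: int = 200,
    seed: int = 0,
):
    """Align source to target: principal axes, all proper sign flips, ICP.

    The four candidate rotations map the source principal frame onto the
    target frame under every proper combination of axis sign flips (covering
    the 180-degree ambiguities of principal axes); each is refined by
    :func:`icp_refine` and the lowest-RMSE result wins.
    """
    Fs = _principal_frame(source.vertices)
    Ft = _principal_frame(target.vertices)
    cs = source.vertices.mean(axis=0)
    ct = target.vertices.mean(axis=0)
    best = (None, np.inf)
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        R = Ft @ np.diag(signs) @ Fs.T
        T0 = RigidTransform(R, ct - R @ cs)
        T, rmse = icp_refine(source, target, T0, n_icp_iter, n_sample, seed)
        if rmse < best[1]:
            best = (T, rmse)
    return best


# -- deviation mapping -------------------------------------------------------------


def mesh_signed_distance(target: TriangleMesh, reference: TriangleMesh) -> DeviationField:
    """Signed distance of every target vertex from the reference surface.

    Positive where the target vertex lies on the outward-normal side of the
    nearest reference triangle ("target outside reference").
    """
    query = ClosestPointQuery(reference)
    d = query.signed_distance(target.vertices)
    return DeviationField(d, target)


def deviation_summary(
    field: DeviationField, midshaft_diameter: float | None = None
) -> DeviationSummary:
    """Unsigned deviation statistics, optionally normalized by a diameter."""
    d = np.abs(field.distances)
    if len(d) == 0:
        raise ValueError("empty deviation field")
    pct = float(d.mean() / midshaft_diameter * 100.0) if midshaft_diameter else None
    return DeviationSummary(
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        max=float(d.max()),
        min=float(d.min()),
        pct_variation=pct,
    )


def midshaft_max_diameter(mesh: TriangleMesh, axis_fraction: float = 0.5) -> float:
    """Maximum caliper diameter of the cross-section at a fraction of the long axis."""
    c = mesh.vertices.mean(axis=0)
    frame = _principal_frame(mesh.vertices)
    local = (mesh.vertices - c) @ frame  # column 0 = long axis
    zmin, zmax = local[:, 0].min(), local[:, 0].max()
    z0 = zmin + axis_fraction * (zmax - zmin)
    # edge-plane intersections of all mesh edges crossing the section plane
    tri_local = local[mesh.faces]
    pts = []
    for i, j in ((0, 1), (1, 2), (2, 0)):
        a, b = tri_local[:, i], tri_local[:, j]
        da, db = a[:, 0] - z0, b[:, 0] - z0
        cross = da * db < 0
        t = da[cross] / (da[cross] - db[cross])
        pts.append(a[cross, 1:] + t[:, None] * (b[cross, 1:] - a[cross, 1:]))
    section = np.concatenate(pts) if pts else np.empty((0, 2))
    if len(section) < 2:
        raise ValueError("empty cross-section at the requested axis fraction")
    if len(section) > 3:
        try:
            section = section[ConvexHull(section).vertices]
        except Exception:
            pass
    d2 = ((section[:, None, :] - section[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def deviation_colors(
    distances: np.ndarray, range_mm: float = 2.5, green_band_mm: float = 0.2
) -> np.ndarray:
    """RGB (uint8) for a signed deviation map.

    Symmetric diverging scale (violet at -range through red at +range);
    |d| <= green band is flat green ("not relevant"); |d| > range is white.
    """
    import matplotlib

    d = np.asarray(distances, dtype=np.float64)
    t = np.clip((d + range_mm) / (2 * range_mm), 0.0, 1.0)
    rgba = matplotlib.colormaps["rainbow"](t)
    rgb = (rgba[:, :3] * 255).astype(np.uint8)
    rgb[np.abs(d) <= green_band_mm] = (0, 255, 0)
    rgb[np.abs(d) > range_mm] = (255, 255, 255)
    return rgb


def export_deviation_mesh(
    field: DeviationField, path, range_mm: float = 2.5, green_band_mm: float = 0.2
) -> None:
    """Colored PLY of the target mesh with per-vertex signed distances."""
    colors = deviation_colors(field.distances, range_mm, green_band_mm)
    write_ply(field.target, path, scalars=field.distances, colors=colors)
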
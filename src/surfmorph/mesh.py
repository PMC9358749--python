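"""Triangle-mesh container and STL/PLY input/output.

The mesh is the central exchange object of the pipeline: segmentation
produces one, smoothing and rigid alignment act on one, deviation maps are
attached to one.  Coordinates are always in millimetres.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

__all__ = ["TriangleMesh", "uv_sphere", "read_stl", "write_stl", "read_ply", "write_ply"]


@dataclass
class TriangleMesh:
    """Indexed triangle mesh with vertices in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Counter-clockwise when viewed from outside for an outward-oriented
        mesh.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    # -- basic derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        if "triangles" not in self._cache:
            self._cache["triangles"] = self.vertices[self.faces]
        return self._cache["triangles"]

    @property
    def face_normals(self) -> np.ndarray:
        if "face_normals" not in self._cache:
            t = self.triangles
            n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            norm = np.linalg.norm(n, axis=1)
            norm[norm == 0] = 1.0
            self._cache["face_normals"] = n / norm[:, None]
        return self._cache["face_normals"]

    @property
    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        if "vertex_normals" not in self._cache:
            t = self.triangles
            fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # area-weighted
            vn = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(vn, self.faces[:, k], fn)
            norm = np.linalg.norm(vn, axis=1)
            norm[norm == 0] = 1.0
            self._cache["vertex_normals"] = vn / norm[:, None]
        return self._cache["vertex_normals"]

    @property
    def edges_unique(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def vertex_adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 vertex-vertex adjacency."""
        e = self.edges_unique
        n = self.n_vertices
        a = sparse.coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
        )
        a = a + a.T
        a.data[:] = 1.0
        return a.tocsr()

    def is_closed(self) -> bool:
        """Every edge shared by exactly two faces."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique) + self.n_faces

    def volume(self) -> float:
        """Signed enclosed volume by the divergence theorem (mm^3).

        Positive for a closed, outward-oriented mesh.
        """
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # -- editing ------------------------------------------------------------------

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(np.asarray(vertices, dtype=np.float64), self.faces.copy())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        return self.with_vertices(self.vertices @ np.asarray(rotation).T + translation)

    def remove_degenerate_faces(self, area_tol: float = 0.0) -> "TriangleMesh":
        keep = self.face_areas > area_tol
        return TriangleMesh(self.vertices.copy(), self.faces[keep])

    def flipped(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces[:, [0, 2, 1]])

    def face_components(self) -> np.ndarray:
        """Connected-component label per face (shared-vertex connectivity)."""
        n = self.n_vertices
        rows = np.repeat(np.arange(self.n_faces), 3)
        inc = sparse.coo_matrix(
            (np.ones(3 * self.n_faces), (rows, self.faces.ravel())),
            shape=(self.n_faces, n),
        ).tocsr()
        adj = inc @ inc.T
        _, labels = csgraph.connected_components(adj, directed=False)
        return labels

    def largest_component(self) -> tuple["TriangleMesh", int]:
        """Keep the largest face-connected component.

        Returns the trimmed mesh and the number of dropped components.
        """
        labels = self.face_components()
        n_comp = labels.max() + 1
        if n_comp == 1:
            return self, 0
        biggest = np.bincount(labels).argmax()
        faces = self.faces[labels == biggest]
        used = np.unique(faces)
        remap = np.full(self.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[used], remap[faces]), int(n_comp - 1)


def uv_sphere(radius: float = 1.0, center=(0.0, 0.0, 0.0), n_lat: int = 24, n_lon: int = 48) -> TriangleMesh:
    """Closed UV sphere, outward-oriented; handy analytic reference surface."""
    lat = np.linspace(0, np.pi, n_lat + 1)[1:-1]
    lon = np.arange(n_lon) * (2 * np.pi / n_lon)
    ll, tt = np.meshgrid(lat, lon, indexing="ij")
    pts = radius * np.stack(
        [np.sin(ll) * np.cos(tt), np.sin(ll) * np.sin(tt), np.cos(ll)], axis=-1
    ).reshape(-1, 3)
    n_ring = len(lat)
    top = len(pts)
    bottom = top + 1
    verts = np.concatenate([pts, [[0, 0, radius], [0, 0, -radius]]]) + np.asarray(center)
    faces = []
    i = np.arange(n_lon)
    for j in range(n_ring - 1):
        a = j * n_lon + i
        b = j * n_lon + (i + 1) % n_lon
        c = a + n_lon
        d = b + n_lon
        faces.append(np.stack([a, c, b], axis=1))
        faces.append(np.stack([b, c, d], axis=1))
    faces.append(np.stack([np.full(n_lon, top), i, (i + 1) % n_lon], axis=1))
    base = (n_ring - 1) * n_lon
    faces.append(
        np.stack([np.full(n_lon, bottom), base + (i + 1) % n_lon, base + i], axis=1)
    )
    mesh = TriangleMesh(verts, np.concatenate(faces))
    if mesh.volume() < 0:
        mesh = mesh.flipped()
    return mesh


# -- STL (binary little-endian) ---------------------------------------------------


def write_stl(mesh: TriangleMesh, path) -> None:
    """Write binary little-endian STL."""
    t = mesh.triangles.astype("<f4")
    n = mesh.face_normals.astype("<f4")
    m = mesh.n_faces
    body = np.zeros((m, 50), dtype=np.uint8)
    raw = np.concatenate([n.reshape(m, 3), t.reshape(m, 9)], axis=1).astype("<f4")
    body[:, :48] = raw.view(np.uint8).reshape(m, 48)
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", m))
        fh.write(body.tobytes())


def read_stl(path) -> TriangleMesh:
    """Read binary little-endian STL, welding exactly coincident vertices."""
    with open(path, "rb") as fh:
        fh.seek(80)
        (m,) = struct.unpack("<I", fh.read(4))
        body = np.frombuffer(fh.read(m * 50), dtype=np.uint8).reshape(m, 50)
    raw = body[:, :48].copy().view("<f4").reshape(m, 12)
    corners = raw[:, 3:].reshape(m * 3, 3).astype(np.float64)
    verts, inverse = np.unique(corners, axis=0, return_inverse=True)
    faces = inverse.reshape(m, 3)
    return TriangleMesh(verts, faces)


# -- PLY (binary little-endian, optional per-vertex scalar + color) ---------------


def write_ply(
    mesh: TriangleMesh,
    path,
    scalars: np.ndarray | None = None,
    colors: np.ndarray | None = None,
) -> None:
    """Binary little-endian PLY; `scalars` as float 'quality', `colors` as uchar RGB."""
    n, m = mesh.n_vertices, mesh.n_faces
    props = ["property double x", "property double y", "property double z"]
    vdtype = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    if scalars is not None:
        props.append("property double quality")
        vdtype.append(("quality", "<f8"))
    if colors is not None:
        props += [f"property uchar {c}" for c in ("red", "green", "blue")]
        vdtype += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        f"element vertex {n}\n" + "\n".join(props) + "\n"
        f"element face {m}\nproperty list uchar int vertex_indices\nend_header\n"
    )
    vrec = np.zeros(n, dtype=vdtype)
    vrec["x"], vrec["y"], vrec["z"] = mesh.vertices.T
    if scalars is not None:
        vrec["quality"] = np.asarray(scalars, dtype=np.float64)
    if colors is not None:
        c = np.asarray(colors, dtype=np.uint8)
        vrec["red"], vrec["green"], vrec["blue"] = c.T
    frec = np.zeros(m, dtype=[("k", "u1"), ("idx", "<i4", 3)])
    frec["k"] = 3
    frec["idx"] = mesh.faces
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(vrec.tobytes())
        fh.write(frec.tobytes())


def read_ply(path):
    """Read a PLY written by :func:`write_ply`.

    Returns (mesh, scalars or None, colors or None).
    """
    with open(path, "rb") as fh:
        header = b""
        while not header.endswith(b"end_header\n"):
            header += fh.readline()
        lines = header.decode("ascii").splitlines()
        n = m = 0
        vdtype: list = []
        in_vertex = False
        for ln in lines:
            parts = ln.split()
            if parts[:2] == ["element", "vertex"]:
                n = int(parts[2])
                in_vertex = True
            elif parts[:2] == ["element", "face"]:
                m = int(parts[2])
                in_vertex = False
            elif parts[0] == "property" and in_vertex:
                kind = {"double": "<f8", "float": "<f4", "uchar": "u1"}[parts[1]]
                vdtype.append((parts[2], kind))
        vrec = np.frombuffer(fh.read(np.dtype(vdtype).itemsize * n), dtype=vdtype)
        frec = np.frombuffer(
            fh.read(m * (1 + 12)), dtype=[("k", "u1"), ("idx", "<i4", 3)]
        )
    verts = np.stack([vrec["x"], vrec["y"], vrec["z"]], axis=1).astype(np.float64)
    names = vrec.dtype.names
    scalars = vrec["quality"].astype(np.float64) if "quality" in names else None
    colors = (
        np.stack([vrec["red"], vrec["green"], vrec["blue"]], axis=1)
        if "red" in names
        else None
    )
    return TriangleMesh(verts, frec["idx"].astype(np.int64)), scalars, colors
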
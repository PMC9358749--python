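"""Volume I/O, bone segmentation, and isosurface extraction.

Three segmentation routes are provided, mirroring standard practice for
cortical bone in CT stacks:

* single intensity threshold;
* half-maximum height (HMH): the threshold is placed midway between the two
  material plateaus of a bone-to-air edge profile, estimated on a handful of
  randomly chosen slices and averaged;
* a two-stage fuzzy c-means segmentation ("MIA clustering"): a global
  c-means pass fixes cluster centers, then local c-means runs in overlapping
  cubic regions make the classification robust to intensity inhomogeneity,
  with per-voxel memberships blended across regions and a margin-based
  fallback to the global classification.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .mesh import TriangleMesh

__all__ = [
    "VoxelVolume",
    "SegmentationMask",
    "MIAParams",
    "read_mhd",
    "write_mhd",
    "read_nifti",
    "write_nifti",
    "single_threshold_segment",
    "hmh_threshold",
    "fuzzy_cmeans",
    "mia_segment",
    "extract_isosurface",
]


@dataclass
class VoxelVolume:
    """3D grayscale grid with physical spacing and origin (mm).

    Convention: ``world = origin + index * spacing`` with 0-based, node-
    centered indices; ``intensities[i, j, k]`` is the sample at world
    position ``origin + (i, j, k) * spacing``.
    """

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.broadcast_to(
            np.asarray(self.origin, dtype=np.float64), (3,)
        ).copy()
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3D grid")
        if (self.spacing <= 0).any():
            raise ValueError("spacing must be positive")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities must be finite")

    @property
    def shape(self):
        return self.intensities.shape


@dataclass
class SegmentationMask:
    """Binary grid congruent with its source volume, plus provenance."""

    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)


@dataclass(frozen=True)
class MIAParams:
    """Parameters of the two-stage fuzzy clustering segmentation.

    ``grid_size`` follows the cited convention of a region edge expressed in
    multiples of a base block (``base_edge`` voxels); ``local_weight_threshold``
    is the minimum blended membership margin (percent) below which a voxel
    falls back to the global classification.  Both semantics are exposed
    because the upstream description names the parameters without defining
    them precisely.
    """

    n_clusters: int = 4
    grid_size: int = 3
    base_edge: int = 32
    local_weight_threshold: float = 2.0
    fuzzifier: float = 2.0
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.grid_size < 1 or self.base_edge < 4:
            raise ValueError("invalid region grid")
        if not (0 < self.local_weight_threshold < 100):
            raise ValueError("threshold must be in (0, 100) percent")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must exceed 1")


# -- I/O ---------------------------------------------------------------------------


def write_mhd(vol: VoxelVolume, path) -> None:
    """MetaImage (.mhd header + .raw little-endian float64 payload)."""
    path = os.fspath(path)
    base, _ = os.path.splitext(path)
    raw_name = os.path.basename(base) + ".raw"
    nx, ny, nz = vol.shape
    header = (
        "ObjectType = Image\nNDims = 3\nBinaryData = True\n"
        "BinaryDataByteOrderMSB = False\nCompressedData = False\n"
        f"TransformMatrix = 1 0 0 0 1 0 0 0 1\n"
        f"Offset = {vol.origin[0]} {vol.origin[1]} {vol.origin[2]}\n"
        f"ElementSpacing = {vol.spacing[0]} {vol.spacing[1]} {vol.spacing[2]}\n"
        f"DimSize = {nx} {ny} {nz}\n"
        "ElementType = MET_DOUBLE\n"
        f"ElementDataFile = {raw_name}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
    # MetaImage raw layout is x-fastest
    vol.intensities.astype("<f8").transpose(2, 1, 0).tofile(base + ".raw")


def read_mhd(path) -> VoxelVolume:
    path = os.fspath(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    dims = [int(x) for x in meta["DimSize"].split()]
    spacing = [float(x) for x in meta["ElementSpacing"].split()]
    origin = [float(x) for x in meta.get("Offset", "0 0 0").split()]
    dtype = {"MET_DOUBLE": "<f8", "MET_FLOAT": "<f4", "MET_UCHAR": "u1", "MET_SHORT": "<i2"}[
        meta["ElementType"]
    ]
    raw_path = os.path.join(os.path.dirname(path), meta["ElementDataFile"])
    data = np.fromfile(raw_path, dtype=dtype).reshape(dims[2], dims[1], dims[0])
    return VoxelVolume(data.transpose(2, 1, 0).astype(np.float64), spacing, origin)


def write_nifti(vol: VoxelVolume, path) -> None:
    import nibabel as nib

    affine = np.diag(np.append(vol.spacing, 1.0))
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.intensities, affine), os.fspath(path))


def read_nifti(path) -> VoxelVolume:
    import nibabel as nib

    img = nib.load(os.fspath(path))
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    return VoxelVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, affine[:3, 3])


# -- segmentation ------------------------------------------------------------------


def single_threshold_segment(vol: VoxelVolume, tau: float) -> SegmentationMask:
    """Voxels strictly above ``tau``."""
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    return SegmentationMask(
        vol.intensities > tau,
        vol.spacing,
        vol.origin,
        provenance={"method": "single_threshold", "tau": float(tau)},
    )


def _hmh_from_profile(profile: np.ndarray, offset: int = 2, width: int = 5):
    """HMH and plateau separation of a 1D edge profile.

    The crossing is the max-|gradient| sample; plateaus are medians of
    ``width`` samples starting ``offset`` samples away on each side.
    Returns ``(hmh, separation)`` or None when the profile is unusable.
    """
    grad = np.abs(np.diff(profile))
    if grad.max() == 0:
        return None
    j = int(np.argmax(grad))  # transition between j and j+1
    lo = j - offset - width + 1
    hi = j + 1 + offset
    if lo < 0 or hi + width > len(profile):
        return None
    left = float(np.median(profile[lo : lo + width]))
    right = float(np.median(profile[hi : hi + width]))
    return 0.5 * (left + right), left, right


def hmh_threshold(
    vol: VoxelVolume, n_slices: int = 10, seed: int = 0, axis: int = 2
) -> float:
    """Half-maximum-height threshold averaged over randomly selected slices.

    For each chosen slice the pixel row with the sharpest bone-to-air
    transition (max gradient) provides the edge profile; its HMH is the
    midpoint of the two plateau medians.  Slices without a usable transition
    are resampled; running out of slices is an error.
    """
    data = np.moveaxis(vol.intensities, axis, 0)
    lo, hi = data.min(), data.max()
    if hi - lo == 0:
        raise ValueError("volume has a single intensity: no bone/air transition")
    midpoint = 0.5 * (lo + hi)
    usable = np.where(
        (data.min(axis=(1, 2)) < midpoint) & (data.max(axis=(1, 2)) > midpoint)
    )[0]
    if len(usable) < n_slices:
        raise ValueError(
            f"only {len(usable)} slices contain a bone-to-air transition; "
            f"{n_slices} required"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(usable)
    # robust material levels: rows are only usable when both plateaus sit on
    # true material intensities (rejects thin/partial-volume features near caps)
    q_air, q_bone = np.quantile(data, [0.01, 0.99])
    band = 0.15 * (q_bone - q_air)
    values = []
    for s in order:
        sl = data[s]
        row_grad = np.abs(np.diff(sl, axis=1)).max(axis=1)
        for r in np.argsort(row_grad)[::-1][:20]:
            result = _hmh_from_profile(sl[r])
            if result is None:
                continue
            hmh, left, right = result
            plo, phi = min(left, right), max(left, right)
            if abs(plo - q_air) <= band and abs(phi - q_bone) <= band:
                values.append(hmh)
                break
        if len(values) == n_slices:
            break
    if len(values) < n_slices:
        raise ValueError("fewer than n_slices slices yielded a usable HMH profile")
    return float(np.mean(values))


def fuzzy_cmeans(
    values: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    init_centers: np.ndarray | None = None,
):
    """Fuzzy c-means on a 1D sample.

    Returns ``(centers, memberships, info)`` with centers ascending,
    memberships of shape (n, c) summing to 1 per value, and ``info`` holding
    the per-iteration objective (non-increasing) and a degeneracy flag.

    Initialization is by intensity quantiles (deterministic), unless
    ``init_centers`` is given.  ``seed`` is accepted for interface symmetry;
    the algorithm itself is deterministic.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if c < 2:
        raise ValueError("need c >= 2")
    if len(x) < c:
        raise ValueError("sample smaller than cluster count")
    if m <= 1:
        raise ValueError("fuzzifier must exceed 1")
    if np.ptp(x) == 0:
        u = np.full((len(x), c), 1.0 / c)
        return np.full(c, x[0]), u, {"objective": [0.0], "degenerate": True}
    if init_centers is None:
        centers = np.quantile(x, (np.arange(c) + 0.5) / c)
        centers = centers + np.arange(c) * 1e-9 * max(1.0, np.ptp(x))  # break ties
    else:
        centers = np.sort(np.asarray(init_centers, dtype=np.float64))
    objective = []
    for _ in range(max_iter):
        d2 = (x[:, None] - centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-30)
        # u_ik = (d_ik^2)^(-1/(m-1)) / sum_j (d_ij^2)^(-1/(m-1))
        w = d2 ** (-1.0 / (m - 1.0))
        u = w / w.sum(axis=1, keepdims=True)
        um = u**m
        objective.append(float((um * d2).sum()))
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    order = np.argsort(centers)
    d2 = np.maximum((x[:, None] - centers[None, :]) ** 2, 1e-30)
    w = d2 ** (-1.0 / (m - 1.0))
    u = w / w.sum(axis=1, keepdims=True)
    return centers[order], u[:, order], {"objective": objective, "degenerate": False}


def _memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = np.maximum((x[..., None] - centers) ** 2, 1e-30)
    w = d2 ** (-1.0 / (m - 1.0))
    return w / w.sum(axis=-1, keepdims=True)


def _region_slices(n: int, edge: int, stride: int):
    starts = list(range(0, max(n - edge, 0) + 1, stride))
    if not starts:
        starts = [0]
    if starts[-1] + edge < n:
        starts.append(n - edge)
    return [(s, min(s + edge, n)) for s in starts]


def _taper_weight(length: int) -> np.ndarray:
    """Linear taper to the region boundary, 1 at the center, > 0 everywhere."""
    i = np.arange(length, dtype=np.float64)
    half = (length - 1) / 2.0 if length > 1 else 1.0
    return 1.0 - np.abs(i - half) / (half + 1.0)


def mia_segment(vol: VoxelVolume, p: MIAParams = MIAParams(), seed: int = 0) -> SegmentationMask:
    """Global + local fuzzy c-means segmentation, robust to bias fields.

    A global c-means over all intensities fixes reference centers; local
    c-means then re-estimates centers in overlapping cubic regions (50%
    overlap), per-voxel memberships are blended with linear taper weights,
    and voxels whose blended top-cluster margin falls below
    ``local_weight_threshold`` percent revert to the global classification.
    The bone mask is the union of the brightest cluster(s) (centers above
    the midpoint of the global center range).
    """
    x = vol.intensities
    flat = x.ravel()
    rng = np.random.default_rng(seed)
    sample = flat if flat.size <= 200_000 else rng.choice(flat, 200_000, replace=False)
    centers, _, _ = fuzzy_cmeans(sample, p.n_clusters, p.fuzzifier, p.tol, p.max_iter)

    edge = p.grid_size * p.base_edge
    stride = max(edge // 2, 1)  # 50% overlap
    c = p.n_clusters
    msum = np.zeros(x.shape + (c,), dtype=np.float64)
    wsum = np.zeros(x.shape, dtype=np.float64)
    slx = _region_slices(x.shape[0], edge, stride)
    sly = _region_slices(x.shape[1], edge, stride)
    slz = _region_slices(x.shape[2], edge, stride)
    for ax0, ax1 in slx:
        wx = _taper_weight(ax1 - ax0)
        for ay0, ay1 in sly:
            wy = _taper_weight(ay1 - ay0)
            for az0, az1 in slz:
                wz = _taper_weight(az1 - az0)
                region = x[ax0:ax1, ay0:ay1, az0:az1]
                if region.size < c:
                    continue  # degenerate sliver: neighbors cover it via overlap
                local_centers, _, info = fuzzy_cmeans(
                    region.ravel(),
                    c,
                    p.fuzzifier,
                    p.tol,
                    max_iter=30,
                    init_centers=centers,
                )
                if info["degenerate"]:
                    local_centers = centers
                u = _memberships(region, local_centers, p.fuzzifier)
                w = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
                msum[ax0:ax1, ay0:ay1, az0:az1] += w[..., None] * u
                wsum[ax0:ax1, ay0:ay1, az0:az1] += w
    wsum = np.maximum(wsum, 1e-12)
    blended = msum / wsum[..., None]

    top2 = np.partition(blended, c - 2, axis=-1)[..., -2:]
    margin = top2[..., 1] - top2[..., 0]
    local_label = np.argmax(blended, axis=-1)
    global_label = np.argmax(_memberships(x, centers, p.fuzzifier), axis=-1)
    label = np.where(margin < p.local_weight_threshold / 100.0, global_label, local_label)

    bone_clusters = np.where(centers > 0.5 * (centers.min() + centers.max()))[0]
    mask = np.isin(label, bone_clusters)
    return SegmentationMask(
        mask,
        vol.spacing,
        vol.origin,
        provenance={
            "method": "mia_clustering",
            "n_clusters": c,
            "grid_size": p.grid_size,
            "base_edge": p.base_edge,
            "local_weight_threshold": p.local_weight_threshold,
            "fuzzifier": p.fuzzifier,
            "global_centers": centers.tolist(),
            "bone_clusters": bone_clusters.tolist(),
            "seed": seed,
        },
    )


# -- isosurface --------------------------------------------------------------------


def extract_isosurface(
    grid, level: float, spacing=None, origin=None, keep_largest: bool = True
) -> TriangleMesh:
    """Marching-cubes isosurface in world coordinates (mm).

    ``grid`` is either a :class:`VoxelVolume` / :class:`SegmentationMask` or a
    raw 3D array (then ``spacing``/``origin`` are required).  The surface is
    oriented outward (positive enclosed volume); by default only the largest
    connected component is kept (speck removal) and the drop count is
    recorded on the returned mesh as ``mesh.dropped_components``.
    """
    if isinstance(grid, VoxelVolume):
        data, spacing, origin = grid.intensities, grid.spacing, grid.origin
    elif isinstance(grid, SegmentationMask):
        data, spacing, origin = grid.mask.astype(np.float64), grid.spacing, grid.origin
    else:
        data = np.asarray(grid, dtype=np.float64)
        if spacing is None or origin is None:
            raise ValueError("raw arrays need explicit spacing and origin")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,))
    origin = np.broadcast_to(np.asarray(origin, dtype=np.float64), (3,))
    if not (data.min() < level < data.max()):
        raise ValueError("isosurface level outside the intensity range")
    verts, faces, _, _ = measure.marching_cubes(data, level=level, spacing=tuple(spacing))
    mesh = TriangleMesh(verts + origin, faces.astype(np.int64))
    dropped = 0
    if keep_largest:
        mesh, dropped = mesh.largest_component()
    if mesh.is_closed() and mesh.volume() < 0:
        mesh = mesh.flipped()
    mesh.dropped_components = dropped
    return mesh
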
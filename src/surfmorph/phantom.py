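"""Synthetic bone phantom: surfaces, CT-like volumes, and landmark studies.

Real long-bone scans are not redistributable, so every stage of the pipeline
is exercised on a parametric phantom instead: a surface of revolution with
angular lobes (a non-circular, fibula-like shaft), flared ends standing in
for the epiphyses, and a smooth random surface detail field.  Because the
solid is analytic, ground truth (inside/outside, surface points, normals) is
available for every downstream test.

The study simulator emulates a replicate digitization design: per specimen,
four labelled landmark configurations (two "CT" segmentations, a laser scan
and its re-digitized replica), with biological shape variation injected as a
smooth low-rank TPS warp, a small systematic outward offset for the CT
digitizations (CT surfaces run slightly large), and tangential operator
jitter for the replica.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .mesh import TriangleMesh

__all__ = [
    "PhantomSpec",
    "StudySimSpec",
    "LandmarkTemplate",
    "LandmarkConfiguration",
    "generate_phantom_mesh",
    "phantom_inside",
    "phantom_surface_point",
    "phantom_surface_normal",
    "voxelize_phantom",
    "voxelize_mesh",
    "define_phantom_template",
    "simulate_landmark_study",
    "simulate_device_meshes",
    "METHODS",
]

METHODS = ("CT-HMH", "CT-MIA", "LASER", "LASER-REP")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the parametric bone phantom (all lengths in mm)."""

    shaft_length: float = 330.0
    shaft_radius: float = 7.0
    cross_section_lobes: int = 3
    lobe_amplitude: float = 0.8
    proximal_flare: float = 4.0          # bump amplitude at the proximal end
    proximal_extent: float = 0.12        # axial extent, fraction of length
    distal_flare: float = 3.0
    distal_extent: float = 0.10
    surface_detail_amplitude: float = 0.15
    mesh_resolution: float = 1.5         # target edge length
    seed: int = 0

    def __post_init__(self):
        if self.shaft_length <= 0 or self.shaft_radius <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be positive")
        for e in (self.proximal_extent, self.distal_extent):
            if not (0.0 < e < 0.5):
                raise ValueError("flare extents must lie in (0, 0.5)")
        if self.lobe_amplitude < 0 or self.proximal_flare < 0 or self.distal_flare < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class StudySimSpec:
    """Parameters of the simulated 13 x 4 replicate digitization study."""

    n_specimens: int = 13
    biological_sd: float = 1.5      # mm, between-specimen shape variation
    device_offset: float = 0.2     # mm, systematic outward offset of CT configs
    device_noise_sd: float = 0.1   # mm, iid digitization noise on CT configs
    operator_sd: float = 0.1       # mm, tangential jitter of the replica
    seed: int = 0

    def __post_init__(self):
        if self.n_specimens < 2:
            raise ValueError("need at least 2 specimens")
        for s in (self.biological_sd, self.device_noise_sd, self.operator_sd):
            if s < 0:
                raise ValueError("standard deviations must be non-negative")


# -- analytic surface --------------------------------------------------------------


def _detail_coeffs(spec: PhantomSpec):
    """Seeded coefficients of the smooth random surface-detail field."""
    rng = np.random.default_rng(spec.seed)
    n_modes = 6
    kz = rng.integers(1, 5, n_modes)
    mth = rng.integers(1, 6, n_modes)
    amp = rng.normal(0.0, 1.0, n_modes)
    phz = rng.uniform(0, 2 * np.pi, n_modes)
    pht = rng.uniform(0, 2 * np.pi, n_modes)
    norm = np.sqrt((amp**2).sum() / 2) or 1.0
    amp = amp / norm * spec.surface_detail_amplitude
    return kz, mth, amp, phz, pht


def _flare(z, length, amplitude, extent, proximal):
    """Smooth cosine-ramp flare; 0 in the shaft, max amplitude at the bone end."""
    z = np.asarray(z, dtype=np.float64)
    w = extent * length
    if proximal:
        s = np.clip((z - (length - w)) / w, 0.0, 1.0)
    else:
        s = np.clip((w - z) / w, 0.0, 1.0)
    return amplitude * 0.5 * (1.0 - np.cos(np.pi * s))


def phantom_radius(spec: PhantomSpec, z, theta):
    """Surface radius r(z, theta) of the phantom solid."""
    z = np.asarray(z, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    r = spec.shaft_radius + spec.lobe_amplitude * np.cos(
        spec.cross_section_lobes * theta
    )
    r = r + _flare(z, spec.shaft_length, spec.proximal_flare, spec.proximal_extent, True)
    r = r + _flare(z, spec.shaft_length, spec.distal_flare, spec.distal_extent, False)
    if spec.surface_detail_amplitude > 0:
        kz, mth, amp, phz, pht = _detail_coeffs(spec)
        for i in range(len(amp)):
            r = r + amp[i] * np.cos(
                2 * np.pi * kz[i] * z / spec.shaft_length + phz[i]
            ) * np.cos(mth[i] * theta + pht[i])
    return r


def phantom_surface_point(spec: PhantomSpec, z, theta):
    r = phantom_radius(spec, z, theta)
    z = np.broadcast_to(np.asarray(z, dtype=np.float64), np.shape(r))
    theta = np.broadcast_to(np.asarray(theta, dtype=np.float64), np.shape(r))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=-1)


def phantom_surface_normal(spec: PhantomSpec, z, theta, h: float = 1e-5):
    """Outward unit normal of the lateral surface (central differences)."""
    z = np.asarray(z, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    p_t = (
        phantom_surface_point(spec, z, theta + h)
        - phantom_surface_point(spec, z, theta - h)
    ) / (2 * h)
    p_z = (
        phantom_surface_point(spec, np.clip(z + h, 0, spec.shaft_length), theta)
        - phantom_surface_point(spec, np.clip(z - h, 0, spec.shaft_length), theta)
    )
    p_z = p_z / np.linalg.norm(p_z, axis=-1, keepdims=True)
    n = np.cross(p_t, p_z)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
    flip = np.sum(n * radial, axis=-1) < 0
    n[flip] *= -1
    return n


def phantom_inside(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Ground-truth indicator of the phantom solid at arbitrary points."""
    p = np.asarray(points, dtype=np.float64)
    z = p[..., 2]
    rho = np.hypot(p[..., 0], p[..., 1])
    theta = np.arctan2(p[..., 1], p[..., 0])
    inside_z = (z > 0) & (z < spec.shaft_length)
    return inside_z & (rho < phantom_radius(spec, z, theta))


def generate_phantom_mesh(spec: PhantomSpec) -> TriangleMesh:
    """Closed, outward-oriented triangle mesh of the phantom solid.

    Deterministic given ``spec.seed`` (the only stochastic ingredient is the
    surface-detail field, whose coefficients are seeded).
    """
    h = spec.mesh_resolution
    nz = max(8, int(round(spec.shaft_length / h)))
    ntheta = max(12, int(round(2 * np.pi * spec.shaft_radius / h)))
    zs = np.linspace(0.0, spec.shaft_length, nz + 1)
    thetas = np.arange(ntheta) * (2 * np.pi / ntheta)
    zz, tt = np.meshgrid(zs, thetas, indexing="ij")
    ring_pts = phantom_surface_point(spec, zz, tt).reshape(-1, 3)

    def vid(j, i):
        return j * ntheta + (i % ntheta)

    faces = []
    jj, ii = np.meshgrid(np.arange(nz), np.arange(ntheta), indexing="ij")
    jj, ii = jj.ravel(), ii.ravel()
    a = jj * ntheta + ii
    b = jj * ntheta + (ii + 1) % ntheta
    c = a + ntheta
    d = b + ntheta
    # outward CCW: for outward normals, wind (a, b, d) and (a, d, c)
    faces.append(np.stack([a, b, d], axis=1))
    faces.append(np.stack([a, d, c], axis=1))
    # end caps as concentric rings so every edge stays near the target length
    extra_verts = [ring_pts]
    n_total = (nz + 1) * ntheta
    i = np.arange(ntheta)
    for zc, boundary_ring, bottom in ((0.0, 0, True), (spec.shaft_length, nz, False)):
        r_edge = phantom_radius(spec, zc, thetas)
        nc = max(1, int(round(float(r_edge.mean()) / h)))
        prev = np.array([vid(boundary_ring, k) for k in range(ntheta)])
        for ring in range(nc - 1, 0, -1):
            f = ring / nc
            pts = np.stack(
                [f * r_edge * np.cos(thetas), f * r_edge * np.sin(thetas),
                 np.full(ntheta, zc)], axis=1
            )
            cur = n_total + np.arange(ntheta)
            extra_verts.append(pts)
            n_total += ntheta
            a, b = prev[i], prev[(i + 1) % ntheta]
            c, d = cur[i], cur[(i + 1) % ntheta]
            if bottom:
                faces.append(np.stack([a, c, b], axis=1))
                faces.append(np.stack([b, c, d], axis=1))
            else:
                faces.append(np.stack([a, b, c], axis=1))
                faces.append(np.stack([b, d, c], axis=1))
            prev = cur
        center = n_total
        extra_verts.append(np.array([[0.0, 0.0, zc]]))
        n_total += 1
        a, b = prev[i], prev[(i + 1) % ntheta]
        if bottom:
            faces.append(np.stack([np.full(ntheta, center), b, a], axis=1))
        else:
            faces.append(np.stack([np.full(ntheta, center), a, b], axis=1))
    verts = np.concatenate(extra_verts)
    mesh = TriangleMesh(verts, np.concatenate(faces))
    if mesh.volume() < 0:
        mesh = mesh.flipped()
    return mesh


# -- voxelization ------------------------------------------------------------------


def voxelize_mesh(mesh: TriangleMesh, voxel_size, origin=None, shape=None, pad: float = 3.0):
    """Even-odd occupancy of a closed mesh sampled at grid nodes.

    World convention: ``world = origin + index * spacing`` (node-centered,
    0-based).  Returns (occupancy bool array indexed [ix, iy, iz], origin).
    """
    if not mesh.is_closed():
        raise ValueError("mesh must be closed for an inside/outside test")
    spacing = np.broadcast_to(np.asarray(voxel_size, dtype=np.float64), (3,)).copy()
    if (spacing <= 0).any():
        raise ValueError("voxel size must be positive")
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    if origin is None:
        origin = lo - pad * spacing
    origin = np.asarray(origin, dtype=np.float64)
    if shape is None:
        shape = np.ceil((hi - origin) / spacing).astype(int) + int(pad) + 1
    nx, ny, nz = (int(s) for s in shape)

    tri = mesh.triangles
    # tiny deterministic shift so rays never hit edges/vertices exactly
    eps = 1e-6 * spacing[:2]
    gx = origin[0] + np.arange(nx) * spacing[0] + eps[0]
    gy = origin[1] + np.arange(ny) * spacing[1] + eps[1]

    col_idx_parts = []
    z_parts = []
    a2 = tri[:, 0, :2]
    ab2 = tri[:, 1, :2] - a2
    ac2 = tri[:, 2, :2] - a2
    det = ab2[:, 0] * ac2[:, 1] - ab2[:, 1] * ac2[:, 0]
    ok = np.abs(det) > 1e-14

    ix_lo = np.clip(np.searchsorted(gx, tri[:, :, 0].min(axis=1)), 0, nx)
    ix_hi = np.clip(np.searchsorted(gx, tri[:, :, 0].max(axis=1)), 0, nx)
    iy_lo = np.clip(np.searchsorted(gy, tri[:, :, 1].min(axis=1)), 0, ny)
    iy_hi = np.clip(np.searchsorted(gy, tri[:, :, 1].max(axis=1)), 0, ny)

    for f in np.where(ok)[0]:
        if ix_hi[f] <= ix_lo[f] or iy_hi[f] <= iy_lo[f]:
            continue
        xs = gx[ix_lo[f] : ix_hi[f]]
        ys = gy[iy_lo[f] : iy_hi[f]]
        px, py = np.meshgrid(xs, ys, indexing="ij")
        qx = px - tri[f, 0, 0]
        qy = py - tri[f, 0, 1]
        inv = 1.0 / det[f]
        u = (qx * ac2[f, 1] - qy * ac2[f, 0]) * inv
        v = (-qx * ab2[f, 1] + qy * ab2[f, 0]) * inv
        hit = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not hit.any():
            continue
        zhit = (
            tri[f, 0, 2]
            + u[hit] * (tri[f, 1, 2] - tri[f, 0, 2])
            + v[hit] * (tri[f, 2, 2] - tri[f, 0, 2])
        )
        iix, iiy = np.nonzero(hit)
        col_idx_parts.append((iix + ix_lo[f]) * ny + (iiy + iy_lo[f]))
        z_parts.append(zhit)

    occ = np.zeros((nx, ny, nz), dtype=bool)
    if col_idx_parts:
        cols = np.concatenate(col_idx_parts)
        zs = np.concatenate(z_parts)
        order = np.lexsort((zs, cols))
        cols, zs = cols[order], zs[order]
        # crossings per column come in pairs (closed mesh)
        diff = np.zeros((nx * ny, nz + 1), dtype=np.int32)
        starts = np.searchsorted(cols, np.unique(cols))
        bounds = np.concatenate([starts, [len(cols)]])
        ucols = np.unique(cols)
        gz0 = origin[2]
        for c0, s0, s1 in zip(ucols, bounds[:-1], bounds[1:]):
            zc = zs[s0:s1]
            for k in range(0, len(zc) - 1, 2):
                k_start = int(np.ceil((zc[k] - gz0) / spacing[2] - 1e-12))
                k_end = int(np.floor((zc[k + 1] - gz0) / spacing[2] + 1e-12)) + 1
                k_start = max(k_start, 0)
                k_end = min(k_end, nz)
                if k_end > k_start:
                    diff[c0, k_start] += 1
                    diff[c0, k_end] -= 1
        occ = (np.cumsum(diff[:, :-1], axis=1) > 0).reshape(nx, ny, nz)
    return occ, origin


def voxelize_phantom(
    mesh: TriangleMesh,
    voxel_size=0.625,
    bone_intensity: float = 1000.0,
    air_intensity: float = -1000.0,
    psf_sigma: float = 0.4,
    noise_sd: float = 0.0,
    bias_field=None,
    seed: int = 0,
):
    """CT-like volume of a closed mesh: occupancy, partial-volume blur, gain, noise.

    ``bias_field`` is either ``None`` or a callable mapping world-coordinate
    arrays (x, y, z) to a multiplicative gain (1.0 = no inhomogeneity).
    Returns a :class:`surfmorph.volseg.VoxelVolume`.
    """
    from .volseg import VoxelVolume

    spacing = np.broadcast_to(np.asarray(voxel_size, dtype=np.float64), (3,)).copy()
    occ, origin = voxelize_mesh(mesh, spacing)
    vol = np.where(occ, bone_intensity, air_intensity).astype(np.float64)
    if psf_sigma > 0:
        vol = ndimage.gaussian_filter(vol, sigma=psf_sigma / spacing, mode="nearest")
    if bias_field is not None:
        nx, ny, nz = vol.shape
        x = origin[0] + np.arange(nx) * spacing[0]
        y = origin[1] + np.arange(ny) * spacing[1]
        z = origin[2] + np.arange(nz) * spacing[2]
        xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
        vol = vol * np.asarray(bias_field(xx, yy, zz), dtype=np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, vol.shape)
    return VoxelVolume(vol, spacing=spacing, origin=origin)


# -- landmark template -------------------------------------------------------------


@dataclass
class LandmarkTemplate:
    """Ordered landmark/semilandmark definitions on the phantom surface.

    ``roles`` are 'fixed', 'curve' or 'surface'; curve points carry a curve id
    and are stored in chain order.  ``params`` holds the analytic (z, theta)
    surface coordinates of each point, which gives exact normals/tangents.
    """

    spec: PhantomSpec
    ids: list
    points: np.ndarray            # (k, 3)
    roles: np.ndarray             # (k,) str
    epiphysis: np.ndarray         # (k,) 'proximal' | 'distal'
    curve_id: np.ndarray          # (k,) int, -1 for non-curve points
    params: np.ndarray            # (k, 2) (z, theta); NaN theta for poles

    @property
    def n_points(self) -> int:
        return len(self.points)

    def subset(self, epiphysis: str) -> np.ndarray:
        return np.where(self.epiphysis == epiphysis)[0]

    def normals(self) -> np.ndarray:
        """Outward unit normals at every template point (analytic)."""
        n = np.zeros_like(self.points)
        pole = np.isnan(self.params[:, 1])
        if pole.any():
            n[pole] = np.where(
                self.params[pole, 0:1] > self.spec.shaft_length / 2,
                [[0.0, 0.0, 1.0]],
                [[0.0, 0.0, -1.0]],
            )
        lat = ~pole
        if lat.any():
            n[lat] = phantom_surface_normal(
                self.spec, self.params[lat, 0], self.params[lat, 1]
            )
        return n


def _epiphysis_points(spec, proximal: bool, n_total: int, ids_prefix: str):
    """Fixed anchors, a ring of curve semilandmarks, and a surface patch."""
    L = spec.shaft_length
    extent = spec.proximal_extent if proximal else spec.distal_extent
    w = extent * L
    if proximal:
        z_end, z_mid, z_edge = L, L - 0.5 * w, L - w
        band = (z_edge, L)
    else:
        z_end, z_mid, z_edge = 0.0, 0.5 * w, w
        band = (0.0, w)

    n_fixed = 5
    if n_total < n_fixed + 4:
        raise ValueError(f"need at least {n_fixed + 4} points per epiphysis")
    n_curve = max(8, int(round(0.3 * (n_total - n_fixed))))
    n_surface = n_total - n_fixed - n_curve

    ids, pts, roles, cids, params = [], [], [], [], []
    # fixed: cap pole + 4 mid-flare apex points
    ids.append(f"{ids_prefix}-pole")
    pts.append([0.0, 0.0, z_end])
    roles.append("fixed")
    cids.append(-1)
    params.append([z_end, np.nan])
    for j, th in enumerate(np.arange(4) * (np.pi / 2)):
        ids.append(f"{ids_prefix}-apex{j + 1}")
        pts.append(phantom_surface_point(spec, z_mid, th))
        roles.append("fixed")
        cids.append(-1)
        params.append([z_mid, th])
    # curve: the flare-edge ring, ordered in theta (closed chain)
    for j, th in enumerate(np.arange(n_curve) * (2 * np.pi / n_curve)):
        ids.append(f"{ids_prefix}-c{j + 1}")
        pts.append(phantom_surface_point(spec, z_edge, th))
        roles.append("curve")
        cids.append(0 if proximal else 1)
        params.append([z_edge, th])
    # surface: sunflower coverage of the epiphyseal band
    golden = np.pi * (3 - np.sqrt(5))
    for j in range(n_surface):
        frac = (j + 0.5) / n_surface
        z = band[0] + frac * (band[1] - band[0])
        th = (j * golden) % (2 * np.pi)
        ids.append(f"{ids_prefix}-s{j + 1}")
        pts.append(phantom_surface_point(spec, z, th))
        roles.append("surface")
        cids.append(-1)
        params.append([z, th])
    return ids, pts, roles, cids, params


def define_phantom_template(
    spec: PhantomSpec, n_proximal: int = 94, n_distal: int = 48
) -> LandmarkTemplate:
    """Landmark template on the phantom: 142 points by default (94 + 48)."""
    ip, pp, rp, cp_, qp = _epiphysis_points(spec, True, n_proximal, "P")
    idd, pd, rd, cd, qd = _epiphysis_points(spec, False, n_distal, "D")
    return LandmarkTemplate(
        spec=spec,
        ids=ip + idd,
        points=np.array(pp + pd, dtype=np.float64),
        roles=np.array(rp + rd),
        epiphysis=np.array(["proximal"] * n_proximal + ["distal"] * n_distal),
        curve_id=np.array(cp_ + cd, dtype=np.int64),
        params=np.array(qp + qd, dtype=np.float64),
    )


# -- simulated study ---------------------------------------------------------------


@dataclass
class LandmarkConfiguration:
    """One digitization of one specimen: k x 3 coordinates plus labels."""

    coords: np.ndarray
    specimen: str
    method: str
    template: LandmarkTemplate | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.isfinite(self.coords).all():
            raise ValueError("landmark coordinates must be finite")


def _biological_warp(template: LandmarkTemplate, sd: float, rng) -> np.ndarray:
    """Smooth low-rank TPS warp of the template points (amplitude ``sd`` mm)."""
    from .gm import tps_fit

    spec = template.spec
    if sd == 0:
        return template.points.copy()
    # control lattice: 3 rings x 4 angles on an enclosing cylinder + axis ends
    zc = np.array([0.0, 0.25, 0.5, 0.75, 1.0]) * spec.shaft_length
    R = spec.shaft_radius + max(spec.proximal_flare, spec.distal_flare) + 4.0
    ctrl = [[0.0, 0.0, -10.0], [0.0, 0.0, spec.shaft_length + 10.0]]
    for z in zc:
        for th in np.arange(4) * (np.pi / 2):
            ctrl.append([R * np.cos(th), R * np.sin(th), z])
    ctrl = np.array(ctrl)
    warped_ctrl = ctrl + rng.normal(0.0, sd, ctrl.shape)
    warp, _ = tps_fit(ctrl, warped_ctrl)
    return warp(template.points)


def simulate_landmark_study(
    template: LandmarkTemplate, sim: StudySimSpec
) -> list[LandmarkConfiguration]:
    """n_specimens x 4 labelled configurations with known injected effects.

    Every digitization is a separate application of the template, so each of
    the four configurations carries its own independent tangential operator
    jitter (sd ``operator_sd``); the CT digitizations additionally get the
    systematic outward normal offset plus isotropic device noise.  With all
    noise terms zero the four configurations of a specimen are identical.
    """
    rng = np.random.default_rng(sim.seed)
    normals = template.normals()
    configs: list[LandmarkConfiguration] = []
    for s in range(sim.n_specimens):
        name = f"S{s + 1:02d}"
        base = _biological_warp(template, sim.biological_sd, rng)
        for method in METHODS:
            noise = rng.normal(0.0, sim.operator_sd, base.shape)
            tang = noise - np.sum(noise * normals, axis=1, keepdims=True) * normals
            coords = base + tang
            if method.startswith("CT"):
                coords = (
                    coords
                    + sim.device_offset * normals
                    + rng.normal(0.0, sim.device_noise_sd, base.shape)
                )
            configs.append(
                LandmarkConfiguration(coords, specimen=name, method=method, template=template)
            )
    return configs


def simulate_device_meshes(
    mesh: TriangleMesh, offset: float, noise_sd: float, seed: int = 0
) -> TriangleMesh:
    """Device analogue of a reference surface: outward offset + vertex noise."""
    v = mesh.vertices + offset * mesh.vertex_normals
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, v.shape)
    return mesh.with_vertices(v)
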
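"""Geometric morphometrics: TPS, sliding semilandmarks, GPA, and RRPP tests.

The validation question this module answers: do landmark configurations
digitized on surfaces from different sources (CT segmentations vs. laser
scans) differ in shape beyond digitization noise?  The tools are the
standard ones of 3D geometric morphometrics:

* a volumetric thin-plate spline with kernel phi(r) = r, used both to map a
  landmark template onto new surfaces and to define the bending energy that
  drives semilandmark sliding;
* generalized Procrustes analysis (GPA) with optional sliding against the
  recursive consensus;
* Procrustes ANOVA with residual randomization (RRPP) and pairwise post-hoc
  distances drawn from the *same* permutation stream, plus a classical
  one-way ANOVA on centroid sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mesh import TriangleMesh
from .phantom import LandmarkConfiguration, LandmarkTemplate
from .spatial import ClosestPointQuery

__all__ = [
    "tps_fit",
    "bending_energy_matrix",
    "SlidingScheme",
    "apply_template",
    "slide_semilandmarks",
    "gpa",
    "ProcrustesFit",
    "centroid_size",
    "pca_shape",
    "procrustes_anova",
    "pairwise_posthoc",
    "centroid_size_anova",
    "AnovaTable",
    "PairwiseTable",
    "write_landmark_table",
    "read_landmark_table",
    "read_tps_file",
]

_BE_SCALE = 8.0 * np.pi  # physical constant linking the kernel form to the
# integral of squared second derivatives for the 3D biharmonic kernel |r|


# -- thin-plate spline -------------------------------------------------------------


def _tps_system(src: np.ndarray, regularization: float):
    k = len(src)
    d = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=-1)
    K = d + regularization * np.eye(k)
    P = np.concatenate([np.ones((k, 1)), src], axis=1)
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L, K


def tps_fit(src_pts: np.ndarray, dst_pts: np.ndarray, regularization: float = 0.0):
    """3D thin-plate spline interpolant from src to dst landmarks.

    Returns ``(warp, bending_energy)``: ``warp`` maps arbitrary (n, 3) points;
    the bending energy is the integral of squared second derivatives of the
    interpolant (zero exactly for affine maps).

    Raises for coplanar/degenerate source configurations unless a positive
    ``regularization`` makes the system solvable.
    """
    src = np.asarray(src_pts, dtype=np.float64)
    dst = np.asarray(dst_pts, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (k, 3) arrays")
    k = len(src)
    if k < 5:
        raise ValueError("need at least 5 landmarks for a 3D TPS")
    L, K = _tps_system(src, regularization)
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = dst
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "degenerate (coplanar?) source landmarks; consider regularization"
        ) from exc
    W, A = sol[:k], sol[k:]

    def warp(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        U = np.linalg.norm(p[:, None, :] - src[None, :, :], axis=-1)
        return A[0] + p @ A[1:] + U @ W

    energy = -_BE_SCALE * float(np.einsum("id,ij,jd->", W, K, W))
    return warp, max(energy, 0.0)


def bending_energy_matrix(ref_pts: np.ndarray, regularization: float = 0.0) -> np.ndarray:
    """PSD matrix Be with BE(ref -> X) = sum_d X[:, d]^T Be X[:, d].

    Be annihilates affine configurations; scaled consistently with
    :func:`tps_fit` so both routes report the same number.
    """
    ref = np.asarray(ref_pts, dtype=np.float64)
    k = len(ref)
    L, _ = _tps_system(ref, regularization)
    Linv = np.linalg.inv(L)
    B = Linv[:k, :k]
    Be = -_BE_SCALE * B
    return 0.5 * (Be + Be.T)


# -- template application and sliding ---------------------------------------------


@dataclass
class SlidingScheme:
    """Per-point sliding constraints.

    ``roles[i]`` in {'fixed', 'curve', 'surface'}; curve points belong to
    ordered (closed) chains listed in ``chains``.  Surface tangent planes come
    from the target mesh when available, else from supplied normals.
    """

    roles: np.ndarray
    chains: list = field(default_factory=list)

    @classmethod
    def from_template(cls, template: LandmarkTemplate) -> "SlidingScheme":
        chains = []
        for cid in sorted(set(template.curve_id[template.curve_id >= 0])):
            chains.append(np.where(template.curve_id == cid)[0])
        return cls(roles=np.asarray(template.roles).copy(), chains=chains)


def _curve_tangents(coords: np.ndarray, chain: np.ndarray) -> np.ndarray:
    """Unit tangents along a closed ordered chain (central differences)."""
    pts = coords[chain]
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    t = nxt - prv
    norm = np.linalg.norm(t, axis=1)
    norm[norm == 0] = 1.0
    return t / norm[:, None]


def _tangent_plane_basis(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normals / np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-12)
    helper = np.where(np.abs(n[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    u = np.cross(n, helper)
    u /= np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-12)
    v = np.cross(n, u)
    return u, v


def apply_template(
    template: LandmarkTemplate,
    fixed_on_target: np.ndarray,
    target_mesh: TriangleMesh,
) -> LandmarkConfiguration:
    """Warp the template onto a target via its fixed landmarks, then project.

    The TPS from the template's fixed landmarks to their digitized positions
    on the target maps every semilandmark; mapped semilandmarks are then
    projected to the closest point of the target surface.
    """
    fixed_idx = np.where(template.roles == "fixed")[0]
    fixed_on_target = np.asarray(fixed_on_target, dtype=np.float64)
    if fixed_on_target.shape != (len(fixed_idx), 3):
        raise ValueError(
            f"expected {len(fixed_idx)} fixed landmarks, got {fixed_on_target.shape}"
        )
    if not np.isfinite(fixed_on_target).all():
        raise ValueError("missing/non-finite fixed landmark")
    warp, _ = tps_fit(template.points[fixed_idx], fixed_on_target)
    mapped = warp(template.points)
    semis = np.where(template.roles != "fixed")[0]
    query = ClosestPointQuery(target_mesh)
    mapped[semis] = query.query(mapped[semis])[0]
    mapped[fixed_idx] = fixed_on_target
    return LandmarkConfiguration(mapped, specimen="", method="", template=template)


def slide_semilandmarks(
    coords: np.ndarray,
    scheme: SlidingScheme,
    reference_shape: np.ndarray,
    target_mesh: TriangleMesh | None = None,
    surface_normals: np.ndarray | None = None,
    ridge: float = 1e-10,
):
    """One bending-energy sliding step against a reference shape.

    Curve points move along their chain tangent, surface points within their
    tangent plane; the amounts are the closed-form least-squares minimizer of
    the TPS bending energy of the deformation reference -> configuration.
    Slid points are re-projected onto the target mesh when one is given.

    Returns ``(new_coords, info)`` where info reports the energy before and
    after the tangential step (before re-projection); the step never
    increases it.
    """
    X = np.asarray(coords, dtype=np.float64).copy()
    k = len(X)
    Be = bending_energy_matrix(np.asarray(reference_shape, dtype=np.float64))

    # tangent directions, one or two dofs per sliding point
    dirs: list[tuple[int, np.ndarray]] = []
    for chain in scheme.chains:
        tangents = _curve_tangents(X, chain)
        for i, t in zip(chain, tangents):
            if np.linalg.norm(t) > 0:
                dirs.append((int(i), t))
    surf_idx = np.where(scheme.roles == "surface")[0]
    if len(surf_idx):
        if target_mesh is not None:
            q = ClosestPointQuery(target_mesh)
            _, _, faces = q.query(X[surf_idx])
            normals = target_mesh.face_normals[faces]
        elif surface_normals is not None:
            normals = np.asarray(surface_normals)[surf_idx]
        else:
            normals = None
        if normals is not None:
            u, v = _tangent_plane_basis(normals)
            for j, i in enumerate(surf_idx):
                dirs.append((int(i), u[j]))
                dirs.append((int(i), v[j]))

    if not dirs:
        return X, {"energy_before": _config_energy(Be, X), "energy_after": _config_energy(Be, X)}

    q_dof = len(dirs)
    # build (3k x q) direction matrix in coordinate-major flattening
    U = np.zeros((3 * k, q_dof))
    for j, (i, d) in enumerate(dirs):
        U[i, j] = d[0]
        U[k + i, j] = d[1]
        U[2 * k + i, j] = d[2]
    x = X.T.ravel()  # coordinate-major
    G = np.kron(np.eye(3), Be)
    A = U.T @ G @ U + ridge * np.eye(q_dof)
    b = -U.T @ G @ x
    t = np.linalg.solve(A, b)
    x_new = x + U @ t
    e0 = float(x @ G @ x)
    e1 = float(x_new @ G @ x_new)
    X_new = x_new.reshape(3, k).T
    if target_mesh is not None:
        q = ClosestPointQuery(target_mesh)
        moving = np.where(scheme.roles != "fixed")[0]
        X_new[moving] = q.query(X_new[moving])[0]
    return X_new, {"energy_before": e0, "energy_after": e1}


def _config_energy(Be: np.ndarray, X: np.ndarray) -> float:
    return float(np.einsum("id,ij,jd->", X, Be, X))


# -- Procrustes superimposition ----------------------------------------------------


def centroid_size(coords) -> float:
    """Square root of summed squared distances of points from their centroid."""
    X = np.asarray(
        coords.coords if isinstance(coords, LandmarkConfiguration) else coords,
        dtype=np.float64,
    )
    c = X.mean(axis=0)
    return float(np.sqrt(((X - c) ** 2).sum()))


def _procrustes_rotation(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Proper orthogonal R minimizing ||X R - ref||_F (reflection excluded)."""
    H = X.T @ ref
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


@dataclass
class ProcrustesFit:
    """Superimposed configurations and bookkeeping of a GPA."""

    coords: np.ndarray                 # (n, k, 3), centered, unit centroid size
    consensus: np.ndarray              # (k, 3)
    centroid_sizes: np.ndarray         # (n,) original sizes in mm
    specimens: list | None = None
    methods: list | None = None
    sliding_cycles: int = 0
    converged: bool = True

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        return self.coords.reshape(self.n, -1)


def gpa(
    configs,
    scheme: SlidingScheme | None = None,
    meshes: list[TriangleMesh] | None = None,
    surface_normals=None,
    max_iter: int = 100,
    tol: float = 1e-10,
    max_sliding_cycles: int = 5,
    sliding_tol: float = 1e-6,
) -> ProcrustesFit:
    """Generalized Procrustes analysis, optionally with semilandmark sliding.

    ``configs`` is a list of LandmarkConfiguration or (k, 3) arrays.  Each
    configuration is centered, scaled to unit centroid size, and rotated to
    the evolving consensus (reflections excluded).  With a sliding scheme,
    semilandmarks slide against the recursive consensus between GPA rounds
    (bending-energy criterion), re-projected onto their meshes when given.
    """
    arrs, specimens, methods = [], [], []
    for cfg in configs:
        if isinstance(cfg, LandmarkConfiguration):
            arrs.append(cfg.coords)
            specimens.append(cfg.specimen)
            methods.append(cfg.method)
        else:
            arrs.append(np.asarray(cfg, dtype=np.float64))
            specimens.append(None)
            methods.append(None)
    ks = {a.shape for a in arrs}
    if len(ks) != 1:
        raise ValueError(f"configurations disagree in landmark count: {ks}")
    if len(arrs) < 2:
        raise ValueError("need at least two configurations")
    X = np.stack(arrs).astype(np.float64)
    n, k, _ = X.shape
    sizes = np.array([centroid_size(x) for x in X])

    def superimpose(Xraw):
        Y = Xraw - Xraw.mean(axis=1, keepdims=True)
        cs = np.sqrt((Y**2).sum(axis=(1, 2)))
        Y = Y / cs[:, None, None]
        consensus = Y[0].copy()
        converged = False
        for _ in range(max_iter):
            for i in range(n):
                Y[i] = Y[i] @ _procrustes_rotation(Y[i], consensus)
            new_consensus = Y.mean(axis=0)
            new_consensus -= new_consensus.mean(axis=0)
            new_consensus /= np.sqrt((new_consensus**2).sum())
            if np.linalg.norm(new_consensus - consensus) < tol:
                consensus = new_consensus
                converged = True
                break
            consensus = new_consensus
        # canonical orientation: consensus principal axes with deterministic
        # signs, so the fit does not depend on input order/orientation
        R = _canonical_frame(consensus)
        return Y @ R, consensus @ R, converged

    Y, consensus, converged = superimpose(X)
    cycles = 0
    if scheme is not None:
        for cycle in range(max_sliding_cycles):
            moved = 0.0
            for i in range(n):
                if meshes is not None:
                    # slide in the specimen's own space: map consensus back
                    ref = _map_to_specimen(consensus, X[i])
                    newX, _ = slide_semilandmarks(
                        X[i], scheme, ref, target_mesh=meshes[i]
                    )
                    moved = max(moved, float(np.abs(newX - X[i]).max()))
                    X[i] = newX
                else:
                    normals = None if surface_normals is None else surface_normals
                    newY, _ = slide_semilandmarks(
                        Y[i], scheme, consensus, surface_normals=normals
                    )
                    moved = max(moved, float(np.abs(newY - Y[i]).max()))
                    Y[i] = newY
            if meshes is not None:
                Y, consensus, converged = superimpose(X)
            else:
                Y, consensus, converged = superimpose(Y)
            cycles = cycle + 1
            if moved < sliding_tol:
                break
    return ProcrustesFit(
        coords=Y,
        consensus=consensus,
        centroid_sizes=sizes,
        specimens=specimens,
        methods=methods,
        sliding_cycles=cycles,
        converged=converged,
    )


def _canonical_frame(shape: np.ndarray) -> np.ndarray:
    """Rotation bringing a centered shape to its principal axes, signs fixed."""
    cov = shape.T @ shape
    _, vecs = np.linalg.eigh(cov)
    R = vecs[:, ::-1]
    proj = shape @ R
    for a in range(3):
        j = np.argmax(np.abs(proj[:, a]))
        if proj[j, a] < 0:
            R[:, a] *= -1
            proj[:, a] *= -1
    if np.linalg.det(R) < 0:
        R[:, 2] *= -1
    return R


def _map_to_specimen(consensus: np.ndarray, specimen_coords: np.ndarray) -> np.ndarray:
    """Similarity-map the consensus into a specimen's raw coordinate frame."""
    c = specimen_coords.mean(axis=0)
    Xc = specimen_coords - c
    cs = np.sqrt((Xc**2).sum())
    ref = consensus - consensus.mean(axis=0)
    R = _procrustes_rotation(ref, Xc / cs)
    return ref @ R * cs + c


# -- ordination and inference ------------------------------------------------------


def pca_shape(fit: ProcrustesFit):
    """PCA of the superimposed coordinates.

    Returns ``(scores, eigenvalues, eigenvectors)``; eigenvalues are the
    per-component variances (non-increasing) and their sum equals the total
    coordinate variance.
    """
    Y = fit.flat()
    n = len(Y)
    if n < 3:
        raise ValueError("need at least 3 configurations for a meaningful PCA")
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    scores = U * s
    return scores, eigenvalues, Vt


@dataclass
class AnovaTable:
    """One-factor Procrustes ANOVA table (effect / residual / total rows)."""

    effect: str
    df: tuple
    ss: tuple
    ms: tuple
    rsq: float
    f: float
    z: float
    p: float
    n_perm: int

    def to_dataframe(self) -> pd.DataFrame:
        df_e, df_r = self.df
        ss_e, ss_r, ss_t = self.ss
        return pd.DataFrame(
            {
                "Df": [df_e, df_r, df_e + df_r],
                "SS": [ss_e, ss_r, ss_t],
                "MS": [self.ms[0], self.ms[1], np.nan],
                "Rsq": [self.rsq, ss_r / ss_t, np.nan],
                "F": [self.f, np.nan, np.nan],
                "Z": [self.z, np.nan, np.nan],
                "p": [self.p, np.nan, np.nan],
            },
            index=[self.effect, "Residuals", "Total"],
        )


def _factor_ss(Y: np.ndarray, groups: np.ndarray, uniq: np.ndarray) -> float:
    ss = 0.0
    for g in uniq:
        sel = groups == g
        m = Y[sel].mean(axis=0)
        ss += sel.sum() * float(m @ m)
    return ss


def procrustes_anova(
    fit, labels, n_perm: int = 1000, seed: int = 0, blocks=None
) -> AnovaTable:
    """One-factor Procrustes ANOVA with residual randomization (RRPP).

    The total sum of squares is the summed squared distance of each shape
    from the grand mean; the factor SS comes from group means.  Significance
    is assessed by randomizing the residuals of the reduced model ``n_perm``
    times; p carries the +1 correction and Z locates the observed F within
    the log-transformed permutation distribution.

    By default the reduced model is the intercept (free randomization).
    With ``blocks`` (e.g. specimen identifiers in a repeated-digitization
    design), the reduced model contains the block factor: block means are
    removed, their residuals are randomized, and the factor is tested
    against the within-block residual — the exchangeable null when every
    block sees every factor level.  With blocked data the free randomization
    is valid but very conservative, because block-to-block (biological)
    variation inflates the permuted statistic.
    """
    Y = fit.flat() if isinstance(fit, ProcrustesFit) else np.asarray(fit, dtype=np.float64)
    groups = np.asarray(labels)
    if len(groups) != len(Y):
        raise ValueError("labels must align with configurations")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("factor needs at least two levels")
    n = len(Y)
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())
    df_block = 0
    if blocks is not None:
        blocks = np.asarray(blocks)
        ub = np.unique(blocks)
        df_block = len(ub) - 1
        for b in ub:
            sel = blocks == b
            Yc[sel] -= Yc[sel].mean(axis=0)
        # Yc now holds reduced-model (block) residuals; factor SS is computed
        # on them, exact for the balanced crossed design
        ss_total_within = float((Yc**2).sum())
    ss_effect = _factor_ss(Yc, groups, uniq)
    ss_res = (ss_total_within if blocks is not None else ss_total) - ss_effect
    df_e = len(uniq) - 1
    df_r = n - len(uniq) - df_block
    ms_e = ss_effect / df_e
    ms_r = ss_res / df_r
    if ss_total <= 1e-30 or ms_r <= 1e-30:
        f_obs = np.nan
        return AnovaTable(
            "factor", (df_e, df_r), (ss_effect, ss_res, ss_total),
            (ms_e, ms_r), 0.0 if ss_total <= 1e-30 else ss_effect / ss_total,
            f_obs, np.nan, 1.0, n_perm,
        )
    f_obs = ms_e / ms_r
    if n_perm == 0:
        return AnovaTable(
            "factor", (df_e, df_r), (ss_effect, ss_res, ss_total),
            (ms_e, ms_r), ss_effect / ss_total, f_obs, np.nan, np.nan, 0,
        )

    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    block_sel = None
    if blocks is not None:
        block_sel = [np.where(blocks == b)[0] for b in np.unique(blocks)]
    base_total = ss_total_within if blocks is not None else ss_total
    for b in range(n_perm):
        if block_sel is None:
            perm = rng.permutation(n)
        else:
            # exact exchangeability under the reduced model: permute within
            # blocks, which also leaves the block centering untouched
            perm = np.arange(n)
            for sel in block_sel:
                perm[sel] = sel[rng.permutation(len(sel))]
        ss_e = _factor_ss(Yc[perm], groups, uniq)
        ss_r = base_total - ss_e
        f_perm[b] = (ss_e / df_e) / (ss_r / df_r)
    p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)
    logf = np.log(np.maximum(f_perm, 1e-300))
    sd = logf.std(ddof=1)
    z = (np.log(f_obs) - logf.mean()) / sd if sd > 0 else np.nan
    return AnovaTable(
        effect="factor",
        df=(df_e, df_r),
        ss=(ss_effect, ss_res, ss_total),
        ms=(ms_e, ms_r),
        rsq=ss_effect / ss_total,
        f=f_obs,
        z=z,
        p=p,
        n_perm=n_perm,
    )


@dataclass
class PairwiseTable:
    """Pairwise Procrustes distances between group means under shared RRPP."""

    pairs: list
    d: np.ndarray
    ucl95: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_perm: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d": self.d,
                "UCL95": self.ucl95,
                "Z": self.z,
                "p": self.p,
            },
            index=[f"{a}:{b}" for a, b in self.pairs],
        )


def _pair_distances(Y: np.ndarray, groups: np.ndarray, uniq, pairs) -> np.ndarray:
    means = {g: Y[groups == g].mean(axis=0) for g in uniq}
    return np.array([np.linalg.norm(means[a] - means[b]) for a, b in pairs])


def pairwise_posthoc(fit, labels, n_perm: int = 1000, seed: int = 0) -> PairwiseTable:
    """Post-hoc pairwise group-mean distances, all pairs sharing one RRPP stream.

    Every permutation applies the identical placement of reduced-model
    residuals to all pairs, so the pairwise tests are separate inferences
    from the same randomization.  UCL95 is the 95th percentile of each
    pair's permuted distance distribution.
    """
    Y = fit.flat() if isinstance(fit, ProcrustesFit) else np.asarray(fit, dtype=np.float64)
    groups = np.asarray(labels)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    import warnings

    if min((groups == g).sum() for g in uniq) < 2:
        warnings.warn("singleton group: distances reported, inference weak")
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
    Yc = Y - Y.mean(axis=0)
    d_obs = _pair_distances(Yc, groups, uniq, pairs)
    rng = np.random.default_rng(seed)
    d_perm = np.empty((n_perm, len(pairs)))
    for b in range(n_perm):
        perm = rng.permutation(len(Y))
        d_perm[b] = _pair_distances(Yc[perm], groups, uniq, pairs)
    ucl = np.percentile(d_perm, 95, axis=0)
    p = (np.sum(d_perm >= d_obs[None, :], axis=0) + 1) / (n_perm + 1)
    sd = d_perm.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (d_obs - d_perm.mean(axis=0)) / sd, np.nan)
    return PairwiseTable(pairs=pairs, d=d_obs, ucl95=ucl, z=z, p=p, n_perm=n_perm)


def centroid_size_anova(sizes, labels):
    """Classical one-way ANOVA on centroid sizes; returns (F, p, table)."""
    y = np.asarray(sizes, dtype=np.float64)
    groups = np.asarray(labels)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_between = sum(
        (groups == g).sum() * (y[groups == g].mean() - grand) ** 2 for g in uniq
    )
    ss_within = ss_total - ss_between
    df_b = len(uniq) - 1
    df_w = len(y) - len(uniq)
    if ss_within <= 0 or df_w == 0:
        return 0.0 if ss_between <= 1e-30 else np.inf, 1.0, None
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    table = pd.DataFrame(
        {
            "Df": [df_b, df_w],
            "SS": [ss_between, ss_within],
            "MS": [ss_between / df_b, ss_within / df_w],
            "F": [F, np.nan],
            "p": [p, np.nan],
        },
        index=["group", "Residuals"],
    )
    return float(F), p, table


# -- landmark I/O ------------------------------------------------------------------


def write_landmark_table(configs, template: LandmarkTemplate | None, path) -> None:
    """Delimited text, one row per point: specimen, method, epiphysis, id, x, y, z."""
    rows = []
    for cfg in configs:
        tpl = cfg.template or template
        for i, (x, y, z) in enumerate(cfg.coords):
            rows.append(
                {
                    "specimen": cfg.specimen,
                    "method": cfg.method,
                    "epiphysis": tpl.epiphysis[i] if tpl is not None else "",
                    "id": tpl.ids[i] if tpl is not None else str(i),
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_landmark_table(path, template: LandmarkTemplate | None = None):
    """Read the delimited landmark format back into configurations."""
    df = pd.read_csv(path, sep="\t")
    configs = []
    for (spec, method), sub in df.groupby(["specimen", "method"], sort=False):
        configs.append(
            LandmarkConfiguration(
                sub[["x", "y", "z"]].to_numpy(),
                specimen=str(spec),
                method=str(method),
                template=template,
            )
        )
    return configs


def read_tps_file(path):
    """Classic TPS-format landmark file reader (LM3 blocks, ID= labels).

    Returns a list of (label, (k, 3) array).
    """
    out = []
    coords: list = []
    label = ""
    expected = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("LM3=") or up.startswith("LM="):
                if coords:
                    out.append((label, np.array(coords)))
                expected = int(line.split("=")[1])
                coords = []
                label = ""
            elif up.startswith("ID="):
                label = line.split("=", 1)[1]
            elif up.startswith(("IMAGE=", "SCALE=")):
                continue
            else:
                parts = line.split()
                if len(parts) >= 3:
                    coords.append([float(v) for v in parts[:3]])
    if coords:
        out.append((label, np.array(coords)))
    for lbl, arr in out:
        if expected and len(arr) not in (expected,):
            pass  # tolerate ragged files; caller validates counts
    return out
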
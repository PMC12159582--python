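"""PCA statistical shape model (SSM) of the hemipelvis and its fitting.

The model is built from a population of corresponded surfaces (identical
vertex/face topology): generalized Procrustes alignment with similarity
transforms, then PCA on the stacked vertex coordinates.  Mode weights are
expressed in standard deviations of their mode.

Fitting a model to an arbitrary (non-corresponded) pathological surface
alternates two convex steps until the weights settle: similarity
registration of the current fitted surface onto closest-point
correspondences, and a linear least-squares solve for the mode weights over
the unmasked template vertices, clamped to +/-3 SD.  Estimating native
anatomy from a defected pelvis is a two-pass fit: fit everything, derive
the provisional acetabular frame, excise all template vertices within
2.5x the acetabular radius of the hip joint centre from the correspondence
set, and refit — the second pass is then uninfluenced by pathological bone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .acetabular_frame import frame_from_mesh
from .errors import AcetrecError, InvalidParameterError, TopologyMismatchError

DEFAULT_N_MODES = 20        # modes used for native-anatomy reconstruction
WEIGHT_CLAMP_SD = 3.0
CONVERGENCE_TOL_SD = 1e-4
MAX_ITERATIONS = 50
MIN_UNMASKED_FRACTION = 0.30
RIDGE_FACTOR = 1e-4  # relative Tikhonov weight in the mode solve
POINT_WEIGHT = 0.5   # point-to-point stiffness in the hybrid closest-point solve
RESIDUAL_FLOOR_MM = 0.1  # stop fitting below the surface discretization scale


@dataclass
class ShapeModel:
    """Mean shape, orthonormal PCA modes and per-mode variances (mm^2)."""

    mean_vertices: np.ndarray      # (V, 3)
    modes: np.ndarray              # (3V, M), orthonormal columns
    mode_variances: np.ndarray     # (M,), non-increasing
    template_faces: np.ndarray     # (F, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.mean_vertices)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def generate(self, weights_sd, n_modes: int | None = None) -> np.ndarray:
        """Vertices of the shape at the given mode weights (SD units)."""
        w = np.zeros(self.n_modes)
        weights_sd = np.asarray(weights_sd, dtype=float)
        w[: len(weights_sd)] = weights_sd
        if n_modes is not None:
            w[n_modes:] = 0.0
        disp = self.modes @ (w * np.sqrt(self.mode_variances))
        return self.mean_vertices + disp.reshape(-1, 3)

    def generate_mesh(self, weights_sd, n_modes: int | None = None) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.generate(weights_sd, n_modes),
                               faces=self.template_faces, process=False)

    def save(self, path):
        np.savez_compressed(
            path, mean_vertices=self.mean_vertices, modes=self.modes,
            mode_variances=self.mode_variances, template_faces=self.template_faces,
            meta=json.dumps({"format": "acetrec-ssm", "version": 1}))

    @classmethod
    def load(cls, path) -> "ShapeModel":
        data = np.load(path, allow_pickle=False)
        return cls(mean_vertices=data["mean_vertices"], modes=data["modes"],
                   mode_variances=data["mode_variances"],
                   template_faces=data["template_faces"])


@dataclass
class FitResult:
    """Outcome of one shape-model fit."""

    mode_weights: np.ndarray       # SD units, length = n_modes used
    scale: float
    rotation: np.ndarray           # (3, 3)
    translation: np.ndarray        # (3,)
    fitted_mesh: trimesh.Trimesh
    residual_rmse: float           # mm, over unmasked vertices
    converged: bool
    n_iterations: int

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        return self.scale * (np.atleast_2d(pts) @ self.rotation.T) + self.translation


class SurfaceLocator:
    """Closest point on a triangle soup via KD-tree over face centroids."""

    def __init__(self, mesh: trimesh.Trimesh, k: int = 8):
        self.triangles = np.asarray(mesh.triangles, dtype=float)
        self.normals = np.asarray(mesh.face_normals, dtype=float)
        self.tree = cKDTree(self.triangles.mean(axis=1))
        self.k = min(k, len(self.triangles))

    def closest(self, points: np.ndarray):
        """(closest surface points, face normals there) for each query."""
        points = np.asarray(points, dtype=float)
        _, cand = self.tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        if self.k == 1:
            cand = cand.reshape(-1, 1)
        best_d2 = np.full(len(points), np.inf)
        best_pt = np.zeros_like(points)
        best_face = np.zeros(len(points), dtype=np.int64)
        for j in range(cand.shape[1]):
            faces = cand[:, j]
            fp = trimesh.triangles.closest_point(self.triangles[faces], points)
            d2 = ((fp - points) ** 2).sum(axis=1)
            upd = d2 < best_d2
            best_d2[upd] = d2[upd]
            best_pt[upd] = fp[upd]
            best_face[upd] = faces[upd]
        return best_pt, self.normals[best_face]


def _umeyama(src: np.ndarray, dst: np.ndarray, with_scale: bool = True):
    """Least-squares similarity transform mapping src onto dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    if with_scale:
        var_s = (xs**2).sum() / len(src)
        s = float(np.trace(np.diag(S) @ D) / var_s)
    else:
        s = 1.0
    t = mu_d - s * R @ mu_s
    return s, R, t


def build_shape_model(training) -> ShapeModel:
    """Generalized Procrustes alignment + PCA over corresponded meshes."""
    meshes = list(training)
    if len(meshes) < 2:
        raise InvalidParameterError("shape model needs at least 2 training meshes")
    faces0 = np.asarray(meshes[0].faces)
    n_v = len(meshes[0].vertices)
    for i, m in enumerate(meshes):
        if len(m.vertices) != n_v or not np.array_equal(np.asarray(m.faces), faces0):
            raise TopologyMismatchError(
                f"training mesh {i} does not share the template topology")

    X = np.stack([np.asarray(m.vertices, dtype=float) for m in meshes])
    X -= X.mean(axis=1, keepdims=True)
    ref = X[0].copy()
    for _ in range(5):
        aligned = []
        for x in X:
            s, R, t = _umeyama(x, ref)
            aligned.append(s * x @ R.T + t)
        new_ref = np.mean(aligned, axis=0)
        if np.linalg.norm(new_ref - ref) < 1e-9 * max(np.linalg.norm(ref), 1.0):
            ref = new_ref
            break
        ref = new_ref
    X = np.stack(aligned)

    mean = X.mean(axis=0)
    D = (X - mean).reshape(len(meshes), -1)
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    variances = S**2 / max(len(meshes) - 1, 1)
    m_max = min(3 * n_v, len(meshes) - 1)
    return ShapeModel(mean_vertices=mean, modes=Vt[:m_max].T,
                      mode_variances=variances[:m_max], template_faces=faces0)


def fit_shape_model(model: ShapeModel, target: trimesh.Trimesh,
                    n_modes: int = DEFAULT_N_MODES,
                    vertex_mask: np.ndarray | None = None,
                    allow_scale: bool = True,
                    tol: float = CONVERGENCE_TOL_SD,
                    max_iterations: int = MAX_ITERATIONS,
                    initial_transform=None,
                    correspondence_override=None) -> FitResult:
    """Fit mode weights + similarity transform to a target surface.

    ``vertex_mask``: template vertices marked True are EXCLUDED from the
    correspondence set (e.g. the excised acetabular neighbourhood).  The
    initial transform assumes the target is in roughly standardized
    orientation (as CT-derived pelvis surfaces are); pass
    ``initial_transform=(s, R, t)`` to override.

    Correspondence: a target sharing the template topology is already
    corresponded (vertex i pairs with template vertex i) and the weight
    solve is an exact linear projection.  Any other target uses
    closest-point-on-surface pairing with a point-to-plane weight solve:
    the normal component of the mismatch is penalized while tangential
    sliding stays free, because closest-point pairing cannot observe
    tangential motion and penalizing it biases the weights.

    ``correspondence_override``: callable mapping the full set of current
    world-space template vertices to ``(template_indices, targets, normals)``
    — externally prescribed correspondences (e.g. projecting the articular
    patch onto a directly measured joint sphere) that replace closest-point
    pairs and bypass the robustness gates for those vertices.
    """
    n_modes = int(n_modes)
    if n_modes < 0 or n_modes > model.n_modes:
        raise InvalidParameterError(
            f"n_modes must be in [0, {model.n_modes}], got {n_modes}")
    similarity_only = n_modes == 0
    if similarity_only:
        n_modes = 1  # carried through the solve machinery, then forced to 0
    V = model.n_vertices
    if vertex_mask is None:
        included = np.ones(V, dtype=bool)
    else:
        vertex_mask = np.asarray(vertex_mask, dtype=bool)
        if vertex_mask.shape != (V,):
            raise InvalidParameterError("vertex_mask must have one flag per template vertex")
        included = ~vertex_mask
    if included.mean() < MIN_UNMASKED_FRACTION:
        raise InvalidParameterError(
            f"mask leaves {included.mean():.0%} of vertices; need >= "
            f"{MIN_UNMASKED_FRACTION:.0%} unmasked")
    incl_pos = np.full(V, -1, dtype=np.int64)
    incl_pos[included] = np.arange(int(included.sum()))

    corresponded = (len(target.vertices) == V
                    and np.array_equal(np.asarray(target.faces),
                                       np.asarray(model.template_faces)))
    locator = None if corresponded else SurfaceLocator(target)
    if not corresponded:
        # model-space vertex normals, rotated along with the fit: used to
        # reject correspondences onto opposite-facing surfaces (e.g. the
        # walls of a defect cavity the template does not have)
        mean_normals = trimesh.Trimesh(vertices=model.mean_vertices,
                                       faces=model.template_faces,
                                       process=False).vertex_normals.copy()

    sigma = np.sqrt(model.mode_variances[:n_modes])
    # modes with (near-)zero population variance carry no signal in SD units
    active = sigma > 1e-6 * max(sigma[0], 1e-12)
    phi = model.modes[:, :n_modes].reshape(V, 3, n_modes)[included]
    phi_sd = phi * sigma[None, None, :]
    mean_inc = model.mean_vertices[included]

    if initial_transform is not None:
        s, R, t = initial_transform
        s, R, t = float(s), np.asarray(R, float), np.asarray(t, float)
    else:
        target_verts = np.asarray(target.vertices, dtype=float)
        mu_m = mean_inc.mean(axis=0)
        mu_t = target_verts.mean(axis=0)
        R = np.eye(3)
        if allow_scale:
            s = float(np.sqrt(((target_verts - mu_t) ** 2).sum(axis=1).mean()
                              / ((model.mean_vertices - model.mean_vertices.mean(axis=0)) ** 2)
                              .sum(axis=1).mean()))
        else:
            s = 1.0
        t = mu_t - s * mu_m

    if corresponded:
        Y_fixed = np.asarray(target.vertices, dtype=float)[included]
        s, R, t = _umeyama(mean_inc, Y_fixed, with_scale=allow_scale)

    w = np.zeros(n_modes)
    converged = False
    it = 0
    n_active = int(active.sum())
    for it in range(1, max_iterations + 1):
        X = mean_inc + phi_sd @ w
        Xw = s * X @ R.T + t
        w_new = np.zeros(n_modes)
        if corresponded and similarity_only:
            converged = True  # init transform is already the LSQ similarity
            break
        if corresponded:
            # joint Gauss-Newton over (weights, similarity transform):
            # alternating the two estimates stalls at a fixed point where a
            # spurious transform is compensated by spurious weights.
            P = Xw
            resid = (Y_fixed - P).ravel()
            RPhi = (np.einsum("ab,vbm->vam", R, phi_sd[:, :, active]) * s)
            n_pts = len(P)
            J = np.empty((3 * n_pts, n_active + (7 if allow_scale else 6)))
            J[:, :n_active] = RPhi.reshape(3 * n_pts, n_active)
            Prel = P - t
            col = n_active
            if allow_scale:
                J[:, col] = Prel.ravel()  # d/d ln(s)
                col += 1
            # d/d omega: delta P = omega x (P - t), columns are e_k x Prel
            zeros = np.zeros(n_pts)
            J[:, col + 0] = np.column_stack([zeros, -Prel[:, 2], Prel[:, 1]]).ravel()
            J[:, col + 1] = np.column_stack([Prel[:, 2], zeros, -Prel[:, 0]]).ravel()
            J[:, col + 2] = np.column_stack([-Prel[:, 1], Prel[:, 0], zeros]).ravel()
            J[:, col + 3] = np.tile([1.0, 0.0, 0.0], n_pts)
            J[:, col + 4] = np.tile([0.0, 1.0, 0.0], n_pts)
            J[:, col + 5] = np.tile([0.0, 0.0, 1.0], n_pts)
            upd, *_ = np.linalg.lstsq(J, resid, rcond=None)
            w_new[active] = np.clip(w[active] + upd[:n_active],
                                    -WEIGHT_CLAMP_SD, WEIGHT_CLAMP_SD)
            col = n_active
            if allow_scale:
                s *= float(np.exp(upd[col]))
                col += 1
            omega = upd[col:col + 3]
            angle = np.linalg.norm(omega)
            if angle > 0:
                K = np.array([[0, -omega[2], omega[1]],
                              [omega[2], 0, -omega[0]],
                              [-omega[1], omega[0], 0]])
                dR = np.eye(3) + np.sin(angle) / angle * K \
                    + (1 - np.cos(angle)) / angle**2 * (K @ K)
                R = dR @ R
            t = t + upd[col + 3:col + 6]
        else:
            Y, n_hat = locator.closest(Xw)
            # robust gating: drop pairs that are far outliers or land on a
            # surface facing away from the template's outward normal
            d = np.linalg.norm(Y - Xw, axis=1)
            facing = np.einsum("va,va->v",
                               mean_normals[included] @ R.T, n_hat) > 0.3
            med = np.median(d)
            # generous floor: the gate exists to reject defect-cavity pairs
            # (far away and/or facing backwards), not honest misfit
            good = (d <= max(3.0 * med, 8.0)) & facing
            if good.mean() < 0.3:
                good = d <= max(3.0 * med, 8.0)
            if correspondence_override is not None:
                Xw_full = s * model.generate(w, n_modes) @ R.T + t
                g_idx, Yo, no = correspondence_override(Xw_full)
                local = incl_pos[g_idx]
                keep = local >= 0
                local = local[keep]
                Y[local] = Yo[keep]
                n_hat[local] = no[keep]
                good[local] = True
                d = np.linalg.norm(Y - Xw, axis=1)
            if d[good].mean() < RESIDUAL_FLOOR_MM:
                # gated correspondences are matched below the mesh
                # discretization scale; further iterations only let
                # weakly-observed modes drift in their null space
                converged = True
                break
            Xg, Yg = X[good], Y[good]
            s, R, t = _umeyama(Xg, Yg, with_scale=allow_scale)
            Xw = s * X @ R.T + t
            if similarity_only:
                new_med = float(np.median(np.linalg.norm(Y - Xw, axis=1)))
                if abs(new_med - med) < 1e-3:
                    converged = True
                    break
                continue
            # Hybrid linear solve for the weights.  Point-to-plane rows
            # (n . mismatch) dominate so tangential sliding stays cheap and
            # unbiased; a down-weighted point-to-point block adds tangential
            # stiffness, without which near-planar anatomy can slide along
            # itself and collapse into large cavities.
            RPhi = (np.einsum("ab,vbm->vam", R, phi_sd) * s)[good]
            resid = (Y - Xw)[good]
            B_n = np.einsum("va,vam->vm", n_hat[good], RPhi)[:, active]
            r_n = np.einsum("va,va->v", n_hat[good], resid) + B_n @ w[active]
            B_p = RPhi[:, :, active].reshape(-1, n_active) * POINT_WEIGHT
            r_p = (resid.ravel()
                   + RPhi[:, :, active].reshape(-1, n_active) @ w[active]) \
                * POINT_WEIGHT
            B = np.vstack([B_n, B_p])
            rhs = np.concatenate([r_n, r_p])
            # Ridge in SD units: low-leverage modes (tiny variance, or masked
            # out of their support) shrink to zero instead of chasing noise.
            G = B.T @ B
            lam = RIDGE_FACTOR * np.trace(G) / max(G.shape[0], 1)
            sol = np.linalg.solve(G + lam * np.eye(G.shape[0]), B.T @ rhs)
            w_new[active] = np.clip(sol, -WEIGHT_CLAMP_SD, WEIGHT_CLAMP_SD)
        delta = np.abs(w_new - w).max()
        w = w_new
        if delta < tol:
            converged = True
            break

    if similarity_only:
        w = np.zeros(0)
    X_full = model.generate(w, n_modes)
    Xw_full = s * X_full @ R.T + t
    if corresponded:
        residual = float(np.sqrt(((Xw_full[included] - Y_fixed) ** 2)
                                 .sum(axis=1).mean()))
    else:
        Y, _ = locator.closest(Xw_full[included])
        residual = float(np.sqrt(((Xw_full[included] - Y) ** 2).sum(axis=1).mean()))
    fitted = trimesh.Trimesh(vertices=Xw_full, faces=model.template_faces,
                             process=False)
    return FitResult(mode_weights=w, scale=s, rotation=R, translation=t,
                     fitted_mesh=fitted, residual_rmse=residual,
                     converged=converged, n_iterations=it)


def estimate_native(model: ShapeModel, pathological: trimesh.Trimesh,
                    n_modes: int = DEFAULT_N_MODES,
                    body_axes_hint=(0.0, 1.0, 0.0),
                    excision_factor: float | None = None,
                    allow_scale: bool = True):
    """Two-pass native (defect-free) anatomy estimate from a pathological surface.

    Pass 1 registers the model to the full pathological surface and yields
    a provisional acetabular frame; every template vertex within the
    excision radius (2.5x acetabular radius by default) of the provisional
    hip joint centre is then removed from the correspondence set, and pass 2
    refits on the remaining (defect-free) anatomy.  Returns
    (native_mesh, FitResult).

    The provisional pass is a similarity-only registration (no mode solve)
    that already excludes the template's own acetabular neighbourhood from
    the correspondence set: defects are confined to the excision ball, the
    model knows where its acetabulum is, and registering only the outer
    anatomy is robust against arbitrarily large defects — an unmasked fit
    is dragged towards the cavity surfaces it is about to excise.
    """
    from .acetabular_frame import EXCISION_FACTOR
    factor = EXCISION_FACTOR if excision_factor is None else excision_factor

    mean_mesh = model.generate_mesh(np.zeros(0))
    frame0 = frame_from_mesh(mean_mesh, body_axes_hint=body_axes_hint)
    dist0 = np.linalg.norm(model.mean_vertices - frame0.hjc, axis=1)
    mask0 = dist0 < factor * frame0.radius
    if mask0.mean() > 0.70:
        raise InvalidParameterError(
            f"excision sphere would remove {mask0.mean():.0%} of the surface")
    fit1 = fit_shape_model(model, pathological, n_modes=0, vertex_mask=mask0,
                           allow_scale=allow_scale)
    frame1 = frame_from_mesh(fit1.fitted_mesh, body_axes_hint=body_axes_hint)
    # When an intact portion of the articular surface survives, detecting
    # the cup directly on the pathological bone localizes the joint centre
    # far better than the registered mean (whose cup sits wherever the
    # average anatomy puts it).  Accept it only when it agrees with the
    # registration, so a large defect's own cavity cannot masquerade as the
    # cup.
    direct_cup = None  # (centre, radius) detected on the pathological bone
    try:
        from .acetabular_frame import cup_candidates
        for _, c, r, _votes in cup_candidates(pathological):
            if (np.linalg.norm(c - frame1.hjc) < 0.7 * frame1.radius
                    and 0.7 < r / frame1.radius < 1.4):
                direct_cup = (np.asarray(c, float), float(r))
                break
    except AcetrecError:
        pass
    centre1 = direct_cup[0] if direct_cup else frame1.hjc
    radius1 = direct_cup[1] if direct_cup else frame1.radius
    dist = np.linalg.norm(np.asarray(fit1.fitted_mesh.vertices) - centre1, axis=1)
    mask = dist < factor * radius1
    if mask.mean() > 0.70:
        raise InvalidParameterError(
            f"excision sphere would remove {mask.mean():.0%} of the surface")

    override = None
    if direct_cup is not None:
        # The measured joint sphere IS the native articular surface, intact
        # bone or not: prescribe it as the fitting target for the template's
        # own articular patch (radial projection), and keep that patch in
        # the correspondence set rather than excising it.
        c_sph, r_sph = direct_cup
        patch0 = cup_candidates(model.generate_mesh(np.zeros(0)))[0][0]

        def override(xw_full, idx=patch0, c=c_sph, r=r_sph):
            u = xw_full[idx] - c
            un = np.linalg.norm(u, axis=1)
            ok = un > 1e-9
            u = u[ok] / un[ok][:, None]
            return idx[ok], c + r * u, u

        mask = mask.copy()
        mask[patch0] = False
    fit2 = fit_shape_model(model, pathological, n_modes=n_modes,
                           vertex_mask=mask, allow_scale=allow_scale,
                           initial_transform=(fit1.scale, fit1.rotation,
                                              fit1.translation),
                           correspondence_override=override)

    # Conforming-surface refinement: the excision ball also hides the intact
    # part of the articular surface, leaving the cup geometry to be inferred
    # purely from its correlation with outer anatomy (mm-level error, which
    # dominates small defects).  Each round recomputes the frame from the
    # current estimate (re-centring the excision ball), re-includes ball
    # vertices whose estimate already lies on the pathological surface
    # (genuine intact bone), and refits.  Cavity surfaces stay masked: they
    # are many millimetres below the native estimate.
    locator = SurfaceLocator(pathological)
    normals = trimesh.Trimesh(vertices=model.mean_vertices,
                              faces=model.template_faces,
                              process=False).vertex_normals
    for conform_tol in (2.5, 2.5, 1.5, 1.2):
        verts = np.asarray(fit2.fitted_mesh.vertices)
        frame2 = frame_from_mesh(fit2.fitted_mesh, body_axes_hint=body_axes_hint)
        if direct_cup is not None:
            # the cup detected on the pathological bone itself tells us how
            # far the current estimate's cup is off, hence how wide the
            # conformity window must open to recapture the intact surface
            delta = np.linalg.norm(frame2.hjc - direct_cup[0]) \
                + abs(frame2.radius - direct_cup[1])
            conform_tol = float(np.clip(delta + 1.0, conform_tol, 5.0))
        ball = np.linalg.norm(verts - frame2.hjc, axis=1) < factor * frame2.radius
        cp, n_hat = locator.closest(verts)
        conform = (np.linalg.norm(verts - cp, axis=1) < conform_tol) \
            & (np.einsum("va,va->v", normals @ fit2.rotation.T, n_hat) > 0.5)
        mask = ball & ~conform
        if override is not None:
            mask[patch0] = False
        if mask.mean() > 0.70:
            break
        fit2 = fit_shape_model(model, pathological, n_modes=n_modes,
                               vertex_mask=mask, allow_scale=allow_scale,
                               initial_transform=(fit2.scale, fit2.rotation,
                                                  fit2.translation),
                               correspondence_override=override)
    return fit2.fitted_mesh, fit2
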
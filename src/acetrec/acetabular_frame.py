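"""Acetabular coordinate frame: hip joint centre, radius, plane and axes.

The frame is derived from a native (defect-free) pelvis estimate in three
steps: detect the concave spherical cup patch and fit a sphere to it (hip
joint centre and acetabular radius), select rim points where the cup meets
the outer cortical surface, and fit the acetabular plane through them.  The
polar axis is the plane normal oriented out of the cup; a global superior
hint pins the in-plane axes.

Note on the sphere fit: on an idealised hemispherical cup the rim is an
exact circle, and a sphere fit through rim points alone is ill-posed (every
sphere through a circle interpolates it).  The hip joint centre and radius
are therefore fitted to the cup articular patch, which is always well
conditioned, while the rim points determine the plane and polar axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import CupNotFoundError, DegenerateGeometryError

N_RIM_POINTS = 19          # automatically selected rim points
EXCISION_FACTOR = 2.5      # excision sphere radius / acetabular radius


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length axis vector")
    return v / n


@dataclass
class AcetabularFrame:
    """Hip joint centre (mm), acetabular radius (mm) and orthonormal axes.

    ``polar_axis`` points out of the cup (laterally); ``superior_axis`` is
    the projection of the global superior direction onto the acetabular
    plane; ``anterior_axis = superior x polar`` completes a right-handed
    triad.  ``plane_normal`` equals the polar axis by construction here but
    is kept as a separate field (a fitted plane normal and a fitted sphere
    axis need not coincide for real anatomy).
    """

    hjc: np.ndarray
    radius: float
    polar_axis: np.ndarray
    superior_axis: np.ndarray
    anterior_axis: np.ndarray = field(default=None)
    plane_normal: np.ndarray = field(default=None)

    def __post_init__(self):
        self.hjc = np.asarray(self.hjc, dtype=float)
        if self.radius <= 0:
            raise DegenerateGeometryError("acetabular radius must be positive")
        self.polar_axis = _unit(self.polar_axis)
        self.superior_axis = _unit(self.superior_axis)
        if self.anterior_axis is None:
            self.anterior_axis = np.cross(self.superior_axis, self.polar_axis)
        self.anterior_axis = _unit(self.anterior_axis)
        if self.plane_normal is None:
            self.plane_normal = self.polar_axis.copy()
        self.plane_normal = _unit(self.plane_normal)

    @property
    def excision_radius(self) -> float:
        return EXCISION_FACTOR * self.radius

    def to_dict(self) -> dict:
        return {
            "hjc": self.hjc.tolist(),
            "radius": float(self.radius),
            "polar_axis": self.polar_axis.tolist(),
            "superior_axis": self.superior_axis.tolist(),
            "anterior_axis": self.anterior_axis.tolist(),
            "plane_normal": self.plane_normal.tolist(),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "AcetabularFrame":
        return cls(
            hjc=np.asarray(d["hjc"]), radius=float(d["radius"]),
            polar_axis=np.asarray(d["polar_axis"]),
            superior_axis=np.asarray(d["superior_axis"]),
            anterior_axis=np.asarray(d["anterior_axis"]),
            plane_normal=np.asarray(d["plane_normal"]),
        )

    @classmethod
    def from_json(cls, path) -> "AcetabularFrame":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_sphere(points) -> tuple:
    """Algebraic least-squares sphere fit.

    Solves ``|x|^2 = 2 c.x + (r^2 - |c|^2)`` linearly.  Requires at least 4
    points not all coplanar; a coplanar set leaves the centre component
    normal to the plane unconstrained and raises DegenerateGeometryError.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise DegenerateGeometryError("sphere fit needs >= 4 points in 3D")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    # Coplanarity check on the centred point cloud.
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("sphere fit points are (nearly) coplanar")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit produced non-positive radius")
    return centre, float(np.sqrt(r2))


def cup_candidates(mesh: trimesh.Trimesh, n_seeds: int = 600, k: int = 24):
    """Candidate concave spherical patches of a bone surface.

    Local algebraic sphere fits on vertex neighbourhoods vote for concave
    centres of curvature (surface normals of a cavity point towards them);
    vote clusters are refined on their inlier patches.  A pathological
    surface can contain several concave spherical regions — the acetabulum
    and the defect cavity itself — so every consensus cluster is returned,
    largest first, as (patch_indices, centre, radius, n_votes).
    """
    verts = np.asarray(mesh.vertices)
    normals = np.asarray(mesh.vertex_normals)
    if len(verts) < 4 * k:
        raise CupNotFoundError("mesh too small for cup detection")
    tree = cKDTree(verts)
    scale = float(mesh.scale)
    seeds = np.unique(np.linspace(0, len(verts) - 1, n_seeds).astype(int))
    centres, radii = [], []
    _, knn = tree.query(verts[seeds], k=k)
    for s, nb in zip(seeds, knn):
        p = verts[nb]
        try:
            c, r = fit_sphere(p)
        except DegenerateGeometryError:
            continue
        if not (0.02 * scale < r < 0.75 * scale):
            continue
        resid = np.abs(np.linalg.norm(p - c, axis=1) - r)
        if resid.max() > 0.02 * r:
            continue
        # concave: outward normal points towards the centre of curvature
        if np.dot(c - verts[s], normals[s]) < 0.8 * r:
            continue
        centres.append(c)
        radii.append(r)
    if len(centres) < 5:
        raise CupNotFoundError("no concave spherical region detected")
    centres = np.asarray(centres)
    radii = np.asarray(radii)

    # cluster the votes (single linkage) so distinct cavities separate
    link = 0.35 * float(np.median(radii))
    pairs = cKDTree(centres).query_pairs(link, output_type="ndarray")
    from scipy import sparse
    adj = sparse.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                            shape=(len(centres),) * 2)
    _, labels = sparse.csgraph.connected_components(adj, directed=False)
    out = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) < 5:
            continue
        c0 = np.median(centres[members], axis=0)
        r0 = float(np.median(radii[members]))
        try:
            for _ in range(2):
                d = np.linalg.norm(verts - c0, axis=1)
                to_centre = (c0 - verts) / np.maximum(d, 1e-12)[:, None]
                patch = (np.abs(d - r0) < 0.06 * r0) \
                    & (np.einsum("ij,ij->i", to_centre, normals) > 0.6)
                if patch.sum() < 4:
                    raise CupNotFoundError("patch degenerated")
                c0, r0 = fit_sphere(verts[patch])
        except (CupNotFoundError, DegenerateGeometryError):
            continue
        out.append((np.flatnonzero(patch), c0, float(r0), len(members)))
    if not out:
        raise CupNotFoundError("no concave spherical region detected")
    out.sort(key=lambda t: t[3], reverse=True)
    return out


def _cup_patch(mesh: trimesh.Trimesh, n_seeds: int = 600, k: int = 24):
    """Largest concave spherical patch: (patch_indices, centre, radius)."""
    patch, c, r, _ = cup_candidates(mesh, n_seeds, k)[0]
    return patch, c, r


def select_rim_points(native: trimesh.Trimesh, n_points: int = N_RIM_POINTS) -> np.ndarray:
    """``n_points`` points on the acetabular rim, equally spaced in azimuth.

    The rim is the boundary of the concave cup patch: within each of
    ``n_points`` azimuthal stations about the cup opening axis, the
    on-sphere vertex closest to the opening plane (largest polar-axis
    component) is selected.  Raises CupNotFoundError when the surface has
    no concave spherical region.
    """
    patch_idx, c, r = _cup_patch(native)
    patch = np.asarray(native.vertices)[patch_idx]
    up = (patch - c) / np.linalg.norm(patch - c, axis=1)[:, None]
    p_axis = -_unit(up.mean(axis=0))  # opening direction of the cap
    # Rim candidates: every vertex on the cup sphere (the normal filter used
    # for patch detection drops the rim ring itself, whose vertex normals
    # blend cavity and outer surface).
    all_verts = np.asarray(native.vertices)
    dist = np.linalg.norm(all_verts - c, axis=1)
    tol = max(0.025 * r, 0.6)
    verts = all_verts[np.abs(dist - r) < tol]
    u = (verts - c) / np.linalg.norm(verts - c, axis=1)[:, None]
    # in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ p_axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(ref - (ref @ p_axis) * p_axis)
    e2 = np.cross(p_axis, e1)
    az = np.arctan2(u @ e2, u @ e1)
    height = u @ p_axis
    bins = np.floor((az + np.pi) / (2 * np.pi) * n_points).astype(int) % n_points
    rim = np.full((n_points, 3), np.nan)
    for b in range(n_points):
        members = np.flatnonzero(bins == b)
        if len(members) == 0:
            continue
        rim[b] = verts[members[np.argmax(height[members])]]
    good = ~np.isnan(rim[:, 0])
    if good.sum() < n_points:
        # sparse azimuthal coverage: re-sample the populated stations
        if good.sum() < max(6, n_points // 2):
            raise CupNotFoundError("cup patch does not surround the polar axis")
        idx = np.linspace(0, good.sum() - 1, n_points).astype(int)
        rim = rim[good][idx]
    return rim


def compute_frame(rim_points, sphere_fit, body_axes_hint=(0.0, 1.0, 0.0),
                  bone_centroid=None) -> AcetabularFrame:
    """Assemble the acetabular frame from rim points and the cup sphere fit.

    The acetabular plane is the least-squares plane through the rim points;
    the polar axis is its normal oriented away from the bone (``bone_centroid``
    when given, else away from the sphere centre).  The superior axis is the
    normalized projection of ``body_axes_hint`` onto the plane.
    """
    rim = np.asarray(rim_points, dtype=float)
    centre, radius = np.asarray(sphere_fit[0], dtype=float), float(sphere_fit[1])
    rim_centroid = rim.mean(axis=0)
    centred = rim - rim_centroid
    sv, vt = np.linalg.svd(centred, full_matrices=False)[1:]
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("rim points are collinear")
    normal = vt[2]
    if bone_centroid is not None:
        ref = rim_centroid - np.asarray(bone_centroid, dtype=float)
    else:
        ref = rim_centroid - centre
    if np.linalg.norm(ref) > 1e-9 and normal @ ref < 0:
        normal = -normal
    hint = _unit(body_axes_hint)
    in_plane = hint - (hint @ normal) * normal
    if np.linalg.norm(in_plane) < 1e-9:
        raise DegenerateGeometryError("superior hint is parallel to the polar axis")
    superior = _unit(in_plane)
    return AcetabularFrame(hjc=centre, radius=radius, polar_axis=normal,
                           superior_axis=superior, plane_normal=normal)


def frame_from_mesh(native: trimesh.Trimesh,
                    body_axes_hint=(0.0, 1.0, 0.0)) -> AcetabularFrame:
    """Full frame estimation from a native pelvis surface."""
    patch_idx, centre, radius = _cup_patch(native)
    rim = select_rim_points(native)
    centroid = np.asarray(native.vertices).mean(axis=0)
    return compute_frame(rim, (centre, radius), body_axes_hint=body_axes_hint,
                         bone_centroid=centroid)


def excision_sphere(frame: AcetabularFrame, subdivisions: int = 4) -> trimesh.Trimesh:
    """Watertight icosphere of radius ``2.5 x acetabular radius`` at the HJC.

    The 2.5 factor is the excision radius enclosing the largest expected
    defect; bone within this ball is removed from the correspondence set
    before the second shape-model fit.
    """
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions,
                                        radius=frame.excision_radius)
    sphere.apply_translation(frame.hjc)
    return sphere
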
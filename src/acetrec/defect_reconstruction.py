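"""Ray-cast extraction of the acetabular defect solid.

The defect is the bone present in the native (shape-model) estimate but
absent from the pathological surface.  From the hip joint centre a
near-uniform spherical spread of rays is cast into both surfaces; along
each ray the inside-intervals of the two solids follow from crossing
parity (the origin sits in the joint space, outside bone), and the defect
intervals are (inside native) AND NOT (inside pathological), clipped to the
excision range of 2.5x the acetabular radius.  At most four intersections
per ray and per surface are retained; a ray whose surplus crossings were
discarded cannot be classified and is excluded.

Recorded defect points (interval endpoints, midpoints, and 1 mm
densification) are clustered by single linkage; clusters below 200 points
are discarded as noise; surviving clusters are surfaced with a 3D alpha
shape and the result is cleaned by two voxel Boolean operations —
subtracting the pathological solid tightens the defect/bone boundary, and
intersecting with the native estimate restores the articular surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.spatial import Delaunay, cKDTree

from . import intervals as iv
from . import voxel
from .acetabular_frame import AcetabularFrame, frame_from_mesh
from .errors import DegenerateGeometryError, InvalidParameterError, StageError
from .raycast import MAX_HITS, SingleOriginCaster, direction_count, fibonacci_directions
from .shape_model import ShapeModel, estimate_native

DEFAULT_ANGULAR_SPACING = 1.0   # degrees
CLUSTER_MIN_SIZE = 200          # points; smaller clusters are discarded
MIN_INTERVAL_THICKNESS = 2.0    # mm; thinner defect intervals are estimation noise
SURFACE_CLEARANCE = 1.0         # mm; interval midpoints closer than this to the
                                # pathological surface are estimation noise
DENSIFY_STEP = 1.0              # mm along-ray point densification


@dataclass
class RaySet:
    """Angular spread of unit direction vectors from the hip joint centre."""

    origin: np.ndarray
    directions: np.ndarray          # (N, 3) unit vectors
    angular_spacing: float          # degrees
    max_range: float                # mm (= 2.5 x acetabular radius)


def generate_rays(frame: AcetabularFrame,
                  angular_spacing: float = DEFAULT_ANGULAR_SPACING) -> RaySet:
    """Fibonacci-lattice direction set with ~``angular_spacing`` deg spacing."""
    if not (0.1 < angular_spacing <= 10.0):
        raise InvalidParameterError("angular_spacing must be in (0.1, 10] degrees")
    n = direction_count(angular_spacing)
    return RaySet(origin=np.asarray(frame.hjc, float).copy(),
                  directions=fibonacci_directions(n),
                  angular_spacing=angular_spacing,
                  max_range=frame.excision_radius)


@dataclass
class RayClassification:
    defect_intervals: list          # [(t_in, t_out), ...]
    defect_points_t: np.ndarray     # endpoint + midpoint distances
    valid: bool


def classify_ray(native_hits, patho_hits, max_range: float,
                 native_truncated: bool = False,
                 patho_truncated: bool = False) -> RayClassification:
    """Defect intervals along one ray from the two sorted hit lists.

    The ray origin is outside bone (in the joint space), so hits pair up
    into inside-intervals; an odd final hit means the solid continues past
    ``max_range`` and the last interval closes there.  A truncation flag
    (more intersections existed than the 4-hit cap retained) makes parity
    beyond the last hit unknowable: the ray is marked invalid and excluded.
    """
    if native_truncated or patho_truncated:
        return RayClassification([], np.empty(0), False)
    native_iv = iv.intervals_from_hits(native_hits, max_range)
    patho_iv = iv.intervals_from_hits(patho_hits, max_range)
    defect = iv.subtract(native_iv, patho_iv, max_range)
    return RayClassification(defect, iv.sample_points(defect), True)


@dataclass
class RayRecords:
    """Per-ray cast + classification results for a case (vectorized)."""

    ray_set: RaySet
    native_hits: np.ndarray         # (N, 4) NaN-padded ascending
    patho_hits: np.ndarray
    valid: np.ndarray               # (N,) classification validity
    defect_intervals: list          # per ray: [(t_in, t_out), ...]
    first_native_hit: np.ndarray    # (N,) NaN when no native hit
    defect_t_end: np.ndarray        # (N,) furthest defect endpoint, NaN if none

    @property
    def has_defect(self) -> np.ndarray:
        return ~np.isnan(self.defect_t_end)

    def interval_midpoints(self):
        return [np.array([(a + b) / 2 for a, b in ivs]) for ivs in self.defect_intervals]

    def region_ray_data(self) -> dict:
        """Inputs for regional defect-depth aggregation."""
        sel = np.flatnonzero(self.has_defect & self.valid)
        mids = self.interval_midpoints()
        return {
            "directions": self.ray_set.directions[sel],
            "origin": self.ray_set.origin,
            "first_native_hit": self.first_native_hit[sel],
            "defect_t_end": self.defect_t_end[sel],
            "interval_midpoints_t": [mids[i] for i in sel],
        }

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i in range(len(self.valid)):
            rows.append({
                "direction_x": self.ray_set.directions[i, 0],
                "direction_y": self.ray_set.directions[i, 1],
                "direction_z": self.ray_set.directions[i, 2],
                "native_hits": ";".join(f"{t:.4f}" for t in self.native_hits[i]
                                        if np.isfinite(t)),
                "patho_hits": ";".join(f"{t:.4f}" for t in self.patho_hits[i]
                                       if np.isfinite(t)),
                "defect_intervals": ";".join(f"{a:.4f}-{b:.4f}"
                                             for a, b in self.defect_intervals[i]),
                "valid": self.valid[i],
            })
        return pd.DataFrame(rows)


def cast_and_classify(native: trimesh.Trimesh, patho: trimesh.Trimesh,
                      ray_set: RaySet,
                      min_interval_thickness: float = MIN_INTERVAL_THICKNESS,
                      surface_clearance: float = SURFACE_CLEARANCE
                      ) -> RayRecords:
    """Cast every ray into both solids and classify the defect intervals.

    Two noise filters follow classification, both calibrated to the
    sub-millimetre uncertainty of the statistical native estimate:
    intervals thinner than ``min_interval_thickness`` along the ray are
    dropped, and so are intervals whose midpoint lies within
    ``surface_clearance`` of the pathological surface.  The second filter
    matters because rays nearly tangent to the articular surface stretch a
    sub-millimetre radial estimation error into centimetre-long chords that
    the thickness filter cannot see; true missing bone has interior
    clearance from the remaining bone surface.
    """
    mr = ray_set.max_range
    nat_hits, nat_counts, nat_trunc = SingleOriginCaster(native, ray_set.origin) \
        .cast(ray_set.directions, mr, MAX_HITS)
    pat_hits, pat_counts, pat_trunc = SingleOriginCaster(patho, ray_set.origin) \
        .cast(ray_set.directions, mr, MAX_HITS)

    n = len(ray_set.directions)
    valid = np.ones(n, dtype=bool)
    defect_intervals = [[] for _ in range(n)]
    first_native = nat_hits[:, 0].copy()
    t_end = np.full(n, np.nan)

    # Rays where the pathological bone already matches the native estimate
    # within the noise floor can be skipped wholesale.
    candidates = np.flatnonzero(
        (nat_counts > 0)
        & ((nat_counts != pat_counts)
           | (np.nan_to_num(np.abs(nat_hits - pat_hits), nan=0.0).max(axis=1)
              >= min_interval_thickness / 2))
    )
    cand_ivs = []  # (ray index, t_in, t_out)
    for i in candidates:
        cls = classify_ray(nat_hits[i, : nat_counts[i]], pat_hits[i, : pat_counts[i]],
                           mr, bool(nat_trunc[i]), bool(pat_trunc[i]))
        if not cls.valid:
            valid[i] = False
            continue
        cand_ivs.extend((i, a, b) for a, b in cls.defect_intervals
                        if b - a >= min_interval_thickness)

    if cand_ivs and surface_clearance > 0:
        from .shape_model import SurfaceLocator

        arr = np.asarray([(a, b) for _, a, b in cand_ivs])
        mids = ray_set.origin \
            + (0.5 * (arr[:, 0] + arr[:, 1]))[:, None] \
            * ray_set.directions[[i for i, _, _ in cand_ivs]]
        cp, _ = SurfaceLocator(patho).closest(mids)
        clear = np.linalg.norm(mids - cp, axis=1) >= surface_clearance
        cand_ivs = [t for t, ok in zip(cand_ivs, clear) if ok]
    for i, a, b in cand_ivs:
        defect_intervals[i].append((a, b))
        t_end[i] = b if np.isnan(t_end[i]) else max(t_end[i], b)
    invalid = ~valid
    if invalid.any():
        t_end[invalid] = np.nan
        for i in np.flatnonzero(invalid):
            defect_intervals[i] = []
    return RayRecords(ray_set=ray_set, native_hits=nat_hits, patho_hits=pat_hits,
                      valid=valid, defect_intervals=defect_intervals,
                      first_native_hit=first_native, defect_t_end=t_end)


def defect_point_cloud(records: RayRecords,
                       densify_step: float = DENSIFY_STEP):
    """World-space defect points (endpoints + midpoints + densification)."""
    pts, ray_idx = [], []
    o = records.ray_set.origin
    dirs = records.ray_set.directions
    for i, ivs in enumerate(records.defect_intervals):
        if not ivs:
            continue
        ts = iv.sample_points(ivs, step=densify_step)
        pts.append(o + ts[:, None] * dirs[i])
        ray_idx.append(np.full(len(ts), i))
    if not pts:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.vstack(pts), np.concatenate(ray_idx)


def cluster_points(points: np.ndarray, linkage_radius: float,
                   min_size: int = CLUSTER_MIN_SIZE):
    """Single-linkage clusters (connected components at ``linkage_radius``).

    Returns a list of index arrays, largest first; clusters with fewer than
    ``min_size`` points are discarded.  An empty result (with a warning)
    means no defect was detected.
    """
    if linkage_radius <= 0:
        raise InvalidParameterError("linkage_radius must be positive")
    n = len(points)
    if n == 0:
        warnings.warn("no defect points to cluster")
        return []
    tree = cKDTree(points)
    pairs = tree.query_pairs(linkage_radius, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = sparse.csgraph.connected_components(adj, directed=False)
    clusters = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    clusters = [c for c in clusters if len(c) >= min_size]
    clusters.sort(key=len, reverse=True)
    if not clusters:
        warnings.warn(f"all point clusters below {min_size} points: "
                      "no defect detected")
    return clusters


def _tet_circumradii(pts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p0 = pts[tets[:, 0]]
    A = 2.0 * (pts[tets[:, 1:]] - p0[:, None, :])          # (T, 3, 3)
    b = ((pts[tets[:, 1:]] ** 2).sum(axis=2)
         - (p0**2).sum(axis=1)[:, None])                   # (T, 3)
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-12
    R = np.full(len(tets), np.inf)
    if ok.any():
        centres = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        R[ok] = np.linalg.norm(centres - p0[ok], axis=1)
    return R


def reconstruct_surface(points: np.ndarray, alpha: float | None) -> trimesh.Trimesh:
    """Alpha-shape surface of a defect point cluster.

    Keeps Delaunay tetrahedra with circumradius below ``alpha`` (all of
    them when ``alpha`` is None, yielding the convex hull) and returns the
    boundary of the kept complex, oriented outward.  The enclosed volume
    (sum of kept tetrahedra) is stored in ``mesh.metadata['tet_volume']``.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise DegenerateGeometryError("alpha shape needs at least 4 points")
    try:
        tri = Delaunay(points)
    except Exception as exc:  # QhullError on degenerate input
        raise DegenerateGeometryError(f"Delaunay triangulation failed: {exc}")
    tets = tri.simplices
    if alpha is not None:
        keep = _tet_circumradii(points, tets) < alpha
        tets = tets[keep]
    if len(tets) == 0:
        raise DegenerateGeometryError(
            "no tetrahedra below alpha: cluster too sparse or too flat")

    # orient each face outward from its tetrahedron, then keep faces used once
    faces = np.empty((4 * len(tets), 3), dtype=np.int64)
    opp = np.empty(4 * len(tets), dtype=np.int64)
    order = ((1, 2, 3, 0), (0, 3, 2, 1), (0, 1, 3, 2), (0, 2, 1, 3))
    for k, (i, j, l, o) in enumerate(order):
        faces[k::4] = tets[:, (i, j, l)]
        opp[k::4] = tets[:, o]
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
    boundary = faces[counts[inverse] == 1]
    opp_b = opp[counts[inverse] == 1]
    # outward orientation: normal away from the opposite vertex
    e1 = points[boundary[:, 1]] - points[boundary[:, 0]]
    e2 = points[boundary[:, 2]] - points[boundary[:, 0]]
    n_hat = np.cross(e1, e2)
    inward = np.einsum("ij,ij->i", n_hat,
                       points[opp_b] - points[boundary[:, 0]]) > 0
    boundary[inward] = boundary[inward][:, [0, 2, 1]]

    v = points[tets]
    tet_vol = np.abs(np.einsum("ij,ij->i",
                               np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                               v[:, 3] - v[:, 0])) / 6.0
    mesh = trimesh.Trimesh(vertices=points, faces=boundary, process=False)
    mesh.remove_unreferenced_vertices()
    mesh.metadata["tet_volume"] = float(tet_vol.sum())
    return mesh


@dataclass
class DefectModel:
    """Final reconstructed defect solid."""

    mesh: trimesh.Trimesh
    source_points: int
    clusters_kept: int
    volume_cm3: float

    @property
    def is_empty(self) -> bool:
        return self.mesh.is_empty or len(self.mesh.faces) == 0


MIN_COMPONENT_CM3 = 0.5  # post-Boolean droplet floor


def refine_booleans(defect: trimesh.Trimesh, pathological: trimesh.Trimesh,
                    native: trimesh.Trimesh, pitch: float = 0.7,
                    source_points: int = 0, clusters_kept: int = 0,
                    min_component_cm3: float = MIN_COMPONENT_CM3) -> DefectModel:
    """(defect - pathological) ∩ native, realised as voxel Booleans.

    The three solids are rasterized on one grid limited to the defect's
    bounding box (the intersection cannot grow it), combined logically and
    re-surfaced with marching cubes; the volume is the divergence-theorem
    volume of the watertight result.  Disconnected droplets below
    ``min_component_cm3`` are removed: near-tangential rays amplify
    sub-millimetre native-estimate error into thin slivers at the rim, the
    volumetric analogue of the sub-200-point clusters already discarded.
    """
    if defect.is_empty or len(defect.faces) == 0:
        return DefectModel(mesh=trimesh.Trimesh(), source_points=source_points,
                           clusters_kept=clusters_kept, volume_cm3=0.0)
    origin, shape = voxel.grid_layout(defect.bounds, pitch, pad_voxels=3)

    def _rast(mesh, name):
        try:
            return voxel.rasterize(mesh, origin, pitch, shape, axis=0, name=name)
        except Exception:
            cleaned = mesh.copy()
            cleaned.merge_vertices()
            cleaned.update_faces(cleaned.nondegenerate_faces())
            return voxel.rasterize(cleaned, origin, pitch, shape, axis=0, name=name)

    mask = _rast(defect, "defect") \
        & ~_rast(pathological, "pathological") \
        & _rast(native, "native")
    grid = voxel.VoxelGrid(origin=origin, pitch=pitch, mask=mask)
    mesh = voxel.surface_from_mask(grid)
    if len(mesh.faces) and min_component_cm3 > 0:
        bodies = mesh.split(only_watertight=False)
        kept = [b for b in bodies if float(b.volume) / 1000.0 >= min_component_cm3]
        if kept and len(kept) < len(bodies):
            mesh = trimesh.util.concatenate(kept) if len(kept) > 1 else kept[0]
        elif not kept:
            mesh = trimesh.Trimesh()
    vol = float(mesh.volume) / 1000.0 if len(mesh.faces) else 0.0
    return DefectModel(mesh=mesh, source_points=source_points,
                       clusters_kept=clusters_kept, volume_cm3=vol)


@dataclass
class ReconstructionResult:
    defect: DefectModel
    records: RayRecords
    frame: AcetabularFrame
    native_estimate: trimesh.Trimesh
    fit: object = None
    point_cloud: np.ndarray = field(default=None, repr=False)


def reconstruct_defect(pathological: trimesh.Trimesh, model: ShapeModel,
                       angular_spacing: float = DEFAULT_ANGULAR_SPACING,
                       n_modes: int = 20,
                       cluster_min_size: int = CLUSTER_MIN_SIZE,
                       min_interval_thickness: float = MIN_INTERVAL_THICKNESS,
                       surface_clearance: float = SURFACE_CLEARANCE,
                       densify_step: float = DENSIFY_STEP,
                       boolean_pitch: float = 0.7,
                       body_axes_hint=(0.0, 1.0, 0.0),
                       allow_scale: bool = True,
                       linkage_radius: float | None = None,
                       alpha: float | None = None,
                       min_component_cm3: float = MIN_COMPONENT_CM3) -> ReconstructionResult:
    """Full pipeline: native estimate -> frame -> rays -> defect solid.

    ``linkage_radius`` defaults to twice the inter-ray arc length at the
    excision range; ``alpha`` defaults to three times the linkage radius.
    """
    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            if isinstance(exc, StageError):
                raise
            raise StageError(name, exc) from exc

    native, fit = _stage("estimate_native", estimate_native, model, pathological,
                         n_modes=n_modes, body_axes_hint=body_axes_hint,
                         allow_scale=allow_scale)
    frame = _stage("acetabular_frame", frame_from_mesh, native,
                   body_axes_hint=body_axes_hint)
    rays = _stage("generate_rays", generate_rays, frame, angular_spacing)
    records = _stage("cast_and_classify", cast_and_classify, native,
                     pathological, rays, min_interval_thickness,
                     surface_clearance)
    points, _ = _stage("defect_points", defect_point_cloud, records, densify_step)

    if linkage_radius is None:
        linkage_radius = max(2.0 * np.deg2rad(angular_spacing) * rays.max_range,
                             1.2 * densify_step)
    if alpha is None:
        alpha = 3.0 * linkage_radius

    clusters = _stage("cluster_points", cluster_points, points, linkage_radius,
                      cluster_min_size)
    if not clusters:
        empty = DefectModel(mesh=trimesh.Trimesh(), source_points=len(points),
                            clusters_kept=0, volume_cm3=0.0)
        return ReconstructionResult(defect=empty, records=records, frame=frame,
                                    native_estimate=native, fit=fit,
                                    point_cloud=points)

    pieces = [_stage("alpha_shape", reconstruct_surface, points[c], alpha)
              for c in clusters]
    raw = trimesh.util.concatenate(pieces) if len(pieces) > 1 else pieces[0]
    defect = _stage("refine_booleans", refine_booleans, raw, pathological,
                    native, boolean_pitch,
                    source_points=len(points), clusters_kept=len(clusters),
                    min_component_cm3=min_component_cm3)
    return ReconstructionResult(defect=defect, records=records, frame=frame,
                                native_estimate=native, fit=fit,
                                point_cloud=points)
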
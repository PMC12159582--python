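"""Parametric hemipelvis phantoms with carved acetabular defects.

Real inputs to the pipeline are segmented hemipelvis surfaces from CT; this
module replaces them with a geometric phantom that keeps every feature the
pipeline consumes — a hemispherical articular cup with a sharp rim, the
surrounding cortical surface, population-scale shape variation — while
retaining analytic ground truth (cup centre/radius/axis, exact solid
membership, voxel-level defect masks).

The phantom is a rectangular bone block with a hemispherical cup carved
into its top face.  Its surface is built by explicit structured
parametrization (radial top-face grid, spherical cap, side and bottom
grids) so that every population member generated from the same template
resolution shares identical vertex/face topology: correspondence for the
statistical shape model is exact by construction.  Pathological (defected)
surfaces are produced the way segmentation pipelines produce them — by
sampling a signed distance field of bone-minus-defect on a voxel grid and
re-surfacing it with marching cubes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from . import voxel
from .acetabular_frame import AcetabularFrame, EXCISION_FACTOR
from .errors import InvalidParameterError, NonWatertightMeshError
from .raycast import fibonacci_directions, direction_count

DEFAULT_ORACLE_PITCH = 0.5  # mm, below the ~0.7 mm median CT slice thickness
DEFAULT_MESH_PITCH = 1.25   # mm, marching-cubes pitch for pathological surfaces

# Grid jitter reserved for the voxel oracle so its voxel centres never
# coincide with the pipeline's own Boolean grids.
_ORACLE_JITTER = (0.5 * (np.sqrt(7.0) - 2.0), 0.5 * (np.sqrt(11.0) - 3.0),
                  0.5 * (np.sqrt(13.0) - 3.0))


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class PhantomParams:
    """Geometry of one phantom hemipelvis.

    ``block_half_extents`` are half-widths of the bone block (mm);
    ``cup_centre`` is the world position of the hemispherical cup centre,
    which lies on the block's top face; ``polar_axis`` is the outward cup
    axis and ``superior_axis`` the in-plane superior direction (orthogonal
    unit vectors).  ``cup_offset`` shifts the cup within the top face in
    canonical (anterior, superior) coordinates.  ``rim_flare`` adds a raised
    lip around the rim (surface ornament only; defect carving requires 0).
    """

    block_half_extents: tuple = (80.0, 80.0, 60.0)
    cup_radius: float = 25.0
    cup_centre: tuple = (0.0, 0.0, 0.0)
    polar_axis: tuple = (0.0, 0.0, 1.0)
    superior_axis: tuple = (0.0, 1.0, 0.0)
    cup_offset: tuple = (0.0, 0.0)
    surface_resolution: float = 2.0
    rim_flare: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self):
        hx, hy, hz = self.block_half_extents
        r = self.cup_radius
        p = np.asarray(self.polar_axis, float)
        s = np.asarray(self.superior_axis, float)
        if r <= 0:
            raise InvalidParameterError("cup_radius must be positive")
        if self.surface_resolution <= 0:
            raise InvalidParameterError("surface_resolution must be positive")
        if self.rim_flare < 0:
            raise InvalidParameterError("rim_flare must be >= 0")
        if abs(np.linalg.norm(p) - 1) > 1e-6 or abs(np.linalg.norm(s) - 1) > 1e-6:
            raise InvalidParameterError("polar_axis and superior_axis must be unit vectors")
        if abs(p @ s) > 1e-6:
            raise InvalidParameterError("polar_axis and superior_axis must be orthogonal")
        ox, oy = self.cup_offset
        margin = 1.0
        if r + abs(ox) > hx - margin or r + abs(oy) > hy - margin or r > 2 * hz - margin:
            raise InvalidParameterError(
                f"cup (radius {r}, offset {self.cup_offset}) not contained in "
                f"block with half extents {self.block_half_extents}")

    # --- pose -----------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        """Columns map canonical (x, y, z) -> world (anterior, superior, polar)."""
        p = _unit(self.polar_axis)
        s = _unit(self.superior_axis)
        a = np.cross(s, p)
        return np.column_stack([a, s, p])

    @property
    def canonical_cup_centre(self) -> np.ndarray:
        hz = self.block_half_extents[2]
        return np.array([self.cup_offset[0], self.cup_offset[1], hz])

    def to_world(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.canonical_cup_centre) @ self.rotation.T \
            + np.asarray(self.cup_centre)

    def to_canonical(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - np.asarray(self.cup_centre)) @ self.rotation \
            + self.canonical_cup_centre

    # --- analytic solid ---------------------------------------------------
    def native_inside(self, pts: np.ndarray) -> np.ndarray:
        """Exact membership: inside block, outside cup ball."""
        q = self.to_canonical(pts)
        h = np.asarray(self.block_half_extents)
        inb = np.all(np.abs(q) <= h, axis=1)
        return inb & (np.linalg.norm(q - self.canonical_cup_centre, axis=1)
                      >= self.cup_radius)

    def native_sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance (exact sign, approximate magnitude) of the solid."""
        q = self.to_canonical(pts)
        h = np.asarray(self.block_half_extents)
        b = np.abs(q) - h
        outside = np.linalg.norm(np.maximum(b, 0.0), axis=1)
        inside = np.minimum(b.max(axis=1), 0.0)
        d_box = outside + inside
        d_ball = np.linalg.norm(q - self.canonical_cup_centre, axis=1) - self.cup_radius
        return np.maximum(d_box, -d_ball)

    def truth_frame(self) -> AcetabularFrame:
        return AcetabularFrame(hjc=np.asarray(self.cup_centre, float),
                               radius=self.cup_radius,
                               polar_axis=self.polar_axis,
                               superior_axis=self.superior_axis)


@dataclass(frozen=True)
class TemplateTopology:
    """Grid counts fixing the template parametrization (hence mesh topology)."""

    n_theta: int
    n_u: int
    n_cap: int
    n_z: int

    @classmethod
    def for_params(cls, p: PhantomParams) -> "TemplateTopology":
        res = p.surface_resolution
        hx, hy, hz = p.block_half_extents
        r = p.cup_radius
        return cls(
            n_theta=max(16, int(round(2 * np.pi * r / res))),
            n_u=max(3, int(round((1.2 * max(hx, hy) - r) / res))),
            n_cap=max(4, int(round(0.5 * np.pi * r / res))),
            n_z=max(3, int(round(2 * hz / res))),
        )


def _flare_profile(u: np.ndarray) -> np.ndarray:
    # raised lip peaking near the rim, zero at the rim ring and the face edge
    with np.errstate(over="ignore"):
        g = (u / 0.15) * np.exp(1.0 - u / 0.15) * (1.0 - u) ** 2
    return np.where((u > 0) & (u < 1), g, 0.0)


def _band(ring_a, ring_b):
    n = len(ring_a)
    j = np.arange(n)
    j1 = (j + 1) % n
    t1 = np.column_stack([ring_a[j], ring_a[j1], ring_b[j1]])
    t2 = np.column_stack([ring_a[j], ring_b[j1], ring_b[j]])
    return np.vstack([t1, t2])


def _fan(ring, apex):
    n = len(ring)
    j = np.arange(n)
    j1 = (j + 1) % n
    return np.column_stack([ring[j], ring[j1], np.full(n, apex)])


def build_phantom_mesh(params: PhantomParams,
                       topology: TemplateTopology | None = None) -> trimesh.Trimesh:
    """Watertight structured surface of the phantom solid.

    Geometry is a smooth function of the parameters for a fixed topology,
    which is what makes population members exactly corresponded.
    """
    topo = topology or TemplateTopology.for_params(params)
    nt, nu, nc, nz = topo.n_theta, topo.n_u, topo.n_cap, topo.n_z
    hx, hy, hz = params.block_half_extents
    r = params.cup_radius
    ox, oy = params.cup_offset

    theta = 2 * np.pi * np.arange(nt) / nt
    ct, st = np.cos(theta), np.sin(theta)
    # distance from the cup axis to the square boundary along each azimuth
    with np.errstate(divide="ignore"):
        tx = np.where(ct > 0, (hx - ox) / ct, np.where(ct < 0, (-hx - ox) / ct, np.inf))
        ty = np.where(st > 0, (hy - oy) / st, np.where(st < 0, (-hy - oy) / st, np.inf))
    tb = np.minimum(tx, ty)
    bx, by = ox + tb * ct, oy + tb * st

    verts = []
    # top face rings: u=0 is the rim circle (exact), u=1 the face boundary
    for i in range(nu + 1):
        u = i / nu
        x = (ox + r * ct) * (1 - u) + bx * u
        y = (oy + r * st) * (1 - u) + by * u
        z = np.full(nt, hz) + params.rim_flare * r * _flare_profile(np.full(nt, u))
        verts.append(np.column_stack([x, y, z]))
    top = [np.arange(i * nt, (i + 1) * nt) for i in range(nu + 1)]
    base = (nu + 1) * nt

    # spherical cap rings below the rim; ring i=0 reuses the rim indices
    cap = [top[0]]
    for i in range(1, nc):
        phi = 0.5 * np.pi * (1.0 + i / nc)
        x = ox + r * np.sin(phi) * ct
        y = oy + r * np.sin(phi) * st
        z = np.full(nt, hz + r * np.cos(phi))
        verts.append(np.column_stack([x, y, z]))
        cap.append(np.arange(base + (i - 1) * nt, base + i * nt))
    pole = base + (nc - 1) * nt
    verts.append(np.array([[ox, oy, hz - r]]))

    # side rings from the top boundary down to the bottom face
    side = [top[nu]]
    sbase = pole + 1
    for i in range(1, nz + 1):
        z = hz - (i / nz) * 2 * hz
        verts.append(np.column_stack([bx, by, np.full(nt, z)]))
        side.append(np.arange(sbase + (i - 1) * nt, sbase + i * nt))
    bottom_centre = sbase + nz * nt
    verts.append(np.array([[ox, oy, -hz]]))

    V = np.vstack(verts)
    faces = []
    for i in range(nu):
        faces.append(_band(top[i], top[i + 1]))
    # cavity faces wind opposite to the outer hull (outward normal points
    # into the cup ball)
    for i in range(nc - 1):
        faces.append(_band(cap[i], cap[i + 1])[:, ::-1])
    faces.append(_fan(cap[nc - 1], pole)[:, ::-1])
    for i in range(nz):
        faces.append(_band(side[i], side[i + 1]))
    faces.append(_fan(side[nz], bottom_centre))
    F = np.vstack(faces)

    V = params.to_world(V)
    mesh = trimesh.Trimesh(vertices=V, faces=F, process=False)
    if mesh.volume < 0:  # world pose is rigid, so this cannot fire; guard anyway
        mesh.invert()
    return mesh


# --------------------------------------------------------------------------
# defects


@dataclass
class DefectPrimitive:
    """A carving primitive: sphere or oriented ellipsoid (world coordinates)."""

    shape: str
    centre: tuple
    semi_axes: tuple
    orientation: tuple | None = None  # 3x3, columns = principal axes

    def __post_init__(self):
        if self.shape not in ("sphere", "ellipsoid"):
            raise InvalidParameterError(f"unknown primitive shape '{self.shape}'")
        if min(self.semi_axes) <= 0:
            raise InvalidParameterError("primitive semi-axes must be positive")

    @classmethod
    def sphere(cls, centre, radius: float) -> "DefectPrimitive":
        return cls("sphere", tuple(np.asarray(centre, float)), (radius,) * 3)

    @classmethod
    def ellipsoid(cls, centre, semi_axes, orientation=None) -> "DefectPrimitive":
        orient = None if orientation is None else tuple(map(tuple, np.asarray(orientation, float)))
        return cls("ellipsoid", tuple(np.asarray(centre, float)),
                   tuple(np.asarray(semi_axes, float)), orient)

    def _local(self, pts: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(pts) - np.asarray(self.centre)
        if self.orientation is not None:
            d = d @ np.asarray(self.orientation)
        return d

    def inside(self, pts: np.ndarray) -> np.ndarray:
        q = self._local(pts) / np.asarray(self.semi_axes)
        return (q**2).sum(axis=1) <= 1.0

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        # exact sign; magnitude exact for spheres, scaled bound for ellipsoids
        q = self._local(pts) / np.asarray(self.semi_axes)
        k = np.linalg.norm(q, axis=1)
        return (k - 1.0) * min(self.semi_axes)

    @property
    def max_extent(self) -> float:
        return float(max(self.semi_axes))


@dataclass
class DefectSpec:
    """Union of carving primitives; may be empty (no defect)."""

    primitives: list = field(default_factory=list)

    def union_inside(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        if not self.primitives:
            return np.zeros(len(pts), dtype=bool)
        return np.any([p.inside(pts) for p in self.primitives], axis=0)

    def union_sdf(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        if not self.primitives:
            return np.full(len(pts), np.inf)
        return np.min([p.sdf(pts) for p in self.primitives], axis=0)


@dataclass
class SyntheticCase:
    """A phantom subject: native + pathological surfaces with ground truth."""

    params: PhantomParams
    native_mesh: trimesh.Trimesh
    pathological_mesh: trimesh.Trimesh
    defect_spec: DefectSpec
    truth_defect_mask: voxel.VoxelGrid
    truth_frame: AcetabularFrame
    seed: int
    truth_regional: object = None

    def native_inside(self, pts):
        return self.params.native_inside(pts)

    def defect_inside(self, pts):
        """Truth defect membership: native bone consumed by the primitives."""
        return self.params.native_inside(pts) & self.defect_spec.union_inside(pts)

    def patho_inside(self, pts):
        return self.params.native_inside(pts) & ~self.defect_spec.union_inside(pts)

    @property
    def truth_defect_volume_cm3(self) -> float:
        return self.truth_defect_mask.volume_cm3


def make_phantom(params: PhantomParams, seed: int = 0) -> SyntheticCase:
    """Defect-free phantom: pathological surface equals the native surface."""
    params.validate()
    mesh = build_phantom_mesh(params)
    empty = voxel.VoxelGrid(origin=np.asarray(params.cup_centre, float),
                            pitch=DEFAULT_ORACLE_PITCH,
                            mask=np.zeros((1, 1, 1), dtype=bool))
    return SyntheticCase(params=params, native_mesh=mesh,
                         pathological_mesh=mesh.copy(),
                         defect_spec=DefectSpec(),
                         truth_defect_mask=empty,
                         truth_frame=params.truth_frame(), seed=seed)


def carve_defect(case: SyntheticCase, spec: DefectSpec,
                 pitch: float = DEFAULT_ORACLE_PITCH,
                 mesh_pitch: float = DEFAULT_MESH_PITCH) -> SyntheticCase:
    """Carve the defect primitives out of the native solid.

    The pathological surface is produced by sampling the signed distance of
    (native minus primitive-union) on a ``mesh_pitch`` grid and re-surfacing
    with marching cubes; the truth mask is the exact analytic membership
    (native AND primitive-union) at ``pitch`` voxel centres.
    """
    params = case.params
    if params.rim_flare != 0:
        raise InvalidParameterError("defect carving requires rim_flare = 0 "
                                    "(analytic solid membership)")
    if pitch <= 0 or mesh_pitch <= 0:
        raise InvalidParameterError("pitch must be positive")
    c = np.asarray(params.cup_centre, float)
    limit = EXCISION_FACTOR * params.cup_radius
    for prim in spec.primitives:
        if np.linalg.norm(np.asarray(prim.centre) - c) - prim.max_extent > limit:
            raise InvalidParameterError(
                f"primitive at {prim.centre} does not intersect the "
                f"{EXCISION_FACTOR}x-radius ball around the cup centre")

    bounds = case.native_mesh.bounds
    # keep primitives that actually remove bone (coarse probe grid)
    origin_p, shape_p = voxel.grid_layout(bounds, 2.0, pad_voxels=1)
    kept = []
    for prim in spec.primitives:
        def overlap(pts, prim=prim):
            return params.native_inside(pts) & prim.inside(pts)
        if voxel.mask_from_function(overlap, origin_p, 2.0, shape_p).any():
            kept.append(prim)
        else:
            warnings.warn(f"defect primitive at {prim.centre} does not overlap "
                          "the native solid; dropped")
    kept_spec = DefectSpec(primitives=kept)

    origin_m, shape_m = voxel.grid_layout(bounds, mesh_pitch, pad_voxels=2)
    def patho_sdf(pts):
        return np.maximum(params.native_sdf(pts), -kept_spec.union_sdf(pts))
    if kept:
        sdf = voxel.sample_sdf(patho_sdf, origin_m, mesh_pitch, shape_m)
        patho_mesh = voxel.surface_from_sdf(sdf, origin_m, mesh_pitch)
    else:
        patho_mesh = case.native_mesh.copy()

    origin_t, shape_t = voxel.grid_layout(bounds, pitch, pad_voxels=1)
    def defect_inside(pts):
        return params.native_inside(pts) & kept_spec.union_inside(pts)
    truth = voxel.VoxelGrid(
        origin=origin_t, pitch=pitch,
        mask=voxel.mask_from_function(defect_inside, origin_t, pitch, shape_t))

    return SyntheticCase(params=params, native_mesh=case.native_mesh,
                         pathological_mesh=patho_mesh, defect_spec=kept_spec,
                         truth_defect_mask=truth,
                         truth_frame=params.truth_frame(), seed=case.seed)


# --------------------------------------------------------------------------
# population sampling


@dataclass
class PopulationModel:
    """Sampling distribution for phantom shape parameters.

    Emulates inter-subject pelvic variation: a shared size factor drives
    both the block extents and the acetabular radius (as in real anatomy,
    where acetabular size scales with pelvis size — which is also what lets
    a shape model predict the cup from the surrounding bone), with
    independent residual variation per parameter.  Marginals: extents
    Normal(base, half_extents_sd), radius Normal(25, 2) mm, cup offset
    Normal(0, 2) mm per in-plane axis.
    """

    base: PhantomParams = field(default_factory=PhantomParams)
    half_extents_sd: tuple = (4.0, 4.0, 3.0)
    cup_radius_sd: float = 2.0
    cup_offset_sd: float = 2.0
    size_correlation: float = 0.9

    def sample_params(self, rng: np.random.Generator) -> PhantomParams:
        rho = self.size_correlation
        resid = np.sqrt(1.0 - rho**2)
        for _ in range(100):
            z = rng.normal()
            he = np.asarray(self.base.block_half_extents) \
                + np.asarray(self.half_extents_sd) * (rho * z + resid * rng.normal(size=3))
            r = self.base.cup_radius \
                + self.cup_radius_sd * (rho * z + resid * rng.normal())
            off = np.asarray(self.base.cup_offset) + rng.normal(0, self.cup_offset_sd, 2)
            try:
                return replace(self.base, block_half_extents=tuple(he),
                               cup_radius=float(r), cup_offset=tuple(off))
            except InvalidParameterError:
                continue
        raise InvalidParameterError("population model cannot produce valid parameters")


def sample_population(n: int, model: PopulationModel | None = None,
                      seed: int = 0):
    """Corresponded training phantoms (canonical pose).

    Returns (meshes, params): all meshes share the template topology of the
    model's base parameters, so vertex i corresponds across the population.
    """
    model = model or PopulationModel()
    topo = TemplateTopology.for_params(model.base)
    rng = np.random.default_rng(seed)
    meshes, params_list = [], []
    for _ in range(int(n)):
        p = model.sample_params(rng)
        meshes.append(build_phantom_mesh(p, topo))
        params_list.append(p)
    return meshes, params_list


# --------------------------------------------------------------------------
# oracles (test instrumentation; the reconstruction pipeline never calls these)


def voxel_oracle(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh | None = None,
                 op: str = "volume", pitch: float = DEFAULT_ORACLE_PITCH):
    """Brute-force voxel Boolean/volume oracle.

    Decides inside/outside per voxel centre by crossing parity on a jittered
    grid distinct from any grid the pipeline uses, and measures volume as
    voxel count x pitch^3.  Used only to validate pipeline output.
    Returns (VoxelGrid, volume_mm3).
    """
    if op not in ("volume", "union", "intersection", "difference"):
        raise InvalidParameterError(f"unknown op '{op}'")
    if pitch <= 0:
        raise InvalidParameterError("pitch must be positive")
    for name, m in (("mesh_a", mesh_a), ("mesh_b", mesh_b)):
        if m is not None and len(m.faces) and not m.is_watertight:
            raise NonWatertightMeshError(name)
    meshes = [mesh_a] + ([mesh_b] if mesh_b is not None else [])
    nonempty = [m for m in meshes if not m.is_empty and len(m.faces)]
    if not nonempty:
        grid = voxel.VoxelGrid(origin=np.zeros(3), pitch=pitch,
                               mask=np.zeros((1, 1, 1), dtype=bool))
        return grid, 0.0
    bounds = np.array([np.min([m.bounds[0] for m in nonempty], axis=0),
                       np.max([m.bounds[1] for m in nonempty], axis=0)])
    origin, shape = voxel.grid_layout(bounds, pitch, pad_voxels=2,
                                      jitter=_ORACLE_JITTER)
    mask_a = voxel.rasterize(mesh_a, origin, pitch, shape, axis=2, name="mesh_a")
    if mesh_b is None:
        mask = mask_a
    else:
        mask_b = voxel.rasterize(mesh_b, origin, pitch, shape, axis=2, name="mesh_b")
        if op == "union":
            mask = mask_a | mask_b
        elif op == "intersection":
            mask = mask_a & mask_b
        elif op == "difference":
            mask = mask_a & ~mask_b
        else:
            mask = mask_a
    grid = voxel.VoxelGrid(origin=origin, pitch=pitch, mask=mask)
    return grid, grid.volume_mm3


def ray_march_oracle(case: SyntheticCase, directions: np.ndarray,
                     max_range: float, step: float = 0.25):
    """Dense ray-march against the analytic solids.

    For each direction from the truth hip joint centre: the first native
    surface crossing, the furthest truth-defect sample, and the defect run
    midpoints (for region assignment).  Returns (first_native, defect_t_end,
    midpoints list); NaN where a ray never enters the native solid.
    """
    origin = case.truth_frame.hjc
    ts = np.arange(step / 2, max_range, step)
    n = len(directions)
    first_native = np.full(n, np.nan)
    t_end = np.full(n, np.nan)
    midpoints = [np.empty(0)] * n
    chunk = max(1, int(2_000_000 // len(ts)))
    for i0 in range(0, n, chunk):
        d = directions[i0:i0 + chunk]
        pts = origin + d[:, None, :] * ts[None, :, None]
        flat = pts.reshape(-1, 3)
        nat = case.native_inside(flat).reshape(len(d), -1)
        dfc = case.defect_inside(flat).reshape(len(d), -1)
        any_nat = nat.any(axis=1)
        fn = np.where(any_nat, ts[np.argmax(nat, axis=1)] - step / 2, np.nan)
        first_native[i0:i0 + len(d)] = fn
        for j in range(len(d)):
            runs = np.flatnonzero(dfc[j])
            if runs.size:
                t_end[i0 + j] = ts[runs[-1]] + step / 2
                breaks = np.flatnonzero(np.diff(runs) > 1)
                starts = np.concatenate([[0], breaks + 1])
                ends = np.concatenate([breaks, [runs.size - 1]])
                midpoints[i0 + j] = 0.5 * (ts[runs[starts]] + ts[runs[ends]])
    return first_native, t_end, midpoints


def compute_truth_regional(case: SyntheticCase, dd_spacing_deg: float = 2.0,
                           dd_step: float = 0.25):
    """Ground-truth regional metrics from analytic membership + ray marching."""
    from . import regional_metrics as rm

    frame = case.truth_frame
    grid = case.truth_defect_mask
    native_mask = voxel.mask_from_function(case.native_inside, grid.origin,
                                           grid.pitch, grid.mask.shape)
    pts = grid.centers()
    vox_cm3 = grid.pitch**3 / 1000.0
    dirs = fibonacci_directions(direction_count(dd_spacing_deg))
    max_range = EXCISION_FACTOR * frame.radius
    first_native, t_end, mids = ray_march_oracle(case, dirs, max_range, dd_step)
    has_defect = ~np.isnan(t_end)
    fn = np.where(np.isnan(first_native), max_range, first_native)
    dd = rm.compute_dd(dirs[has_defect], frame.hjc, fn[has_defect],
                       t_end[has_defect],
                       [mids[i] for i in np.flatnonzero(has_defect)], frame)
    rows = {}
    for name in rm.REGION_NAMES + ("total",):
        member = rm.region_membership(name, frame, pts)
        adv = float((grid.mask.ravel() & member).sum()) * vox_cm3
        native_ref = float((native_mask.ravel() & member).sum()) * vox_cm3
        depth, n_rays = dd[name]
        rows[name] = {"adv_cm3": adv,
                      "rdv_pct": np.nan if native_ref <= 0 else 100.0 * adv / native_ref,
                      "dd_mm": depth, "native_cm3": native_ref,
                      "n_valid_rays": n_rays}
    return rm.RegionalMetrics.from_rows(rows)


# --------------------------------------------------------------------------
# standard defect presets and the synthetic study suite

#: Size presets loosely spanning small contained defects up to large
#: two-lobed superior-wall loss.  Factors are relative to the cup radius so
#: presets scale with subject anatomy.
DEFECT_PRESETS = ("small", "medium", "large")


def defect_preset(name: str, params: PhantomParams) -> DefectSpec:
    """A preset defect anchored to the subject's cup frame."""
    c = np.asarray(params.cup_centre, float)
    r = params.cup_radius
    R = params.rotation  # columns: anterior, superior, polar
    a, s, p = R[:, 0], R[:, 1], R[:, 2]
    if name == "small":
        # contained cavitary loss at the cup floor, ~10 cm3 at r = 25 mm
        return DefectSpec([DefectPrimitive.sphere(c - 1.0 * r * p, 0.63 * r)])
    if name == "medium":
        # deeper medial cavitary loss, ~30 cm3 at r = 25 mm
        return DefectSpec([DefectPrimitive.ellipsoid(
            c - 1.15 * r * p, (0.91 * r, 0.84 * r, 0.76 * r), orientation=R)])
    if name == "large":
        # two-lobed medial + superior-wall loss, ~80 cm3 at r = 25 mm
        return DefectSpec([
            DefectPrimitive.ellipsoid(c - 1.20 * r * p,
                                      (1.10 * r, 1.01 * r, 0.93 * r), orientation=R),
            DefectPrimitive.sphere(c + 1.0 * r * s - 0.40 * r * p, 0.93 * r),
        ])
    raise InvalidParameterError(f"unknown defect preset '{name}'")


def make_subject(size: str, seed: int, model: PopulationModel | None = None,
                 pitch: float = DEFAULT_ORACLE_PITCH,
                 mesh_pitch: float = DEFAULT_MESH_PITCH,
                 max_rotation_deg: float = 10.0) -> SyntheticCase:
    """One pathological subject: sampled anatomy, modest pose, preset defect."""
    model = model or PopulationModel()
    rng = np.random.default_rng([seed, 9151])
    base = model.sample_params(rng)
    angle = np.deg2rad(rng.uniform(0, max_rotation_deg))
    axis = _unit(rng.normal(size=3))
    Rw = trimesh.transformations.rotation_matrix(angle, axis)[:3, :3]
    translation = rng.uniform(-20, 20, 3)
    posed = replace(base,
                    cup_centre=tuple(translation),
                    polar_axis=tuple(Rw @ [0.0, 0.0, 1.0]),
                    superior_axis=tuple(Rw @ [0.0, 1.0, 0.0]))
    case = make_phantom(posed, seed=seed)
    spec = defect_preset(size, posed)
    return carve_defect(case, spec, pitch=pitch, mesh_pitch=mesh_pitch)


def standard_suite(seed: int = 1, n_per_size: int = 4,
                   model: PopulationModel | None = None, **kwargs):
    """The 12-case validation suite: 3 defect sizes x ``n_per_size`` subjects."""
    cases = []
    for size_i, size in enumerate(DEFECT_PRESETS):
        for k in range(n_per_size):
            case_seed = (seed * 100 + size_i * 10 + k) % (2**31 - 1)
            cases.append((f"{size}-{k}", size,
                          make_subject(size, case_seed, model=model, **kwargs)))
    return cases
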
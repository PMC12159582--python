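"""Voxel machinery: solid rasterization, membership grids and remeshing.

All solids in the pipeline are closed triangulated surfaces in millimetres.
A solid is converted to a binary occupancy mask by crossing-parity
rasterization: for every grid column along a cast axis the intersections of
the column line with the surface are collected, and a voxel centre is inside
exactly when an odd number of crossings lies below it.  This is the classic
scan-conversion rule for watertight surfaces and needs no spatial index.

Masks are converted back to watertight surfaces with marching cubes
(scikit-image), which is also how the pipeline realises mesh Boolean
operations: rasterize the operands on a shared grid, combine the masks
logically, and re-surface the result.  Volumes can then be measured either
by voxel counting or by the divergence theorem on the re-surfaced mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from skimage import measure

from .errors import NonWatertightMeshError

# Irrational sub-voxel offsets decorrelate grid planes from mesh vertices so
# that column lines essentially never pass exactly through edges or vertices.
_DEFAULT_JITTER = (0.5 * (np.sqrt(2.0) - 1.0), 0.5 * (np.sqrt(3.0) - 1.0), 0.5 * (np.sqrt(5.0) - 2.0))


@dataclass
class VoxelGrid:
    """Axis-aligned binary occupancy grid.

    origin is the corner of voxel (0,0,0); the centre of voxel ``(i,j,k)``
    is ``origin + (i+0.5, j+0.5, k+0.5) * pitch``.
    """

    origin: np.ndarray
    pitch: float
    mask: np.ndarray  # bool, shape (nx, ny, nz)

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.pitch**3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def axis_centers(self):
        """Per-axis 1D arrays of voxel-centre coordinates."""
        return tuple(
            self.origin[a] + (np.arange(self.mask.shape[a]) + 0.5) * self.pitch
            for a in range(3)
        )

    def centers(self) -> np.ndarray:
        """(N,3) coordinates of all voxel centres (row-major order)."""
        xs, ys, zs = self.axis_centers()
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def same_grid(self, other: "VoxelGrid") -> bool:
        return (
            self.mask.shape == other.mask.shape
            and abs(self.pitch - other.pitch) < 1e-9
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )


def grid_layout(bounds: np.ndarray, pitch: float, pad_voxels: int = 2,
                jitter=_DEFAULT_JITTER):
    """Origin and shape of a grid covering ``bounds`` (2x3 min/max array)."""
    lo = np.asarray(bounds[0], dtype=float) - pad_voxels * pitch
    hi = np.asarray(bounds[1], dtype=float) + pad_voxels * pitch
    origin = lo + np.asarray(jitter) * pitch
    shape = np.maximum(np.ceil((hi - origin) / pitch).astype(int), 1)
    return origin, tuple(int(n) for n in shape)


def _cross2(ax, ay, bx, by):
    return ax * by - ay * bx


def rasterize(mesh: trimesh.Trimesh, origin, pitch: float, shape,
              axis: int = 2, name: str = "mesh") -> np.ndarray:
    """Crossing-parity occupancy of ``mesh`` on the given grid.

    ``axis`` selects the casting direction of the scan columns.  Triangles
    parallel to the cast axis contribute no crossings (their effect on the
    parity of any generic column is nil).  Columns whose total crossing
    count is odd indicate a surface hole (or a column through a degenerate
    configuration); a tiny number of such columns is repaired by dropping
    their outermost crossing, anything more raises NonWatertightMeshError.
    """
    origin = np.asarray(origin, dtype=float)
    shape = tuple(shape)
    if mesh.is_empty or len(mesh.faces) == 0:
        return np.zeros(shape, dtype=bool)

    u_ax, v_ax = [a for a in range(3) if a != axis]
    tri = mesh.triangles  # (F, 3, 3)
    pu, pv, pw = tri[:, :, u_ax], tri[:, :, v_ax], tri[:, :, axis]
    nu, nv, nw = shape[u_ax], shape[v_ax], shape[axis]
    ou, ov, ow = origin[u_ax], origin[v_ax], origin[axis]

    # 2D signed area in the projection plane; drop degenerate projections.
    e1u, e1v = pu[:, 1] - pu[:, 0], pv[:, 1] - pv[:, 0]
    e2u, e2v = pu[:, 2] - pu[:, 0], pv[:, 2] - pv[:, 0]
    denom = _cross2(e1u, e1v, e2u, e2v)
    scale = float(mesh.scale) if mesh.scale > 0 else 1.0
    keep = np.abs(denom) > 1e-12 * scale**2
    if not np.any(keep):
        return np.zeros(shape, dtype=bool)
    pu, pv, pw = pu[keep], pv[keep], pw[keep]
    e1u, e1v, e2u, e2v, denom = e1u[keep], e1v[keep], e2u[keep], e2v[keep], denom[keep]

    # Column index ranges covered by each triangle's projected bbox.
    iu0 = np.ceil((pu.min(axis=1) - ou) / pitch - 0.5).astype(np.int64)
    iu1 = np.floor((pu.max(axis=1) - ou) / pitch - 0.5).astype(np.int64)
    iv0 = np.ceil((pv.min(axis=1) - ov) / pitch - 0.5).astype(np.int64)
    iv1 = np.floor((pv.max(axis=1) - ov) / pitch - 0.5).astype(np.int64)
    iu0, iu1 = np.clip(iu0, 0, nu - 1), np.clip(iu1, 0, nu - 1)
    iv0, iv1 = np.clip(iv0, 0, nv - 1), np.clip(iv1, 0, nv - 1)
    du, dv = iu1 - iu0 + 1, iv1 - iv0 + 1
    nonempty = (du > 0) & (dv > 0) & (iu1 >= iu0) & (iv1 >= iv0)

    col_u, col_v, col_w = [], [], []
    # Batch triangles sharing a bbox footprint so the inner test is one
    # vectorized evaluation per (footprint-size) group.
    sizes = du * 10_000 + dv
    for size in np.unique(sizes[nonempty]):
        sel = np.flatnonzero((sizes == size) & nonempty)
        g_du, g_dv = int(size // 10_000), int(size % 10_000)
        offs_u, offs_v = np.meshgrid(np.arange(g_du), np.arange(g_dv), indexing="ij")
        offs_u, offs_v = offs_u.ravel(), offs_v.ravel()
        cu = iu0[sel][:, None] + offs_u[None, :]  # (G, cells)
        cv = iv0[sel][:, None] + offs_v[None, :]
        qu = ou + (cu + 0.5) * pitch - pu[sel, 0][:, None]
        qv = ov + (cv + 0.5) * pitch - pv[sel, 0][:, None]
        a = _cross2(qu, qv, e2u[sel][:, None], e2v[sel][:, None]) / denom[sel][:, None]
        b = _cross2(e1u[sel][:, None], e1v[sel][:, None], qu, qv) / denom[sel][:, None]
        inside = (a >= 0.0) & (b >= 0.0) & (a + b <= 1.0)
        if not inside.any():
            continue
        w0 = pw[sel, 0][:, None]
        w = w0 + a * (pw[sel, 1] - pw[sel, 0])[:, None] + b * (pw[sel, 2] - pw[sel, 0])[:, None]
        col_u.append(cu[inside])
        col_v.append(cv[inside])
        col_w.append(w[inside])

    mask_perm = np.zeros((nu, nv, nw), dtype=bool)
    if col_u:
        cu = np.concatenate(col_u)
        cv = np.concatenate(col_v)
        w = np.concatenate(col_w)

        counts = np.zeros((nu, nv), dtype=np.int64)
        np.add.at(counts, (cu, cv), 1)
        odd = (counts % 2) == 1
        n_odd = int(odd.sum())
        if n_odd:
            n_cols = max(int((counts > 0).sum()), 1)
            if n_odd > max(3, n_cols // 1000):
                raise NonWatertightMeshError(
                    name, f"{n_odd} scan columns have odd crossing parity")
            # Grazing artifact on a handful of columns: drop the outermost
            # crossing so the column closes.
            for cu_bad, cv_bad in zip(*np.nonzero(odd)):
                idx = np.flatnonzero((cu == cu_bad) & (cv == cv_bad))
                drop = idx[np.argmax(w[idx])]
                keep_rows = np.ones(len(w), dtype=bool)
                keep_rows[drop] = False
                cu, cv, w = cu[keep_rows], cv[keep_rows], w[keep_rows]

        # A crossing at height w flips the parity of every voxel centre above it.
        k0 = np.floor((w - ow) / pitch - 0.5).astype(np.int64) + 1
        valid = k0 < nw
        k0 = np.clip(k0[valid], 0, nw - 1)
        delta = np.zeros((nu, nv, nw), dtype=np.int64)
        np.add.at(delta, (cu[valid], cv[valid], k0), 1)
        mask_perm = (np.cumsum(delta, axis=2) % 2).astype(bool)

    perm = (u_ax, v_ax, axis)
    inv = np.argsort(perm)
    return np.transpose(mask_perm, axes=inv)


def solid_mask(mesh: trimesh.Trimesh, pitch: float, axis: int = 2,
               pad_voxels: int = 2, jitter=_DEFAULT_JITTER,
               name: str = "mesh") -> VoxelGrid:
    """Rasterize a mesh on a grid fitted to its own bounds."""
    origin, shape = grid_layout(mesh.bounds, pitch, pad_voxels, jitter)
    mask = rasterize(mesh, origin, pitch, shape, axis=axis, name=name)
    return VoxelGrid(origin=origin, pitch=pitch, mask=mask)


def eval_on_grid(fn, origin, pitch: float, shape, dtype) -> np.ndarray:
    """Evaluate ``fn((N,3) points) -> (N,)`` at every voxel centre.

    Works in x-slabs so large grids never materialize a full (N,3)
    coordinate array.
    """
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = shape
    ys = origin[1] + (np.arange(ny) + 0.5) * pitch
    zs = origin[2] + (np.arange(nz) + 0.5) * pitch
    out = np.empty(shape, dtype=dtype)
    slab = max(1, int(4_000_000 // max(ny * nz, 1)))
    for x0 in range(0, nx, slab):
        xs = origin[0] + (np.arange(x0, min(x0 + slab, nx)) + 0.5) * pitch
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        out[x0:x0 + len(xs)] = np.asarray(fn(pts)).reshape(gx.shape)
    return out


def mask_from_function(inside, origin, pitch: float, shape) -> np.ndarray:
    """Membership callable -> boolean occupancy at voxel centres."""
    return eval_on_grid(inside, origin, pitch, shape, dtype=bool)


def sample_sdf(sdf, origin, pitch: float, shape) -> np.ndarray:
    """Sample a signed-distance callable (negative inside) on the grid."""
    return eval_on_grid(sdf, origin, pitch, shape, dtype=float)


def _as_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def surface_from_mask(grid: VoxelGrid) -> trimesh.Trimesh:
    """Marching-cubes surface of a binary occupancy grid (watertight)."""
    if not grid.mask.any():
        return trimesh.Trimesh()
    vol = np.pad(grid.mask, 1, mode="constant").astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5)
    verts = grid.origin + (verts - 1.0 + 0.5) * grid.pitch
    return _as_outward(trimesh.Trimesh(vertices=verts, faces=faces, process=False))


def surface_from_sdf(values: np.ndarray, origin, pitch: float) -> trimesh.Trimesh:
    """Marching-cubes surface of a signed-distance sample (level 0).

    The grid must enclose the solid with at least one positive (outside)
    layer on every border; values are clipped so distant geometry cannot
    produce spurious components.
    """
    if values.min() >= 0:
        return trimesh.Trimesh()
    vol = values.astype(np.float32)
    if (vol[0] < 0).any() or (vol[-1] < 0).any() or (vol[:, 0] < 0).any() \
            or (vol[:, -1] < 0).any() or (vol[:, :, 0] < 0).any() or (vol[:, :, -1] < 0).any():
        vol = np.pad(vol, 1, mode="constant", constant_values=float(pitch))
        shift = 1.0
    else:
        shift = 0.0
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0)
    verts = np.asarray(origin) + (verts - shift + 0.5) * pitch
    return _as_outward(trimesh.Trimesh(vertices=verts, faces=faces, process=False))


def shared_grid_masks(meshes, pitch: float, axis: int = 0, pad_voxels: int = 3,
                      names=None) -> list:
    """Rasterize several solids on one common grid (required for Booleans)."""
    meshes = list(meshes)
    names = names or [f"mesh_{i}" for i in range(len(meshes))]
    bounds = np.array([
        np.min([m.bounds[0] for m in meshes if not m.is_empty], axis=0),
        np.max([m.bounds[1] for m in meshes if not m.is_empty], axis=0),
    ])
    origin, shape = grid_layout(bounds, pitch, pad_voxels)
    return [
        VoxelGrid(origin=origin, pitch=pitch,
                  mask=rasterize(m, origin, pitch, shape, axis=axis, name=n))
        for m, n in zip(meshes, names)
    ]
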
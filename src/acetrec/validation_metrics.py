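"""Geometric agreement metrics between two defect solids.

Mirrors how automated reconstructions are validated against a reference
(ground truth, or a manually derived model): volumetric Dice on binary
masks voxelized on one shared grid, absolute and relative volume errors,
and the symmetric Hausdorff distance between densely sampled surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from . import voxel
from .errors import InvalidParameterError, NonWatertightMeshError

DEFAULT_DICE_PITCH = 1.0          # mm; within the CT slice-thickness range
DEFAULT_SAMPLE_DENSITY = 10.0     # Hausdorff surface samples per mm^2


@dataclass
class ValidationReport:
    """Agreement between an automatic defect model and a reference."""

    dice: float
    volume_mae_cm3: float
    volume_mare_pct: float | None
    hausdorff_mm: float
    pitch: float
    n_points_sampled: int

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "volume_mae_cm3": self.volume_mae_cm3,
            "volume_mare_pct": self.volume_mare_pct,
            "hausdorff_mm": self.hausdorff_mm,
            "pitch": self.pitch,
            "n_points_sampled": self.n_points_sampled,
        }


def voxelize(mesh: trimesh.Trimesh, pitch: float,
             grid: tuple | None = None) -> voxel.VoxelGrid:
    """Binary mask of a watertight solid (voxel-centre inside test).

    ``grid`` is an (origin, shape) pair; both meshes of a comparison must
    be voxelized on the same grid.
    """
    if pitch <= 0:
        raise InvalidParameterError("pitch must be positive")
    if len(mesh.faces) and not mesh.is_watertight:
        raise NonWatertightMeshError("mesh")
    if grid is None:
        if mesh.is_empty or len(mesh.faces) == 0:
            return voxel.VoxelGrid(origin=np.zeros(3), pitch=pitch,
                                   mask=np.zeros((1, 1, 1), dtype=bool))
        origin, shape = voxel.grid_layout(mesh.bounds, pitch, pad_voxels=2)
    else:
        origin, shape = grid
    mask = voxel.rasterize(mesh, origin, pitch, shape, axis=2, name="mesh")
    return voxel.VoxelGrid(origin=np.asarray(origin, float), pitch=pitch, mask=mask)


def shared_voxelize(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh,
                    pitch: float = DEFAULT_DICE_PITCH):
    """Voxelize two solids on one grid covering both."""
    nonempty = [m for m in (mesh_a, mesh_b) if not m.is_empty and len(m.faces)]
    if not nonempty:
        g = voxel.VoxelGrid(origin=np.zeros(3), pitch=pitch,
                            mask=np.zeros((1, 1, 1), dtype=bool))
        return g, voxel.VoxelGrid(origin=np.zeros(3), pitch=pitch,
                                  mask=np.zeros((1, 1, 1), dtype=bool))
    bounds = np.array([np.min([m.bounds[0] for m in nonempty], axis=0),
                       np.max([m.bounds[1] for m in nonempty], axis=0)])
    layout = voxel.grid_layout(bounds, pitch, pad_voxels=2)
    return voxelize(mesh_a, pitch, grid=layout), voxelize(mesh_b, pitch, grid=layout)


def dice(mask_a: voxel.VoxelGrid, mask_b: voxel.VoxelGrid) -> float:
    """Volumetric Dice 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    if not mask_a.same_grid(mask_b):
        raise InvalidParameterError("dice requires masks on the same grid")
    a, b = mask_a.mask, mask_b.mask
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0  # two empty defects agree perfectly
    return 2.0 * int((a & b).sum()) / denom


def volume_errors(v_auto_cm3: float, v_ref_cm3: float):
    """(absolute error cm3, relative error %); the relative error is None
    for a zero reference volume."""
    mae = abs(float(v_auto_cm3) - float(v_ref_cm3))
    mare = 100.0 * mae / v_ref_cm3 if v_ref_cm3 > 0 else None
    return mae, mare


def _surface_samples(mesh: trimesh.Trimesh, density: float, seed: int = 0):
    n = max(int(np.ceil(mesh.area * density)), len(mesh.vertices), 16)
    pts, _ = trimesh.sample.sample_surface(mesh, n, seed=seed)
    return np.vstack([np.asarray(mesh.vertices), pts])


def hausdorff(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh,
              sample_density: float = DEFAULT_SAMPLE_DENSITY) -> float:
    """Symmetric Hausdorff distance (mm) between triangulated surfaces.

    Directed distances are measured from surface samples (>=
    ``sample_density`` points/mm^2 plus all vertices) to the exact closest
    point on the other surface, so the estimate converges to the true value
    from below as density grows.
    """
    from .shape_model import SurfaceLocator

    for name, m in (("mesh_a", mesh_a), ("mesh_b", mesh_b)):
        if m.is_empty or len(m.faces) == 0:
            raise InvalidParameterError(f"hausdorff: {name} is empty")
    pa = _surface_samples(mesh_a, sample_density)
    pb = _surface_samples(mesh_b, sample_density)
    cp_a, _ = SurfaceLocator(mesh_b).closest(pa)
    cp_b, _ = SurfaceLocator(mesh_a).closest(pb)
    da = np.linalg.norm(pa - cp_a, axis=1).max()
    db = np.linalg.norm(pb - cp_b, axis=1).max()
    return float(max(da, db))


def compare_defects(auto: trimesh.Trimesh, reference: trimesh.Trimesh,
                    pitch: float = DEFAULT_DICE_PITCH,
                    sample_density: float = DEFAULT_SAMPLE_DENSITY) -> ValidationReport:
    """Full report: Dice, volume MAE/MARE, Hausdorff for two defect solids."""
    ga, gb = shared_voxelize(auto, reference, pitch)
    d = dice(ga, gb)
    v_auto = float(auto.volume) / 1000.0 if len(auto.faces) else 0.0
    v_ref = float(reference.volume) / 1000.0 if len(reference.faces) else 0.0
    mae, mare = volume_errors(v_auto, v_ref)
    if len(auto.faces) and len(reference.faces):
        hd = hausdorff(auto, reference, sample_density)
        n_pts = int(np.ceil(auto.area * sample_density)
                    + np.ceil(reference.area * sample_density))
    else:
        hd, n_pts = float("nan"), 0
    return ValidationReport(dice=d, volume_mae_cm3=mae, volume_mare_pct=mare,
                            hausdorff_mm=hd, pitch=pitch,
                            n_points_sampled=n_pts)


def validate_against_truth(defect_mesh: trimesh.Trimesh, case,
                           pitch: float = DEFAULT_DICE_PITCH) -> ValidationReport:
    """Compare a reconstructed defect with a synthetic case's ground truth.

    The truth mask is re-evaluated analytically on the shared comparison
    grid (independent of any mesh rasterization); the truth surface for the
    Hausdorff term is the marching-cubes surface of the stored truth mask.
    """
    truth_grid = case.truth_defect_mask
    truth_mesh = voxel.surface_from_mask(truth_grid)
    if defect_mesh.is_empty or len(defect_mesh.faces) == 0:
        if not truth_grid.mask.any():
            return ValidationReport(dice=1.0, volume_mae_cm3=0.0,
                                    volume_mare_pct=None, hausdorff_mm=0.0,
                                    pitch=pitch, n_points_sampled=0)
        return ValidationReport(dice=0.0,
                                volume_mae_cm3=truth_grid.volume_cm3,
                                volume_mare_pct=100.0, hausdorff_mm=float("nan"),
                                pitch=pitch, n_points_sampled=0)
    bounds = np.array([
        np.minimum(defect_mesh.bounds[0], truth_mesh.bounds[0]),
        np.maximum(defect_mesh.bounds[1], truth_mesh.bounds[1]),
    ])
    layout = voxel.grid_layout(bounds, pitch, pad_voxels=2)
    auto_grid = voxelize(defect_mesh, pitch, grid=layout)
    truth_on_grid = voxel.VoxelGrid(
        origin=np.asarray(layout[0], float), pitch=pitch,
        mask=voxel.mask_from_function(case.defect_inside, layout[0], pitch,
                                      layout[1]))
    d = dice(auto_grid, truth_on_grid)
    mae, mare = volume_errors(float(defect_mesh.volume) / 1000.0,
                              case.truth_defect_volume_cm3)
    hd = hausdorff(defect_mesh, truth_mesh)
    n_pts = int(np.ceil(defect_mesh.area * DEFAULT_SAMPLE_DENSITY))
    return ValidationReport(dice=d, volume_mae_cm3=mae, volume_mare_pct=mare,
                            hausdorff_mm=hd, pitch=pitch, n_points_sampled=n_pts)
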
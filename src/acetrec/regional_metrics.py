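"""Regional partitioning of the acetabular neighbourhood and bone-loss metrics.

Four clinically motivated regions are anchored to the acetabular frame:

* superior: dominant-positive-superior angular sector, truncated at 2.2x
  the acetabular radius from the hip joint centre,
* anterior / posterior: dominant +/- anterior sectors truncated at 1.9x,
* medial wall: a cylinder of radius 0.86x aligned with the polar axis,
  extending medially (into the bone) by the excision radius 2.5x.

Sector membership compares the superior against the anterior components of
the offset from the HJC ("dominant axis" rule); regions may overlap and do
not partition space.  Per region the pipeline reports the absolute defect
volume (ADV, cm3), the relative defect volume (RDV, % of the regional
native bone, where native bone is the shape-model estimate united with the
defect solid), and the mean defect depth (DD, mm) over rays whose defect
interval midpoint falls in the region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from . import voxel
from .acetabular_frame import AcetabularFrame

REGION_NAMES = ("superior", "posterior", "anterior", "medial_wall")
SUPERIOR_EXTENT_FACTOR = 2.2
ANTEROPOSTERIOR_EXTENT_FACTOR = 1.9
MEDIAL_WALL_RADIUS_FACTOR = 0.86
MEDIAL_WALL_DEPTH_FACTOR = 2.5


@dataclass
class Region:
    """One region: analytic membership plus an on-demand watertight solid."""

    name: str
    frame: AcetabularFrame
    _mesh: trimesh.Trimesh = field(default=None, repr=False)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return region_membership(self.name, self.frame, points)

    def mesh(self, pitch: float = 1.5) -> trimesh.Trimesh:
        """Watertight region solid (signed-distance + marching cubes)."""
        if self._mesh is None:
            f = self.frame
            half = MEDIAL_WALL_DEPTH_FACTOR * f.radius + 3 * pitch
            bounds = np.array([f.hjc - half, f.hjc + half])
            origin, shape = voxel.grid_layout(bounds, pitch)
            sdf = voxel.sample_sdf(lambda p: _region_sdf(self.name, f, p),
                                   origin, pitch, shape)
            self._mesh = voxel.surface_from_sdf(sdf, origin, pitch)
        return self._mesh


@dataclass
class RegionSet:
    frame: AcetabularFrame
    regions: dict

    def __iter__(self):
        return iter(self.regions.values())

    def __getitem__(self, name: str) -> Region:
        return self.regions[name]


def _frame_components(frame: AcetabularFrame, points: np.ndarray):
    d = np.atleast_2d(points) - frame.hjc
    return (d @ frame.superior_axis, d @ frame.anterior_axis,
            d @ frame.polar_axis, np.linalg.norm(d, axis=1))


def region_membership(name: str, frame: AcetabularFrame,
                      points: np.ndarray) -> np.ndarray:
    """Boolean membership of points in a named region."""
    ds, da, dp, dist = _frame_components(frame, points)
    r = frame.radius
    # strict dominance: points on the polar axis (ds = da = 0) belong to no
    # angular sector — the medial-wall cylinder covers them
    if name == "superior":
        return (ds > np.abs(da)) & (dist <= SUPERIOR_EXTENT_FACTOR * r)
    if name == "anterior":
        return (da > np.abs(ds)) & (dist <= ANTEROPOSTERIOR_EXTENT_FACTOR * r)
    if name == "posterior":
        return (-da > np.abs(ds)) & (dist <= ANTEROPOSTERIOR_EXTENT_FACTOR * r)
    if name == "medial_wall":
        radial = np.sqrt(np.maximum(dist**2 - dp**2, 0.0))
        return (radial <= MEDIAL_WALL_RADIUS_FACTOR * r) \
            & (dp <= 0.0) & (dp >= -MEDIAL_WALL_DEPTH_FACTOR * r)
    if name == "total":
        return np.any([region_membership(n, frame, points) for n in REGION_NAMES],
                      axis=0)
    raise KeyError(name)


def _region_sdf(name: str, frame: AcetabularFrame, points: np.ndarray) -> np.ndarray:
    """Approximate signed distance (exact sign) used only for region meshes."""
    ds, da, dp, dist = _frame_components(frame, points)
    r = frame.radius
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    if name == "superior":
        return np.maximum.reduce([
            dist - SUPERIOR_EXTENT_FACTOR * r,
            (da - ds) * inv_sqrt2, (-da - ds) * inv_sqrt2])
    if name == "anterior":
        return np.maximum.reduce([
            dist - ANTEROPOSTERIOR_EXTENT_FACTOR * r,
            (ds - da) * inv_sqrt2, (-ds - da) * inv_sqrt2])
    if name == "posterior":
        return np.maximum.reduce([
            dist - ANTEROPOSTERIOR_EXTENT_FACTOR * r,
            (ds + da) * inv_sqrt2, (-ds + da) * inv_sqrt2])
    if name == "medial_wall":
        radial = np.sqrt(np.maximum(dist**2 - dp**2, 0.0))
        return np.maximum.reduce([
            radial - MEDIAL_WALL_RADIUS_FACTOR * r,
            dp, -dp - MEDIAL_WALL_DEPTH_FACTOR * r])
    raise KeyError(name)


def define_regions(frame: AcetabularFrame) -> RegionSet:
    return RegionSet(frame=frame,
                     regions={n: Region(n, frame) for n in REGION_NAMES})


@dataclass
class RegionalMetrics:
    """ADV (cm3), RDV (%), DD (mm) and supporting counts per region + total."""

    table: pd.DataFrame  # index: region names + 'total'

    def __getitem__(self, region: str) -> pd.Series:
        return self.table.loc[region]

    def to_csv(self, path):
        self.table.to_csv(path, index_label="region")

    def to_dict(self) -> dict:
        return {r: self.table.loc[r].to_dict() for r in self.table.index}

    @classmethod
    def from_rows(cls, rows: dict) -> "RegionalMetrics":
        df = pd.DataFrame.from_dict(rows, orient="index")
        df = df.reindex(list(REGION_NAMES) + ["total"])
        return cls(table=df)


def regional_volume(solid: trimesh.Trimesh, region: Region,
                    pitch: float = 0.7) -> float:
    """Volume (cm3) of ``solid`` inside a region.

    The solid is rasterized once and region membership is evaluated
    analytically at the occupied voxel centres, which is the voxel Boolean
    intersection without a second rasterization.
    """
    if solid.is_empty or len(solid.faces) == 0:
        return 0.0
    grid = voxel.solid_mask(solid, pitch, axis=0, name="solid")
    pts = grid.centers()[grid.mask.ravel()]
    if len(pts) == 0:
        return 0.0
    return float(region.contains(pts).sum()) * pitch**3 / 1000.0


def compute_rdv(defect_vol_cm3: float, native_ref_vol_cm3: float):
    """Relative defect volume (%) against the regional native reference.

    The native reference is vol((native U defect) ∩ region): the shape-model
    native estimate united with the defect solid, so a defect that consumed
    bone the estimate does not cover still counts against the denominator.
    Returns None when the region holds no native bone.
    """
    if native_ref_vol_cm3 <= 0:
        warnings.warn("zero native regional volume: RDV undefined")
        return None
    return 100.0 * defect_vol_cm3 / native_ref_vol_cm3


def ray_depths(first_native_hit, defect_t_end):
    """Defect depth per ray (mm): furthest defect-interval endpoint minus the
    first native-surface intersection, floored at zero."""
    return np.maximum(np.asarray(defect_t_end) - np.asarray(first_native_hit), 0.0)


def compute_dd(ray_dirs, ray_origin, first_native_hit, defect_t_end,
               interval_midpoints_t, frame: AcetabularFrame):
    """Mean defect depth (mm) per region and overall.

    ``interval_midpoints_t`` is a list (per ray) of defect-interval midpoint
    distances; a ray contributes its depth to every region containing at
    least one of its midpoints.  Rays without a positive depth are excluded
    from the averages (zero-depth rays would make DD an artefact of ray
    density rather than of the defect).
    """
    depths = ray_depths(first_native_hit, defect_t_end)
    ray_dirs = np.asarray(ray_dirs, dtype=float)
    ray_origin = np.asarray(ray_origin, dtype=float)
    ids, ts = [], []
    for i in np.flatnonzero(depths > 0):
        mids = np.asarray(interval_midpoints_t[i], dtype=float)
        if mids.size:
            ids.append(np.full(mids.size, i))
            ts.append(mids)
    out = {}
    if ids:
        ids = np.concatenate(ids)
        ts = np.concatenate(ts)
        pts = ray_origin + ts[:, None] * ray_dirs[ids]
        for name in REGION_NAMES + ("total",):
            member = region_membership(name, frame, pts)
            rays = np.unique(ids[member])
            out[name] = (float(depths[rays].mean()), int(len(rays))) if len(rays) \
                else (0.0, 0)
    else:
        out = {n: (0.0, 0) for n in REGION_NAMES + ("total",)}
    return out


def compute_regional_metrics(defect: trimesh.Trimesh, native: trimesh.Trimesh,
                             frame: AcetabularFrame, ray_data=None,
                             pitch: float = 0.7) -> RegionalMetrics:
    """Full per-region ADV/RDV/DD table for a defect solid.

    ``ray_data`` (optional) is a mapping with keys ``directions``, ``origin``,
    ``first_native_hit``, ``defect_t_end``, ``interval_midpoints_t`` as
    produced by the reconstruction stage; without it DD is reported as NaN.
    """
    regions = define_regions(frame)
    # One shared grid covering native+defect, two rasterizations.
    meshes = [m for m in (native, defect) if not m.is_empty and len(m.faces)]
    grids = voxel.shared_grid_masks(meshes, pitch, axis=0,
                                    names=["native", "defect"][: len(meshes)])
    native_grid = grids[0]
    defect_mask = grids[1].mask if len(grids) > 1 else np.zeros_like(native_grid.mask)
    ref_mask = native_grid.mask | defect_mask
    pts = native_grid.centers()
    vox_cm3 = pitch**3 / 1000.0

    if ray_data is not None:
        dd = compute_dd(ray_data["directions"], ray_data["origin"],
                        ray_data["first_native_hit"], ray_data["defect_t_end"],
                        ray_data["interval_midpoints_t"], frame)
    else:
        dd = {n: (np.nan, 0) for n in REGION_NAMES + ("total",)}

    rows = {}
    for name in REGION_NAMES + ("total",):
        member = region_membership(name, frame, pts)
        adv = float((defect_mask.ravel() & member).sum()) * vox_cm3
        native_ref = float((ref_mask.ravel() & member).sum()) * vox_cm3
        rdv = compute_rdv(adv, native_ref) if native_ref > 0 else None
        depth, n_rays = dd[name]
        rows[name] = {
            "adv_cm3": adv,
            "rdv_pct": np.nan if rdv is None else rdv,
            "dd_mm": depth,
            "native_cm3": native_ref,
            "n_valid_rays": n_rays,
        }
    return RegionalMetrics.from_rows(rows)
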
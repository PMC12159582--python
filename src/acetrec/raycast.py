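"""Batched ray casting from a single origin against a triangle mesh.

The defect pipeline casts tens of thousands of rays from the hip joint
centre.  All rays share one origin, so triangle culling can happen in
direction space: each triangle subtends an angular footprint around the
direction of its centroid, and only rays within that footprint need the
exact Moller-Trumbore test.  Candidate rays are found with a KD-tree over
the unit direction vectors (chord distance <-> angle), which keeps the
pairing near-linear in rays + triangles.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

_EPS_T = 1e-9          # reject hits at/behind the origin
DEDUP_TOL = 1e-6       # merge grazing duplicate hits (mm), per pipeline contract
MAX_HITS = 4           # retained intersections per ray

# Full-sphere solid angle in square degrees; a spacing of s degrees per
# direction therefore needs ~(129600/pi)/s^2 directions.
SPHERE_SQUARE_DEGREES = 129600.0 / np.pi


def direction_count(angular_spacing_deg: float) -> int:
    """Number of directions so each covers ~spacing^2 square degrees."""
    return max(16, int(round(SPHERE_SQUARE_DEGREES / angular_spacing_deg**2)))


def fibonacci_directions(n: int) -> np.ndarray:
    """Near-uniform unit directions on the full sphere (Fibonacci lattice).

    Uniform solid-angle coverage avoids the polar oversampling of a
    latitude-longitude grid, which would otherwise bias the density of
    recorded defect points (and hence the cluster-size filter).
    """
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


class SingleOriginCaster:
    """Casts many unit-direction rays from one origin through a mesh."""

    def __init__(self, mesh, origin):
        self.origin = np.asarray(origin, dtype=float)
        tri = np.asarray(mesh.triangles, dtype=float) - self.origin
        self.v0 = tri[:, 0]
        self.e1 = tri[:, 1] - tri[:, 0]
        self.e2 = tri[:, 2] - tri[:, 0]
        cent = tri.mean(axis=1)
        self.cent_dist = np.linalg.norm(cent, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.cent_dir = cent / self.cent_dist[:, None]
        # Angular footprint: largest angle centroid-direction <-> vertex-direction.
        vdist = np.linalg.norm(tri, axis=2)
        ok = (self.cent_dist > 1e-12) & np.all(vdist > 1e-12, axis=1)
        cosang = np.ones(len(tri))
        if ok.any():
            vdir = tri[ok] / vdist[ok][:, :, None]
            cosang[ok] = np.einsum("fvc,fc->fv", vdir, self.cent_dir[ok]).min(axis=1)
        self.ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        # Triangles subtending a huge angle (origin close by) are checked
        # against every ray instead of being culled.
        self.brute = ~ok | (self.ang > np.deg2rad(60.0))
        self.min_vdist = vdist.min(axis=1)

    def cast(self, directions: np.ndarray, max_range: float,
             max_hits: int = MAX_HITS):
        """Intersect all rays; return (hits, counts, truncated).

        hits: (n_rays, max_hits) ascending distances, NaN-padded.
        counts: retained hits per ray.
        truncated: True where more than ``max_hits`` distinct intersections
        existed within max_range (the surplus was discarded, so interval
        parity beyond the last retained hit is unknowable).
        """
        directions = np.asarray(directions, dtype=float)
        n_rays = len(directions)

        in_range = self.min_vdist <= max_range
        cull = in_range & ~self.brute
        pair_tri = []
        pair_ray = []
        if cull.any():
            tree = cKDTree(directions)
            # chord distance on the unit sphere for angle ang (+5% margin + abs pad)
            radius = 2.0 * np.sin(np.minimum(self.ang[cull] * 1.05 + 1e-3, np.pi) / 2.0)
            lists = tree.query_ball_point(self.cent_dir[cull], radius)
            tri_idx = np.flatnonzero(cull)
            for t_i, rays in zip(tri_idx, lists):
                if rays:
                    pair_tri.append(np.full(len(rays), t_i, dtype=np.int64))
                    pair_ray.append(np.asarray(rays, dtype=np.int64))
        bf = np.flatnonzero(in_range & self.brute)
        if len(bf):
            pair_tri.append(np.repeat(bf, n_rays))
            pair_ray.append(np.tile(np.arange(n_rays, dtype=np.int64), len(bf)))

        hits = np.full((n_rays, max_hits), np.nan)
        counts = np.zeros(n_rays, dtype=np.int64)
        truncated = np.zeros(n_rays, dtype=bool)
        if not pair_tri:
            return hits, counts, truncated
        ti = np.concatenate(pair_tri)
        ri = np.concatenate(pair_ray)

        # Moller-Trumbore on the candidate pairs.
        d = directions[ri]
        e1, e2, v0 = self.e1[ti], self.e2[ti], self.v0[ti]
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = -v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("ij,ij->i", d, qvec) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        good = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1.0 + 1e-12) \
            & (t > _EPS_T) & (t <= max_range)
        if not good.any():
            return hits, counts, truncated
        ri, t = ri[good], t[good]

        order = np.lexsort((t, ri))
        ri, t = ri[order], t[order]
        # Dedup grazing hits (same ray, |dt| < tol): vertex/edge-adjacent
        # triangles both report the crossing.
        same = np.zeros(len(t), dtype=bool)
        same[1:] = (ri[1:] == ri[:-1]) & (np.diff(t) < DEDUP_TOL)
        ri, t = ri[~same], t[~same]

        ray_ids, start = np.unique(ri, return_index=True)
        end = np.append(start[1:], len(ri))
        for rid, s, e in zip(ray_ids, start, end):
            n = e - s
            if n > max_hits:
                truncated[rid] = True
                n = max_hits
            hits[rid, :n] = t[s:s + n]
            counts[rid] = n
        return hits, counts, truncated


def cast_ray(origin, direction, mesh, max_range: float,
             max_hits: int = MAX_HITS):
    """Single-ray convenience wrapper: sorted hit distances (<= max_hits,
    <= max_range) and a truncation flag."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    caster = SingleOriginCaster(mesh, origin)
    hits, counts, trunc = caster.cast(direction[None, :], max_range, max_hits)
    return hits[0, : counts[0]].tolist(), bool(trunc[0])
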
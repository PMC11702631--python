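"""Spatial correlations between cortical maps and spin-permutation nulls.

The Pearson correlation between two vertex maps overstates significance when
both maps are spatially autocorrelated.  The spin test builds a null that
preserves each map's autocorrelation: the spherical coordinates of one map are
rotated by a uniformly random 3x3 rotation, vertex values are re-sampled by
nearest neighbour, and the correlation is recomputed.  The left-hemisphere
rotation R is mirrored to the right hemisphere as M R M with M = diag(-1,1,1),
so the two hemispheres spin as one rigid, mirror-consistent motion.  Rotated
source vertices that land on the medial wall are treated as missing and
dropped pairwise per spin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .surface import MeshMismatchError, Parcellation, SphereMesh, VertexMap

__all__ = [
    "SpinNullSet",
    "SpatialCorrelation",
    "RegionCorrelationTable",
    "pearson_map_correlation",
    "generate_spins",
    "spin_pvalue",
    "region_correlations",
]

_MISSING = -1  # permutation entry for "source fell on the medial wall"
_MIN_REGION_VERTICES = 10


@dataclass
class SpinNullSet:
    """Seeded set of rotation-induced vertex permutations.

    ``permutations[s, v]`` is the source vertex whose value map ``v`` receives
    under spin ``s`` (or -1 when the source is a medial-wall vertex).
    Entries only ever reference same-hemisphere vertices.
    """

    permutations: np.ndarray  # (n_spins, n_vertices) int
    rotations: np.ndarray  # (n_spins, 3, 3) left-hemisphere rotations
    seed: int
    mesh_id: str

    @property
    def n_spins(self) -> int:
        return self.permutations.shape[0]


@dataclass
class SpatialCorrelation:
    r: float
    p_spin: float
    n_vertices_used: int
    n_spins: int


@dataclass
class RegionCorrelationTable:
    """Per paired region: Pearson r on that region's valid vertices."""

    region_ids: np.ndarray
    region_names: list[str]
    r: np.ndarray
    n_vertices: np.ndarray
    low_coverage: np.ndarray  # True where a region had < 10 valid vertices

    def as_records(self) -> list[dict]:
        return [
            {
                "region_id": int(i),
                "region": nm,
                "r": float(r),
                "n_vertices": int(n),
                "low_coverage": bool(lc),
            }
            for i, nm, r, n, lc in zip(
                self.region_ids, self.region_names, self.r, self.n_vertices, self.low_coverage
            )
        ]


def _paired_valid(map_a: VertexMap, map_b: VertexMap) -> np.ndarray:
    if map_a.n_vertices != map_b.n_vertices:
        raise MeshMismatchError("maps have different vertex counts")
    if map_a.mesh_id and map_b.mesh_id and map_a.mesh_id != map_b.mesh_id:
        raise MeshMismatchError("maps belong to different meshes")
    return map_a.mask & map_b.mask & np.isfinite(map_a.values) & np.isfinite(map_b.values)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on the valid vertex set")
    return float((xc @ yc) / (sx * sy))


def pearson_map_correlation(map_a: VertexMap, map_b: VertexMap) -> float:
    """Sample Pearson r over the intersection of both maps' valid vertices."""
    valid = _paired_valid(map_a, map_b)
    if valid.sum() < 3:
        raise ValueError(f"need at least 3 jointly valid vertices, got {valid.sum()}")
    return _pearson(map_a.values[valid], map_b.values[valid])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform (Haar) random rotation: QR of a Gaussian matrix with the sign
    correction, det forced to +1 by negating the third column if needed."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def generate_spins(mesh: SphereMesh, n_spins: int, seed: int) -> SpinNullSet:
    """Build ``n_spins`` rotation permutations of the mesh vertices.

    For each spin a uniform rotation R is applied to the left-hemisphere
    sphere coordinates and its mirror conjugate M R M to the right; each
    vertex's permuted source is the nearest rotated vertex (ties broken by
    lowest vertex index).  Because the right hemisphere is the exact x-mirror
    of the left, the right-hemisphere permutation equals the left's under the
    index correspondence, which is how it is constructed.  Sources that are
    medial-wall vertices are recorded as missing (-1).
    """
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    rng = np.random.default_rng(seed)
    n = mesh.n_per_hemi
    left = mesh.coords[:n]
    cortex_left = mesh.cortex_mask[:n]
    perms = np.empty((n_spins, mesh.n_vertices), dtype=np.int64)
    rots = np.empty((n_spins, 3, 3))
    for s in range(n_spins):
        rot = _random_rotation(rng)
        rots[s] = rot
        rotated = left @ rot.T
        # nearest rotated vertex for every original position; cKDTree resolves
        # exact ties toward the lowest index
        tree = cKDTree(rotated)
        _, src = tree.query(left, k=1)
        src = np.asarray(src, dtype=np.int64)
        src_l = np.where(cortex_left[src], src, _MISSING)
        src_r = np.where(src_l == _MISSING, _MISSING, src_l + n)
        perms[s, :n] = src_l
        perms[s, n:] = src_r
    return SpinNullSet(perms, rots, seed, mesh.mesh_id)


def spin_pvalue(map_a: VertexMap, map_b: VertexMap, spins: SpinNullSet) -> SpatialCorrelation:
    """Two-sided spin-permutation p-value for the correlation of two maps.

    ``map_a`` is the map that gets spun (by convention the association map);
    ``map_b`` stays fixed.  p = (1 + #{|r_null| >= |r_obs|}) / (n_spins + 1),
    guaranteeing p in (0, 1].
    """
    if spins.mesh_id and map_a.mesh_id and spins.mesh_id != map_a.mesh_id:
        raise MeshMismatchError("spin set was built on a different mesh")
    valid = _paired_valid(map_a, map_b)
    if valid.sum() < 3:
        raise ValueError("need at least 3 jointly valid vertices")
    r_obs = _pearson(map_a.values[valid], map_b.values[valid])

    a = map_a.values
    b = map_b.values
    count = 0
    for s in range(spins.n_spins):
        src = spins.permutations[s]
        ok = valid & (src != _MISSING)
        a_perm = a[src[ok]]
        pair_ok = np.isfinite(a_perm)
        x = a_perm[pair_ok]
        y = b[ok][pair_ok]
        if len(x) < 3:
            continue
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        if denom == 0:
            continue
        r_null = (xc @ yc) / denom
        if abs(r_null) >= abs(r_obs):
            count += 1
    p = (1.0 + count) / (spins.n_spins + 1.0)
    return SpatialCorrelation(r_obs, p, int(valid.sum()), spins.n_spins)


def region_correlations(
    map_a: VertexMap, map_b: VertexMap, parcellation: Parcellation
) -> RegionCorrelationTable:
    """Pearson r of the two maps within each paired region.

    Left/right vertices of the same-named region are pooled (paired
    parcellation).  Regions with fewer than 10 jointly valid vertices are
    flagged as low coverage; regions with degenerate (constant) values within
    the valid set get r = NaN.
    """
    if len(parcellation.labels) != map_a.n_vertices:
        raise MeshMismatchError("parcellation does not match the maps' mesh")
    if parcellation.mesh_id and map_a.mesh_id and parcellation.mesh_id != map_a.mesh_id:
        raise MeshMismatchError("parcellation was built on a different mesh")
    valid = _paired_valid(map_a, map_b)
    ids = parcellation.region_ids
    rs = np.full(len(ids), np.nan)
    counts = np.zeros(len(ids), dtype=int)
    low = np.zeros(len(ids), dtype=bool)
    for j, rid in enumerate(ids):
        sel = (parcellation.labels == rid) & valid
        counts[j] = sel.sum()
        if counts[j] < _MIN_REGION_VERTICES:
            low[j] = True
        if counts[j] >= 3:
            try:
                rs[j] = _pearson(map_a.values[sel], map_b.values[sel])
            except ValueError:
                rs[j] = np.nan
    names = [parcellation.region_names.get(i, str(i)) for i in ids]
    return RegionCorrelationTable(np.asarray(ids), names, rs, counts, low)
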
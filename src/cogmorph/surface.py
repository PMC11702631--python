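"""Spherical cortical surface substrate: meshes, masks, parcellations, smoothing.

Every downstream analysis in this package operates on vertex-indexed maps over a
two-hemisphere spherical mesh, playing the role the registered ``fsaverage``
sphere plays for real cortical data.  Each hemisphere is a full icosphere of
radius 100 mm (the FreeSurfer convention), the right hemisphere being the
mirror image of the left through the x = 0 plane, so vertex ``i`` of the left
hemisphere corresponds to vertex ``i + n_per_hemi`` on the right.  Non-cortical
tissue (the medial wall) is represented in-band as ``cortex_mask = False``
rather than by dropping vertices, so all maps stay length-aligned.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "SphereMesh",
    "VertexMap",
    "Parcellation",
    "build_icosphere",
    "make_medial_wall",
    "geodesic_parcellate",
    "smooth_map",
    "HeatKernelSmoother",
    "MeshMismatchError",
]

#: FWHM of a Gaussian = sigma * sqrt(8 ln 2)
_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

MAX_SUBDIVISION = 7


class MeshMismatchError(ValueError):
    """A map or parcellation was combined with a mesh it does not belong to."""


@dataclass(frozen=True)
class SphereMesh:
    """Two-hemisphere triangulated sphere (radius in mm per hemisphere).

    Attributes
    ----------
    coords : (n_vertices, 3) float array on the sphere of radius ``radius_mm``.
    faces : (n_faces, 3) int array of triangle vertex indices.
    hemisphere : (n_vertices,) int8 array; 0 = left, 1 = right.
    cortex_mask : (n_vertices,) bool; False marks the medial wall.
    """

    coords: np.ndarray
    faces: np.ndarray
    hemisphere: np.ndarray
    cortex_mask: np.ndarray
    radius_mm: float
    subdivision: int

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def n_per_hemi(self) -> int:
        return self.n_vertices // 2

    @property
    def mesh_id(self) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.coords).tobytes())
        h.update(np.ascontiguousarray(self.cortex_mask).tobytes())
        return h.hexdigest()[:12]

    def hemi_indices(self, hemi: str) -> np.ndarray:
        code = {"left": 0, "L": 0, "right": 1, "R": 1}[hemi]
        return np.flatnonzero(self.hemisphere == code)

    def mirror_index(self, idx: np.ndarray) -> np.ndarray:
        """Index of the mirror vertex in the opposite hemisphere."""
        idx = np.asarray(idx)
        n = self.n_per_hemi
        return np.where(idx < n, idx + n, idx - n)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) array."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self, *, weighted: bool = False) -> sparse.csr_matrix:
        """Symmetric vertex adjacency; weights are edge lengths if requested."""
        e = self.edges()
        if weighted:
            w = np.linalg.norm(self.coords[e[:, 0]] - self.coords[e[:, 1]], axis=1)
        else:
            w = np.ones(len(e))
        n = self.n_vertices
        a = sparse.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        return a.tocsr()


@dataclass
class VertexMap:
    """One real value per mesh vertex, with an in-band validity mask.

    Masked-out entries hold NaN, never a silent zero.
    """

    values: np.ndarray
    mask: np.ndarray
    name: str = ""
    mesh_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        self.mask = np.asarray(self.mask, dtype=bool).copy()
        if self.values.shape != self.mask.shape or self.values.ndim != 1:
            raise ValueError("values and mask must be 1-D arrays of equal length")
        self.values[~self.mask] = np.nan

    @classmethod
    def from_values(cls, values: np.ndarray, name: str = "", mesh: SphereMesh | None = None) -> "VertexMap":
        values = np.asarray(values, dtype=float)
        mask = np.isfinite(values)
        if mesh is not None:
            if len(values) != mesh.n_vertices:
                raise MeshMismatchError(
                    f"map has {len(values)} values but mesh has {mesh.n_vertices} vertices"
                )
            mask = mask & mesh.cortex_mask
            return cls(values, mask, name=name, mesh_id=mesh.mesh_id)
        return cls(values, mask, name=name)

    @property
    def n_vertices(self) -> int:
        return len(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class Parcellation:
    """Region id per vertex; id 0 is the reserved "unknown" (medial wall) label.

    With ``paired=True`` the same region id appears in both hemispheres
    (the left/right paired convention of the Desikan-Killiany atlas).
    """

    labels: np.ndarray
    region_names: dict[int, str]
    paired: bool
    mesh_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).copy()

    @property
    def region_ids(self) -> list[int]:
        return sorted(k for k in self.region_names if k != 0)

    def vertices_of(self, region_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == region_id)


# ----------------------------------------------------------------------------
# Icosphere construction
# ----------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return v, f


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One 4-to-1 midpoint subdivision with a shared-edge midpoint cache."""
    cache: dict[tuple[int, int], int] = {}
    verts = list(verts)

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = cache.get(key)
        if idx is None:
            idx = len(verts)
            verts.append((np.asarray(verts[a]) + np.asarray(verts[b])) / 2.0)
            cache[key] = idx
        return idx

    out = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])
    return np.asarray(verts, dtype=float), np.asarray(out, dtype=int)


def build_icosphere(subdivision_level: int, radius_mm: float = 100.0) -> SphereMesh:
    """Two mirrored full-sphere hemispheres, each an icosahedron subdivided
    ``subdivision_level`` times and projected to the sphere of ``radius_mm``.

    Vertex counts follow 10 * 4**s + 2 per hemisphere.
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    if subdivision_level > MAX_SUBDIVISION:
        raise ValueError(
            f"subdivision_level {subdivision_level} exceeds the guard limit {MAX_SUBDIVISION}"
        )
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    v, f = _icosahedron()
    for _ in range(subdivision_level):
        v, f = _subdivide(v, f)
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * radius_mm
    n = len(v)
    # right hemisphere: reflect through x = 0; reverse winding to keep
    # outward-facing orientation
    v_r = v * np.array([-1.0, 1.0, 1.0])
    f_r = f[:, ::-1] + n
    coords = np.vstack([v, v_r])
    faces = np.vstack([f, f_r])
    hemisphere = np.repeat(np.array([0, 1], dtype=np.int8), n)
    mask = np.ones(2 * n, dtype=bool)
    return SphereMesh(coords, faces, hemisphere, mask, float(radius_mm), subdivision_level)


def make_medial_wall(
    mesh: SphereMesh, cap_fraction: float, pole: tuple[float, float, float] = (1.0, 0.0, 0.0)
) -> SphereMesh:
    """Mark a symmetric polar cap per hemisphere as non-cortex.

    In each hemisphere the ``floor(cap_fraction * n_per_hemi)`` vertices with
    the smallest angular distance to the (mirrored) pole direction get
    ``cortex_mask = False``, emulating the medial-wall mask of a registered
    template surface.  The right-hemisphere pole is the x-mirror of the left's,
    so the mask is mirror-symmetric.
    """
    if not (0.0 <= cap_fraction < 0.5):
        raise ValueError("cap_fraction must satisfy 0 <= cap_fraction < 0.5")
    p = np.asarray(pole, dtype=float)
    nrm = np.linalg.norm(p)
    if nrm == 0:
        raise ValueError("pole direction must be non-zero")
    p = p / nrm
    n = mesh.n_per_hemi
    n_cap = int(np.floor(cap_fraction * n))
    mask = np.ones(mesh.n_vertices, dtype=bool)
    if n_cap > 0:
        left = mesh.coords[:n] @ p
        # stable argsort on (-dot, index): deterministic under ties
        order = np.argsort(-left, kind="stable")
        capped = order[:n_cap]
        mask[capped] = False
        mask[capped + n] = False  # mirror symmetry by index correspondence
    return replace(mesh, cortex_mask=mask)


# ----------------------------------------------------------------------------
# Geodesic parcellation
# ----------------------------------------------------------------------------

def geodesic_parcellate(mesh: SphereMesh, n_regions_per_hemi: int, seed: int) -> Parcellation:
    """Paired geodesic-Voronoi parcellation of the cortex.

    Seeds are placed on the left-hemisphere cortex by farthest-point sampling
    under graph-geodesic distance, every cortex vertex is assigned to its
    nearest seed, and the labels are mirrored to the right hemisphere so that
    regions are left/right paired.  Deterministic given ``seed``.
    """
    if n_regions_per_hemi < 1:
        raise ValueError("n_regions_per_hemi must be >= 1")
    n = mesh.n_per_hemi
    cortex_left = np.flatnonzero(mesh.cortex_mask[:n])
    if n_regions_per_hemi > len(cortex_left):
        raise ValueError(
            f"n_regions_per_hemi={n_regions_per_hemi} exceeds the "
            f"{len(cortex_left)} cortex vertices per hemisphere"
        )
    adj = mesh.adjacency(weighted=True)[:n, :n]
    # restrict walks to cortex vertices
    keep = np.zeros(n, dtype=bool)
    keep[cortex_left] = True
    keep_d = sparse.diags(keep.astype(float))
    adj = (keep_d @ adj @ keep_d).tocsr()
    adj.eliminate_zeros()

    rng = np.random.default_rng(seed)
    first = int(rng.choice(cortex_left))
    seeds = [first]
    min_dist = dijkstra(adj, directed=False, indices=first)
    labels_left = np.zeros(n, dtype=int)
    labels_left[cortex_left] = 1
    for k in range(1, n_regions_per_hemi):
        cand = cortex_left[np.argmax(min_dist[cortex_left])]
        seeds.append(int(cand))
        d = dijkstra(adj, directed=False, indices=int(cand))
        closer = d < min_dist
        labels_left[closer] = k + 1
        min_dist = np.minimum(min_dist, d)
    if not np.all(np.isfinite(min_dist[cortex_left])):
        raise RuntimeError("cortex is not edge-connected; unreachable vertices found")
    labels = np.zeros(mesh.n_vertices, dtype=int)
    labels[:n][mesh.cortex_mask[:n]] = labels_left[mesh.cortex_mask[:n]]
    labels[n:] = labels[:n]  # mirror by index correspondence
    labels[~mesh.cortex_mask] = 0
    names = {0: "unknown"}
    names.update({k: f"region_{k:02d}" for k in range(1, n_regions_per_hemi + 1)})
    return Parcellation(labels, names, paired=True, mesh_id=mesh.mesh_id)


# ----------------------------------------------------------------------------
# Heat-kernel smoothing
# ----------------------------------------------------------------------------

class HeatKernelSmoother:
    """Approximate Gaussian smoothing on the mesh by explicit heat-equation steps.

    The Gaussian FWHM (mm along the surface) is converted to a diffusion time
    t = sigma**2 / 2 with sigma = fwhm / sqrt(8 ln 2), and the heat equation is
    integrated on the cortex subgraph with the symmetric combinatorial
    Laplacian, scaled by the mean edge length so that time has mm**2 units.
    The step size is capped so the per-step diffusion length stays below half
    the mean edge length (and below the explicit-Euler stability bound), hence
    the kernel is Gaussian-like but exact Gaussian equivalence is not promised.

    The operator is symmetric and annihilates constants, so the mean over the
    smoothed vertex set is preserved to round-off and smoothing is linear.
    Vertices outside ``valid`` neither contribute nor receive mass.
    """

    def __init__(self, mesh: SphereMesh, fwhm_mm: float, mask: np.ndarray | None = None):
        if fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        self.mesh = mesh
        self.fwhm_mm = float(fwhm_mm)
        valid = mesh.cortex_mask.copy()
        if mask is not None:
            valid &= np.asarray(mask, dtype=bool)
        self.valid = valid
        if fwhm_mm == 0:
            self.n_steps = 0
            return
        adj = mesh.adjacency(weighted=True)
        keep = sparse.diags(valid.astype(float))
        adj = keep @ adj @ keep
        lengths = adj.data[adj.data > 0]
        lbar = float(lengths.mean())
        w = adj.copy()
        w.data = np.ones_like(w.data)  # uniform weights on the kept edges
        deg = np.asarray(w.sum(axis=1)).ravel()
        sigma = fwhm_mm * _FWHM_TO_SIGMA
        t_graph = (sigma**2 / 2.0) / lbar**2  # diffusion time in edge-length units
        max_deg = float(deg.max()) if deg.max() > 0 else 1.0
        lam_max = min(1.0 / 8.0, 0.5 / max_deg)
        self.n_steps = max(1, int(np.ceil(t_graph / lam_max)))
        self.lam = t_graph / self.n_steps
        self._w = w.tocsr()
        self._deg = deg

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Smooth one map (1-D) or a stack of maps (rows of a 2-D array)."""
        x = np.array(values, dtype=float, copy=True)
        if self.n_steps == 0:
            return x
        one_d = x.ndim == 1
        if one_d:
            x = x[None, :]
        if x.shape[1] != self.mesh.n_vertices:
            raise MeshMismatchError("value array length does not match the mesh")
        v = self.valid
        y = x[:, v]
        y = np.nan_to_num(y, nan=0.0)
        wv = self._w[v][:, v]
        dv = self._deg[v]
        for _ in range(self.n_steps):
            y = y + self.lam * (y @ wv.T - y * dv)
        x[:, v] = y
        return x[0] if one_d else x


def smooth_map(mesh: SphereMesh, vmap: VertexMap, fwhm_mm: float) -> VertexMap:
    """Heat-kernel smooth a vertex map at the given FWHM (mm).

    Masked vertices are excluded from the diffusion (mask-aware): they keep
    their input values and stay masked in the output.
    """
    if vmap.mesh_id and vmap.mesh_id != mesh.mesh_id:
        raise MeshMismatchError(
            f"map belongs to mesh {vmap.mesh_id!r}, not {mesh.mesh_id!r}"
        )
    if len(vmap.values) != mesh.n_vertices:
        raise MeshMismatchError("map length does not match mesh vertex count")
    sm = HeatKernelSmoother(mesh, fwhm_mm, mask=vmap.mask)
    out = sm.apply(vmap.values)
    return VertexMap(out, vmap.mask & mesh.cortex_mask, name=vmap.name, mesh_id=mesh.mesh_id)
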
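"""Decomposition of a stack of neurobiological cortical profile maps.

A profile stack is the vertices x maps matrix of group-level cortical maps
(receptor densities, gene expression, metabolism, similarity gradients, ...),
restricted to the vertices valid in *all* maps and column-standardized.  PCA
of the column correlation matrix identifies the few spatial dimensions the
maps share; the retained components are varimax-rotated toward simple
structure, vertex component scores are mapped back to the surface, and Tucker
congruence coefficients match components across solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .surface import MeshMismatchError, VertexMap

__all__ = [
    "ProfileStack",
    "PCAResult",
    "build_stack",
    "pca",
    "varimax",
    "congruence",
    "metabolism_pc1",
    "category_abs_r_test",
]

CATEGORIES = ("microstructure", "macrostructure", "functional", "receptor")


@dataclass
class ProfileStack:
    """Column-standardized valid-vertex x map matrix with map metadata."""

    matrix: np.ndarray  # (n_valid_vertices, n_maps), each column mean 0 / SD 1
    map_names: list[str]
    categories: list[str]
    mask: np.ndarray  # (n_vertices,) common valid-vertex set
    mesh_id: str = ""

    @property
    def n_maps(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_valid(self) -> int:
        return self.matrix.shape[0]

    def correlation_matrix(self) -> np.ndarray:
        return (self.matrix.T @ self.matrix) / (self.n_valid - 1)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # all n_maps eigenvalues of the correlation matrix
    pct_variance: np.ndarray  # percent of total variance per component
    loadings: np.ndarray  # (n_maps, n_retained), sqrt-eigenvalue metric
    rotated_loadings: np.ndarray
    rotation_matrix: np.ndarray
    scores: np.ndarray  # (n_valid, n_retained) unrotated, unit-SD columns
    rotated_scores: np.ndarray
    n_retained: int
    mask: np.ndarray
    mesh_id: str = ""

    def score_map(self, component: int, rotated: bool = True) -> VertexMap:
        src = self.rotated_scores if rotated else self.scores
        vals = np.full(len(self.mask), np.nan)
        vals[self.mask] = src[:, component]
        tag = "rc" if rotated else "pc"
        return VertexMap(vals, self.mask.copy(), name=f"{tag}{component + 1}", mesh_id=self.mesh_id)


def build_stack(
    maps: list[VertexMap], categories: list[str] | None = None
) -> ProfileStack:
    """Stack maps on their common valid-vertex set and z-score each column."""
    if not maps:
        raise ValueError("need at least one map")
    n = maps[0].n_vertices
    mesh_ids = {m.mesh_id for m in maps if m.mesh_id}
    if len(mesh_ids) > 1:
        raise MeshMismatchError("maps belong to different meshes")
    mask = np.ones(n, dtype=bool)
    for m in maps:
        if m.n_vertices != n:
            raise MeshMismatchError("maps have different vertex counts")
        mask &= m.mask & np.isfinite(m.values)
    if mask.sum() < len(maps) + 2:
        raise ValueError("too few jointly valid vertices for a stable stack")
    cols = np.column_stack([m.values[mask] for m in maps])
    sd = cols.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        names = [maps[j].name or f"map {j}" for j in zero]
        raise ValueError(f"zero variance on the intersection mask: {names}")
    cols = (cols - cols.mean(axis=0)) / sd
    if categories is None:
        categories = ["unknown"] * len(maps)
    if len(categories) != len(maps):
        raise ValueError("one category per map required")
    names = [m.name or f"map_{j:02d}" for j, m in enumerate(maps)]
    return ProfileStack(cols, names, list(categories), mask, mesh_ids.pop() if mesh_ids else "")


def _orient_columns(loadings: np.ndarray) -> np.ndarray:
    """Sign convention: each component's largest-|loading| entry is positive."""
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return flip


def pca(stack: ProfileStack, n_retain: int, *, kaiser_normalize: bool = True) -> PCAResult:
    """Correlation-matrix PCA of the stack, with varimax-rotated retained part.

    Loadings are reported in the sqrt-eigenvalue metric (the loading of map m
    on component c is the correlation between map m and component c), so
    simple-structure thresholds like |loading| < 0.3 are meaningful.
    Component scores (unit SD over valid vertices) are returned both unrotated
    and as regression scores from the rotated loadings.
    """
    if not (1 <= n_retain <= stack.n_maps):
        raise ValueError("n_retain must lie in [1, n_maps]")
    z = stack.matrix
    nv = stack.n_valid
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = s**2 / (nv - 1)
    pct = 100.0 * eig / eig.sum()
    vecs = vt.T[:, :n_retain]
    flip = _orient_columns(vecs * np.sqrt(eig[:n_retain]))
    vecs = vecs * flip
    loadings = vecs * np.sqrt(eig[:n_retain])
    scores = u[:, :n_retain] * flip * np.sqrt(nv - 1)  # unit-SD columns
    rotated, rot = varimax(loadings, kaiser_normalize=kaiser_normalize)
    # regression scores from the rotated loadings, rescaled to unit SD
    w = rotated @ np.linalg.inv(rotated.T @ rotated)
    rot_scores = z @ w
    rot_sd = rot_scores.std(axis=0, ddof=1)
    rot_scores = rot_scores / np.where(rot_sd > 0, rot_sd, 1.0)
    return PCAResult(
        eigenvalues=eig,
        pct_variance=pct,
        loadings=loadings,
        rotated_loadings=rotated,
        rotation_matrix=rot,
        scores=scores,
        rotated_scores=rot_scores,
        n_retained=n_retain,
        mask=stack.mask.copy(),
        mesh_id=stack.mesh_id,
    )


def _varimax_criterion(lam: np.ndarray) -> float:
    """Sum over components of the variance of squared loadings."""
    sq = lam**2
    return float(np.sum(sq**2) - np.sum(sq.sum(axis=0) ** 2) / lam.shape[0])


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a maps x components loading matrix.

    Iterative pairwise planar rotations maximize the varimax criterion (the
    summed variance of squared loadings, after optional Kaiser row
    normalization).  The criterion is non-decreasing across sweeps; iteration
    stops when a full sweep gains less than ``tol``.  Returns the rotated
    loadings and the orthogonal rotation matrix R with ``rotated = L @ R``.
    """
    lam = np.asarray(loadings, dtype=float).copy()
    p, k = lam.shape
    rot = np.eye(k)
    if k == 1:
        return lam, rot
    comm = None
    if kaiser_normalize:
        comm = np.sqrt((lam**2).sum(axis=1))
        comm[comm == 0] = 1.0
        lam = lam / comm[:, None]
    crit = _varimax_criterion(lam)
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = lam[:, i], lam[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                a, b = u.sum(), v.sum()
                c = (u**2 - v**2).sum()
                d = 2.0 * (u * v).sum()
                num = d - 2.0 * a * b / p
                den = c - (a**2 - b**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                g = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
                lam[:, [i, j]] = lam[:, [i, j]] @ g
                rot[:, [i, j]] = rot[:, [i, j]] @ g
        new_crit = _varimax_criterion(lam)
        if new_crit - crit < tol:
            break
        crit = new_crit
    if kaiser_normalize:
        lam = lam * comm[:, None]
    flip = _orient_columns(lam)
    lam = lam * flip
    rot = rot * flip
    return lam, rot


def congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient phi = sum(ab) / sqrt(sum(a^2) sum(b^2))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("loading vectors must have equal length")
    na = a @ a
    nb = b @ b
    if na == 0 or nb == 0:
        raise ValueError("congruence is undefined for a zero vector")
    return float((a @ b) / np.sqrt(na * nb))


def metabolism_pc1(maps: list[VertexMap]) -> tuple[VertexMap, np.ndarray, float]:
    """First principal component of exactly three metabolism maps.

    Returns (PC1 score map, loadings, percent variance explained); the
    component is oriented so all loadings are positive when the inputs
    positively covary (higher scores = higher metabolic activity).
    """
    if len(maps) != 3:
        raise ValueError(f"metabolism PC1 expects exactly 3 maps, got {len(maps)}")
    stack = build_stack(maps, categories=["functional"] * 3)
    res = pca(stack, n_retain=1)
    load = res.loadings[:, 0]
    scores = res.scores[:, 0]
    if load.sum() < 0:  # orient toward higher metabolism
        load, scores = -load, -scores
    vals = np.full(len(res.mask), np.nan)
    vals[res.mask] = scores
    pc1_map = VertexMap(vals, res.mask.copy(), name="metabolism_pc1", mesh_id=res.mesh_id)
    return pc1_map, load, float(res.pct_variance[0])


def category_abs_r_test(
    corr_matrix: np.ndarray,
    categories: list[str],
    group_a: str = "receptor",
    grouping: str = "pooled_other",
):
    """Welch t-test comparing |r| of within-group map pairs against the rest.

    Group A pairs are those where *both* maps belong to ``group_a`` (e.g. the
    within-neurotransmitter pairs).  With ``grouping='pooled_other'`` the
    comparison group is all pairs among non-group-A maps; with
    ``grouping='within_category'`` it is restricted to pairs whose two maps
    share some other category.  Self-correlations and duplicate pairs are
    excluded.  Returns (t, df, p, summary dict).
    """
    r = np.asarray(corr_matrix, dtype=float)
    m = r.shape[0]
    if r.shape != (m, m) or len(categories) != m:
        raise ValueError("corr_matrix must be square with one category per map")
    cats = list(categories)
    in_a = [c == group_a for c in cats]
    if grouping not in ("pooled_other", "within_category"):
        raise ValueError(f"unknown grouping {grouping!r}")
    a_vals, b_vals = [], []
    for i in range(m):
        for j in range(i + 1, m):
            if in_a[i] and in_a[j]:
                a_vals.append(abs(r[i, j]))
            elif not in_a[i] and not in_a[j]:
                if grouping == "within_category" and cats[i] != cats[j]:
                    continue
                b_vals.append(abs(r[i, j]))
    if len(a_vals) < 2 or len(b_vals) < 2:
        raise ValueError("each group needs at least 2 map pairs")
    a = np.asarray(a_vals)
    b = np.asarray(b_vals)
    res = stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite df
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    summary = {
        "group_a_mean": float(a.mean()),
        "group_a_sd": float(a.std(ddof=1)),
        "group_a_n_pairs": len(a),
        "other_mean": float(b.mean()),
        "other_sd": float(b.std(ddof=1)),
        "other_n_pairs": len(b),
    }
    return float(res.statistic), float(df), float(res.pvalue), summary
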
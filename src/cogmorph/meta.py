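"""Random-effects meta-analysis of per-vertex cohort estimates.

Each vertex carries k cohort estimates (beta, SE).  They are pooled under the
additive between-cohort heterogeneity model  beta_i ~ N(mu, SE_i^2 + tau^2),
with tau^2 estimated either in closed form (DerSimonian-Laird) or by REML via
Fisher scoring (the default, matching common meta-analysis software).  All
estimators are vectorized across vertices.  Per-map multiplicity is handled by
Benjamini-Hochberg FDR, reported as Q values and natural-log-Q maps (note
ln 0.05 = -2.9957).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaResult",
    "MetaMap",
    "pool_random_effects",
    "meta_regression",
    "fdr_bh",
    "log_q_map",
    "meta_analyse_maps",
    "pool_mean_maps",
]


@dataclass
class MetaResult:
    """Pooled estimate(s); scalars for one outcome, arrays for vertex maps."""

    beta: np.ndarray | float
    se: np.ndarray | float
    tau2: np.ndarray | float
    q_het: np.ndarray | float  # Cochran's Q (NaN when k = 1)
    z: np.ndarray | float
    p: np.ndarray | float
    k: int
    method: str


@dataclass
class MetaMap:
    """Vertex-wise meta-analysis bundle for one (predictor, measure) map."""

    pooled_beta: np.ndarray
    pooled_se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    tau2: np.ndarray
    q_het: np.ndarray
    fdr_q: np.ndarray
    method: str
    moderator_beta: np.ndarray | None = None
    moderator_p: np.ndarray | None = None

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.pooled_beta) & np.isfinite(self.pooled_se)


def _as_2d(y: np.ndarray) -> tuple[np.ndarray, bool]:
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.ndim == 1:
        return y[None, :], True
    return y, False


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DerSimonian-Laird tau^2 and Cochran's Q, vectorized over rows."""
    w = 1.0 / v
    sw = w.sum(axis=1)
    mu_fe = (w * y).sum(axis=1) / sw
    q = (w * (y - mu_fe[:, None]) ** 2).sum(axis=1)
    k = y.shape[1]
    c = sw - (w**2).sum(axis=1) / sw
    tau2 = np.maximum(0.0, (q - (k - 1)) / c)
    return tau2, q


def _reml_tau2(
    y: np.ndarray, v: np.ndarray, x: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """REML tau^2 by Fisher scoring, vectorized over rows (vertices).

    x is the common (k, p) fixed-effects design (a column of ones for plain
    pooling; [1, moderator] for meta-regression).
    """
    n_rows, k = y.shape
    p = x.shape[1]
    tau2, _ = _dl_tau2(y, v)  # start from the moment estimator
    for _ in range(max_iter):
        w = 1.0 / (v + tau2[:, None])  # (n, k)
        a = np.einsum("nk,kp,kq->npq", w, x, x)  # X' W X
        a_inv = np.linalg.inv(a)
        xtwy = np.einsum("kp,nk->np", x, w * y)
        b = np.einsum("npq,nq->np", a_inv, xtwy)
        resid = y - b @ x.T
        wr = w * resid
        b_mat = np.einsum("nk,kp,kq->npq", w**2, x, x)  # X' W^2 X
        c_mat = np.einsum("nk,kp,kq->npq", w**3, x, x)  # X' W^3 X
        tr_p = w.sum(axis=1) - np.einsum("npq,nqp->n", a_inv, b_mat)
        ab = a_inv @ b_mat
        tr_pp = (
            (w**2).sum(axis=1)
            - 2.0 * np.einsum("npq,nqp->n", a_inv, c_mat)
            + np.einsum("npq,nqp->n", ab, ab)
        )
        score = 0.5 * ((wr**2).sum(axis=1) - tr_p)
        info = 0.5 * tr_pp
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        new = np.maximum(0.0, tau2 + step)
        done = np.abs(new - tau2) < tol * (1.0 + tau2)
        tau2 = new
        if done.all():
            break
    return tau2


def _wls(y: np.ndarray, v: np.ndarray, tau2: np.ndarray, x: np.ndarray):
    """Weighted LS with weights 1/(v + tau2); returns (coef, cov) per row."""
    w = 1.0 / (v + tau2[:, None])
    a = np.einsum("nk,kp,kq->npq", w, x, x)
    a_inv = np.linalg.inv(a)
    coef = np.einsum("npq,nq->np", a_inv, np.einsum("kp,nk->np", x, w * y))
    return coef, a_inv


def pool_random_effects(
    betas: np.ndarray, ses: np.ndarray, method: str = "REML"
) -> MetaResult:
    """Pool k estimates per vertex under a random-effects model.

    ``betas``/``ses`` are (k,) for a single outcome or (V, k) for vertex maps.
    With a single estimate the pooled value is that estimate, tau^2 = 0 and
    Cochran's Q is reported missing.
    """
    if method not in ("DL", "REML"):
        raise ValueError(f"method must be 'DL' or 'REML', got {method!r}")
    y, squeeze = _as_2d(betas)
    s, _ = _as_2d(ses)
    if y.shape != s.shape:
        raise ValueError("betas and ses must have the same shape")
    finite = np.isfinite(y) & np.isfinite(s)
    if np.any(finite & (s <= 0)):
        raise ValueError("standard errors must be positive")
    k = y.shape[1]
    out_shape = y.shape[0]
    beta = np.full(out_shape, np.nan)
    se = np.full(out_shape, np.nan)
    tau2 = np.full(out_shape, np.nan)
    q = np.full(out_shape, np.nan)
    rows = finite.all(axis=1)
    if k == 1:
        beta[rows] = y[rows, 0]
        se[rows] = s[rows, 0]
        tau2[rows] = 0.0
    elif rows.any():
        yy, vv = y[rows], s[rows] ** 2
        tau2_dl, q_rows = _dl_tau2(yy, vv)
        x = np.ones((k, 1))
        tau2_rows = tau2_dl if method == "DL" else _reml_tau2(yy, vv, x)
        coef, cov = _wls(yy, vv, tau2_rows, x)
        beta[rows] = coef[:, 0]
        se[rows] = np.sqrt(cov[:, 0, 0])
        tau2[rows] = tau2_rows
        q[rows] = q_rows
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if squeeze:
        return MetaResult(
            float(beta[0]), float(se[0]), float(tau2[0]), float(q[0]),
            float(z[0]), float(p[0]), k, method,
        )
    return MetaResult(beta, se, tau2, q, z, p, k, method)


def meta_regression(
    betas: np.ndarray, ses: np.ndarray, moderator: np.ndarray, method: str = "REML"
):
    """Mixed-effects meta-regression of estimates on one cohort-level moderator.

    Returns (slope, slope_se, z, p) — scalars for (k,) inputs, arrays for
    (V, k) vertex maps.  Requires k >= 3 for one moderator (else zero residual
    degrees of freedom).  The slope is tested with a Wald z-test.
    """
    y, squeeze = _as_2d(betas)
    s, _ = _as_2d(ses)
    mod = np.asarray(moderator, dtype=float)
    k = y.shape[1]
    if len(mod) != k:
        raise ValueError("moderator must have one value per cohort")
    if k < 3:
        raise ValueError("meta-regression with one moderator needs at least 3 estimates")
    if np.ptp(mod) == 0:
        raise ValueError("moderator is constant: collinear with the intercept")
    x = np.column_stack([np.ones(k), (mod - mod.mean()) / mod.std(ddof=1)])
    rows = np.isfinite(y).all(axis=1) & np.isfinite(s).all(axis=1)
    slope = np.full(y.shape[0], np.nan)
    slope_se = np.full(y.shape[0], np.nan)
    if rows.any():
        yy, vv = y[rows], s[rows] ** 2
        if method == "REML":
            tau2 = _reml_tau2(yy, vv, x)
        else:
            tau2, _ = _dl_tau2(yy, vv)  # moment start; adequate for DL use
        coef, cov = _wls(yy, vv, tau2, x)
        slope[rows] = coef[:, 1]
        slope_se[rows] = np.sqrt(cov[:, 1, 1])
    z = slope / slope_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if squeeze:
        return float(slope[0]), float(slope_se[0]), float(z[0]), float(p[0])
    return slope, slope_se, z, p


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted Q values.

    Monotone, capped at 1; NaN entries are passed through untouched and do not
    count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def log_q_map(fdr_q: np.ndarray, floor: float = -300.0) -> np.ndarray:
    """Natural log of FDR Q, clamped below at ``floor`` (ln 0.05 = -2.9957)."""
    if floor >= 0:
        raise ValueError("floor must be negative")
    q = np.asarray(fdr_q, dtype=float)
    with np.errstate(divide="ignore"):
        lg = np.log(q)
    return np.where(np.isfinite(q), np.maximum(lg, floor), np.nan)


def meta_analyse_maps(
    betas: np.ndarray,
    ses: np.ndarray,
    method: str = "REML",
    moderator: np.ndarray | None = None,
) -> MetaMap:
    """Full vertex-map pooling: random effects + BH FDR (+ optional moderator)."""
    res = pool_random_effects(betas, ses, method=method)
    fdr = fdr_bh(res.p)
    mod_beta = mod_p = None
    if moderator is not None:
        mod_beta, _, _, mod_p = meta_regression(betas, ses, moderator, method=method)
    return MetaMap(
        res.beta, res.se, res.z, res.p, res.tau2, res.q_het, fdr, method, mod_beta, mod_p
    )


def pool_mean_maps(
    means: np.ndarray, sds: np.ndarray, ns: np.ndarray, method: str = "REML"
) -> MetaResult:
    """Pool cohort mean maps with per-vertex SE = SD / sqrt(n).

    ``means``/``sds`` are (V, k); ``ns`` is the per-cohort sample size vector.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    ses = sds / np.sqrt(ns)[None, :]
    return pool_random_effects(means, ses, method=method)
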
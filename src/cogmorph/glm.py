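"""Mass-univariate vertex models: standardized associations and allometry.

Per vertex, the morphometry value is regressed on a focal predictor plus
nuisance covariates by ordinary least squares.  Outcome and continuous
predictors are z-scored within cohort (sample, n-1 SD), sex enters as a 0/1
indicator and site as indicator contrasts, so the focal coefficient is a
standardized beta: with no covariates it equals the Pearson correlation
between predictor and vertex value.  The solve is vectorized across vertices
(one design matrix, all vertex outcomes at once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import CohortDataset

__all__ = [
    "AssociationMap",
    "GlobalAssociation",
    "CollinearityError",
    "vertex_association",
    "global_association",
    "allometric_map",
]

_MIN_SUBJECTS = 20


class CollinearityError(ValueError):
    """The design matrix is rank deficient; the message names the columns."""


@dataclass
class AssociationMap:
    """Per-vertex standardized beta and SE for one cohort/measure/predictor."""

    beta: np.ndarray
    se: np.ndarray
    n: int
    predictor: str
    measure: str
    cohort: str = ""

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.beta) & np.isfinite(self.se)


@dataclass
class GlobalAssociation:
    beta: float
    se: float
    n: int
    predictor: str
    measure: str
    cohort: str = ""


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (x - x.mean()) / sd


def _predictor_column(
    cohort: CohortDataset, name: str, g_scores: np.ndarray | None, standardize: bool
) -> np.ndarray:
    if name == "g":
        if g_scores is None:
            raise ValueError("predictor 'g' requires g_scores (see latent.score)")
        x = np.asarray(g_scores, dtype=float)
    elif name == "age":
        x = cohort.covariates["age"].to_numpy().astype(float)
    elif name == "sex":
        # 0/1 indicator: beta is an SD-unit group contrast (male - female),
        # never z-scored
        return cohort.covariates["sex"].to_numpy().astype(float)
    else:
        raise ValueError(f"unknown predictor {name!r}")
    return _zscore(x) if standardize else x


def _covariate_columns(cohort: CohortDataset, names: list[str]) -> tuple[np.ndarray, list[str]]:
    cols, labels = [], []
    cov = cohort.covariates
    for name in names:
        if name == "site":
            site = cov["site"].to_numpy()
            levels = np.unique(site)
            for lev in levels[1:]:  # indicator contrasts, first level reference
                cols.append((site == lev).astype(float))
                labels.append(f"site_{lev}")
        elif name == "sex":
            cols.append(cov["sex"].to_numpy().astype(float))
            labels.append("sex")
        elif name in ("age", "lag", "hp_x", "hp_y", "hp_z"):
            x = cov[name].to_numpy().astype(float)
            if x.std(ddof=1) == 0:
                continue  # constant nuisance carries no information
            cols.append(_zscore(x))
            labels.append(name)
        elif name == "head_position":
            for c in ("hp_x", "hp_y", "hp_z"):
                x = cov[c].to_numpy().astype(float)
                if x.std(ddof=1) > 0:
                    cols.append(_zscore(x))
                    labels.append(c)
        else:
            raise ValueError(f"unknown covariate {name!r}")
    if cols:
        return np.column_stack(cols), labels
    return np.empty((len(cov), 0)), labels


def _check_rank(x: np.ndarray, labels: list[str]) -> None:
    r = np.linalg.matrix_rank(x)
    if r < x.shape[1]:
        rdiag = np.abs(np.diag(np.linalg.qr(x, mode="r")))
        bad = [labels[i] for i in np.flatnonzero(rdiag < 1e-10 * max(rdiag.max(), 1.0))]
        raise CollinearityError(f"design matrix is rank deficient; collinear columns: {bad}")


def _ols_many(y: np.ndarray, x: np.ndarray, focal: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS of every column of y on the common design x; returns (beta, se) of
    the focal column."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = xtx_inv @ (x.T @ y)  # (p, V)
    resid = y - x @ coefs
    dof = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * xtx_inv[focal, focal])
    return coefs[focal], se


def _build_design(
    cohort: CohortDataset,
    predictor: str,
    covariates: list[str],
    g_scores: np.ndarray | None,
    standardize: bool = True,
) -> tuple[np.ndarray, int, list[str]]:
    pred_col = _predictor_column(cohort, predictor, g_scores, standardize)
    cov_mat, cov_labels = _covariate_columns(cohort, covariates)
    x = np.column_stack([np.ones(len(pred_col)), pred_col, cov_mat])
    labels = ["intercept", predictor] + cov_labels
    _check_rank(x, labels)
    return x, 1, labels


def vertex_association(
    cohort: CohortDataset,
    measure: str,
    predictor: str,
    covariates: list[str] | None = None,
    g_scores: np.ndarray | None = None,
    standardize: bool = True,
) -> AssociationMap:
    """Standardized beta (with SE) between the predictor and every vertex.

    With ``standardize=True`` (default) outcome and focal predictor are
    z-scored, so with no covariates the coefficient is the Pearson
    correlation.  ``standardize=False`` reports the raw OLS slope (used e.g.
    for exact-recovery checks in noise-free simulations, where the
    standardized coefficient would degenerate to +/-1).
    Vertices with missing or constant data come back NaN in both fields.
    Input smoothing is the caller's responsibility (typically 20 mm FWHM
    upstream via :class:`cogmorph.surface.HeatKernelSmoother`).
    """
    covariates = list(covariates or [])
    y_raw = cohort.morphometry[measure]
    n = y_raw.shape[0]
    if n < _MIN_SUBJECTS:
        raise ValueError(f"need at least {_MIN_SUBJECTS} subjects, got {n}")
    x, focal, _ = _build_design(cohort, predictor, covariates, g_scores, standardize)

    valid = np.all(np.isfinite(y_raw), axis=0)
    sd = np.zeros(y_raw.shape[1])
    sd[valid] = y_raw[:, valid].std(axis=0, ddof=1)
    usable = valid & (sd > 0)
    if standardize:
        z = (y_raw[:, usable] - y_raw[:, usable].mean(axis=0)) / sd[usable]
    else:
        z = y_raw[:, usable]

    beta = np.full(y_raw.shape[1], np.nan)
    se = np.full(y_raw.shape[1], np.nan)
    beta[usable], se[usable] = _ols_many(z, x, focal)
    return AssociationMap(beta, se, n, predictor, measure, cohort.label)


_AGGREGATE = {"volume": "sum", "area": "sum", "thickness": "mean", "curvature": "mean", "sulc": "mean"}


def global_association(
    cohort: CohortDataset,
    measure: str,
    predictor: str,
    covariates: list[str] | None = None,
    g_scores: np.ndarray | None = None,
    standardize: bool = True,
) -> GlobalAssociation:
    """Same model on the cortex-aggregated measure (sum for volume/area,
    mean for thickness/curvature/sulcal depth)."""
    covariates = list(covariates or [])
    y_raw = cohort.morphometry[measure]
    valid = np.all(np.isfinite(y_raw), axis=0)
    agg = _AGGREGATE[measure]
    g_val = y_raw[:, valid].sum(axis=1) if agg == "sum" else y_raw[:, valid].mean(axis=1)
    x, focal, _ = _build_design(cohort, predictor, covariates, g_scores, standardize)
    z = (_zscore(g_val) if standardize else g_val)[:, None]
    beta, se = _ols_many(z, x, focal)
    return GlobalAssociation(float(beta[0]), float(se[0]), y_raw.shape[0], predictor, measure, cohort.label)


def allometric_map(
    cohort: CohortDataset, adjust_age_sex: bool = False
) -> AssociationMap:
    """Per-vertex allometric scaling: slope of ln(vertex area) on ln(total area).

    A slope of 1 is isometry; slopes above 1 mark vertices that are
    disproportionately larger in subjects with larger total surface area.
    No covariates by default; ``adjust_age_sex`` adds them.
    """
    area = cohort.morphometry["area"]
    valid = np.all(np.isfinite(area), axis=0)
    if np.any(area[:, valid] <= 0):
        raise ValueError("allometric scaling requires strictly positive vertex areas")
    total = area[:, valid].sum(axis=1)
    log_total = np.log(total)
    cols = [np.ones(len(total)), log_total]
    if adjust_age_sex:
        cols.append(_zscore(cohort.covariates["age"].to_numpy()))
        cols.append(cohort.covariates["sex"].to_numpy().astype(float))
    x = np.column_stack(cols)
    _check_rank(x, ["intercept", "log_total_area"] + (["age", "sex"] if adjust_age_sex else []))
    beta = np.full(area.shape[1], np.nan)
    se = np.full(area.shape[1], np.nan)
    b, s = _ols_many(np.log(area[:, valid]), x, 1)
    beta[valid], se[valid] = b, s
    return AssociationMap(beta, se, area.shape[0], "log_total_area", "area", cohort.label)
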
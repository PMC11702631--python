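"""One-factor measurement model of a cognitive battery.

A single latent factor g is fitted to the test battery by maximum-likelihood
factor analysis of the sample correlation matrix, minimizing the ML
discrepancy  F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p  over loadings and
uniquenesses, with the factor identified by unit variance.  Model adequacy is
summarised by the standard SEM fit indices (CFI, TLI, RMSEA, SRMR), and factor
scores are extracted by the regression (Thomson) or Bartlett method.  Scores
are oriented so that the mean loading is positive: higher scores mean better
performance on a positive-manifold battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FactorModel",
    "GScores",
    "FactorAnalysisError",
    "fit_one_factor",
    "fit_from_correlation",
    "fit_indices",
    "score",
]

_PSI_FLOOR = 0.005  # Heywood clamp on uniquenesses


class FactorAnalysisError(RuntimeError):
    """Raised on non-PD input or failed convergence; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class FactorModel:
    """Fitted one-factor model in the correlation metric."""

    loadings: np.ndarray  # lambda per test
    uniquenesses: np.ndarray  # psi per test, in (0, 1]
    n: int  # sample size the model was fitted on
    discrepancy: float  # ML fit function F at the optimum
    chi_square: float
    df: int
    cfi: float
    tli: float
    rmsea: float | None
    srmr: float
    heywood: bool  # any uniqueness clamped at the floor
    sample_corr: np.ndarray

    @property
    def implied_corr(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.uniquenesses)

    @property
    def communalities(self) -> np.ndarray:
        return self.loadings**2

    def passes_conventional_fit(self) -> bool:
        """CFI > 0.95, TLI > 0.88, RMSEA < 0.08 and SRMR < 0.04."""
        if self.rmsea is None:
            return False
        return (
            self.cfi > 0.95 and self.tli > 0.88 and self.rmsea < 0.08 and self.srmr < 0.04
        )


@dataclass
class GScores:
    """Standardized factor scores (sample mean 0, SD 1)."""

    scores: np.ndarray
    method: str  # "regression" | "bartlett"


def _ml_discrepancy(s: np.ndarray, lam: np.ndarray, psi: np.ndarray) -> float:
    p = len(lam)
    sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(s)
    return float(logdet_sigma + np.trace(s @ np.linalg.inv(sigma)) - logdet_s - p)


def _concentrated(psi: np.ndarray, s: np.ndarray) -> tuple[float, np.ndarray]:
    """Profile the loadings out: for fixed psi the optimal single-factor
    loadings come from the leading eigenpair of psi^-1/2 S psi^-1/2."""
    d = 1.0 / np.sqrt(psi)
    s_star = s * np.outer(d, d)
    w, v = np.linalg.eigh(s_star)
    theta1 = w[-1]
    u1 = v[:, -1]
    lam = np.sqrt(psi) * u1 * np.sqrt(max(theta1 - 1.0, 0.0))
    # F at the profiled optimum: the non-leading eigenvalues contribute
    rest = w[:-1]
    f = float(np.sum(rest - np.log(rest) - 1.0))
    if theta1 < 1.0:  # degenerate: no positive factor variance
        f += float(theta1 - np.log(theta1) - 1.0)
    return f, lam


def fit_from_correlation(s: np.ndarray, n: int, max_iter: int = 500) -> FactorModel:
    """ML one-factor fit to a correlation matrix with ``n`` observations."""
    s = np.asarray(s, dtype=float)
    p = s.shape[0]
    if s.shape != (p, p) or not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("input must be a symmetric correlation matrix")
    if p < 3:
        raise ValueError("a one-factor model needs at least 3 tests")
    eigvals = np.linalg.eigvalsh(s)
    if eigvals.min() <= 1e-10:
        raise FactorAnalysisError("sample correlation matrix is not positive definite")

    # conventional start: psi0_j = (1 - m/2p) / (S^-1)_jj with m = 1 factor
    psi0 = np.clip((1.0 - 0.5 / p) / np.diag(np.linalg.inv(s)), _PSI_FLOOR, 1.0)

    def objective(log_psi: np.ndarray) -> float:
        f, _ = _concentrated(np.exp(log_psi), s)
        return f

    res = optimize.minimize(
        objective,
        np.log(psi0),
        method="L-BFGS-B",
        bounds=[(np.log(_PSI_FLOOR), 0.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    psi = np.exp(res.x)
    if not res.success and res.nit >= max_iter:
        raise FactorAnalysisError(
            f"one-factor ML fit did not converge in {max_iter} iterations", last_iterate=psi
        )
    f_opt, lam = _concentrated(psi, s)
    heywood = bool(np.any(psi <= _PSI_FLOOR * (1 + 1e-6)))
    if lam.sum() < 0:  # orientation: mean loading positive
        lam = -lam
    f_opt = _ml_discrepancy(s, lam, psi)
    df = p * (p + 1) // 2 - 2 * p
    chi_square = (n - 1) * f_opt
    cfi, tli, rmsea, srmr = _fit_indices_from_parts(s, lam, psi, f_opt, df, n)
    return FactorModel(
        loadings=lam,
        uniquenesses=psi,
        n=n,
        discrepancy=f_opt,
        chi_square=chi_square,
        df=df,
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        srmr=srmr,
        heywood=heywood,
        sample_corr=s,
    )


def fit_one_factor(test_data: np.ndarray, max_iter: int = 500) -> FactorModel:
    """Fit the one-factor model to a subjects x tests score matrix.

    Tests are standardized internally (the model lives in the correlation
    metric), so the fit is invariant to affine rescaling of any single test.
    """
    x = np.asarray(test_data, dtype=float)
    if x.ndim != 2:
        raise ValueError("test_data must be a 2-D subjects x tests matrix")
    n, p = x.shape
    if p < 3:
        raise ValueError("need at least 3 tests")
    if n <= p:
        raise ValueError("need more subjects than tests")
    if np.isnan(x).any():
        raise ValueError("missing test scores are not supported; complete cases only")
    s = np.corrcoef(x, rowvar=False)
    return fit_from_correlation(s, n, max_iter=max_iter)


def _fit_indices_from_parts(
    s: np.ndarray, lam: np.ndarray, psi: np.ndarray, f: float, df: int, n: int
) -> tuple[float, float, float | None, float]:
    p = len(lam)
    t = (n - 1) * f
    # independence baseline: Sigma_b = I, so F_b = -ln|S| (trace of a
    # correlation matrix is p)
    _, logdet_s = np.linalg.slogdet(s)
    f_b = float(-logdet_s)
    df_b = p * (p - 1) // 2
    t_b = (n - 1) * f_b
    denom = max(t_b - df_b, t - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(t - df, 0.0) / denom
    if df_b > 0 and t_b / df_b != 1.0 and df > 0:
        tli = ((t_b / df_b) - (t / df)) / ((t_b / df_b) - 1.0)
    else:
        tli = 1.0
    rmsea = None if df == 0 else float(np.sqrt(max(t - df, 0.0) / (df * (n - 1))))
    resid = s - (np.outer(lam, lam) + np.diag(psi))
    tril = np.tril_indices(p)  # lower triangle including the diagonal
    srmr = float(np.sqrt(np.mean(resid[tril] ** 2)))
    return float(np.clip(cfi, 0.0, 1.0)), float(tli), rmsea, srmr


def fit_indices(model: FactorModel, sample_corr: np.ndarray | None = None, n: int | None = None):
    """(CFI, TLI, RMSEA, SRMR) for a fitted model; recomputed if a different
    sample correlation or n is supplied."""
    s = model.sample_corr if sample_corr is None else np.asarray(sample_corr, dtype=float)
    nn = model.n if n is None else n
    f = _ml_discrepancy(s, model.loadings, model.uniquenesses)
    return _fit_indices_from_parts(s, model.loadings, model.uniquenesses, f, model.df, nn)


def score(model: FactorModel, test_data: np.ndarray, method: str = "regression") -> GScores:
    """Extract standardized factor scores for each subject.

    Regression (Thomson) scores are ``z Sigma^-1 lambda``; Bartlett scores are
    ``z Psi^-1 lambda / (lambda' Psi^-1 lambda)``.  Either way the result is
    rescaled to unit sample variance and oriented positively.
    """
    x = np.asarray(test_data, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(model.loadings):
        raise ValueError(
            f"test_data must have {len(model.loadings)} columns to match the fitted battery"
        )
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    lam = model.loadings
    if method == "regression":
        weights = np.linalg.solve(model.implied_corr, lam)
    elif method == "bartlett":
        pinv_lam = lam / model.uniquenesses
        weights = pinv_lam / (lam @ pinv_lam)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    raw = z @ weights
    sd = raw.std(ddof=1)
    if sd > 0:
        raw = raw / sd
    raw = raw - raw.mean()
    if lam.mean() < 0:  # orientation guard (loadings are already positive-mean)
        raw = -raw
    return GScores(scores=raw, method=method)
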
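"""Synthetic multi-cohort surface morphometry with known ground truth.

This module generates everything the analysis pipeline consumes, standing in
for restricted cohort data: per-subject vertex-wise morphometry for the five
standard measures (volume, surface area, thickness, curvature, sulcal depth),
a positive-manifold one-factor cognitive battery, demographic and nuisance
covariates, and stacks of group-level neurobiological profile maps built from
a small number of latent spatial patterns.

The generative model for a vertex measure is::

    y_iv = mu_v + (beta_g,v + tau * dev_v) * g_i + beta_age,v * z(age_i)
           + beta_sex,v * sex_i + gamma * headpos_i + site_v[s_i] + eps_iv

with smooth, amplitude-bounded effect fields (|beta| <= 0.2 by default,
matching the observed range of standardized vertex-wise effects in large
adult cohorts), an additive smooth per-cohort deviation field scaled by the
between-cohort SD tau (so a random-effects meta-analysis has real
heterogeneity to estimate), and unit-SD vertex residuals so the planted
fields are on the standardized-beta scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surface import HeatKernelSmoother, SphereMesh, VertexMap

__all__ = [
    "MEASURES",
    "TruthConfig",
    "TruthMaps",
    "CohortSpec",
    "CohortDataset",
    "smooth_noise_map",
    "make_truth",
    "simulate_cohort",
    "simulate_profiles",
    "simple_structure_loadings",
    "apply_outlier_rule",
    "default_cohort_specs",
]

MEASURES = ("volume", "area", "thickness", "curvature", "sulc")

# Per-vertex baseline level and spatial SD of the mean field, loosely matching
# the units of FreeSurfer qcache outputs (mm^3, mm^2, mm, 1/mm, mm).
_MEAN_LEVELS = {
    "volume": (2.0, 0.5),
    "area": (0.8, 0.2),
    "thickness": (2.5, 0.3),
    "curvature": (0.0, 0.1),
    "sulc": (0.0, 5.0),
}


def smooth_noise_map(
    mesh: SphereMesh,
    fwhm_mm: float,
    rng: np.random.Generator,
    smoother: HeatKernelSmoother | None = None,
) -> np.ndarray:
    """A smooth random field: white noise diffused at ``fwhm_mm``, then
    demeaned and scaled to unit SD over the cortex.  NaN off-cortex."""
    if smoother is None:
        smoother = HeatKernelSmoother(mesh, fwhm_mm)
    x = rng.standard_normal(mesh.n_vertices)
    x = smoother.apply(x)
    m = mesh.cortex_mask
    x[~m] = np.nan
    x[m] -= x[m].mean()
    sd = x[m].std(ddof=1)
    if sd > 0:
        x[m] /= sd
    return x


@dataclass
class TruthConfig:
    """Amplitudes (max |beta|) and smoothness of the planted effect fields."""

    amplitude_g: float = 0.15
    amplitude_age: float = 0.15
    amplitude_sex: float = 0.10
    fwhm_mm: float = 20.0
    heterogeneity_sd: float = 0.02  # tau: between-cohort SD of beta_g
    max_abs_beta: float = 0.2

    def __post_init__(self) -> None:
        for a in (self.amplitude_g, self.amplitude_age, self.amplitude_sex):
            if abs(a) > self.max_abs_beta:
                raise ValueError(
                    f"requested amplitude {a} exceeds the |beta| envelope {self.max_abs_beta}"
                )


@dataclass
class TruthMaps:
    """Planted ground-truth effect fields, per morphometry measure."""

    beta_g: dict[str, VertexMap]
    beta_age: dict[str, VertexMap]
    beta_sex: dict[str, VertexMap]
    mean: dict[str, VertexMap]
    heterogeneity_sd: dict[str, float]
    config: TruthConfig
    pattern_seed: int
    mesh_id: str


def _effect_field(
    mesh: SphereMesh, amplitude: float, rng: np.random.Generator, sm: HeatKernelSmoother
) -> np.ndarray:
    """Smooth zero-mean field rescaled so max |value| equals ``amplitude`` exactly."""
    x = smooth_noise_map(mesh, sm.fwhm_mm, rng, smoother=sm)
    m = mesh.cortex_mask
    if amplitude == 0:
        x[m] = 0.0
        return x
    peak = np.max(np.abs(x[m]))
    x[m] *= amplitude / peak
    return x


def make_truth(mesh: SphereMesh, config: TruthConfig, seed: int) -> TruthMaps:
    """Draw smooth effect-size and mean fields for every measure, deterministically."""
    rng = np.random.default_rng(seed)
    sm = HeatKernelSmoother(mesh, config.fwhm_mm)
    beta_g, beta_age, beta_sex, mean = {}, {}, {}, {}
    for meas in MEASURES:
        beta_g[meas] = VertexMap.from_values(
            _effect_field(mesh, config.amplitude_g, rng, sm), f"beta_g_{meas}", mesh
        )
        beta_age[meas] = VertexMap.from_values(
            _effect_field(mesh, config.amplitude_age, rng, sm), f"beta_age_{meas}", mesh
        )
        beta_sex[meas] = VertexMap.from_values(
            _effect_field(mesh, config.amplitude_sex, rng, sm), f"beta_sex_{meas}", mesh
        )
        level, spread = _MEAN_LEVELS[meas]
        mu = smooth_noise_map(mesh, config.fwhm_mm, rng, smoother=sm)
        mcx = mesh.cortex_mask
        mu[mcx] = level + spread * mu[mcx]
        if meas in ("volume", "area"):  # physical quantities stay positive
            mu[mcx] = np.maximum(mu[mcx], 0.05 * level if level else 0.05)
        mean[meas] = VertexMap.from_values(mu, f"mean_{meas}", mesh)
    tau = {meas: config.heterogeneity_sd for meas in MEASURES}
    return TruthMaps(beta_g, beta_age, beta_sex, mean, tau, config, seed, mesh.mesh_id)


@dataclass
class CohortSpec:
    """Size, demographics, battery and noise level of one simulated cohort."""

    label: str
    n_subjects: int
    age_mean: float
    age_sd: float
    sex_ratio: float = 0.5  # proportion male
    n_sites: int = 1
    test_loadings: tuple[float, ...] = (0.7, 0.7, 0.7, 0.7, 0.7, 0.7)
    residual_sd: float = 1.0
    head_position_gamma: float = 0.01
    site_effect_sd: float = 0.0
    lag_mean_days: float | None = None
    lag_sd_days: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if not all(0.0 < l < 1.0 for l in self.test_loadings):
            raise ValueError("test loadings must lie strictly inside (0, 1)")

    @property
    def n_tests(self) -> int:
        return len(self.test_loadings)


@dataclass
class CohortDataset:
    """Subject-level data for one cohort: morphometry, tests, covariates."""

    label: str
    morphometry: dict[str, np.ndarray]  # measure -> (n_subjects, n_vertices)
    tests: np.ndarray  # (n_subjects, n_tests)
    covariates: pd.DataFrame  # age, sex, site, hp_x, hp_y, hp_z [, lag]
    true_g: np.ndarray  # latent scores, retained for validation only
    mesh_id: str

    @property
    def n_subjects(self) -> int:
        return len(self.true_g)


def simulate_cohort(
    mesh: SphereMesh,
    truth: TruthMaps,
    spec: CohortSpec,
    seed: int,
    *,
    measures: tuple[str, ...] = MEASURES,
    noise_free: bool = False,
) -> CohortDataset:
    """Draw one cohort from the generative model.

    ``noise_free=True`` zeroes the vertex residual, test uniqueness and
    nuisance draws (used for exact-recovery checks).
    """
    if truth.mesh_id != mesh.mesh_id:
        raise ValueError("truth maps were generated on a different mesh")
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    nv = mesh.n_vertices
    cortex = mesh.cortex_mask

    g = rng.standard_normal(n)
    age = spec.age_mean + spec.age_sd * rng.standard_normal(n)
    sex = (rng.random(n) < spec.sex_ratio).astype(float)
    site = rng.integers(0, spec.n_sites, size=n)
    headpos = rng.standard_normal((n, 3)) * (0.0 if noise_free else 1.0)

    lam = np.asarray(spec.test_loadings)
    uniq = np.zeros((n, len(lam))) if noise_free else rng.standard_normal((n, len(lam)))
    tests = g[:, None] * lam[None, :] + uniq * np.sqrt(1.0 - lam**2)[None, :]

    z_age = (age - age.mean()) / age.std(ddof=1) if spec.age_sd > 0 else np.zeros(n)

    sm = HeatKernelSmoother(mesh, truth.config.fwhm_mm)
    morph: dict[str, np.ndarray] = {}
    for meas in measures:
        tau = truth.heterogeneity_sd[meas]
        dev = smooth_noise_map(mesh, truth.config.fwhm_mm, rng, smoother=sm) if tau > 0 else 0.0
        beta_cohort = np.nan_to_num(truth.beta_g[meas].values) + tau * np.nan_to_num(dev)
        y = np.nan_to_num(truth.mean[meas].values)[None, :].repeat(n, axis=0)
        y += g[:, None] * beta_cohort[None, :]
        y += z_age[:, None] * np.nan_to_num(truth.beta_age[meas].values)[None, :]
        y += sex[:, None] * np.nan_to_num(truth.beta_sex[meas].values)[None, :]
        if not noise_free:
            y += spec.head_position_gamma * headpos.sum(axis=1)[:, None]
            if spec.site_effect_sd > 0 and spec.n_sites > 1:
                shifts = rng.standard_normal(spec.n_sites) * spec.site_effect_sd
                y += shifts[site][:, None]
            if spec.residual_sd > 0:
                y += spec.residual_sd * rng.standard_normal((n, nv))
        y[:, ~cortex] = np.nan
        morph[meas] = y

    cov = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "site": site,
            "hp_x": headpos[:, 0],
            "hp_y": headpos[:, 1],
            "hp_z": headpos[:, 2],
        }
    )
    if spec.lag_mean_days is not None:
        cov["lag"] = spec.lag_mean_days + spec.lag_sd_days * rng.standard_normal(n)
    return CohortDataset(spec.label, morph, tests, cov, g, mesh.mesh_id)


# ----------------------------------------------------------------------------
# Neurobiological profile stacks
# ----------------------------------------------------------------------------

def _orthonormal_patterns(
    mesh: SphereMesh, n_latent: int, fwhm_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth, mean-zero, mutually orthogonal unit-SD fields (cortex x k)."""
    sm = HeatKernelSmoother(mesh, fwhm_mm)
    cols = [smooth_noise_map(mesh, fwhm_mm, rng, smoother=sm)[mesh.cortex_mask] for _ in range(n_latent)]
    x = np.column_stack(cols)
    x -= x.mean(axis=0)
    q, r = np.linalg.qr(x)
    q *= np.sign(np.diag(r))  # deterministic orientation
    return q * np.sqrt(x.shape[0] - 1)  # unit sample SD columns


def simple_structure_loadings(
    n_maps: int, n_latent: int, rng: np.random.Generator, signal_share: float = 0.6
) -> tuple[np.ndarray, float]:
    """Loading matrix where each map loads mainly on one latent pattern.

    Rows have unit norm, so with unit-SD orthogonal patterns and white vertex
    noise of SD ``sqrt((1 - signal_share) / signal_share)`` each map carries
    the requested share of signal variance.  Returns (loadings, noise_sd).
    """
    blocks = np.array_split(np.arange(n_maps), n_latent)
    load = np.zeros((n_maps, n_latent))
    for k, idx in enumerate(blocks):
        load[idx, k] = 0.95
    load += 0.1 * rng.standard_normal(load.shape)
    load *= np.where(rng.random(n_maps) < 0.3, -1.0, 1.0)[:, None]  # mixed signs
    load /= np.linalg.norm(load, axis=1, keepdims=True)
    noise_sd = float(np.sqrt((1.0 - signal_share) / signal_share))
    return load, noise_sd


def simulate_profiles(
    mesh: SphereMesh,
    n_maps: int,
    n_latent: int,
    loading_matrix: np.ndarray,
    noise_sd: float,
    seed: int,
    *,
    pattern_fwhm_mm: float = 20.0,
) -> tuple[list[VertexMap], np.ndarray, np.ndarray]:
    """Profile maps as mixtures of latent spatial patterns plus white noise.

    Returns (maps, planted loadings, patterns) where ``patterns`` is the
    (n_cortex_vertices, n_latent) matrix of orthogonal unit-SD fields used,
    for recovery tests against the decomposition.
    """
    load = np.asarray(loading_matrix, dtype=float)
    if load.shape != (n_maps, n_latent):
        raise ValueError(f"loading_matrix must be {n_maps} x {n_latent}, got {load.shape}")
    rng = np.random.default_rng(seed)
    patterns = _orthonormal_patterns(mesh, n_latent, pattern_fwhm_mm, rng)
    cortex = mesh.cortex_mask
    maps = []
    for m in range(n_maps):
        vals = np.full(mesh.n_vertices, np.nan)
        sig = patterns @ load[m]
        if noise_sd > 0:
            sig = sig + noise_sd * rng.standard_normal(cortex.sum())
        vals[cortex] = sig
        maps.append(VertexMap.from_values(vals, f"profile_{m:02d}", mesh))
    return maps, load, patterns


def apply_outlier_rule(
    values: np.ndarray, threshold_sd: float = 4.0
) -> tuple[np.ndarray, int]:
    """Flag entries more than ``threshold_sd`` sample SDs from the sample mean.

    The rule is applied per variable (series), not per subject: flagged
    entries become NaN, the rest are untouched.  Returns (filtered, n_excluded).
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    x = np.asarray(values, dtype=float).copy()
    ok = np.isfinite(x)
    mu = x[ok].mean()
    sd = x[ok].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return x, 0
    out = ok & (np.abs(x - mu) > threshold_sd * sd)
    x[out] = np.nan
    return x, int(out.sum())


def default_cohort_specs() -> list[CohortSpec]:
    """Three cohorts emulating a large biobank, a mid-size population study,
    and a small narrow-age birth cohort (sizes chosen for desk-scale runs)."""
    return [
        CohortSpec(
            label="cohort_large",
            n_subjects=2000,
            age_mean=64.0,
            age_sd=7.6,
            sex_ratio=0.47,
            n_sites=4,
            test_loadings=(0.45, 0.5, 0.55, 0.6, 0.6, 0.65, 0.65, 0.7, 0.75, 0.8),
        ),
        CohortSpec(
            label="cohort_mid",
            n_subjects=800,
            age_mean=59.0,
            age_sd=10.0,
            sex_ratio=0.40,
            n_sites=2,
            test_loadings=(0.5, 0.6, 0.65, 0.7, 0.75),
        ),
        CohortSpec(
            label="cohort_small",
            n_subjects=400,
            age_mean=73.0,
            age_sd=0.7,
            sex_ratio=0.53,
            n_sites=1,
            test_loadings=(0.4, 0.45, 0.5, 0.55, 0.6, 0.6, 0.65, 0.65, 0.7, 0.7, 0.75, 0.75, 0.8),
            lag_mean_days=65.0,
            lag_sd_days=38.0,
        ),
    ]
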
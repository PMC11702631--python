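"""End-to-end orchestration: simulate -> fit g -> vertex GLMs -> meta-analysis
-> spatial correlations -> profile PCA -> report.

Every stochastic stage draws its seed from the master seed through
``numpy.random.SeedSequence``, so a run is fully reproducible from its config.
Stage outputs are persisted as delimited tables, JSON summaries and curv maps
under the configured output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm, latent, maps_io, meta, spatial, synth
from .surface import HeatKernelSmoother, SphereMesh, VertexMap, build_icosphere, geodesic_parcellate, make_medial_wall

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]

_STAGES = (
    "mesh", "truth", "cohorts", "latent_g", "vertex_models",
    "meta", "profiles", "spins", "pca",
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly to YAML."""

    seed: int = 0
    out_dir: str = "cogmorph_run"
    # mesh
    subdivision: int = 4
    radius_mm: float = 100.0
    medial_wall_fraction: float = 0.05
    n_regions_per_hemi: int = 34
    # truth / cohorts
    amplitude_g: float = 0.15
    amplitude_age: float = 0.15
    amplitude_sex: float = 0.10
    heterogeneity_sd: float = 0.02
    fwhm_mm: float = 20.0
    cohorts: list[dict] = field(default_factory=list)  # CohortSpec kwargs
    # models
    measures: tuple[str, ...] = synth.MEASURES
    predictor: str = "g"
    covariates: tuple[str, ...] = ("age", "sex", "site", "head_position")
    meta_method: str = "REML"
    # spatial / profiles
    n_spins: int = 500
    n_profiles: int = 33
    n_latent: int = 4
    profile_signal_share: float = 0.6
    pca_retain: int = 4

    def __post_init__(self) -> None:
        # canonical form so a config compares equal after a YAML round trip
        self.measures = tuple(self.measures)
        self.covariates = tuple(self.covariates)
        self.cohorts = [
            {**c, "test_loadings": tuple(c["test_loadings"])} for c in self.cohorts
        ]

    def cohort_specs(self) -> list[synth.CohortSpec]:
        if not self.cohorts:
            return synth.default_cohort_specs()
        return [synth.CohortSpec(**c) for c in self.cohorts]

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_STAGES))
        return {
            name: int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
            for name, child in zip(_STAGES, children)
        }


def save_config(config: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d = json.loads(json.dumps(d))  # tuples -> lists for plain YAML
    Path(path).write_text(yaml.safe_dump(d))


def load_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["measures"] = tuple(d.get("measures", synth.MEASURES))
    d["covariates"] = tuple(d.get("covariates", ()))
    return RunConfig(**d)


_PROFILE_CATEGORIES_33 = (
    ["microstructure"] * 6 + ["macrostructure"] * 4 + ["functional"] * 4 + ["receptor"] * 19
)


def _profile_categories(n: int) -> list[str]:
    if n == 33:
        return list(_PROFILE_CATEGORIES_33)
    # roughly the same mix at other sizes: ~58% receptor maps
    n_receptor = max(2, int(round(0.58 * n)))
    other = ["microstructure", "macrostructure", "functional"]
    cats = [other[i % 3] for i in range(n - n_receptor)] + ["receptor"] * n_receptor
    return cats


class StageFailure(RuntimeError):
    """A pipeline stage failed; partial outputs stay on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    save_config(config, out / "config.yaml")
    report: dict = {"seeds": seeds}

    stage = "mesh"
    try:
        mesh = build_icosphere(config.subdivision, config.radius_mm)
        mesh = make_medial_wall(mesh, config.medial_wall_fraction)
        parc = geodesic_parcellate(mesh, config.n_regions_per_hemi, seeds["mesh"])
        report["mesh"] = {
            "n_vertices": mesh.n_vertices,
            "n_cortex": int(mesh.cortex_mask.sum()),
            "mesh_id": mesh.mesh_id,
        }

        stage = "truth"
        tcfg = synth.TruthConfig(
            amplitude_g=config.amplitude_g,
            amplitude_age=config.amplitude_age,
            amplitude_sex=config.amplitude_sex,
            fwhm_mm=config.fwhm_mm,
            heterogeneity_sd=config.heterogeneity_sd,
        )
        truth = synth.make_truth(mesh, tcfg, seeds["truth"])

        stage = "cohorts"
        specs = config.cohort_specs()
        cohort_seed_root = np.random.SeedSequence(seeds["cohorts"]).spawn(len(specs))
        smoother = HeatKernelSmoother(mesh, config.fwhm_mm)

        stage = "latent_g"
        g_models: dict[str, latent.FactorModel] = {}
        fit_rows = []
        cohort_assoc: dict[str, dict[str, glm.AssociationMap]] = {}
        global_rows = []
        mean_rows: dict[str, list] = {m: [] for m in config.measures}
        cohort_meta_rows = []
        for spec, css in zip(specs, cohort_seed_root):
            cseed = int(css.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
            cohort = synth.simulate_cohort(mesh, truth, spec, cseed, measures=config.measures)
            model = latent.fit_one_factor(cohort.tests)
            g_models[spec.label] = model
            scores = latent.score(model, cohort.tests).scores
            fit_rows.append(
                {
                    "cohort": spec.label,
                    "n": spec.n_subjects,
                    "n_tests": spec.n_tests,
                    "cfi": model.cfi,
                    "tli": model.tli,
                    "rmsea": model.rmsea,
                    "srmr": model.srmr,
                    "score_truth_r": float(np.corrcoef(scores, cohort.true_g)[0, 1]),
                }
            )
            cohort_meta_rows.append({"cohort": spec.label, "age_mean": spec.age_mean})

            stage = "vertex_models"
            for meas in config.measures:
                cohort.morphometry[meas] = smoother.apply(cohort.morphometry[meas])
                vals = cohort.morphometry[meas]
                mean_rows[meas].append(
                    (vals.mean(axis=0), vals.std(axis=0, ddof=1), spec.n_subjects)
                )
                amap = glm.vertex_association(
                    cohort, meas, config.predictor, list(config.covariates), g_scores=scores
                )
                cohort_assoc.setdefault(meas, {})[spec.label] = amap
                gassoc = glm.global_association(
                    cohort, meas, config.predictor, list(config.covariates), g_scores=scores
                )
                global_rows.append(dataclasses.asdict(gassoc))
            del cohort
        pd.DataFrame(fit_rows).to_csv(out / "latent_g_fits.tsv", sep="\t", index=False)
        pd.DataFrame(global_rows).to_csv(out / "global_associations.tsv", sep="\t", index=False)
        report["latent_g"] = fit_rows
        report["global_associations"] = global_rows

        # between-cohort agreement of the estimated association maps
        agree_rows = []
        labels = [s.label for s in specs]
        for meas in config.measures:
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    a = cohort_assoc[meas][labels[i]]
                    b = cohort_assoc[meas][labels[j]]
                    ok = a.mask & b.mask
                    r = float(np.corrcoef(a.beta[ok], b.beta[ok])[0, 1])
                    agree_rows.append(
                        {"measure": meas, "cohort_a": labels[i], "cohort_b": labels[j], "r": r}
                    )
        pd.DataFrame(agree_rows).to_csv(out / "cohort_agreement.tsv", sep="\t", index=False)
        report["cohort_agreement"] = agree_rows

        stage = "meta"
        age_means = np.array([row["age_mean"] for row in cohort_meta_rows])
        meta_maps: dict[str, meta.MetaMap] = {}
        meta_summary = {}
        for meas in config.measures:
            betas = np.column_stack([cohort_assoc[meas][l].beta for l in labels])
            ses = np.column_stack([cohort_assoc[meas][l].se for l in labels])
            mm = meta.meta_analyse_maps(
                betas, ses, method=config.meta_method,
                moderator=age_means if len(labels) >= 3 else None,
            )
            meta_maps[meas] = mm
            ok = mm.mask
            beta_map = VertexMap(mm.pooled_beta, ok, name=f"meta_beta_{meas}", mesh_id=mesh.mesh_id)
            maps_io.write_map(out / f"meta_beta_{meas}.curv", beta_map)
            logq = meta.log_q_map(mm.fdr_q)
            summary = {
                "beta_min": float(np.nanmin(mm.pooled_beta)),
                "beta_max": float(np.nanmax(mm.pooled_beta)),
                "n_fdr_sig": int(np.nansum(mm.fdr_q < 0.05)),
                "median_tau2": float(np.nanmedian(mm.tau2)),
                "min_log_q": float(np.nanmin(logq)),
            }
            if mm.moderator_p is not None:
                summary["n_moderator_p05"] = int(np.nansum(mm.moderator_p < 0.05))
                summary["n_moderator_fdr05"] = int(
                    np.nansum(meta.fdr_bh(mm.moderator_p) < 0.05)
                )
            meta_summary[meas] = summary
        report["meta"] = meta_summary

        # meta-analysed mean maps per measure (random-effects pooling of
        # cohort means with SE = SD/sqrt(n))
        ns = np.array([s.n_subjects for s in specs])
        mean_summary = {}
        for meas in config.measures:
            mm_means = np.column_stack([m for m, _, _ in mean_rows[meas]])
            mm_sds = np.column_stack([s for _, s, _ in mean_rows[meas]])
            pooled = meta.pool_mean_maps(mm_means, mm_sds, ns, method=config.meta_method)
            mean_map = VertexMap(pooled.beta, np.isfinite(pooled.beta),
                                 name=f"meta_mean_{meas}", mesh_id=mesh.mesh_id)
            maps_io.write_map(out / f"meta_mean_{meas}.curv", mean_map)
            mean_summary[meas] = {
                "mean_of_means": float(np.nanmean(pooled.beta)),
                "median_tau2": float(np.nanmedian(pooled.tau2)),
            }
        report["meta_means"] = mean_summary

        stage = "profiles"
        prof_rng = np.random.default_rng(seeds["profiles"])
        loadings, noise_sd = synth.simple_structure_loadings(
            config.n_profiles, config.n_latent, prof_rng, config.profile_signal_share
        )
        profile_maps, planted, _ = synth.simulate_profiles(
            mesh, config.n_profiles, config.n_latent, loadings, noise_sd,
            seeds["profiles"], pattern_fwhm_mm=config.fwhm_mm,
        )
        categories = _profile_categories(config.n_profiles)

        stage = "spins"
        spins = spatial.generate_spins(mesh, config.n_spins, seeds["spins"])
        corr_rows = []
        region_rows = []
        for meas in config.measures:
            mm = meta_maps[meas]
            gmap = VertexMap(mm.pooled_beta, mm.mask, name=f"g_{meas}", mesh_id=mesh.mesh_id)
            for pmap in profile_maps:
                sc = spatial.spin_pvalue(gmap, pmap, spins)
                corr_rows.append(
                    {
                        "measure": meas,
                        "profile": pmap.name,
                        "r": sc.r,
                        "p_spin": sc.p_spin,
                        "n_vertices": sc.n_vertices_used,
                    }
                )
            table = spatial.region_correlations(gmap, profile_maps[0], parc)
            for rec in table.as_records():
                rec["measure"] = meas
                rec["profile"] = profile_maps[0].name
                region_rows.append(rec)
        pd.DataFrame(corr_rows).to_csv(out / "spatial_correlations.tsv", sep="\t", index=False)
        pd.DataFrame(region_rows).to_csv(out / "region_correlations.tsv", sep="\t", index=False)
        sig = [r for r in corr_rows if r["p_spin"] < 0.05]
        report["spatial"] = {
            "n_correlations": len(corr_rows),
            "n_spin_significant": len(sig),
            "n_spins": config.n_spins,
        }

        stage = "pca"
        from . import profiles as profiles_mod

        stack = profiles_mod.build_stack(profile_maps, categories)
        res = profiles_mod.pca(stack, config.pca_retain)
        phi = profiles_mod.congruence(res.loadings[:, 0], res.rotated_loadings[:, 0])
        tstat, tdf, tp, tsummary = profiles_mod.category_abs_r_test(
            stack.correlation_matrix(), categories, group_a="receptor"
        )
        load_df = pd.DataFrame(
            res.rotated_loadings,
            columns=[f"rc{i+1}" for i in range(res.n_retained)],
        )
        load_df.insert(0, "map", stack.map_names)
        load_df.insert(1, "category", categories)
        load_df.to_csv(out / "pca_loadings.tsv", sep="\t", index=False)
        pc_corr = {}
        for c in range(res.n_retained):
            smap = res.score_map(c)
            for meas in config.measures:
                mm = meta_maps[meas]
                gmap = VertexMap(mm.pooled_beta, mm.mask, name=f"g_{meas}", mesh_id=mesh.mesh_id)
                sc = spatial.spin_pvalue(gmap, smap, spins)
                pc_corr[f"rc{c+1}_{meas}"] = {"r": sc.r, "p_spin": sc.p_spin}
        report["pca"] = {
            "pct_variance_first_k": float(res.pct_variance[: config.pca_retain].sum()),
            "pct_variance": res.pct_variance[: config.pca_retain].tolist(),
            "pc1_rotation_congruence": phi,
            "category_t": tstat,
            "category_t_df": tdf,
            "category_t_p": tp,
            "category_summary": tsummary,
            "pc_g_correlations": pc_corr,
        }
    except StageFailure:
        raise
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
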
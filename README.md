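# cogmorph

Vertex-wise associations between cortical morphometry and general cognitive
function (g), as a tested, reusable pipeline on synthetic spherical surfaces
with known ground truth.

## The problem

Individual differences in cognitive ability correlate modestly with regional
brain structure. Mapping *where* — at the resolution of the cortical-surface
vertex, across several morphometry measures (volume, surface area, thickness,
curvature, sulcal depth) — requires a chain of steps, each easy to get subtly
wrong:

1. **A latent g score** per subject from a multi-domain cognitive battery:
   one-factor maximum-likelihood factor analysis of the test correlation
   matrix, checked with SEM fit indices (CFI, TLI, RMSEA, SRMR), scores by the
   regression (Thomson) method.
2. **Mass-univariate surface GLMs** per cohort: for every vertex v, the
   standardized coefficient β_v of z(measure_v) on z(g) with age, sex, site
   and head-position nuisance covariates, after 20 mm FWHM heat-kernel
   smoothing on the mesh.
3. **Random-effects meta-analysis** across cohorts per vertex:
   β_i ~ N(μ, SE_i² + τ²), with τ² by REML (DerSimonian–Laird available in
   closed form), Benjamini–Hochberg FDR per map, and natural-log-Q maps
   (ln 0.05 = −2.9957).
4. **Spin-permutation spatial correlations** against stacks of neurobiological
   profile maps: Pearson r over cortex vertices, with p-values from uniformly
   random rotations of the sphere that preserve each map's spatial
   autocorrelation, plus within-region correlations on a paired geodesic
   parcellation (which expose regional structure that cancels in the
   cortex-wide r).
5. **Varimax-rotated PCA** of the profile stack, with Tucker congruence to
   match components across solutions.

Real analyses of this kind run on restricted cohort data. Here every input is
generated by the `synth` module with *planted* effect fields, heterogeneity
and latent patterns, so each stage of the pipeline can be validated against
ground truth.

## Worked example

Three simulated cohorts (n = 2000 / 800 / 400) with a planted g–volume effect
field (max |β| = 0.15, between-cohort SD τ = 0.02), fitted and pooled:

```python
import numpy as np
from cogmorph import latent, meta, synth, glm
from cogmorph.surface import build_icosphere, make_medial_wall, HeatKernelSmoother

mesh = make_medial_wall(build_icosphere(3), 0.05)
truth = synth.make_truth(mesh, synth.TruthConfig(amplitude_g=0.15,
                                                 heterogeneity_sd=0.02), seed=1)
smoother = HeatKernelSmoother(mesh, fwhm_mm=20.0)

betas, ses = [], []
for i, spec in enumerate(synth.default_cohort_specs()):
    cohort = synth.simulate_cohort(mesh, truth, spec, seed=10 + i)
    model = latent.fit_one_factor(cohort.tests)
    g = latent.score(model, cohort.tests).scores
    cohort.morphometry["volume"] = smoother.apply(cohort.morphometry["volume"])
    amap = glm.vertex_association(cohort, "volume", "g",
                                  ["age", "sex", "site", "head_position"], g_scores=g)
    print(f"{spec.label}: n={spec.n_subjects}, CFI={model.cfi:.3f}, "
          f"median |beta|={np.nanmedian(np.abs(amap.beta)):.3f}")
    betas.append(amap.beta); ses.append(amap.se)

mm = meta.meta_analyse_maps(np.column_stack(betas), np.column_stack(ses), method="REML")
ok = mm.mask
r = np.corrcoef(mm.pooled_beta[ok], truth.beta_g["volume"].values[ok])[0, 1]
print(f"pooled beta range [{np.nanmin(mm.pooled_beta):.3f}, {np.nanmax(mm.pooled_beta):.3f}], "
      f"FDR Q<.05 at {int(np.nansum(mm.fdr_q < 0.05))}/{ok.sum()} vertices, "
      f"truth correlation r={r:.3f}")
```

prints

```
cohort_large: n=2000, CFI=1.000, median |beta|=0.046
cohort_mid: n=800, CFI=1.000, median |beta|=0.050
cohort_small: n=400, CFI=0.997, median |beta|=0.061
pooled beta range [-0.190, 0.251], FDR Q<.05 at 461/1220 vertices, truth correlation r=0.859
```

The one-factor model fits cleanly in each cohort (CFI ≈ 1), per-cohort
vertex effects are small (median |β| ≈ 0.05, inside the realistic ±0.2
envelope), and the REML-pooled map recovers the planted field at r = 0.86 —
even though the smallest cohort alone would be badly underpowered.

The same flow is available from the shell: `cogmorph run` executes
simulate → fit-g → fit-vertex → meta → spin-corr/region-corr → pca from a
YAML config and writes TSV tables, JSON summaries and curv maps;
`cogmorph simulate`, `fit-g`, `spin-corr`, `region-corr`, `meta` and `pca`
expose the individual stages.

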
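# glymmark

MRI markers of brain glymphatic function — the **DTI-ALPS index** and
**gBOLD-CSF coupling strength** — with the cohort-statistics and
diagnostic-model layer used to relate them to anxiety in Parkinson's
disease, plus synthetic ground-truth generators that make the whole
pipeline testable without any imaging download.

**Who it is for:** neuroimaging researchers who want a tested,
scriptable implementation of these two glymphatic proxies (and of the
group-comparison/ROC layer around them), working from template-space
NIfTI volumes and plain cohort tables.

## The markers

**DTI-ALPS** ("analysis along the perivascular space"): at the level of
the lateral-ventricle body, projection fibers (superior corona radiata,
z-oriented) and association fibers (superior longitudinal fasciculus,
y-oriented) both run perpendicular to the x-oriented medullary veins,
so diffusivity along x is dominated by the perivascular space. With
mean diffusivities over four 5 mm spherical ROIs on the JHU-ICBM-FA
template,

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

per hemisphere, averaged into a mean index. Healthy adults sit near
1.3; lower values indicate poorer glymphatic function.

**gBOLD-CSF coupling**: low-frequency global gray-matter BOLD
fluctuations drive CSF inflow at the foramen magnum with a delay. The
Pearson cross-correlation r(τ) of gBOLD(t + τ) with CSF(t) over lags
−5..+5 TR (TR = 1.5 s) is extreme at τ = −3 (gBOLD leads); |r(−3)| is
the coupling strength. The construction is validated by the negative
temporal derivative of gBOLD coupling maximally with CSF at lag 0, and
per-subject significance comes from a 10,000-draw mismatched-subject
permutation null.

The statistics layer (ANOVA / gated two-sample t / chi-square /
Kruskal-Wallis / Bonferroni / partial correlation) runs from raw cohort
tables *or* directly from printed group summaries (n, mean, sd), so the
published summary tables ship as recomputable fixtures. The
diagnostics layer provides ROC/AUC with DeLong confidence intervals and
curve comparisons, Youden operating points, and a logistic multivariate
combined score.

## Worked example

```python
import numpy as np
from glymmark import (
    PhantomSpec, generate_dwi_phantom, fit_diffusion_tensor,
    default_rois, compute_alps_index,
    CoupledSeriesSpec, generate_coupled_series, analyze_pair,
    load_table, t_test,
)
from glymmark.alps import roi_masks
from glymmark.tables import group_summaries

# --- ALPS on a noisy DWI phantom (SNR 20) with known ground truth
spec = PhantomSpec(noise_sd=50.0, seed=11)          # 91x109x91 grid, 2 mm
data = generate_dwi_phantom(spec)
rois = default_rois(spec.grid_shape, spec.voxel_size)
mask = np.zeros(spec.grid_shape, bool)
for m in roi_masks(rois, spec.grid_shape, spec.voxel_size).values():
    mask |= m
tv = fit_diffusion_tensor(data.dwi, data.bvals, data.bvecs,
                          mask=mask, voxel_size=spec.voxel_size)
res = compute_alps_index(tv, rois)
print(f"ALPS L={res.alps_left:.4f} R={res.alps_right:.4f} "
      f"mean={res.alps_mean:.4f} (truth {spec.true_alps()['mean']:.4f})")
# ALPS L=1.3540 R=1.3286 mean=1.3413 (truth 1.3125)

# --- gBOLD-CSF coupling on a generated pair (coupling 0.8, lag 3)
pair = generate_coupled_series(
    CoupledSeriesSpec(amplitude=0.8, noise_sd=0.2, seed=11))
r = analyze_pair(pair)
print(f"strength={r.strength:.3f} signed={r.signed_r:+.3f} peak_lag={r.peak_lag}")
# strength=0.764 signed=-0.764 peak_lag=-3   (analytic target 0.769)

# --- a printed-table statistic recomputed from (n, mean, sd)
t1 = load_table("table1")
dur = t_test(*group_summaries(t1, "duration"))      # auto pooled/Welch gate
print(f"disease duration: t={dur.statistic:.3f}, p={dur.p:.3f}")
# disease duration: t=2.578, p=0.016
```

The phantom's fitted index lands within a couple of percent of its
prescribed ratio at SNR 20 (and is exact without noise); the coupling
pair recovers the prescribed lag and sign, with strength attenuated by
measurement noise exactly as the generator's analytic target predicts;
the recomputed duration t matches the published 2.573 (Welch-routed by
the variance gate) to printed rounding.

A thin CLI wraps the same stages:

```bash
glymmark simulate cohort --seed 3 --out out/
glymmark stats --plan tables --out stats.tsv
glymmark roc --cohort out/cohort.tsv --out roc.json
```

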
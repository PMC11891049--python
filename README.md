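# ivimrad — multi-software robustness of first-order IVIM radiomics

Intravoxel incoherent motion (IVIM) imaging fits the diffusion-weighted
MRI signal of each voxel to a biexponential decay,

    S(b)/S0 = f_p·exp(−b·D_p) + (1 − f_p)·exp(−b·D_t),

separating tissue diffusivity *D_t* (mm²/s) from perfusion-driven
pseudo-diffusion *D_p* with perfusion fraction *f_p*. In breast imaging
these coefficients discriminate benign from malignant lesions — but every
software package estimates them differently, and that algorithmic
variability can swamp the biology. This package implements, as a tested
library plus a sequence of analysis drivers, the full robustness study a
multi-site trial would need:

1. **Synthetic multi-site cohort** (`ivimrad.cohort`) — 302 seeded
   patients across three sites with the published site-specific b-value
   schemes, benign/malignant counts, per-class IVIM parameter
   distributions, right-skewed ROI sizes and Rician noise.
2. **Three voxelwise fitters** (`ivimrad.fitting`, `ivimrad.bayes`) —
   two iterative segmented least-squares variants and a Bayesian
   posterior-mean grid fit, emulating the algorithm families of widely
   used packages, plus a multi-start full-NLLS oracle for testing.
3. **First-order histogram radiomics** (`ivimrad.radiomics`) — fixed
   100-bin histograms (f_p: 0–1, D_p: 0–0.1, D_t: 0–0.003 mm²/s);
   min/max/mean/variance/skewness/kurtosis with per-parameter
   utilized-voxel accounting; 16 reported metrics.
4. **Agreement statistics** (`ivimrad.agreement`) — pairwise Pearson r
   per site, mean r and CV across the 9 pair×site cells, ICC(2,1), and
   Bland-Altman summaries.
5. **Diagnostics** (`ivimrad.diagnostics`) — site-adjusted logistic
   regression (per-site intercept and slope), apparent and
   leave-one-patient-out AUC with DeLong SEs and paired DeLong tests,
   and cross-software AUC mean/CV rankings.

Audience: imaging scientists evaluating IVIM biomarker robustness, and
anyone who needs well-tested reference implementations of segmented /
Bayesian IVIM fitting, fixed-bin histogram radiomics, ICC(2,1), or DeLong
machinery. Users with their own data can load 4-D NIfTI + `.bval` + mask
via `ivimrad.nifti_io.import_external_case`.

## Worked example

```python
import numpy as np
from ivimrad import (IVIMParams, VoxelDecay, ivim_signal, add_rician_noise,
                     fit_segmented_lsq, fit_bayesian, site_bvalue_scheme)

scheme = site_bvalue_scheme("C")            # 13 b-values, 0–1000 s/mm²
truth = IVIMParams(f_p=0.10, D_p=0.01, D_t=0.001, S0=1.0)
clean = ivim_signal(truth, scheme.b_values)
noisy = add_rician_noise(clean, snr=40, rng=np.random.default_rng(0))

seg = fit_segmented_lsq(VoxelDecay(noisy, scheme), "seg_a")
bay = fit_bayesian(VoxelDecay(noisy, scheme))
print(f"segmented: f_p={seg.params.f_p:.3f} D_p={seg.params.D_p:.4f} "
      f"D_t={seg.params.D_t:.5f}")
print(f"bayesian : f_p={bay.params.f_p:.3f} D_p={bay.params.D_p:.4f} "
      f"D_t={bay.params.D_t:.5f}")
```

prints

```
segmented: f_p=0.112 D_p=0.0056 D_t=0.00110
bayesian : f_p=0.086 D_p=0.0312 D_t=0.00114
```

— on this noise draw both fitters pin the tissue diffusivity to ~10–14%
and the perfusion fraction to ~15%, while their pseudo-diffusion
estimates disagree by a factor of five: the robustness ordering (D_t most
stable, then f_p, then D_p) that drives the whole study, visible in a
single voxel.

## The analysis

The numbered drivers under `analysis/` run the study stage by stage
(each re-runnable on its own; `--tiny` for a quick pass):

```bash
cd analysis
python 01_simulate.py   --out ../results/study --seed 1   # cohort + signals
python 02_fit.py        --out ../results/study --seed 1   # 3 fitters / voxel
python 03_radiomics.py  --out ../results/study --seed 1   # 16-metric table
python 04_agreement.py  --out ../results/study --seed 1   # r / ICC / Bland-Altman
python 05_diagnostics.py --out ../results/study --seed 1  # AUC / LOU / DeLong
python 06_report.py     --out ../results/study --seed 1   # report.md
```

or as one call: `ivimrad.run_study(StudyConfig(seed=1), "results/study")`.
On the seeded default cohort the study reproduces the qualitative
structure expected of multi-software IVIM radiomics: mean and maximum of
D_t lead the agreement ranking (mean inter-software r ≈ 0.97), D_p
metrics trail badly (r ≈ 0.2–0.5), segmented–segmented pairs agree better
than segmented–Bayesian, f_p is utilized in 100% of voxels while the
bound-rejecting segmented variant drops D_p voxels, and D_t_mean tops the
diagnostic ranking (mean apparent AUC ≈ 0.86, LOU ≈ 0.83).

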
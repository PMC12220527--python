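# choroquant

Choroidal vascularity quantification for swept-source OCT, with a synthetic
acquisition simulator for studying B-scan frame averaging.

The choroid — the vascular layer between retina and sclera — is quantified
on OCT by segmenting its boundaries, binarizing the interior into dark
vessel lumina and bright stroma, and integrating 18 radial B-scans into
volumes over the 6-mm fovea-centred disc:

* **LV, SV, TCV** — luminal, stromal and total choroidal volume (mm³),
  with LA + SA = TCA per scan and LV + SV = TCV per eye;
* **CT** — mean choroidal thickness (µm);
* **CVI = LV / TCV** — the choroidal vascularity index.

How many frames the device averages per B-scan changes speckle noise and
therefore these numbers.  `choroquant` implements the full measurement
chain — CLAHE enhancement, shortest-path boundary search with an explicit
edge-confidence model, Niblack local thresholding (T = m + k·s), polar
sector quadrature (V = Δθ·Σ_m ∫ f_m(r)·r·dr), and the repeatability
battery (Sw, CoR = 1.96·√2·Sw, ICC(A,1), Bland–Altman, repeated-measures
ANOVA with Bonferroni pairwise tests) — plus a phantom/acquisition
simulator that emulates the whole experiment: layered eye cross-sections
with three vascular strata, fully developed speckle whose contrast falls
as 1/√N under N-frame averaging, log display compression, chinrest-remount
variability and a signal-strength exclusion gate.  See `docs/methods.md`
for the models and calibration.

## Worked example

```python
import dataclasses
from choroquant import StudyConfig, run_averaging_study
from choroquant.experiment import averaging_study_summary

cfg = dataclasses.replace(StudyConfig(), master_seed=1)  # 22 eyes, 2 repeats,
result = run_averaging_study(cfg)                        # levels 4..64 (~6 min)

for level, ct in result.metrics.groupby("n_avg").ct_um.mean().items():
    print(f"N={level:>2}: mean CT {ct:6.1f} um")
print(averaging_study_summary(result))
```

prints

```
N= 4: mean CT  270.9 um
N= 8: mean CT  274.9 um
N=16: mean CT  275.8 um
N=32: mean CT  277.1 um
N=64: mean CT  277.6 um
{'cvi_anova_p': 0.18532207095750622, 'volume_plateau_frames': 16,
 'sv_plateau_frames': 8, 'min_icc': 0.9864475943288874,
 'max_cvi_cor_pct': 1.0143108273812365}
```

Read: thickness climbs with frame averaging as the noisy choroidal–scleral
interface becomes distinct, and stabilises from 16 frames (no significant
Bonferroni pair among 16/32/64); stromal volume stabilises already at 8;
the vascularity index CVI never differs across levels (ANOVA p = 0.19) —
it is a ratio and the averaging artefacts cancel.  Repeatability is
excellent throughout (all ICC ≥ 0.986, CVI coefficient of repeatability
≤ 1.0 percentage point).

A `choroquant` command-line tool wraps the same library for shell use:
`simulate`, `segment`, `quantify`, `stats` and `experiment` (YAML config,
`--seed`, `--scale`, `--outdir`).

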
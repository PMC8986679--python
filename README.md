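# cochleapy

Synthetic cochlear morphometry and test-retest agreement analysis for
cochlear-implant imaging studies.

Pre-operative planning of cochlear implantation relies on two diameters
read off an oblique CT reformat of the basal turn (the *cochlear view*):
the cochlear diameter **A** (round window, through the modiolus, to the
far lateral wall) and the width **B** (wall to wall, perpendicular to A
through the modiolus).  From these the duct length along the organ of
Corti is estimated with the elliptic circular approximation,

```
CDL_OC = 1.71·(1.18·A + 2.69·B) − 0.18·√(0.72·A·B) + 1.58   [mm]
```

where 1.58 mm is the fixed hook-region length (an alternative grouping,
in which 1.71 multiplies both terms, is provided as `mode="grouped"`;
see `docs/methods.md`).  Post-operatively, the twelve contact centers of
a FLEX28 array (nominal pitch 2.1 mm) yield insertion depths and
inter-electrode distances (IED).

How repeatable these measurements are depends on the imaging modality —
multislice CT (600 µm slices), flat-panel volume CT (466 µm), and its
high-resolution secondary reconstruction (99 µm).  `cochleapy` is for
researchers who want to study that reliability chain quantitatively: it
provides

- **`cochleapy.synthetic`** — a parametric cochlea phantom (shifted
  logarithmic spiral with exact A/B constraints and a realistic wall
  length), electrode placement at fixed arc-length pitch, and a
  modality-specific observation model (landmark noise scaled to slice
  thickness, medial/lateral wall bias, metal-artifact bias, recorded
  random rigid transforms);
- **`cochleapy.geometry`** — cochlear-view plane fitting, A/B
  measurement, CDL_OC, insertion depths and IEDs from labeled 3D
  landmark CSVs;
- **`cochleapy.agreement`** — the reliability toolkit: two-way
  absolute-agreement single-measures ICC with F-based confidence
  intervals and Cicchetti-style categories, Cronbach's alpha, paired
  t-tests, Shapiro–Wilk + Lilliefors normality gating, repeated-measures
  ANOVA / Friedman omnibus, and Bland–Altman analysis against clinical
  margins (±1.5 mm CDL, ±0.09 mm IED);
- **`cochleapy.pipeline`** and a `cochleapy` CLI — the full
  simulate → measure → agree study, reproducible from a seed and a YAML
  config.

## Worked example

```python
import cochleapy as cp

print(f"CDL_OC(9.0, 6.5) grouped = {cp.cdl_oc(9.0, 6.5, mode='grouped'):.2f} mm")

cfg = cp.PipelineConfig(equation_mode="grouped", rng_seed=1)
report = cp.run_study(cfg)
b = report.block(1, "MSCT")
print(f"Group 1 MSCT CDL_OC: mean {b.mean:.2f} mm (SD {b.sd:.2f}), "
      f"ICC {b.reliability.icc:.3f} [{b.reliability.icc_ci_low:.3f}, "
      f"{b.reliability.icc_ci_high:.3f}] ({b.reliability.icc_category}), "
      f"alpha {b.reliability.alpha:.3f}, outliers {b.bland_altman.n_outliers}/{b.n}")
```

prints

```
CDL_OC(9.0, 6.5) grouped = 38.54 mm
Group 1 MSCT CDL_OC: mean 36.48 mm (SD 1.62), ICC 0.801 [0.571, 0.916] (excellent), alpha 0.891, outliers 3/20
```

Reading: over 20 simulated non-implanted ears measured twice with
600 µm MSCT-like noise, the duct length averages 36.5 mm with a
test-retest ICC of 0.801 (excellent band, but with a wide CI at n = 20)
and 3 subjects whose two series disagree by more than the clinically
acceptable 1.5 mm.  The same cohort under the 99 µm secondary
reconstruction gives ICC 0.979 and zero clinical outliers — the
high-resolution setting is the reliable one, and the cross-modality
contrast is significant against it (paired p ≈ 4e-13) while
MSCT-vs-fpVCT is not (p = 0.19).

The same study from the shell:

```sh
cochleapy run --seed 1 --equation-mode grouped --out results/study
cochleapy margins --cdl-margin 1.5 --pitch 2.1 --ref-cdl 35   # -> 0.09
```

which writes `report.json`, `report.csv`, `measurements.csv` and
`bland_altman_points.csv` (plot-ready per-subject means/differences).

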
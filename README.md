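# liverperf

Quantitative liver perfusion from dynamic contrast-enhanced (DCE) MRI with
a dual-input two-compartment distributed-parameter model.

The liver is supplied by both the hepatic artery and the portal vein, and
its microvasculature (sinusoids) communicates with an interstitial space
(the Space of Disse) through endothelial fenestrations that close in
cirrhosis and tumours. `liverperf` models a voxel's contrast concentration
as

```
Ct(t) = F [ α·Ca(t−τa) + (1−α)·Cp(t−τp) ] ∗ R(t)
```

where the impulse residue function `R(t)` is 1 during the vascular transit
(`t < t1`), jumps to the extraction ratio `E = 1 − exp(−PS/F)` at `t1`, and
then decays following the distributed-parameter back-flux solution built on
the modified Bessel function `I1`. Fitting this model voxel-by-voxel yields
six perfusion parameters — total flow `F`, arterial fraction `α`, vascular
transit time `t1`, vascular and interstitial volume fractions `v1` (derived
as `F·t1`) and `v2`, and the permeability–surface area product `PS` — plus
two input arrival delays.

The package is aimed at researchers developing or validating liver DCE-MRI
perfusion pipelines: it provides the forward model, a robust voxelwise
fitter, a synthetic phantom generator with four tissue classes (volunteer,
cirrhosis, HCC, metastasis), ROI/group statistics, NIfTI/CSV I/O and a CLI.

## Worked example

Simulate a noiseless volunteer voxel and refit it:

```python
from liverperf import (FitConfig, TimeGrid, fit_voxel, generate_aif,
                       generate_pif, tissue_curve, worked_example_parameters)

grid = TimeGrid(n=120, dt=2.0)          # 120 volumes at 2.0 s
Ca, Cp = generate_aif(grid), generate_pif(grid)
truth = worked_example_parameters()     # F=81.0, α=0.31, t1=23.3 s, v2=0.057, PS=35.1
Ct = tissue_curve(truth, Ca, Cp, grid)

fit = fit_voxel(Ct, Ca, Cp, FitConfig()).params
print(f"F  = {fit.F:.1f} mL/min/100mL")
print(f"α  = {100 * fit.alpha:.1f} %")
print(f"t1 = {fit.t1:.1f} s")
print(f"v2 = {100 * fit.v2:.1f} %")
print(f"PS = {fit.PS:.1f} mL/min/100mL")
print(f"v1 = {100 * fit.v1(hct=0.4):.1f} % (plasma convention)")
```

prints

```
F  = 81.0 mL/min/100mL
α  = 31.0 %
t1 = 23.3 s
v2 = 5.7 %
PS = 35.1 mL/min/100mL
v1 = 18.9 % (plasma convention)
```

i.e. the fitter recovers the generating parameters exactly on noiseless
data: total flow 81 mL/min per 100 mL of tissue, about a third of it
arterial, a 23 s vascular transit, a small interstitial space (5.7 %), and
an extraction ratio `E = 1 − exp(−35.1/81.0) ≈ 0.35` per pass.

The same pipeline from the shell:

```bash
liverperf simulate --seed 7 --output phantom/       # 4D NIfTI + truth + input CSVs
liverperf fit --dynamic phantom/dynamic.nii --output maps/
liverperf stats --seed 7 --output stats/            # group comparison tables
liverperf roundtrip --seed 7 --output out/          # all of the above + recovery report
```

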
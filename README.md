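# qibcdeg

Quantitative image-based cytometry (QIBC) and kinetics tooling for studies of
nuclear protein turnover — built around the workflow used to characterize
cell-cycle-coupled degradation of nuclear cGAS by the CRL5–SPSB3 ubiquitin
ligase. The package provides, as tested reusable components:

* **Synthetic ground truth** — seeded generators for multichannel nuclei
  fields (DAPI / EdU / cGAS-GFP), arrayed 96-well RNAi screen plates,
  cycloheximide-chase time courses, and BLI sensorgrams, each with an exported
  truth table so every downstream stage can be validated without raw data.
* **Segmentation & features** — Otsu + distance-transform-watershed nuclear
  masks from DAPI, dilation-based cytoplasmic ring masks, and per-cell
  MFI/integrated intensities with per-field lower-quartile background
  subtraction.
* **Cell-cycle gating** — a two-component Gaussian mixture on log integrated
  DAPI places the 2N/4N peaks; EdU gates S phase; elevated DAPI MFI (condensed
  chromatin) or H3pS10 splits M out of the 4N window. Per-phase summaries and
  condition contrasts (one-way ANOVA, Šídák-adjusted pairwise tests,
  bootstrap CIs).
* **Screen scoring** — per-plate three-anchor normalization with the control
  conventions cGAS siRNA = −1, negative control = 0, epoxomicin = +1:

  ```
  score(x) = (x − c0)/(c0 − c−)   if x < c0
             (x − c0)/(c+ − c0)   otherwise
  ```

  and hit calling at |score − mean(negative)| > 3 s.d. (strict), with a
  hit-resistant s.d. estimate calibrated to the Gaussian two-sided rate
  2·Φ(−3).
* **Decay kinetics** — greedy nearest-centroid nucleus tracking, first-frame
  relative normalization, exponential decay fits N(t) = N₀·e^(−kt) with
  t½ = ln 2 / k, and PCNA diffuse/punctate classification for G1→S / S→G2
  transition timing.
* **Binding kinetics** — global 1:1 Langmuir fits across BLI concentration
  series, R(t) = R_eq(C)(1 − e^(−(k_on·C + k_off)t)) in association and
  single-exponential k_off decay in dissociation, with K_d = k_off / k_on.

## Worked example

```python
import math
from qibcdeg.synthetic_data import (ChaseTruth, simulate_chase,
                                    simulate_sensorgrams,
                                    make_cell_population, measure_population)
from qibcdeg.kinetics import fit_exponential_decay
from qibcdeg.binding import fit_1to1
from qibcdeg.gating import fit_gates, call_phases, phase_summaries

# chase decay: planted half-life 4 h, 5% multiplicative noise
chase = simulate_chase(ChaseTruth(rate_k=math.log(2)/4, noise_cv=0.05), seed=3)
fit = fit_exponential_decay(chase["time_h"], chase["abundance"])
print(f"half-life = {fit.half_life:.2f} h  (k = {fit.rate_k:.3f}/h, r^2 = {fit.r_squared:.3f})")

# BLI: five concentrations around a planted Kd of 352 nM
sg = simulate_sensorgrams(1e5, 3.52e-2,
                          [8.8e-8, 1.76e-7, 3.52e-7, 7.04e-7, 1.408e-6],
                          noise_sd=0.005, seed=4)
bf = fit_1to1(sg)
print(f"kon = {bf.kon:.3g} /M/s, koff = {bf.koff:.3g} /s, Kd = {bf.kd*1e9:.0f} nM")

# QIBC gating of a 5,000-cell population with G2 nuclear cGAS at half of G1
cells = make_cell_population(5000, seed=1, place=False)
rec = measure_population(cells, noise_cv=0.05, seed=2)
gates = fit_gates(rec)
phases = call_phases(rec, gates)
print(f"4N/2N peak ratio = {gates.peak_ratio:.3f}")
print(phase_summaries(rec, phases, "cgas_gfp_mfi", "G1").round(3).to_string(index=False))
```

prints

```
half-life = 3.74 h  (k = 0.185/h, r^2 = 0.965)
kon = 9.98e+04 /M/s, koff = 0.0351 /s, Kd = 352 nM
4N/2N peak ratio = 1.996
phase  n_cells  mean_mfi  sd_mfi  relative_mfi
   G1     2450   300.484  15.080         1.000
    S     1552   220.433  11.223         0.734
   G2      713   150.081   7.628         0.499
    M      243   149.991   7.255         0.499
```

The 4-point chase recovers the planted 4 h half-life within its noise; the
global Langmuir fit returns the planted sub-micromolar affinity; the gating
table shows the planted interphase decline of nuclear cGAS (G2 at half the G1
level) with a DNA-content peak ratio of 2, as expected for 2N vs 4N.

A `qibcdeg` command-line tool wraps the same functions
(`qibcdeg simulate {field,plate,chase,bli}`, `segment`, `qibc`, `screen`,
`chase`, `track`, `bli`); see `qibcdeg --help`.

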
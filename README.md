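# autospill

Automated computation of flow-cytometry **spillover matrices** from
single-color compensation controls, and of the **spillover spreading matrix**
(SSM), with autofluorescence treated as an extra dye.

Fluorescent dyes emit into detectors other than their assigned one. For true
per-event dye abundances `x` (length *d*) and observed detector signals `y`
(length *c* ≥ *d*), the mixing model is `x S = y`, where `S` is the *d × c*
row-normalized spillover matrix; compensation applies `S⁻¹` (or a per-event
least-squares solve in the spectral case *c* > *d*). Estimating `S` by hand
from positive/negative populations becomes unreliable in high-parameter
panels, with residual over/under-compensation that accumulates across dozens
of channels. This package is aimed at cytometrists and computational
immunologists who want a fully automated, reproducible alternative:

1. **Automated gating** of the cell or bead population on forward/side
   scatter: extreme-value trimming, two successive density tessellations
   (kernel density maxima → Voronoi tiles), debris rejection, and a
   density-threshold convex-hull gate.
2. **Robust initial estimate**: each coefficient `S_ij` is the slope of a
   Huber M-regression (k = 1.345) of secondary-detector vs primary-detector
   fluorescence over the gated events — no positive/negative populations
   required, so smears and dim controls work.
3. **Iterative refinement**: compensating with an erroneous estimate
   `U = S + T` leaves residual slopes `E_ij` (the compensation error matrix)
   that satisfy the exact identity `T = −E U`. The update
   `S ← row-normalize(S + E S)` is iterated — switching from linear to
   bi-exponential (logicle) scale once max|E| < 10⁻², damping the update to
   10% when a moving average of the decrease of sd(E) signals oscillations
   (< 10⁻⁶) — until max|E| < 10⁻⁴ across all controls.
4. **Autofluorescence removal**: an unstained control is folded in as an
   extra "AF" dye whose primary is a free detector, so endogenous
   fluorescence is compensated out like any other dye.
5. **AutoSpread**: the SSM coefficient `SS_C^P` (incremental robust SD
   induced in channel C per unit √fluorescence of P) is estimated from
   quantile bins of each compensated control via two regressions,
   `σ = β f_√(F) + σ₀` (intercept = noise floor) and the no-intercept fit of
   `f_√(σ² − σ₀²)` on `f_√(F)`, with F-test/negative zeroing, where
   `f_√(x) = sign(x)(√(|x|+1) − 1)`.

A synthetic-panel generator with exact ground truth (spectra, noise model,
autofluorescence, scatter/debris geometry) makes every stage testable
offline; see `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
import autospill as asp

spec = asp.SyntheticPanelSpec(seed=11)          # 7 dyes + AF, 8 detectors, 20k events
panel = asp.generate_panel(spec)

results = asp.SpilloverModel(panel.controls, autofluorescence=True).fit()
print(results.summary())
print("recovered vs true spillover, max abs difference:",
      round(float(np.abs(results.spillover.coef - panel.spillover.coef).max()), 4))

spread = asp.SpreadingModel.from_results(results).fit()
print(spread.summary())
```

prints

```
Spillover estimation results
============================================================
 dye primary  events
dye1   FL1-A   11945
dye2   FL2-A   11804
dye3   FL3-A   11782
dye4   FL4-A   11931
dye5   FL5-A   11972
dye6   FL6-A   11671
dye7   FL7-A   12070
  AF   FL8-A   12041
------------------------------------------------------------
status:            converged
iterations:        17
final scale:       biexp
final max |error|: 9.473e-05
final sd(error):   1.255e-05
recovered vs true spillover, max abs difference: 0.0161
```

Each control was gated to ~12,000 events (the generator plants 20% debris);
refinement switched to the bi-exponential scale and stopped once the largest
residual compensation slope fell below 10⁻⁴. The initial sd of the error
slopes on this panel is 0.193 (the generator's autofluorescence biases the
per-row initial regressions, as in real cell data), so convergence reduces
the error spread by more than four orders of magnitude. The remaining 0.016
deviation from the generating matrix is the sampling limit of a finite
control (concentrated in the dim dye's autofluorescence column). The
spreading summary that follows lists `SS_C^P` per dye pair, with
non-significant and negative coefficients zeroed and annotated.

The same pipeline runs from the shell:

```sh
autospill fixtures  --out panel --dyes 7 --detectors 8 --events 20000 --seed 11
autospill spillover --controls panel --index panel/index.csv --out result \
                    --autofluorescence --plots
autospill spread    --controls panel --index panel/index.csv \
                    --spillover result/spillover.csv --out result/ssm.csv
```

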
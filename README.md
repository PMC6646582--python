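# fatkin

Individual-based fatigue kinetics of repeated maximal contractions.

`fatkin` is a Python package for exercise physiologists studying how
maximal torque, voluntary activation and evoked torque decline during
prolonged maximal-intensity exercise, and whether peripheral (muscle)
fatigue is held under an individual *critical threshold* by reduced
central drive. It covers the complete analysis chain from raw
dynamometer traces to cohort statistics:

1. **Trace extraction** — from a 2 kHz isometric torque trace of one
   neuromuscular test (a maximal contraction with a superimposed 100 Hz
   doublet, then a resting potentiated doublet), compute the IMVC
   plateau, the superimposed twitch ST, the potentiated resting twitch
   Q_tw, and voluntary activation by corrected twitch interpolation:

   VA = [1 − (ST × T_stim/T_max) / Q_tw] × 100

2. **Kinetics** — fit, per subject and condition, the two-parameter
   exponential model of each variable (DV = IMVC, VA or Q_tw, in % of
   its pre-fatigue baseline) against accumulated contraction time *t*:

   DV(t) = A + (100 − A)·e^(−t/τ)

   where *A* (%) is the asymptote — the stable state, interpreted as the
   individual critical threshold — and τ (s) the curvature constant
   (95 % of the decline is completed by ≈ 3τ).

3. **Iso-decrement mapping** — eliminate time between fitted models to
   express VA and Q_tw in closed form at a given IMVC decrease:

   DV = A_DV + (100 − A_DV)·[(IMVC − A_IMVC)/(100 − A_IMVC)]^(τ_IMVC/τ_DV)

   evaluated per subject at 10, 20 and 30 % IMVC decrease (levels at or
   below a subject's IMVC asymptote are flagged unreachable).

4. **Cohort statistics** — paired high-force (HF) vs low-force (LF)
   comparisons with Bonferroni correction, and simple linear regressions
   between individual parameters (signed r and R²).

A synthetic-data module generates correlated cohorts, noisy time series
and raw torque traces with known ground truth, so the whole chain is
testable end to end; a packaged fixture ships the published 13-subject
parameter table used by the `reproduce` command.

## Worked example

```python
import numpy as np
from fatkin import (FatigueSeries, exp_decay, fit_exponential, predict,
                    time_to_fraction, invert_imvc, dv_at_imvc,
                    load_table1_fixture, run_parameter_correlations)

t = np.arange(0, 161, 20)                       # one test every 20 s of contraction
series = FatigueSeries("01", "HF", "IMVC", t, exp_decay(t, 64.0, 31.0))
fit = fit_exponential(series)
print(f"A = {fit.A:.1f} %   tau = {fit.tau:.1f} s   R^2 = {fit.r_squared:.3f}")
print(f"IMVC predicted at t = 60 s: {predict(fit, 60):.1f} %")
print(f"95 % of the loss completed by {time_to_fraction(fit, 0.95):.1f} s (~3 tau)")
print(f"20 % IMVC decrease reached at t = {invert_imvc(fit, 80.0):.1f} s")

cohort = load_table1_fixture()
for r in run_parameter_correlations(cohort)[:5]:
    print(f"{r.name:22s} R^2 = {r.r_squared:.2f}  p = {r.p_value:.4f}")
```

prints

```
A = 64.0 %   tau = 31.0 s   R^2 = 1.000
IMVC predicted at t = 60 s: 69.2 %
95 % of the loss completed by 92.9 s (~3 tau)
20 % IMVC decrease reached at t = 25.1 s
A_VA~A_QTW_HF          R^2 = 0.48  p = 0.0084
A_VA~A_QTW_LF          R^2 = 0.47  p = 0.0096
tau_VA~tau_QTW_HF      R^2 = 0.68  p = 0.0005
tau_VA~tau_QTW_LF      R^2 = 0.34  p = 0.0361
A_QTW_HF~A_QTW_LF      R^2 = 0.45  p = 0.0122
```

The first block fits one subject's high-force IMVC decline: the torque
settles at 64 % of baseline with a 31 s time constant, so the subject
has lost 95 % of their eventual torque deficit after ~93 s of
accumulated contraction. The regressions show that subjects with a
lower voluntary-activation asymptote plateau at a *higher* evoked-torque
asymptote (negative slope, R² ≈ 0.48–0.47 in both conditions), the
individual-level signature of a critical peripheral fatigue threshold.

## Command line

```bash
fatkin simulate  --seed 1 --out out/sim          # synthetic cohort + traces
fatkin extract   --trace out/sim/trace.csv --out out/nm
fatkin fit       --series out/sim/series.csv --out out/fit
fatkin decrement --fits out/fit/fits.csv --out out/dec
fatkin stats     --fits out/fit/fits.csv --out out/stats
fatkin reproduce --out out/repro                 # packaged 13-subject table
```

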
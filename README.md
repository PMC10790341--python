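# follisim

Quantitative toolkit for studying how mouse ovarian follicles are selected
into the preovulatory cohort. It covers the three stages of that analysis:

1. **BrdU labeling-index quantification** — compute the granulosa labeling
   index LI = A⁺ / (A⁺ + A⁻) from multi-class segmentation masks inside a
   basal-lamina region of interest, with cumulus exclusion, plus the
   stereological rules for serially sectioned ovaries (pseudodiameter from
   the widest cross-section, exclusion of follicles whose widest section is
   at the edge of the sampling volume, five-criterion atresia
   classification, stage assignment at 80 / 130 / 170 / 350 µm).
2. **Iterative granulosa-cell growth model** — the mural granulosa layer
   volume scales with follicle diameter as V_M = 0.18·D^3.05 (µm³) and is
   filled by cells of 132.6 µm³. Cell number grows daily as
   N_i = N_{i−1}·(1 + LI_eff), with
   LI_eff = f·max(0, LI₀ − s·(D_{i−1} − D₀)), where s is the linear decline
   of proliferation with diameter (default 0.0008 per µm) and f = 0.795 is
   an adjustment factor calibrated against observed follicle growth across
   the estrous cycle. The new cell number maps back to a diameter through
   the volume law.
3. **Population analysis and cohort simulation** — LI-vs-diameter
   regressions (all follicles, or the fast-growing top 20% per 50-µm bin),
   preovulatory counts, pulse-chase survivor-effect comparisons, and
   simulation of preovulatory-cohort recruitment to obtain the minimum
   estrous-cycle length a starting population permits.

A synthetic-data module generates every input with known ground truth:
follicle populations with the four-phase LI trajectory (slow preantral
phase with LIs rarely above 30%, a proliferative spurt at 130–170 µm, then
a linear decline), LI-percentile-dependent atresia, serial-section stacks
of spherical follicles and class-coded label masks.

## Worked example

Grow a 250-µm follicle carrying a labeling index of 0.45 (a fast grower)
for four days:

```python
from follisim import simulate_growth

traj = simulate_growth(250.0, 0.45, 4)
print(traj.to_frame().round(4).to_string(index=False))
```

```
 day  diameter_um  cell_count  effective_li
   0     250.0000  27954.1317        0.3578
   1     276.3678  37954.7224        0.3410
   2     304.2743  50896.5259        0.3232
   3     333.5384  67347.8880        0.3046
   4     363.9230  87863.3712           NaN
```

Day 0 starts with 2.8 × 10⁴ mural granulosa cells (the number filling the
mural volume at 250 µm). The applied LI starts at 0.795 × 0.45 = 0.358 and
shrinks as the follicle gains diameter; the follicle crosses the 350-µm
preovulatory threshold on day 4. Twelve such follicles therefore fill a
cohort of ten within four days, giving a minimum cycle length of five days
(one extra day for proestrus/ovulation):

```python
from follisim import CohortScenario, simulate_cohort

report = simulate_cohort(CohortScenario(tuple((250.0, 0.45) for _ in range(12))), seed=1)
print(report.day_target_met, report.minimum_cycle_length)   # 4  5
```

At the median rate (LI 0.37 at 250 µm) the same follicle reaches only
319 µm by day 3 — a 250-µm follicle growing at the median rate cannot make
the preovulatory size inside a 4-day cycle.

Calibrating the adjustment factor from an observed diameter sequence uses
the statsmodels-style model/results pair:

```python
from follisim.calibration import GrowthCalibrationModel

res = GrowthCalibrationModel([(0, 334.0), (1, 358.49), (2, 383.61)], li_initial=0.303).fit()
print(res.summary())
```

```
Growth adjustment-factor calibration
============================================
n observations                 3
adjustment factor         0.8009
std err (curvature)       0.0021
residual SSE (um^2)      0.03558
RMSE (um)                 0.1089
converged                   True
```

(The observations here are the model's own day-1/day-2 diameters rounded
to 0.01 µm, so the recovered factor sits within 0.006 of the generating
0.795.)

The same pipeline is scriptable from the shell: `follisim table1`,
`follisim grow`, `follisim simulate-population`, `follisim quantify-masks`,
`follisim fit-regression`, `follisim min-cycle`, `follisim calibrate`,
`follisim survivor-effect`, `follisim count-preovulatory`. Every run writes
its outputs as CSV/JSON together with a manifest recording inputs,
parameters, seed and package version.

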
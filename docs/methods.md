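# Methods

## The growth model

Antral follicle growth is driven by proliferation of the mural granulosa
layer. The model rests on three empirical relations:

* **Mural volume allometry.** V_M = a·D^b with a = 0.18 and b = 3.05
  (V_M in µm³, D in µm). The exponent slightly above 3 reflects the mural
  shell thickening, in absolute terms, as the follicle enlarges.
* **Cell packing.** One granulosa cell occupies V_G = 132.6 µm³, so the
  mural layer at diameter D holds N = V_M / V_G cells, and conversely
  D = (N·V_G / a)^(1/b). Both conversions are closed-form and exact
  inverses of each other (round-trip relative error < 1e-9 is a tested
  invariant).
* **Proliferation.** The BrdU labeling index LI measured over a 2-h pulse
  is used as the fraction of mural cells that divide over one 24-h
  iteration: N_i = N_{i−1}·(1 + LI_eff).

Iterations are synchronous 24-h steps because ovulation is gated to one
time of day — each day is one opportunity to ovulate. Fractional days are
not modelled. Cell counts stay real-valued during iteration: the recursion
is a deterministic rate equation, and rounding to integers would break its
closed-form limit (with no LI decline and unit adjustment, the n-day count
is exactly N₀·(1 + LI₀)^n, which the tests assert to 1e-9).

### The effective labeling index

Proliferation slows as follicles mature, so the day-0 labeling index is not
applied unchanged. The effective LI on the step leaving day i−1 is

    LI_eff = f · max(0, LI₀ − s·(D_{i−1} − D₀)),  clamped to [0, 1]

with s the decline of LI per µm of diameter gained (default 0.0008/µm) and
f = 0.795 the adjustment factor. At the first iteration (no diameter gain
yet) this reduces to 0.795·LI₀.

Two modelling choices deserve comment:

* The printed recursion for the correction term is self-referential in the
  cell increment and dimensionally inconsistent with the verbal definition
  of f (a slope in LI per µm times a diameter increase). We implement the
  verbal definition — decline proportional to diameter gained since day 0,
  damped by f — which is the only reading that yields exactly 0.795·LI₀ on
  the first iteration and cannot go negative.
* The decline is floored at zero before applying f: a proliferating
  fraction cannot be negative. The linear decline would otherwise cross
  zero near D₀ + LI₀/s.

The default slope/intercept pair (s = 0.0008/µm, intercept 0.57 at D = 0)
is the exact straight line through the mean proliferation-rate column of
the regenerated size table (49% at 100 µm down to 21% at 450 µm). Any
fitted `LiRegression` can override it.

### Calibration of the adjustment factor

`GrowthCalibrationModel` estimates f by matching simulated diameters to an
observed (day, mean diameter) sequence — in the source data, the mean of
the five largest follicles at successive cycle stages (334, 388, 441 µm) —
minimising the residual sum of squared diameters by bounded scalar search
on (0, 1.5]. The objective and bounds are our choices; how the original
0.795 was obtained is not documented. The standard error reported in
`summary()` comes from the curvature of the objective at the optimum and is
meaningful only when the observations carry noise. Parameter recovery from
noiseless self-generated trajectories is accurate to ±0.01 (tested for
planted factors 0.795 and 1.0). Because the spacing of the observed
stage-wise diameters in calendar days is not known (cycle stages vary in
length), calibration is demonstrated on synthetic trajectories only.

### What the model predicts

With median parameters a 250-µm follicle reaches ~319 µm after 3 iterations
— it cannot make the 350-µm preovulatory size inside the 3 growing days of
a 4-day cycle — while at LI₀ = 0.45 it crosses 350 µm on day 4. A 170-µm
follicle at the local median LI (0.434) needs 9 days to reach 350 µm under
the default adjustment (7 days if the adjustment is removed).
`days_to_diameter` is non-increasing in both LI₀ and starting diameter,
checked on a grid.

## Labeling-index quantification

Masks are single-channel integer images: 0 background, 1 BrdU⁻ granulosa,
2 BrdU⁺ granulosa, 3 antrum, 4 oocyte. The LI is the *area* fraction
A⁺/(A⁺+A⁻) inside the basal-lamina polygon minus cumulus exclusion
polygons (rasterised by pixel-centre containment); no nucleus instance
segmentation is attempted, matching a pixel-classifier workflow. The LI is
invariant to pixel size by construction.

Stereology: the cross-sectional area at the widest observed section maps to
a pseudodiameter 2·√(area/π). Ties in widest-section area break to the
lower section index (an arbitrary deterministic choice). A follicle whose
widest observed section is the first or last sampled section of the series
is excluded — its equator may lie outside the sampling volume. Stage
boundaries use [lower, upper) intervals with "preovulatory" strictly above
350 µm; 170 µm therefore belongs to the FSH-dependent stage.

## Synthetic data

The generators are pure functions of (config, seed) and exist so every
pipeline stage can be tested against known ground truth.

* **Populations.** Diameters are log-normal within each stage interval
  (log-sd 0.25 about the interval's geometric centre). The mean LI
  trajectory is piecewise linear with knots at the 130- and 170-µm stage
  boundaries: flat at 0.20 through the preantral phase, rising through the
  spurt to the 170-µm value of the decline line, then declining as
  0.57 − 0.0008·D. Between-follicle heterogeneity at fixed diameter is
  Gaussian with sd 0.06 (so ~95% of preantral true LIs stay below 0.30);
  measurement noise adds truncated-Gaussian sd 0.03.
* **Atresia.** Daily hazard = base · stage-multiplier ·
  logistic(steepness·((1 − LI percentile) − ½)), applied at and above
  170 µm. Stage multipliers 0.3 / 1.0 / 1.2 / 1.0 for estrus / metestrus /
  diestrus / proestrus. Base 0.6/day and steepness 8 are set so that a
  majority of FSH-dependent follicles become atretic over a two-day chase
  ending at diestrus, as seen in that stage's histology. The mechanism
  (percentile-logistic) is invented; only its qualitative property —
  slow-growing follicles die preferentially — is data-motivated.
* **Pulse-chase.** The 2-h design reads the instantaneous LI. The 48-h
  design grows each follicle 1–2 model days with its true injection-time
  LI, carries that LI as the label signal (label dilution over 1–2 days is
  assumed not to push it below detectability), and applies the hazard
  daily. Survivor-effect cohorts start in the 250–350 µm band, the size
  range from which preovulatory follicles plausibly arose over the chase.
* **Section stacks.** Spheres sliced at section midplanes (5-µm sections;
  75 consecutive for the 2-h design, every 25th — 125-µm spacing — for the
  48-h design), so the widest-sampled-section ground truth is analytic.
* **Masks.** A mural annulus whose thickness follows T ≈ −1.4 + 0.0975·D
  (least-squares so the spherical-shell volume matches the power-law mural
  volume within 10% over 170–450 µm; floored at 3 µm), an antrum, an
  oocyte wrapped in a BrdU-negative cumulus ring (so skipping the cumulus
  exclusion biases the LI), and exactly round(li·n) positive mural pixels
  in one contiguous angular patch. Recovery is tested to within
  1/n + 0.02.

What passing these tests shows — and does not. The generators reproduce the
phase structure, heterogeneity, selection mechanism and sampling geometry
of the study design, so they validate the *arithmetic and the rules*. They
do not contain real staining variability, section artefacts, non-spherical
follicles, or classifier error, so quantitative agreement on synthetic data
does not by itself establish accuracy on real histology.

## Cohort simulation

`simulate_cohort` grows each starting follicle independently (no hormonal
coupling between follicles — FSH/LH/inhibin feedback is out of scope),
optionally applies the atresia hazard to follicles still short of the
preovulatory size, and reports the first day the cumulative count at or
above the threshold meets the cohort target (default 10, configurable 6–12
to span observed ovulation numbers). The minimum cycle length is that day
plus one, the proestrus/ovulation day. With the hazard off the runs are
deterministic; with it on they are reproducible given the seed.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the checks
sharp but quick: 100-point grids for oracle equivalence, 200-follicle
populations for regression recovery (slope standard error ≈ 1e-4, well
inside the ±2e-4 assertion), 100 seeded replicates for the survivor-effect
sign, 100 random placements for the stereology rules. The brute-force
trajectory oracle in the tests re-codes the daily recursion independently
and must agree with `simulate_growth` to 1e-12 relative — both paths use
the same double-precision closed forms, so the tolerance covers only
ordering/rounding differences. Scalar minimisation uses
`scipy.optimize.minimize_scalar(method="bounded")` with xatol 1e-10.

## Known limitations

* The LI→daily-division-fraction identification is the source study's
  premise; the model inherits it.
* No per-cell stochastic division, antrum fluid volume, oocyte growth or
  hormone dynamics.
* The "fast" regression is fitted from data (synthetic or user-supplied);
  no canonical fast-slope constants exist.
* Calibration against real stage-wise diameters requires knowing the
  day spacing of those observations, which varies with cycle-stage length.
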
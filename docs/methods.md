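# Methods

## The model chain

The package treats a leaf's nitrogen budget as an accounting identity built
on three measurable capacities.

**FvCB photosynthesis model.** Net assimilation at intercellular CO₂
concentration Ci is A = min(Ac, Aj) − Rd, where the Rubisco-limited rate is
Ac = Vcmax (Ci − Γ\*)/(Ci + Km), Km = Kc(1 + O/Ko), and the
RuBP-regeneration-limited rate is Aj = J (Ci − Γ\*)/(4Ci + 8Γ\*).
Assumptions: measurements at 25 °C leaf temperature (inputs at other
temperatures are rejected unless explicitly allowed; no temperature
response functions are applied); saturating light, so the operating
electron transport rate J equals Jmax (the gas-exchange protocol holds
PPFD at 1000 µmol m⁻² s⁻¹ — this is flagged rather than modelled with a
light response); no triose-phosphate-utilisation limitation; no mesophyll
conductance, so Ci stands in for the chloroplastic CO₂ concentration. The
kinetic constants default to the standard tobacco-derived 25 °C values
(Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹, Γ\* = 42.75 µmol mol⁻¹,
O = 210 mmol mol⁻¹) and are overridable.

**Chlorophyll.** Extract concentrations (mg L⁻¹) come from the
two-wavelength 95%-ethanol equations (Chla = 13.95 A665 − 6.88 A649,
Chlb = 24.96 A649 − 7.32 A665); the extraction geometry (default 25 mL on
0.2 g fresh tissue) converts to mg g⁻¹, and LMA converts to the area
density Cc = chl·LMA/M in mmol m⁻². The chlorophyll molar mass M defaults
to 900 g mol⁻¹, between chlorophyll a (893.5) and b (907.5); the choice
moves Cc by under 1%, but it is explicit and configurable. Absorbance
tables may label the second wavelength 645 nm; the reader maps `a645` onto
`a649` with a logged warning because the equations above are the operative
definition. A negative computed Chla or Chlb marks an inconsistent
absorbance pair; the value is carried with a flag, never clipped.

**Nitrogen partition.** With Na the total leaf N per area (g N m⁻²):
Nresp = Rt/33.69 with Rt = 0.015·Vcmax; Ncb = Vcmax/(6.25·20.8);
Net = Jmax/(8.06·155.6); Ncl = Cc/2.15; Nstr is the measured SDS-insoluble
protein N; Npsn = Ncb + Net + Ncl; and Nstore = Na − Npsn − Nresp − Nstr is
the residual. Defining storage as the residual makes conservation exact by
construction — the invariant Σpools = Na holds for every sample, which is
why a negative residual is reported and flagged (and excluded from
regressions by default) instead of being clipped: clipping would silently
break the budget. The fitted Rd is carried as a diagnostic only; the
respiratory pool uses 0.015·Vcmax by definition. All seven conversion
constants live in one `PartitionConstants` block so sensitivity analyses
(e.g. doubling the Rubisco specific activity) are one override away.

**Statistics.** PNUE = Asat/Na. Pool-response relationships are ordinary
least squares per predictor, fitted per cultivar and pooled, with two-sided
slope tests and no multiple-testing correction across the family (a Holm
option would be a one-line addition; the default mirrors common practice in
this literature). Trait responses to the factorial are two-way ANOVAs with
type-II sums of squares — on the balanced design all types coincide.
Post-hoc letter displays use Tukey HSD at α = 0.05. The importance analysis
fits a bagged regression forest (features per split = ⌈d/3⌉, minimum leaf
5, unlimited depth, trees from scikit-learn) and measures %IncMSE per tree
on out-of-bag samples: the mean relative increase in OOB MSE when one
feature's OOB values are permuted. Significance follows the
response-permutation scheme: the forest is refit on `n_null_permutations`
response-shuffled copies, and each feature's p-value is
(1 + #{null ≥ observed})/(1 + n_perm); the model-level p-value applies the
same formula to the OOB explained variance. The +1 smoothing means the
smallest attainable p is 1/(n_perm + 1), so detecting p < 0.01 requires at
least 100 permutations (the default).

## Synthetic data generator

`generate_experiment` runs the science backwards. True pools per
cultivar × level cell define Vcmax = Ncb·6.25·20.8, Jmax = Net·8.06·155.6
and Cc = Ncl·2.15; Rd = 0.015·Vcmax; Na is the exact pool sum. Gas exchange
is the forward FvCB model on the 13-step ladder (400, 300, 200, 150, 100,
50, 400, 400, 600, 800, 1000, 1200, 1500 µmol mol⁻¹ — the protocol's
reference-chamber gradient used directly as Ci targets, since the fit
operates on Ci and stomatal behaviour is deliberately not modelled; the
repeated 400s are kept as replicate observations). Absorbances are the
exact inverse of the pigment equations at an a:b ratio of 3. The
trait-table Asat is the forward model at an operating Ci of 280 µmol mol⁻¹
(a typical value at ambient 400 with moderate stomatal opening).

Noise defaults: additive Gaussian sd 0.5 µmol m⁻² s⁻¹ on every
assimilation reading (typical IRGA precision) and multiplicative Gaussian
cv 3% on measured traits (Na, Nstr, LMA, gsw) and absorbances. These
magnitudes are conventions for instrument-grade measurements, not values
taken from any specific dataset.

Default truth profiles encode the qualitative fertilisation-response
shapes the design targets: Na monotone increasing in applied N
(≈1.4 → 2.6 g N m⁻² across N0–N4); Ncb and Net peaking at N3 and declining
at N4; Ncl steadily increasing in cultivar "JF" but peaking near N2–N3 in
"FD"; Nstr near-flat; Nstore rising convexly. The implied Jmax/Vcmax ratio
is ≈2.2–2.4 and PNUE peaks at N3.

What the generator does **not** emulate: stomatal or mesophyll conductance
(so no Ca→Ci mapping error), light-response curvature, temperature
variation, leaf-age and canopy-position structure, between-replicate
biological variance beyond the 3% measurement cv, and any correlation
structure in the noise. Passing recovery tests therefore demonstrates that
the estimation and accounting chain is correct and well calibrated under
idealised measurement error — not that field data meet these assumptions.

## Fitting procedure and numerical choices

`fit_aci` uses the partitioned-range convention: stage 1 fits (Vcmax, Rd)
by linear least squares on points with Ci ≤ 300 µmol mol⁻¹ (Rubisco
limited — the model is linear in the parameters there), stage 2 fits Jmax
on points with Ci ≥ 600 holding Rd. Stage 3 refines jointly by
limitation assignment: given an assignment of each point to the Ac or Aj
limb, the full model is linear in (Vcmax, Jmax, Rd) and solved exactly;
points are then reassigned to the limb the new parameters predict as
limiting, and the loop repeats until the assignment is stable (cap 80
iterations, best-sse iterate kept; a cycling assignment is flagged). On
noiseless model output this converges to the generating parameters at
machine precision, which is what makes the zero-noise end-to-end recovery
checks meaningful. The min() of the limbs is used as-is — no hyperbolic
co-limitation smoothing — and the reported transition Ci solves Ac = Aj in
closed form: Ci\* = (Jmax·Km − 8Γ\*·Vcmax)/(4Vcmax − Jmax) (infinite when
the limbs never cross). Degenerate cases: an assignment that empties one
limb keeps that parameter at its previous value; a negative Rd triggers a
refit with Rd fixed at 0 and a flag. Curves must have ≥6 points and cover
both Ci ≤ 300 and Ci ≥ 600; the error names the missing region. The range
boundaries (300/600) are configurable.

Determinism: every stochastic component (generator, forest, permutation
tests) draws from `numpy.random.Generator` seeded via `SeedSequence`; the
pipeline splits one root seed per stage and records it in
`run_manifest.json`. Reruns with the same seed produce byte-identical CSV
artifacts.

In the pipeline's simulate mode the synthetic "world" is always generated
with the package-default constants and kinetics; configured overrides apply
to the analysis stages only. Overriding a constant is thus a sensitivity
analysis against a fixed truth (e.g. doubling CB halves every recovered
Ncl), not a change of the simulated reality.

## Problem sizes used in validation

The test suite validates at sizes chosen to exercise the claims while
keeping a full run on one CPU comfortably short: 200 replicate curves for
the noisy-recovery distribution (median |relative error| of Vcmax and Jmax
< 2% at noise sd 0.5); a 50×50×10 brute-force parameter grid as the
optimizer's independent oracle; 1,000 randomized samples for conservation;
the full 30-sample design for end-to-end recovery (design-mean per pool
within 5% at default noise, exact to 1e-6 at zero noise); 200 pure-noise
repetitions for the false-positive-rate calibration of the permutation
test (expected fraction of p < 0.05 ≈ 0.04 with 50 permutations; accepted
band 0.02–0.09) and 50 seeded repetitions for signal detection (forest at
100 trees, the configuration floor, for the calibration runs; pipeline
default is 500 trees).

## Known limitations

- Vcmax/Jmax identifiability degrades when the true transition Ci falls
  outside the measured ladder; the per-limb point counts in the output are
  the diagnostic to watch.
- The residual storage pool absorbs every upstream error (fit error, Na
  measurement error, constant misspecification); its uncertainty is always
  the largest of the six pools.
- The partition constants are literature conversion factors for C₃ leaves;
  applying them to other systems is a modelling decision the constants
  block makes explicit but cannot justify.
- The importance p-values are exchangeability-based; with only 30 samples
  the forest's explained variance is noisy, and ranks between correlated
  pools (e.g. Ncb and Net, which co-vary by construction in the default
  truth profiles) should not be over-read.
- OLS regressions treat samples as independent, ignoring the
  replicate-within-cell structure of the factorial design.
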
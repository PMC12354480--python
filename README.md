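# leafn — leaf nitrogen economy toolkit

`leafn` is a Python library for analysing how leaves invest their nitrogen,
aimed at plant ecophysiologists working with gas exchange and pigment data
from fertilisation trials (the default design is a two-cultivar ×
five-nitrogen-level × three-replicate tea-plant experiment, but every piece
is reusable on its own). It covers the full chain from raw measurements to
the question "which nitrogen pool drives photosynthesis and nitrogen use
efficiency?":

1. **A-Ci curve fitting (FvCB model).** Net assimilation is
   A = min(Ac, Aj) − Rd with
   Ac = Vcmax (Ci − Γ\*)/(Ci + Kc(1 + O/Ko)) and
   Aj = J (Ci − Γ\*)/(4Ci + 8Γ\*), J = Jmax under saturating light.
   `fit_aci` estimates Vcmax, Jmax and Rd from a 13-step CO₂-response
   ladder by a partitioned-range fit plus joint refinement.
2. **Chlorophyll quantification.** Extract concentrations from two-wavelength
   absorbances (Chla = 13.95 A665 − 6.88 A649, Chlb = 24.96 A649 − 7.32 A665),
   scaled by extraction geometry to mg g⁻¹ and by LMA to the area density
   Cc (mmol m⁻²).
3. **Nitrogen partitioning.** Total leaf N per area (Na, g N m⁻²) splits into
   respiratory, carboxylation, electron-transport, light-capture, structural
   and storage pools:
   Nresp = 0.015·Vcmax/33.69, Ncb = Vcmax/(6.25·20.8),
   Net = Jmax/(8.06·155.6), Ncl = Cc/2.15, Nstr = SDS-insoluble protein N,
   Nstore = Na − Npsn − Nresp − Nstr (residual, so the pools conserve Na
   exactly).
4. **PNUE and statistics.** PNUE = Asat/Na; per-pool OLS regressions against
   Pn and PNUE (per cultivar and pooled); two-way ANOVA over the
   cultivar × nitrogen factorial; permutation-tested random-forest
   importance (%IncMSE with response-permutation p-values) to rank the
   pools.
5. **Synthetic experiments with known truth.** `generate_experiment` builds
   the whole dataset backwards from chosen true pools, so the complete
   pipeline can be validated end to end: a noiseless dataset round-trips to
   the exact truth.

## Worked example

Fit a noisy simulated A-Ci curve (`python examples/02_fit_aci_curve.py`):

```
true:   Vcmax=60.00  Jmax=120.00  Rd=1.00
fitted: Vcmax=62.44  Jmax=122.46  Rd=1.55
transition Ci: 516 umol mol-1 (8 Rubisco-limited points, 5 RuBP-limited)
residual sse: 0.572 (umol m-2 s-1)^2
```

With instrument noise of sd 0.5 µmol m⁻² s⁻¹ the capacities come back
within a few percent; across 200 replicate curves the median error is
below 2%. Partition a leaf's nitrogen
(`python examples/04_partition_nitrogen.py`):

```
pool         g N m-2   % of Na
n_resp        0.0289      1.4%
n_cb          0.5000     23.8%
n_et          0.1196      5.7%
n_cl          0.2884     13.7%
n_str         0.3600     17.1%
n_store       0.8031     38.2%
sum           2.1000    100.0%
```

The six pools sum to Na = 2.10 g N m⁻² exactly; about 43% of this leaf's
nitrogen sits in the photosynthetic machinery. The remaining examples cover
simulation (`01`), chlorophyll (`03`), regressions and ANOVA (`05`) and
forest importance (`06`).

The same pipeline runs from a shell:

```bash
leafn simulate --out run1 --seed 7        # synthetic data + full analysis
leafn run-all --traits t.csv --aci a.csv --absorbance b.csv --out run2
leafn validate t.csv a.csv b.csv          # schema/join report
```

Outputs are plain CSV/JSON artifacts (`params.csv`, `pigments.csv`,
`pools.csv`, `fractions.csv`, `regressions.csv`, `anova.csv`,
`importance_*.csv`, `run_manifest.json`); reruns with the same seed are
byte-identical.

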
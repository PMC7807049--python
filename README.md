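# senequant

Label-free quantification of replicative senescence in human mesenchymal
stromal cell (hMSC) cultures.

hMSC batches lose therapeutic potency as senescent cells accumulate during
serial expansion, but the standard readout — histochemical SA-β-galactosidase
staining — is destructive and operator-dependent. `senequant` implements and
benchmarks the label-free and flow-cytometric alternatives on a common
statistical footing:

* **Autofluorescence spectral unmixing.** Each background-corrected cell
  emission spectrum *I(λ)* over 400–850 nm is decomposed into four
  endogenous fluorophore components by non-negative least squares,

  *I(λ) = Σₖ aₖ·Sₖ(λ) + ε(λ)*,  *aₖ ≥ 0*,

  with *Sₖ* the unit-peak shapes of free NADH, bound NADH, FAD and
  lipopigment (lipofuscin-like pigment, the broad 450–700 nm band that
  accumulates in non-proliferating cells). The three reference-trainable
  components are fitted as Gaussian sums from pure-solution spectra; the
  lipopigment component, which has no clean reference solution, is learned
  from the unmixing residuals of known-senescent cells. Per cell, the
  pipeline tabulates each component's fitted peak value and integrated
  intensity, plus the model-free total autofluorescence ∫I(λ)dλ.
* **Flow cytometry.** Forward-scatter (FSC, cell size) and C12FDG/FL1
  (fluorogenic β-galactosidase substrate) channel means after a debris
  gate.
* **Growth curves.** Population doublings PD = log₂(harvested/seeded),
  cumulative PD, and the early/senescent passage rules (E: cPD closest to
  six; S: first passage under one doubling per week).
* **Benchmarking statistics.** Per-donor senescent/early fold differences
  and their cross-donor ranges, one-tailed Welch (unequal-variance)
  *t*-tests with star annotation, and Spearman rank correlation — exact
  permutation *p* at small *n* — of every candidate metric against the
  β-gal percentage standard.

A synthetic cohort generator reproduces the statistical structure of all
four data streams (spectral mixtures with noise and background, lognormal
flow events with debris, binomial stain counts, declining growth curves)
with a full latent-truth record, so every stage is testable end to end
without any experimental data.

## Worked example

```python
from senequant import CohortConfig, generate_cohort, run_cohort_pipeline

config = CohortConfig(rng_seed=1)        # 6 donors, 10 cells/passage, 1e5 events
bundle, truth = generate_cohort(config)  # raw data + latent truth
table, report = run_cohort_pipeline(bundle)

for metric in ("bgal_pct", "c12fdg_mean", "fsc_mean",
               "total_af_mean", "lipopigment_mean"):
    lo, hi = report.fold_ranges[metric]
    corr = report.correlations[metric]
    stars = [w.stars for w in report.welch[metric].values()]
    print(f"{metric:18s} fold range {lo:5.3f}-{hi:5.3f}   "
          f"Spearman r={corr.r:+.3f} (p={corr.p:.4f})   stars: {' '.join(stars)}")
```

prints

```
bgal_pct           fold range 5.371-7.015   Spearman r=+1.000 (p=0.0000)   stars: *** *** *** *** *** ***
c12fdg_mean        fold range 2.997-3.008   Spearman r=+0.937 (p=0.0000)   stars: *** *** *** *** *** ***
fsc_mean           fold range 1.298-1.303   Spearman r=+0.937 (p=0.0000)   stars: *** *** *** *** *** ***
total_af_mean      fold range 1.282-1.315   Spearman r=+0.853 (p=0.0004)   stars: *** *** *** *** *** ***
lipopigment_mean   fold range 1.985-2.032   Spearman r=+0.944 (p=0.0000)   stars: *** *** *** *** *** ***
```

Reading this: this cohort was generated with the lipopigment abundance
doubled, the FSC median raised 1.3-fold and β-gal positivity raised from
10% to 60% between early and senescent passages. The pipeline recovers
those shifts in every donor's fold difference (lipopigment ≈ 2, FSC ≈ 1.3),
every per-donor Welch test is significant at p ≤ 0.001 (`***`), and each
candidate metric correlates positively and significantly with the β-gal
standard across the 12 donor-passage points. `bgal_pct` correlated with
itself is the sanity row (r = 1).

The same stages are available as a CLI: `senequant simulate`,
`senequant train-library`, `senequant unmix`, `senequant flow-summarize`,
`senequant benchmark` (see `--help` on each).

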
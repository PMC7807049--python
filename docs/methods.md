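# Methods

This note documents the models implemented in `senequant`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Spectral model

Cell autofluorescence over 400–850 nm is modelled as a non-negative linear
mixture of four endogenous fluorophore components — free NADH, bound NADH,
FAD, and lipopigment — plus an imaging-solution background and additive
noise. Each component shape is a sum of one to three Gaussians in
wavelength, unit-peak normalised over the domain. A Gaussian-sum
parametrisation is smooth, strictly positive, and has few parameters;
emission bands of these fluorophores are single broad peaks (NADH, FAD)
or a broad two-lobed band (lipopigment), all well captured by one to
three terms.

Default ground-truth shapes used by the simulator (center σ in nm):

| component   | Gaussians (center, σ, rel. amplitude)       | rationale |
|-------------|---------------------------------------------|-----------|
| NADH_free   | (460, 45, 1)                                | literature emission maximum ≈ 460 nm, FWHM ≈ 105 nm |
| NADH_bound  | (440, 33, 1)                                | enzyme binding blue-shifts and narrows NADH emission |
| FAD         | (525, 38, 1)                                | emission maximum 525 nm (the 525/50 detection band) |
| lipopigment | (540, 60, 1) + (620, 70, 0.55)              | broad band spanning ≈ 450–700 nm with a red shoulder |

The NADH widths matter for conditioning: free and bound NADH are only
20 nm apart, and their distinguishability under noise rests on the bound
form being genuinely narrower. With the literature-typical widths above,
1% additive noise propagates to under 5% relative error on every
unmixing coefficient; artificially broadened NADH bands would make the
two forms nearly collinear and inflate that error severalfold.

## Preprocessing

Cell spectra are corrected by subtracting the pointwise mean of the
accompanying background measurements (five per well by design), cropped
to 400–850 nm, smoothed with a Savitzky–Golay filter (window 11 grid
points, polynomial order 3 — short enough to leave ≈ 30–70 nm-wide
emission peaks essentially unchanged), and clipped at zero, since
emission is physically non-negative. Resampling between grids is linear;
extrapolation is refused.

## Unmixing

Coefficients solve `min ‖I − Σ aₖSₖ‖₂ s.t. aₖ ≥ 0` (scipy NNLS). The
non-negativity constraint reflects physics (emission only adds) and is a
deliberate choice; an unconstrained fit can cancel collinear components
against each other. Reported per-cell metrics:

* `coefficient_k` — the loading per unit-peak shape (a.u.);
* `peak_k` — max of the fitted contribution aₖSₖ(λ);
* `integral_k` — trapezoidal integral of aₖSₖ(λ) over the full domain
  (the "sum of intensities under the peak"; integration bounds are the
  whole working range, so overlapping components are each credited with
  their full fitted emission);
* `total_af` — the integral of the corrected spectrum itself. This is
  model-free by design: it does not depend on the decomposition. For a
  noiseless exact mixture it equals the sum of component integrals.
* `r_squared` is uncentered (no-intercept convention), `residual_l2` the
  fit residual norm.

One measured spectrum is one observation; sample means/sds are taken over
measurements.

## Library training

The three reference-trainable components are fitted from pure-solution
spectra: background-correct, average, smooth, clip, then greedy
Gaussian-sum least squares (terms added at the running residual's peak,
jointly refined with bounded least squares, stopping at R² ≥ 0.9995 or
the term cap). Fit R² is stored in the component provenance. Training is
invariant to uniform intensity scaling because components are unit-peak
normalised.

**Lipopigment residual learning.** There is no clean lipopigment
reference solution, so the fourth component is learned from
known-senescent cells. A one-pass estimate — unmix each senescent
spectrum against the three trained components, average the residuals,
floor at zero, smooth — is biased: wherever the fourth band overlaps FAD
or NADH, the overlap is absorbed into those components' non-negative
coefficients, so the plain residual keeps mostly the red tail of the
band. Worse, the free-form problem is not identifiable at all: adding any
non-negative combination of the trained shapes to a candidate fourth
component leaves every fit unchanged. Identifiability is restored by the
parametric form. The learned component is constrained to be a sum of at
most three Gaussians, and its parameters are estimated by
variable-projection least squares over all senescent spectra jointly
(per-spectrum coefficients re-solved by NNLS at every trial shape),
initialised from the one-pass residual. A Gaussian sum cannot absorb the
trained components exactly, so the pooled objective is minimised at the
true shape; Gaussian terms are added one at a time and kept only while
they improve the pooled residual by more than 2%, which keeps the
component parsimonious. When the mean residual carries no signal above
0.1% of the corrected spectra's peak (the Savitzky–Golay bias floor is
orders of magnitude below this, any real band orders of magnitude above),
the procedure reports "no residual component detectable" instead of
fitting noise.

Libraries persist as versioned JSON; floats round-trip bit-exactly via
`repr`, and loading validates the schema, version and name uniqueness.

## Flow cytometry

Events carry FSC and FL1 values on a linear scale; summaries are
arithmetic channel means with sample sd, computed after a single FSC
threshold gate excluding debris. The default threshold can be derived as
the 1st FSC percentile of an unstained control, or set explicitly (the
pipeline default of 100 a.u. sits far above the simulated debris
population and below ~4 σ of the cell FSC distribution). Gating is
idempotent and never mutates its input. CSV (`FSC,FL1` header) is the
canonical event format; common acquisition column names (`FSC-A`,
`FL1-A`) are remapped automatically.

## Growth and staining

PD = log₂(harvested/seeded); cPD is the exact running sum. The early
passage is the one whose cPD is closest to six, ties broken toward the
earlier passage. Two senescence rules ship, because both circulate in
practice: fewer than one doubling per 7 days of culture (default), and
failure to double within 14 days; both are rate rules over a passage's
recorded culture days, and any callable can be substituted. β-gal
positivity is 100·positive/total per well, with a warning below the
200-cell counting floor.

## Benchmark statistics

* **Fold difference** is the senescent/early ratio of sample means per
  donor; ranges are (min, max) over donors. Reversed effects (fold < 1)
  are reported, not suppressed.
* **Welch test**: t = (m_S − m_E)/√(s²_S/n_S + s²_E/n_E) with
  Welch–Satterthwaite df (computed on variance fractions for numerical
  stability) and a one-tailed upper p — the alternative S > E is fixed a
  priori for every metric, so a reversed effect simply yields p > 0.5.
  Stars: *** p ≤ 0.001, ** p ≤ 0.01, * p ≤ 0.05 (thresholds inclusive),
  else ns. Zero variance in both groups with equal means is defined as
  t = 0, p = 0.5. Sample sd (n−1) throughout.
* **Spearman**: Pearson correlation of mid-ranks. For n ≤ 9 the p-value
  enumerates all n! rank permutations exactly (the t-approximation is
  poor there); above, the usual t approximation with df = n−2. Two-sided
  by default. Constant input is flagged as undefined rather than raised.
* **Report assembly** correlates each metric's donor-passage means
  against the β-gal percentage over all early and senescent points
  jointly (two points per donor, 12 for six donors). Donors missing an E
  or S row are excluded with a warning. No multiple-testing correction is
  applied — the benchmarking design reports each metric's evidence
  separately.

## Synthetic cohort generator

Defaults encode the study design: 6 donors; 10 cell spectra per passage
per donor with five background measurements each; 10⁵ flow events per
sample with 5% debris; three stained wells of 200 counted cells per
passage; serial passages of 7 days with the first-passage PD ≈ 3.3
declining 15% per passage (early passages reach cPD ≈ 6 around passage 2,
senescence near cPD ≈ 17–18). Early→senescent shifts: lipopigment
abundance ×2 (other fluorophores unchanged, which raises total
autofluorescence ≈ ×1.3 through the lipopigment share), FSC median ×1.3,
FL1 median ×3, β-gal positivity 10% → 60%.

Two dispersion scales shape the cohort:

* **Within-sample**: per-cell abundances are lognormal around the
  donor-passage mean with CV 5%, and spectra carry 1% (of peak) additive
  Gaussian noise — measurement-scale variability that makes ten cells
  sufficient to pin a sample mean to a few percent.
* **Between-donor**: each donor has a lognormal "senescent burden"
  factor (σ = 0.15) that jointly scales its β-gal probabilities, its
  spectral abundance baseline and (square-root damped) its flow medians
  in both passages. Donors therefore differ in overall severity — as real
  hMSC cohorts conspicuously do — while every donor's configured E→S fold
  is left untouched (the factor cancels in the ratio). This shared factor
  is also what gives the metric-vs-β-gal Spearman correlation its
  within-passage signal.

What the generator does **not** emulate: real cell-to-cell lipofuscin
heterogeneity is far larger than CV 5% (senescent cultures are mosaics of
senescent and still-dividing cells, so per-cell distributions are
bimodal and heavy-tailed); spectra have wavelength-correlated noise,
instrument spectral response and photobleaching; flow channels show
compensation spill-over and aggregates, not just low-FSC debris; β-gal
scoring has observer variance beyond binomial counting error. Passing
recovery tests therefore demonstrates correctness of the estimators under
the assumed model, not robustness to these real-data effects.

Determinism: one `numpy` Generator seeded from `rng_seed` drives the
whole bundle, and serialisation uses exact float `repr`, so identical
configs produce byte-identical datasets.

## Numerical and design choices

* NNLS (scipy's active-set implementation) is the single solver for all
  decompositions; tests cross-check it against an independent bounded
  least-squares solver.
* The unmixing grid is the measured grid cropped to the library domain;
  components are evaluated analytically on it, so no resampling error
  enters the design matrix.
* Peak locations/normalisation use a 0.1 nm evaluation grid; unit-peak
  tolerance is 1e-6.
* Degenerate inputs are errors, not silent results: empty gates, empty
  background lists, spectra not covering the working range,
  underdetermined grids, non-positive counts, early means ≤ 0 in fold
  ratios.
* The scikit-learn-style `SpectralUnmixer` transformer wraps the same
  NNLS path for matrix-shaped workflows (fit binds the grid; transform
  maps intensities to coefficients); the rest of the pipeline is plain
  functions over typed containers, which matches its multi-stage,
  non-estimator character.
* Problem sizes in the test-suite and acceptance runs (100-spectrum
  recovery batches, 10⁴ Welch null replicates, 10⁵-event flow samples,
  six-donor cohorts) were chosen so each check pins its statistic well
  inside its tolerance band.

## Limitations

* Emission shapes are stand-ins with literature-typical parameters, not
  measurements of any instrument's response; absolute units are
  arbitrary.
* The lipopigment learner assumes the residual band is expressible as at
  most three Gaussians; a strongly structured non-Gaussian band would be
  approximated, not recovered.
* Whether FL1 means should be computed on gated or all events, and the
  exact gate geometry, are acquisition-protocol decisions; a single FSC
  threshold is implemented.
* Days in the senescence rules are the recorded culture days of each
  passage; calendar gaps between passages are not modelled.
* FCS binary files are not read; events are exchanged as CSV.
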
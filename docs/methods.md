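# Methods

## Scientific setting

Skin fibroblasts from hereditary cancer syndromes (ataxia telangiectasia,
Nijmegen breakage syndrome, neurofibromatosis 1, Fanconi anemia, Bloom
syndrome, retinoblastoma, BRCA1/BRCA2 families) differ from healthy controls
in two measurable cellular features: the rate of DNA **hyper-recombination**
(mutability) and the degree of **cell-cycle checkpoint escape** after a 2 Gy
X-ray challenge (proliferation capacity). Each syndrome also carries a
literature excess relative cancer risk (ERR). The package implements the
quantitative link between the two cellular features and ERR: endpoint
formulas, mechanistic dose-response models in ERR, their fitting, a
composite predictor, and inverse prediction of ERR from measured endpoints.

## Endpoints

From raw assay records, four endpoints are computed per cell line
(replicates summarized as mean ± SEM, sample-sd convention, n−1
denominator; SEM = sd/√n):

| endpoint | definition | units |
|---|---|---|
| H | hyg⁺/neo⁺ colonies in the pTPSN plasmid assay × 100 | % |
| F | 6-thioguanine-resistant/seeded colonies × 100 | % |
| E | (ΔG2/M + ΔS) after 2 Gy, irradiated − unirradiated | % points |
| G | ΔG2/M after 2 Gy | % points |

E (and the auxiliary G1 escape, ΔG1) may be negative; H, F and G are
validated to [0, 100] and out-of-range inputs raise rather than clamp. The
grouping of E is read as (ΔG2/M) + (ΔS), without absolute values. Fewer
than 20 neo-resistant colonies triggers a warning by default and an error
under strict mode: the 20-colony floor is an experimental practice, not a
formula precondition.

## Mechanistic models

**Hyper-recombination (constrained cubic).** H grows with ERR at a basal
rate k0 opposed by a quadratic "brake" exerted by nuclear ATM monomers,
maximal at mid-range ERR:

    dH/dERR = k0 − k1·ERR·(ERRmax − ERR),  H(0) = 0.

Requiring the rate to be non-negative with equality exactly at ERRmax/2
ties the parameters: **k0 = k1·ERRmax²/4**. The solution is

    H(ERR) = (k1/3)·ERR³ − (k1·ERRmax/2)·ERR² + (k1·ERRmax²/4)·ERR.

Panel-calibrated defaults: k1 = 0.9 %/ERR³, ERRmax = 10.28, hence
k0 = 23.7776 ≈ 23.78 %/ERR (quoted elsewhere as 23.77 — a rounding
difference; the constraint is enforced exactly and k0 is never stored
independently).

**G2/M escape (logistic).** G is bounded between a floor Gmin (escape of
zero-excess-risk cells) and a ceiling Gmax and follows

    dG/dERR = c0·G·(1 − G/Gmax),  G(0) = Gmin,
    G(ERR) = Gmax / (1 + (Gmax/Gmin − 1)·e^(−c0·ERR)).

Defaults: c0 = 0.5473 /ERR, Gmax = 10.98 %, Gmin = 0.8655 %. The derived
shape factor Gmax/Gmin − 1 = 11.69 is the constant multiplying the
exponential in the sigmoid's annotated form.

**Composite predictor.** H×G in "percent" convention is the
percent×percent product divided by 100 (equivalently H as a fraction times
G in percent); the literal product is available as the "raw" scale. The
percent convention is what makes the composite commensurate with the
calibration line y = −0.3 + 0.623·ERR (the raw product reaches ≈ 587 at
ERR = 9 where the line reaches ≈ 5.3). The unit convention is a package
choice; both scales are exposed.

**Inverse prediction.** Two routes from a measured H×G to an ERR:

* *model inversion* (pipeline default): the composite is strictly
  increasing on (0, ∞), so the ERR is found by root bracketing (Brent's
  method, xtol 1e−10). On exact model values this is error-free.
* *linear calibration*: ERR = (H×G − intercept)/slope with the packaged
  line, or a line refit from lines with known reference ERR. Because the
  composite is convex near the top of the panel range, linear inversion
  carries a systematic error of up to ≈ 0.8 ERR even on noiseless data —
  the reason it is not the default. Negative predictions are clamped to 0
  with a warning (ERR is non-negative by definition).

**ODE cross-checks.** Both growth laws are also integrated numerically
(adaptive RK45, rtol = atol = 1e−9); the integrators exist purely to verify
the closed forms (max |difference| < 1e−6 over ERR 0–10 on a 0.1 grid) and
are not used in fitting or prediction.

## Fitting

* The **constrained mechanistic H fit** estimates (k1, ERRmax) by bounded
  nonlinear least squares under H(0) = 0 and the k0 constraint, started
  from an unconstrained cubic (k1 ≈ 3·c₃). It is deliberately
  *unweighted*: k1 is identified almost entirely by the high-ERR tail, and
  down-weighting those (noisier) points discards most of the information
  about it — the efficiency loss of OLS relative to GLS here is ~2%
  while estimated weights add their own variance.
* The **logistic G fit** estimates (c0, Gmax, Gmin) by nonlinear least
  squares with multi-start initialization (Gmax ← 1.05·max y,
  Gmin ← max(min y, 1e−3), c0 ← 4/range x, plus 8 deterministic jittered
  restarts; best converged start wins). The pipeline weights it by
  smoothed inverse variances: raw triplicate SEMs are too unstable to
  weight by directly, so SEM is regressed linearly on the mean and weights
  are 1/fitted² (floored at 30% of the median SEM). Weighting matters here
  because Gmin and c0 live in the low-noise, low-mean region.
* **Empirical fits** (quadratic F, cubic H/E, linear composite) are plain
  unconstrained OLS — figure-annotation style, nonzero intercepts allowed.
* Every fit reports Pearson's r between observed and fitted values;
  degenerate inputs (constant response, rank deficiency) are flagged or
  raised, not silently absorbed.
* The **correlation screen** (used for FDR, MRE11max, G1 escape vs ERR)
  is Pearson's r with the two-sided t-test, "significant" iff p < 0.05.

## Synthetic panel generator

Raw per-replicate data for the real panel are not publicly deposited, so
the generator emulates the study conditions: nine representative lines
(eight syndromes + control at ERR {0, 0.4, 1, 1.4, 2.4, 3.2, 3.6, 7, 9}),
three replicates per assay, per-replicate Gaussian noise whose sd is
anchored to the published SEM magnitudes (sd = floor + rel·mean, e.g. H:
1.6 + 0.11·mean, reproducing ±2 at the control's 3.5% and ±8 at the
highest-risk line's 56%; endpoints with no published SEM use ~8–10%
relative scales). Mean curves are the fitted models themselves: H
mechanistic cubic, G logistic, F the empirical quadratic, E the empirical
cubic, G1 targeted as pure noise about 0, FDR a weak linear trend
(21 → 61 a.u. over ERR 0 → 9) dominated by line-level scatter (sd 18 a.u.)
so its screen at n = 9 is usually not significant, MRE11max a decreasing
line (40 → 10 foci), SF2 = 0.6·e^(−0.25·ERR). The literature ERR axis can
be perturbed with 15% relative Gaussian error (truncated at 0), the
documented uncertainty of the published risk estimates.

Noise models:

* ``gaussian_sem`` (default): replicate endpoint values are drawn directly.
  Colony-count payloads must be integers, so the drawn rate is encoded
  against a 10⁶ denominator, preserving it to 1e−4 %.
* ``count_level``: physically grounded sampling — binomial colony counts
  (20 neo / 500 seeded by default) and multinomial cytometry counts
  (10⁴ cells over G1/S/G2M/other). Both models converge to the same
  endpoint means as counts grow.

Known divergences from the emulated data, accepted and documented rather
than hidden:

* the mechanistic model pins H(0) = 0 while the measured control baseline
  is 3.5 ± 2%; an optional additive baseline term reproduces the latter
  (default off);
* compositional closure (phase fractions within a condition sum to ≤ 100,
  unirradiated controls ≥ 95% G0/G1) truncates the E curve near ERR = 0
  (the empirical cubic's −4.2 would require an S fraction below zero) and
  caps the irradiated G1 fraction for high-evasion lines, so the realized
  G1-vs-ERR screen on synthetic panels is typically significant (negative)
  even though the target is pure noise. Real panels reported no such
  association; passing synthetic tests therefore says nothing about G1
  behaviour in real data.

Panels are byte-identical for a fixed config and seed (single
`numpy.random.Generator` stream, fixed draw order).

## Verification strategy and problem sizes

* Analytic identities of the calibrated parameter set (the k0 constraint
  and its inverse, the cubic's coefficient identification, the logistic
  shape factor and floor) are checked to the printed precision.
* Closed forms vs ODE integration: < 1e−6 max abs over ERR 0–10, 0.1 grid.
* Parameter recovery: 100 synthetic panels under default study conditions;
  median relative errors (k1 ≈ 9.7%, ERRmax ≈ 4.2%, c0 ≈ 5.2%,
  Gmax ≈ 4.6%, Gmin ≈ 4.4%) all below 10%, and the median predicted-vs-true
  ERR Pearson r ≈ 0.998. The run takes a few seconds; 100 panels gives a
  Monte-Carlo standard error on a median of roughly one percentage point,
  sufficient for the 10% bound.
* Correlation-screen calibration: type-I rate 5.3% over 1000 null panels
  of n = 10 at the 0.05 level.

## Limitations

* The models are calibrated on nine syndrome-level points; parameters
  beyond the panel's ERR range (0–9, vs ERRmax = 10.28) are extrapolations.
* The generator reproduces the *fitted* mean structure, not the raw
  biological scatter of the original lines; recovery results certify the
  pipeline's statistical machinery, not the biology.
* Prediction via the composite requires both the plasmid and cytometry
  assays; lines missing either are reported but not predicted.
* The ERR values themselves are literature estimates for rare diseases
  with ~15% relative uncertainty; predictions inherit that uncertainty.
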
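# Methods

This note documents the statistical models, the synthetic-data generator,
numerical conventions, and the design choices that were genuinely open.

## Data model

Intensities are log2 relative intensities in a protein × sample grid with an
explicit boolean missing mask; a non-detection is never represented by a
number (masked cells are stored as NaN so they cannot silently enter
arithmetic). Ingest follows the MaxQuant `proteinGroups` dialect: zero or
empty intensity cells become missing, rows whose identifier starts with
`REV__`/`CON__` or that carry a `+` in the `Reverse`/`Potential contaminant`
columns are dropped, and raw-scale input is log2-transformed at read time.
Either a plain `Intensity <sample>` or an LFQ column layout can be ingested
by passing the column names explicitly. Sample metadata (kidney, compartment
Glom/PT/Bulk, batch, preservation OCT/FFPE) is validated so that each kidney
contributes at most one sample per compartment per batch — the invariant the
paired analysis relies on.

## Synthetic data

Per protein *p*, kidney *k*, compartment *c*:

    x_pkc = mu_p + delta·1[c is the enriched side] + b_k + e_pkc

with `mu_p ~ N(mu0, sigma0)`, `b_k ~ N(0, sigma_kidney)`, and
`e ~ N(0, sigma_run)` independent per measurement. Planted statuses are
`null`, `enriched_glom/pt` (log2 shift `delta`), and `unique_glom/pt`
(structurally absent on the opposing side — no latent value; a `censored`
mode instead shifts the opposing side `unique_censor_depth` log2 units down,
for robustness checks). Bulk tissue is a linear-scale mixture
`log2(0.8·2^PT + 0.2·2^Glom)` plus its own run noise: mixing physical
material is additive in intensity, not in log intensity, and an absent side
simply contributes nothing. The PT-dominant weight reflects that proximal
tubule is by far the more abundant parenchymal cell type, which is also why
bulk samples resemble PT and why Glom-restricted proteins are
disproportionately lost in bulk.

Detection is Bernoulli with probability `logistic((x − lod)/tau)` followed
by MCAR dropout at `mcar_rate`. The smooth logistic (rather than a hard
threshold) avoids degenerate all-or-none missingness per protein; `tau → 0`
recovers hard censoring. All draws come from named sub-streams spawned from
a single seed in fixed order, so identical configurations give bit-identical
output and adding a downstream draw never perturbs earlier ones.

Defaults: `mu0 = 23`, `sigma0 = 1.5` (log2 scale chosen so per-protein means
land in the 21–25 range with SDs of 0.25–2 in the detected compartment),
`sigma_kidney = 0.3`, `sigma_run = 0.5`, `lod = 21`, `tau = 0.8`,
`mcar_rate = 0.02`, `delta = 1` (2-fold). Planted fractions
(0.12 Glom-enriched, 0.14 PT-enriched, 0.04/0.015 unique) emulate enriched
and unique set sizes of a few hundred and a few dozen out of ~1,500–2,000
analyzable proteins. The noise magnitudes are illustrative, not estimated
from data: real LCM data add peptide-level effects, intensity-dependent
variance, batch drift and preservation chemistry that the generator does not
model, so passing recovery tests demonstrate correctness of the statistical
machinery under the assumed model, not performance on real tissue.

Spectral counts for run-QC are negative binomial via the gamma–Poisson
mixture with per-protein mean `count_depth · 2^(x_p − mu0)` shared between
runs, so between-run differences are pure counting noise; infinite
dispersion collapses to Poisson.

## Agreement QC

For two runs, only proteins observed in both enter (zeros are
non-detections for counts); proteins observed in exactly one run are
reported as a discordance count. The reproducibility limit is
`k · SD(d)` with `k = 1.96` by default, centred at the mean difference.
Centring is a deliberate choice: the study text does not determine whether
its limits used raw or mean-centred differences, and both are computable
(`center=False` gives the raw version). `k` is configurable (`2` and `3`
reproduce the 2-SD/3-SD bands of difference-vs-mean plots).

Fisher's exact test reports the **conditional maximum-likelihood odds
ratio**, not the sample cross-product ratio: the published value 3.207089
for the 244/374 vs 76/374 table is inconsistent with the sample ratio
(3.2105) and matches the conditional estimate, which is what standard
exact-test software prints. The two-sided p sums null hypergeometric
probabilities of tables no more probable than the observed one (with the
customary 1 + 1e−7 relative slack for float ties); the exact CI inverts the
one-sided tail tests at 2.5% per tail, with a bound at 0 or ∞ when the
observed cell sits at the edge of its support. Numerics: log-space weights
via `gammaln`, normalization by log-sum-exp, monotone roots by Brent's
method on log ψ with automatic bracket expansion.

Annotation-set enrichment is the one-sided hypergeometric upper tail with
fold = observed/expected overlap; term databases are out of scope.

## Missingness

Each protein's (observed, missing) × (group) 2×2 table is tested with the
likelihood-ratio G-test, `G = 2 Σ O ln(O/E)` with `0·ln(0/E) ≡ 0` and 1 df.
**The Williams small-sample correction is on by default**: at ~10 samples
per group and realistic missingness the uncorrected G rejects at ~7.5%
instead of 5%, while the corrected test is within Monte-Carlo error of
nominal (this calibration is exercised in the test suite). A table with a
zero margin carries no information (G = 0): fully observed proteins are MAR
by definition and never-observed proteins are `indeterminate`. Because the
per-protein test is a flagging device rather than an inference, no
multiple-testing correction is applied to it; a dataset-level pooled G is
also reported since compartment-wide censoring is better detected globally.

The two-step filter composes as: step 1 (observed in ≥ `min_frac` of all
samples, boundary inclusive, default 50%) *removes*; step 2 (G-test)
*flags* MNAR proteins but keeps them — the semi-conservative reading in
which the observation-rate filter is the only hard exclusion. The filter is
idempotent. No imputation is performed anywhere.

## Paired enrichment

Pairs are formed within kidney and batch; a protein enters the paired
t-test only with complete pairs (both compartments detected) and needs
`min_pairs = 3` of them, else it is `untested`. The log2 fold change is the
difference of complete-case compartment means. Degenerate zero-spread
differences get the convention p = 0 (nonzero common difference) or p = 1,
and are flagged. BH adjustment is applied once across all tested proteins
of the comparison. Calls: `enriched_*` requires `q ≤ 0.1` **and** a
strictly >2-fold change; `unique_*` requires detection in ≥ `min_detect`
(default all) of one compartment's samples and zero detections in the
other, and takes precedence over the t-test call. Note that planting a true
fold change exactly at the strict threshold makes call-based sensitivity
top out near 50% however small the noise — the estimated fold is symmetric
about the boundary — so recovery studies should plant effects clear of the
gate. No variance moderation is used (plain t-test by design).

Unique proteins are summarized as mean ± sample SD of log2 relative
intensity over the detected compartment's observed samples (SD reported as
NA for a single observation), to 2 decimals. Abundance values around 21–25
with sub-unit SDs are means of log2 relative intensity, not finite fold
changes — a unique protein has no finite fold.

## Cross-batch validation

Per-batch compartment means (observed samples only, pairwise protein
dropping) are compared by Pearson correlation and OLS of batch 2 on batch 1;
the regression direction is fixed for display while r is symmetric.
Pointwise 95% prediction intervals use
`ŷ ± t_{n−2,0.975}·s·√(1 + 1/n + (x−x̄)²/Sxx)`; simultaneous bands are not
implemented. On correctly specified Gaussian simulations the empirical
holdout coverage is 0.95 within Monte-Carlo error; the interval width is
minimal at `x̄` and grows with `|x − x̄|`.

## Problem sizes and determinism

The automated checks run at 2,000–3,000 proteins, 6–9 kidneys, and 10–50
Monte-Carlo replicates — sizes at which binomial/Monte-Carlo standard
errors are small enough for the asserted tolerances while the full suite
stays fast. All simulations are seeded; the acceptance script derives all
of its sub-stream seeds from the single `--seed` argument.

## Known limitations

- The generator omits peptide-level structure, intensity-dependent variance,
  chromatographic drift and preservation chemistry; its noise levels are
  plausible rather than estimated.
- The G-test flags only group-dependent missingness; MNAR censoring that is
  identical in both compartments is invisible to it by construction (the
  pooled test helps only when censoring differs globally between groups).
- Exact-test CIs are conservative (exact inversion over-covers at small
  counts).
- `min_detect = 1.0` makes unique calls fragile to a single censored
  detection on the present side; relaxing it trades specificity for
  robustness.
- Published dataset-dependent values (specific limits, correlations and set
  sizes) require the deposited raw data; the package validates the
  machinery by planted-truth recovery and calibration instead.
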
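# Methods

## Model and procedure

The package analyses beta-value matrices (probes × subjects, values in
[0, 1], missing allowed) from MZ-twin cohorts. The pipeline is:

1. **Validity filter.** A site is retained when at least a fraction
   `min_valid_fraction` (default 0.5) of the cohort's subjects have a
   present value. The default corresponds to requiring half of the
   subjects measured, the usual reliability threshold for 450K-style
   matrices. The filter runs before any pair arithmetic.
2. **Age split.** Pairs are split at `age_cutoff` (years, or `"median"`,
   the default). A pair whose age equals the cutoff is elderly. MZ twins
   share one age; if per-subject ages are supplied and disagree the mean
   is used with a warning. A split that empties either group is an error.
3. **Within-pair differences.** At each site, d = beta(subject_a) −
   beta(subject_b) in pair-table order, per group; pairs with a missing
   member are dropped at that site (an all-missing site yields an empty,
   flagged set).
4. **EFI.** The ratio of the elderly-group spread to the young-group
   spread of those differences. Spread is the sample SD (n−1 denominator)
   by default. EFI is undefined — flagged, not infinite — when the young
   spread is zero or either group has fewer than two valid pairs.
5. **Testing.** Per site, Levene's test on the two difference sets:
   absolute deviations from the group center (median by default, the
   Brown–Forsythe variant; the median is also the default centering of the
   scientific-Python implementation this test is cross-checked against),
   one-way ANOVA F on 1 and n1+n2−2 degrees of freedom. If every deviation
   is zero in both groups the statistic is 0/0 and p = 1 by convention.
6. **Multiplicity.** Storey q-values over the tested family only:
   undefined-EFI sites are excluded *before* q-value computation, so m
   counts tested sites. pi0 is estimated on the lambda grid 0, 0.05, …,
   0.90 with a cubic least-squares smoother evaluated at the largest
   lambda and clipped to (0, 1]; pi0 may also be fixed (pi0 = 1 reduces
   the procedure to Benjamini–Hochberg exactly). q-values are the usual
   running minimum of pi0·m·p_(j)/j, capped at 1.
7. **Classification.** q < alpha (default 0.01) with EFI > 1 is
   elderly-significant; with EFI < 1 young-significant; EFI exactly 1
   cannot be significant by construction (identical spreads give p ≈ 1).
   Undefined-EFI sites are reported as excluded.

Downstream, "significant" means either class, and a gene is a *hit* when
at least one significant site maps to it. A probe annotated to several
genes counts toward all of them (the conservative reading when per-gene
site counts are aggregated; configurable by supplying a filtered
annotation). The elite-gene coincidence test is a two-sided Fisher exact
test (sum of tables no more probable than the observed one); the reported
odds ratio is the sample cross-product ratio ad/bc, which reproduces
published worked values exactly, with the conditional-MLE estimator
available as an option. Marker panels use the exact upper-tail binomial
probability P(X ≥ hits) at a user-supplied background hit probability
(the package can also estimate that rate empirically by seeded random
probe draws). The CpG-feature table reports, per island/shore/shelf
category, significant/total counts, the within-feature percentage, and
the percentage of all tabulated probes.

## Difference-sign convention

The within-pair difference needs an ordering of the twins. The package
canonicalizes the pair-table order (subject_a − subject_b) and keeps the
signed differences, matching the index's plain definition; the sample SD
is then not invariant to flipping the sign of a *single* pair (it is
invariant to flipping all). `difference_mode = "rms"`
(sqrt(mean(d²))) is provided as a sign-invariant alternative. Signed mode
is the default; the two agree closely whenever the mean difference is
near zero, which holds for within-MZ-pair differences.

## Synthetic cohorts

The generator emulates the structure the EFI targets, in beta space:

* per site, a baseline drawn from a bimodal Beta mixture
  (Beta(1.5, 8) / Beta(8, 1.5), equal weights) — most 450K probes sit
  near 0 or 1;
* per pair, a shared offset around the baseline (SD `sigma_pair` = 0.03),
  standing in for between-pair biological and batch variation;
* a within-pair difference d ~ Normal(0, σ), with σ = `sigma_young`
  (default 0.02 beta units, a typical MZ discordance scale) at null sites
  and for young pairs, and σ = `true_ratio`·`sigma_young` at affected
  sites for pairs at or above the generative age cutoff — so the
  population EFI of an affected site equals `true_ratio`;
* twins receive baseline ± d/2; values are clipped to [0, 1] (clip events
  counted, sites with > 50% clipped values warned about, and an unclipped
  diagnostic mode exists for calibration checks); entries go missing
  independently at `missing_rate` (default 0.02).

Defaults are fixed at one set of study-like conditions: 245 pairs, ages
uniform on [20, 86] years (median 53, quartiles near 36 and 70, matching
the adult-cohort geometry the method is designed for; an explicit age
list can replay any distribution), 5% affected sites, true ratio 2,
female fraction 178/245. The generative cutoff defaults to the analysis
cutoff but can be set independently for misspecification experiments.

What the generator does **not** emulate: probe-level measurement-error
heterogeneity, genetic (between-pair) covariance structure, batch and
cell-composition effects, and any dependence between sites. Passing tests
therefore demonstrate the estimator's statistical behaviour under the
stated generative model, not robustness to those real-data features.

## Numerical choices

* Matrix-scale Levene and EFI computations are vectorised numpy
  reductions (NaN-aware, float64 accumulation over float32 storage);
  row-wise medians use a single sort with NaNs ordered last. A 481,190 ×
  490 synthetic run completes in minutes on one CPU; test-suite and
  acceptance-script simulations use 2,000–20,000 sites, which already
  give stable operating characteristics.
* Scalar and matrix Levene paths share one implementation and agree with
  an independent brute-force deviation-ANOVA and with the ecosystem
  reference to ~1e-12.
* pi0 smoothing uses a cubic polynomial least-squares fit over the
  19-point lambda grid (with < 4 grid points the raw estimate at the
  largest lambda is used). On pure-null p-vectors of m ≥ 10,000 the
  estimate sits in [0.8, 1].
* Ties in site ranking break by ascending q then probe id; gene ranking
  ties break by symbol — all orderings deterministic.
* Degenerate inputs: empty difference sets are flagged, never raised
  mid-pipeline; zero-margin 2×2 tables report p = 1 with an undefined
  odds-ratio flag; zero-site CpG features report 0 with a
  zero-denominator flag.

## Known limitations

* The two-group contrast discards within-group age information;
  continuous-age variance modelling is out of scope by design.
* Clipping at the beta boundaries compresses spread at sites with
  baselines near 0 or 1, attenuating the EFI there; the clip-rate
  warnings flag the affected sites and the unclipped mode quantifies the
  effect.
* Of the two published odds ratios in the elite-gene worked example, the
  top-genes value (7.12) is reproduced exactly by the cross-product ratio
  on the printed counts, but the top-sites value (0.86) is not derivable
  from any printed 2×2 of those counts (2/7 vs 19/77 gives ≈ 1.22); the
  package reports the cross-product value computed from the counts.
* The elite-gene background is a single random draw of probes, as in the
  published design; its sampling noise propagates into the Fisher test.
  Repeated draws (`estimate_background_hit_rate`) give a tighter
  empirical background for the binomial tests.
* Published full-cohort quantities that depend on the private study data
  (significant-site counts, median EFI of the real cohort, clock-panel
  summaries) are not reproducible here; the package instead validates
  the worked examples whose inputs are fully printed, plus the
  pipeline's operating characteristics on synthetic cohorts.
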
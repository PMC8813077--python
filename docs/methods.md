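# Methods

This note records the statistical models implemented in `twinewas`, the
defaults and why they were chosen, what the synthetic cohort generator
does and does not emulate, and the numerical conventions.

## Study design assumed

Three groups of monozygotic twin pairs: discordant (exactly one twin
exposed), concordant-unexposed, concordant-exposed — by default 62/28/28
pairs. Every individual contributes buccal methylation at ages 5, 10 and
18 and whole blood at 18 (944 samples at the default design). β values are
analyzed untransformed; effects are on the β scale and quoted ×100 as %.
Missing β values propagate as missing and each per-CpG model is fit
complete-case for that probe only.

## Unpaired cluster-robust regression

OLS per CpG with a CR1 cluster sandwich (clusters = twin families, scale
G/(G−1)·(N−1)/(N−k)) and a t(G−1) reference. CR1 with G−1 degrees of
freedom is the common conservative default when the estimator flavour is
otherwise unspecified; tests verify exact agreement with an independent
brute-force sandwich and with statsmodels' clustered covariance
(`use_correction=True, use_t=True`).

Longitudinal model: age categorical with 5 as reference, two interaction
terms, headline quantity = the (exposed×age18 − exposed×age10) contrast,
i.e. the exposure-associated difference in 10→18 change. The exposed×age10
coefficient (5→10 childhood contrast) is reported as
`effect_childhood`/`p_childhood`. The interaction-contrast reading of the
reported ∆β is a design choice — an adjusted age-18 mean difference is the
main alternative — and is what the "difference in change during
adolescence" interpretation requires.

Degenerate probes (constant β, rank-deficient design, zero contrast SE)
are flagged `degenerate` with missing p rather than dropped. Covariate
columns with zero variance in the model subset (single-sex stratum,
all-zero pack-years, constant cell proportion) are dropped with a logged
warning. Multiple testing uses the fixed 5e-05 (suggestive) and 9e-08
(EPIC experiment-wide) flags only; no FDR column.

## Paired discordant-twin analysis

Unadjusted by design: within-pair differencing removes genotype and all
pair-shared covariates, and the analysis deliberately does not model
individual-level covariates. Differences are exposed − unexposed within
each discordant pair; the paired t statistic is mean/(sd/√n) on n−1 df.
If every difference is identical the test is flagged: p = 1 when the
common value is 0 (no signal), missing otherwise.

Ranking: rank_p ascending in p, rank_mag descending in |∆β| (average rank
for ties), rank_sum = rank_p + rank_mag; the final order breaks rank_sum
ties by smaller p, then probe id, so the output is a deterministic
permutation of 1..P.

Specificity: concordant pairs carry no exposure contrast, so their
within-pair difference is |twin A − twin B| with A/B fixed by sorted
individual id (order-invariant by construction). For comparability the
discordant differences enter the ANOVA as absolute values too — mixing
signed and unsigned quantities in one ANOVA would be incoherent. Post-hoc
comparisons are pooled-variance two-sample t-tests, unadjusted, with a
Bonferroni column for transparency.

## DMR calling

1. **ACF**: Pearson correlation of z = Φ⁻¹(1−p) over all same-chromosome
   probe pairs, binned by distance (default 50 bp bins to 500 bp; explicit
   edges supported). Negative bin estimates are retained in the table but
   floored at 0 when used in combination — at these pair counts they are
   sampling noise, and negative correlations would deflate the combined
   variance.
2. **Smoothing**: each probe's p is replaced by the Stouffer–Liptak
   combination of all probes within ±500 bp, z_comb = Σz/√(Σᵢⱼ corrᵢⱼ),
   with correlations from the ACF by pair distance. The smoothing window
   equals the chaining distance (one parameter governs both).
3. **Peak finding**: seeds at smoothed p < 1e-4, bidirectional extension
   over probes with smoothed p < 0.05 while gaps stay ≤500 bp, minimum 3
   probes. The extension threshold is a second, looser threshold in the
   comb-p style; only the seed threshold is externally prescribed.
4. **Scoring**: region p = Stouffer–Liptak over the members' *original*
   p-values with ACF correlations; Šidák correction with
   n_eff = max(1, covered bp / region bp), where covered bp sums
   (max − min + 1) positions per chromosome over tested probes. Evaluated
   via log1p/expm1 so tiny p survive. p_sidak ≥ p_region always.

## Synthetic cohort generator

Methylation is built on the logit scale as

    baseline(probe) + pair effect + individual effect + age drift
    + sex/smoking/cell covariate terms + exposure effect + noise,

then inverse-logit transformed and clipped to (0,1). Probe baselines come
from a two-component logit-normal mixture (±2.2 ± 0.7), reproducing the
bimodal marginal distribution of array β values. The pair/individual
split of both the biological level and the age drift is governed by
`pair_icc` (default 0.7): as pair_icc→1 with zero noise, co-twin
trajectories become identical. Spatial structure decays with genomic
distance, corr = `acf_rho`^(gap/`probe_spacing_bp`) (defaults 0.3, 150 bp),
applied to the pair, individual, drift and noise fields, giving the DMR
stage a realistic autocorrelation signal. Smoking pack-years are
zero-inflated gamma (25% smokers), constant across an individual's
samples; cell proportions are Beta-distributed epithelial content for
buccal and Dirichlet leukocyte fractions for blood, redrawn per sample.

Planted effects are specified as a β-scale target at reference β = 0.5
and converted per probe by the local logistic derivative,
Δlogit = δ/(β₀(1−β₀)); effect probes receive intermediate baselines
(logit ~ N(0, 0.4)) so the realized β-scale effect is close to the target
everywhere. The longitudinal effect is added to exposed twins' buccal
age-18 values only (so it appears in the 10→18 change); the
cross-sectional effect is added to exposed twins' blood age-18 values.
The truth table stores the *exactly* realized per-probe effect — the mean
exposed-twin difference between the matrices generated with and without
the planted shift — which is what recovery tests compare against (the
logistic transform makes the realized effect a few % smaller than the
target).

Default variance components (logit units: subject 0.5, drift 0.12/interval,
noise 0.10) were chosen to give plausible β-scale dispersion (≈0.02–0.13
depending on baseline) and useful test power at the design's sample sizes;
no published variance-component estimates were available to calibrate
against, so they are stated choices, not fitted quantities.

**What the generator does not emulate**: DZ twins, batch/chip effects,
probe chemistry differences, cross-reactive probes, age-varying cell-type
reference panels, and real LD-like methylation correlation structure.
Passing tests therefore demonstrate correctness of the statistics under
the stated generative model, not robustness to array artefacts.

## Calibration checks and the exchangeability null

Null-calibration tests simulate an effect-free cohort with covariate
effect scales set to 0 and independent probes. The distinction matters
for the paired arm: it is unadjusted, so within-pair differences in cell
composition or smoking are *signal* to it, not noise — with the default
covariate scales the paired p-values show λ ≈ 1.4 even with no exposure
effect anywhere. That reflects the design's sensitivity to within-pair
covariate differences (a known property of unadjusted discordant-twin
analyses), not a defect of the t statistic, so calibration is assessed
under the exchangeability null where the test's assumptions hold. The
covariate-adjusted unpaired arms are calibrated in either regime.

Because a median-based λ from 2000 probes has sampling SD ≈0.05, the λ
band check pools the p-values of the three arms (6000 values); per-arm λ
is still computed and logged.

## Problem sizes used in the checks

Null calibration runs the full 118-pair design at 2000 probes; planted
effect recovery uses 1000 probes with 100 planted; DMR operating
characteristics use 100 planted and 100 null replicates of a 500-probe,
80 bp-spacing genome with 25 pairs and a 5-probe planted cluster at 0.13 β
(strong enough for per-probe power ≈0.99 at the seed threshold, the regime
in which region recovery is the question rather than single-probe power).
Small genomes are deliberately avoided for the DMR checks: with only a
few hundred probes, a strong planted cluster inflates the ACF estimate
itself and weakens the smoothing — an artefact of tiny genomes, not of
the method.

## Known limitations

- The β-scale linear model on bounded data is the field's convention and
  the one implemented; no M-value option in this version.
- The DMR Šidák accounting (covered bp summed per chromosome) is one of
  several definitions in circulation; it is fixed and documented here.
- `estimate_acf` is quadratic in local probe density within 500 bp;
  fine up to ~10⁵ probes per chromosome at array-like spacing.
- The paired analysis offers no covariate adjustment by design; users
  needing it should use the unpaired arm.
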
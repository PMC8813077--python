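"""Cross-tissue concordance of exposure effect sizes.

Runs the unpaired cross-sectional EWAS separately in age-18 blood and
age-18 buccal samples from the same individuals, then (a) correlates the
effect sizes of the top-100 blood probes with the same probes in buccal
and (b) tests sign agreement of the suggestive probes with an exact
binomial test.
"""

from twinewas import (
    ModelSpec, SimConfig, directional_consistency_test, effect_correlation,
    run_unpaired_ewas, simulate_cohort,
)

cfg = SimConfig(
    n_probes=1500, effect_probes=tuple(range(0, 1500, 15)),
    effect_delta=0.05, xsec_effect_delta=0.05, seed=1,
)
r = simulate_cohort(cfg)

blood = run_unpaired_ewas(r.matrices["blood_18"], r.sheet,
                          ModelSpec("cross_sectional", tissue="blood"))
buccal = run_unpaired_ewas(r.matrices["buccal_18"], r.sheet,
                           ModelSpec("cross_sectional", tissue="buccal"))

corr = effect_correlation(blood, buccal, top_k=100)
print("top-100 blood probes vs buccal: r = %.3f (p = %.2g, n = %d)"
      % (corr.r, corr.p, corr.n))

cons = directional_consistency_test(blood, buccal, selection_p_threshold=5e-05)
print("directional consistency: %d of %d same sign (one-sided binomial p = %.3g)"
      % (cons.n_concordant, cons.n_common, cons.p_one_sided))
# A positive r says exposure shifts methylation the same way in both
# peripheral tissues; the binomial test asks the same question using only
# the sign of each effect.
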
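"""Two-sample MR with and without horizontal pleiotropy.

Runs all five summary-statistic estimators on (a) a clean dataset with
causal log-OR 0.25 per g/L, (b) directional pleiotropy with a null
causal effect — where IVW is badly biased but the Egger intercept
recovers the mean direct effect — and (c) two planted outlier variants
that MR-PRESSO detects and removes.
"""

from fibromr import (
    SimConfig,
    harmonize,
    ivw,
    mr_egger,
    mr_presso,
    simulate_summary_stats,
    split_summary_tables,
    weighted_mbe,
    weighted_median,
)
from fibromr.synthetic_data import outlier_variant_ids


def report(pairs, seed=0):
    for fit in (
        ivw(pairs),
        mr_egger(pairs),
        weighted_median(pairs, seed=seed),
        weighted_mbe(pairs, phi=1.0, seed=seed),
        mr_presso(pairs, seed=seed),
    ):
        lo, hi = fit.or_ci
        extra = ""
        if fit.egger_intercept is not None:
            extra = f", intercept {fit.egger_intercept:+.4f} (P {fit.egger_intercept_p:.2f})"
        if fit.presso_outlier_ids:
            extra = f", outliers removed: {fit.presso_outlier_ids}"
        print(f"  {fit.method:16s} OR {fit.odds_ratio:.3f} (95% CI {lo:.3f}-{hi:.3f}){extra}")


print("clean instruments, true OR exp(0.25) = 1.284 per 1 g/L:")
clean = SimConfig(causal_effect=0.25, seed=5)
# exercise allele harmonization on the way in: every 3rd outcome row is
# reported on the opposite allele and must be flipped back
exposure, outcome = split_summary_tables(simulate_summary_stats(clean), swap_every=3)
report(harmonize(exposure, outcome))

print("\ndirectional pleiotropy (mean direct effect +0.05), true OR 1.0:")
directional = SimConfig(causal_effect=0.0, pleiotropy_mode="directional", seed=5)
report(simulate_summary_stats(directional))
print("  -> IVW is pushed far from the null; the Egger slope stays near it")

print("\ntwo planted outlier variants, true OR 1.284:")
outliers = SimConfig(causal_effect=0.25, pleiotropy_mode="outliers", seed=5)
print(f"  planted: {outlier_variant_ids(outliers)}")
report(simulate_summary_stats(outliers))
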
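"""When does quantile normalization help, and when does it hurt?

Simulates intensity matrices censored by (a) sample-dependent and
(b) batch-dependent detection limits, reports the mean-vs-%missing
correlation across samples, and compares the 90th-percentile sample bias
before and after quantile normalization.  The correlation's sign predicts
the verdict: positive -> normalization amplifies bias; negative ->
normalization removes it.
"""

from omicschar import SimulationSpec, evaluate_normalization

for mode in ("sample", "batch"):
    spec = SimulationSpec.default(mode, seed=1)
    result = evaluate_normalization(spec)
    verdict = "recommended" if result.recommend_normalization else "NOT recommended"
    print(f"{mode}-dependent detection limits "
          f"(sample_bias_sd={spec.sample_bias_sd}, limit_sd={spec.limit_sd}):")
    print(f"  Corr(mean vs %NA) across samples: {result.corr_mean_na_samples:+.3f}")
    print(f"  sample bias before normalization: {result.bias_before:.3f}")
    print(f"  sample bias after  normalization: {result.bias_after:.3f}")
    print(f"  quantile normalization is {verdict}\n")

print(
    "Sample-dependent limits censor each sample at a different intensity: "
    "the surviving values are already correct, and forcing a common "
    "distribution distorts them (bias goes up). Batch-dependent limits "
    "combined with real sample shifts leave a shared threshold but shifted "
    "distributions: normalization removes the shifts (bias goes down)."
)
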
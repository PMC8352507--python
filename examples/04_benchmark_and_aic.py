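"""Selector benchmarking and the stepwise-AIC ordering curve.

Compares feature sets by repeated stratified threefold cross-validation
(MCC and accuracy, identical folds for every set and classifier family),
then shows that introducing features into a logistic model in an
informative-first order minimizes the AIC at a smaller model size than a
noise-first order.
"""

from rfpt import (
    CVProtocol,
    SynthSpec,
    compare_selectors,
    generate_dataset,
    stepwise_aic_curve,
)

data, _ = generate_dataset(
    SynthSpec(n_samples=80, n_features=10, n_separable=0, n_monotone_weak=2,
              delta_weak=2.0, seed=13)
)

protocol = CVProtocol(folds=3, repeats=20, seed=13)
report = compare_selectors(
    data,
    {"informative": ["f0", "f1"], "noise": ["f5", "f6"]},
    protocol,
)
print("repeated-CV comparison (mean +/- sd over 60 fold evaluations):")
print(report[["feature_set", "classifier", "mcc", "ca"]].to_string(index=False))

info_first = ["f0", "f1", "f5", "f6"]
noise_first = ["f5", "f6", "f0", "f1"]
a = stepwise_aic_curve(data, info_first, 4)
b = stepwise_aic_curve(data, noise_first, 4)
print("\nAIC by number of features entered (k=0 is the intercept-only model):")
print("  informative-first:", [f"{v:.1f}" for v in a["aic"]])
print("  noise-first:      ", [f"{v:.1f}" for v in b["aic"]])
print(f"minimum AIC at k={int(a['aic'].idxmin())} (informative-first) "
      f"vs k={int(b['aic'].idxmin())} (noise-first)")

# Informative features drop the AIC immediately; noise features cost ~2 AIC
# each, so the informative-first curve bottoms out earlier and lower.
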
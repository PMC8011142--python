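"""Train the classifiers and score them under stratified 10-fold CV.

200 bouts per behaviour from the back-mounted bird preset, simplified
5-feature set; for each method we report the mean overall accuracy with
its 95% confidence interval over folds and the per-behaviour F1 scores.
"""

import ethoclass as ec

config, specs = ec.preset("stork")
bouts = ec.generate_labelled_bouts(specs, 200, config.bout_len_records,
                                   config.fs, seed=1)
table = ec.feature_table(bouts, "simplified", "back")
X = table.drop(columns=["bout_id", "label"])
y = table["label"].to_numpy(dtype=object)

for method in ("lda", "dt", "svm", "rf", "ann", "xgboost"):
    hp = ec.default_hyperparams(method, "simplified")
    report = ec.cross_validate(method, X, y, hp, k=10, seed=1)
    lo, hi = report.ci_accuracy
    f1 = ", ".join(f"{lbl}={v:.2f}" for lbl, v in report.mean_f1.items())
    print(f"{method:>8}: accuracy {report.mean_accuracy:.3f} "
          f"(95% CI {lo:.3f}-{hi:.3f})  F1: {f1}")
# Every bout is validated exactly once across the 10 folds; the held-out
# fold never enters training (feature scaling is fitted per training split).
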